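"""Chromosome-level dosage statistics.

X:autosome expression ratios with bootstrapped autosomal backgrounds,
same-active-allele fold changes across XCI states (the direct, allelic
measurement of X-upregulation), the elastic-tuning linear model of
allelic dosage against the cell's maternal X-fraction, escapee and
X-Y-homolog dosage tests, female:male ratios, and percentile-bootstrap
group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .data import AllelicCountMatrix
from .allelic import cell_dosage, filter_expressed, DEFAULT_TRIM

DEFAULT_MIN_GENES = 20
DEFAULT_N_BOOT = 1000
DEFAULT_CI_LEVEL = 0.95


# ---------------------------------------------------------------------------
# group summaries (percentile bootstrap)
# ---------------------------------------------------------------------------

def percentile_bootstrap_ci(values: np.ndarray, statistic=np.median,
                            n_boot: int = DEFAULT_N_BOOT,
                            level: float = DEFAULT_CI_LEVEL,
                            seed: int | None = 0) -> tuple[float, float, float]:
    """Point estimate and percentile-bootstrap CI of a statistic.

    Returns ``(point, lower, upper)``. The interval is the empirical
    (alpha/2, 1 - alpha/2) percentile of ``n_boot`` resampled statistics.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("empty input")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = statistic(values[idx], axis=1)
    alpha = 1.0 - level
    lower, upper = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(statistic(values)), float(lower), float(upper)


def group_summary(values: np.ndarray, n_boot: int = DEFAULT_N_BOOT,
                  level: float = DEFAULT_CI_LEVEL, seed: int | None = 0,
                  statistic=np.median) -> dict:
    """Median (default) with percentile-bootstrap CI, as used for all
    "median ± 95% CI" summaries."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        raise ValueError(f"need >= 3 values, got {values.size}")
    point, lo, hi = percentile_bootstrap_ci(values, statistic, n_boot, level, seed)
    return {"point": point, "ci_lower": lo, "ci_upper": hi,
            "n": int(values.size), "level": level, "n_boot": n_boot}


# ---------------------------------------------------------------------------
# X:A ratios
# ---------------------------------------------------------------------------

def _trimmed_mean(a, axis=None):
    return stats.trim_mean(a, DEFAULT_TRIM, axis=axis)


#: "median" is the convention for deep expression data; "mean" suits
#: binary-like accessibility scores; "trimmed_mean" (20% per tail) is the
#: robust choice for sparse allelic UMI layers, where per-cell medians
#: degenerate to small integers or zero.
_AGGREGATORS = {"median": np.nanmedian, "mean": np.nanmean,
                "trimmed_mean": _trimmed_mean}


def xa_ratio(expr: np.ndarray, acm: AllelicCountMatrix,
             aggregation: str = "median", exclude_escapees: bool = True,
             expression_rule: str = "tpm_gt_one",
             min_genes: int = DEFAULT_MIN_GENES,
             numerator_scope: str = "X") -> np.ndarray:
    """Per-cell chromosome:autosome expression ratio on one layer.

    ``aggregation="median"`` is the RNA convention; ``"mean"`` serves
    binary-like accessibility scores. Escapees are excluded from the X
    scope by default; expressed genes are selected over all cells by the
    given rule.
    """
    try:
        agg = _AGGREGATORS[aggregation]
    except KeyError:
        raise ValueError(f"unknown aggregation {aggregation!r}") from None
    expr = np.asarray(expr, dtype=float)
    num_mask = acm.gene_mask(numerator_scope, exclude_escapees=exclude_escapees)
    auto_mask = acm.gene_mask("autosomal")
    expressed = filter_expressed(expr, expression_rule)
    num_mask = num_mask & expressed
    auto_mask = auto_mask & expressed
    if num_mask.sum() < min_genes or auto_mask.sum() < min_genes:
        raise ValueError(
            f"need >= {min_genes} expressed genes on each side, got "
            f"{int(num_mask.sum())} {numerator_scope} and {int(auto_mask.sum())} autosomal")
    with np.errstate(invalid="ignore", divide="ignore"):
        num = agg(expr[num_mask, :], axis=0)
        den = agg(expr[auto_mask, :], axis=0)
        out = np.where(den > 0, num / den, np.nan)
    return out


def bootstrap_xa_ratio(expr: np.ndarray, acm: AllelicCountMatrix, cell: int | str,
                       n_boot: int = DEFAULT_N_BOOT, aggregation: str = "median",
                       exclude_escapees: bool = True,
                       expression_rule: str = "tpm_gt_one",
                       seed: int | None = 0) -> dict:
    """Autosomal-background calibration of one cell's X:A ratio.

    Draws ``n_boot`` random autosomal gene sets of the same size as the X
    set and computes their ratio to the full autosomal aggregate; reports
    the background distribution summary and the empirical quantile of the
    observed X ratio within it.
    """
    if isinstance(cell, str):
        cell = acm.cell_ids.get_loc(cell)
    agg = _AGGREGATORS[aggregation]
    expr = np.asarray(expr, dtype=float)
    expressed = filter_expressed(expr, expression_rule)
    x_mask = acm.gene_mask("X", exclude_escapees=exclude_escapees) & expressed
    auto_mask = acm.gene_mask("autosomal") & expressed
    n_x, n_auto = int(x_mask.sum()), int(auto_mask.sum())
    if n_auto < n_x:
        raise ValueError(f"insufficient autosomal genes ({n_auto}) for X set of {n_x}")
    vals_auto = expr[auto_mask, cell]
    vals_x = expr[x_mask, cell]
    den = agg(vals_auto)
    if not den > 0:
        return {"observed": np.nan, "background": np.full(n_boot, np.nan),
                "quantile": np.nan, "background_median": np.nan,
                "background_q025": np.nan, "background_q975": np.nan,
                "reason": "zero autosomal aggregate (sparse layer; consider "
                          "aggregation='mean')"}
    observed = agg(vals_x) / den
    rng = np.random.default_rng(seed)
    subsets = rng.integers(0, n_auto, size=(n_boot, n_x))
    background = agg(vals_auto[subsets], axis=1) / den
    quantile = float(np.mean(background < observed))
    return {"observed": float(observed), "background": background,
            "quantile": quantile,
            "background_median": float(np.median(background)),
            "background_q025": float(np.percentile(background, 2.5)),
            "background_q975": float(np.percentile(background, 97.5))}


# ---------------------------------------------------------------------------
# same-active-allele fold change
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    """Per-gene fold change of the same active allele between two cell groups."""

    per_gene: pd.DataFrame           # gene, chrom, fold, log2_fold
    x_median: float
    autosomal_median: float
    wilcoxon_stat: float
    wilcoxon_p: float
    n_cells_a: int
    n_cells_b: int
    allele: str
    group_a: str
    group_b: str


def same_allele_fold_change(expr: np.ndarray, acm: AllelicCountMatrix,
                            cells_a: np.ndarray, cells_b: np.ndarray,
                            allele: str = "maternal",
                            group_a: str = "XaXa", group_b: str = "XaXi",
                            min_cells: int = 20,
                            exclude_escapees: bool = True) -> FoldChangeResult:
    """Gene-wise expression fold of one allele between two XCI-state groups.

    ``expr`` is the allelic expression layer for the tested allele. Folds
    are pseudobulk: per-gene mean over cells in group_b divided by the
    mean in group_a, for genes expressed (mean > 0) in both. Reports the
    X-gene and autosomal medians and a one-sample Wilcoxon signed-rank
    test of X-gene log2-folds against zero shift.
    """
    cells_a = np.asarray(cells_a, dtype=bool)
    cells_b = np.asarray(cells_b, dtype=bool)
    for name, mask in ((group_a, cells_a), (group_b, cells_b)):
        if mask.sum() < min_cells:
            raise ValueError(f"group {name!r} has {int(mask.sum())} cells, "
                             f"needs >= {min_cells}")
    expr = np.asarray(expr, dtype=float)
    mean_a = np.nanmean(expr[:, cells_a], axis=1)
    mean_b = np.nanmean(expr[:, cells_b], axis=1)
    ok = (mean_a > 0) & (mean_b > 0)
    x_mask = acm.gene_mask("X", exclude_escapees=exclude_escapees)
    auto_mask = acm.gene_mask("autosomal")
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(ok, mean_b / mean_a, np.nan)
    per_gene = pd.DataFrame({
        "chrom": acm.gene_annotation["chrom"].to_numpy(),
        "fold": fold, "log2_fold": np.log2(fold)}, index=acm.gene_ids)
    x_folds = fold[x_mask & ok]
    auto_folds = fold[auto_mask & ok]
    if x_folds.size == 0 or auto_folds.size == 0:
        raise ValueError("no genes expressed in both groups on one scope")
    stat, p = stats.wilcoxon(np.log2(x_folds))
    return FoldChangeResult(
        per_gene=per_gene, x_median=float(np.median(x_folds)),
        autosomal_median=float(np.median(auto_folds)),
        wilcoxon_stat=float(stat), wilcoxon_p=float(p),
        n_cells_a=int(cells_a.sum()), n_cells_b=int(cells_b.sum()),
        allele=allele, group_a=group_a, group_b=group_b)


def paired_x_autosome_wilcoxon(result: FoldChangeResult,
                               seed: int | None = 0) -> tuple[float, float]:
    """Alternative fold-change test: X log2-folds against a size-matched
    random sample of autosomal log2-folds (Mann-Whitney form)."""
    per_gene = result.per_gene.dropna(subset=["log2_fold"])
    x = per_gene.loc[per_gene["chrom"] == "X", "log2_fold"].to_numpy()
    auto = per_gene.loc[~per_gene["chrom"].isin(("X", "Y", "MT")),
                        "log2_fold"].to_numpy()
    stat, p = stats.mannwhitneyu(x, auto, alternative="two-sided")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# tuning regression
# ---------------------------------------------------------------------------

@dataclass
class TuningFit:
    """Linear model of per-cell allelic X dosage vs maternal X-fraction."""

    allele: str
    slope: float
    intercept: float
    adj_r_squared: float
    p_value: float
    n_cells: int
    gene_correlations: pd.Series = field(repr=False)  # per-gene Pearson r
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def tuning_fit(expr: np.ndarray, acm: AllelicCountMatrix,
               maternal_fraction: np.ndarray, allele: str = "maternal",
               trim: float = DEFAULT_TRIM, min_cells: int = 30,
               min_cells_per_gene: int = 10,
               expression_rule: str = "mean_gt_zero") -> TuningFit:
    """Fit the elastic-tuning model for one allele.

    The response is the cell's trimmed-mean allelic expression over
    expressed X genes; the regressor is the cell's maternal X-fraction.
    OLS slope/intercept with adjusted R^2 and slope p-value, plus
    gene-wise Pearson correlations of allelic expression against the
    maternal X-fraction.
    """
    x = np.asarray(maternal_fraction, dtype=float)
    expr = np.asarray(expr, dtype=float)
    x_mask = acm.gene_mask("X") & filter_expressed(expr, expression_rule)
    y = cell_dosage(expr, x_mask, trim=trim)
    ok = ~np.isnan(x) & ~np.isnan(y)
    n = int(ok.sum())

    gene_idx = np.flatnonzero(x_mask)
    cors = np.full(gene_idx.size, np.nan)
    for i, g in enumerate(gene_idx):
        vals = expr[g, :]
        use = ok & ~np.isnan(vals)
        if use.sum() >= min_cells_per_gene and np.ptp(vals[use]) > 0 \
                and np.ptp(x[use]) > 0:
            cors[i] = stats.pearsonr(x[use], vals[use])[0]
    gene_correlations = pd.Series(cors, index=acm.gene_ids[gene_idx], name="pearson_r")

    if n < min_cells:
        return TuningFit(allele, np.nan, np.nan, np.nan, np.nan, n,
                         gene_correlations, reason=f"only {n} usable cells")
    if np.ptp(x[ok]) == 0:
        return TuningFit(allele, np.nan, np.nan, np.nan, np.nan, n,
                         gene_correlations, reason="degenerate maternal fraction")
    model = sm.OLS(y[ok], sm.add_constant(x[ok])).fit()
    return TuningFit(allele=allele, slope=float(model.params[1]),
                     intercept=float(model.params[0]),
                     adj_r_squared=float(model.rsquared_adj),
                     p_value=float(model.pvalues[1]), n_cells=n,
                     gene_correlations=gene_correlations)


def escapee_tuning_test(tuning: TuningFit, escapee_flags: pd.Series,
                        min_escapees: int = 5) -> dict:
    """Kolmogorov-Smirnov comparison of gene-wise tuning correlations,
    escapees vs other X genes, for one allele's fit."""
    cors = tuning.gene_correlations.dropna()
    flags = escapee_flags.reindex(cors.index).fillna(False).astype(bool)
    esc = cors[flags].to_numpy()
    rest = cors[~flags].to_numpy()
    if esc.size < min_escapees:
        return {"allele": tuning.allele, "statistic": np.nan, "p_value": np.nan,
                "n_escapee": int(esc.size), "n_other": int(rest.size),
                "reason": f"only {esc.size} escapees with defined correlations"}
    stat, p = stats.ks_2samp(esc, rest)
    return {"allele": tuning.allele, "statistic": float(stat),
            "p_value": float(p), "n_escapee": int(esc.size),
            "n_other": int(rest.size), "reason": None}


# ---------------------------------------------------------------------------
# homolog and female:male comparisons
# ---------------------------------------------------------------------------

def homolog_dosage_test(ratios_by_group: dict[str, np.ndarray],
                        mu: float = 0.5) -> pd.DataFrame:
    """One-sample Wilcoxon test of per-cell chromosome:autosome ratios
    against ``mu`` (0.5 = one balanced allele), per cell group."""
    if not ratios_by_group:
        raise ValueError("empty group set")
    rows = []
    for group, values in ratios_by_group.items():
        values = np.asarray(values, dtype=float)
        values = values[~np.isnan(values)]
        if values.size == 0:
            raise ValueError(f"group {group!r} has no defined ratios")
        diffs = values - mu
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(diffs)
        rows.append({"group": group, "n_cells": values.size,
                     "median_ratio": float(np.median(values)),
                     "statistic": float(stat), "p_value": float(p), "mu": mu})
    return pd.DataFrame(rows).set_index("group")


def female_male_ratio(expr: np.ndarray, acm: AllelicCountMatrix,
                      groups: pd.Series | None = None,
                      exclude_escapees: bool = True,
                      expression_rule: str = "mean_gt_zero") -> pd.DataFrame:
    """Per-gene female:male expression ratios within cell groups.

    Expression is first normalized to the gene's average over the group's
    cells (both sexes), then averaged per sex; the ratio is female/male.
    Returns one row per gene per group plus scope labels; groups missing a
    sex are reported with NaN ratios and a reason.
    """
    expr = np.asarray(expr, dtype=float)
    sex = acm.cell_annotation["sex"].to_numpy(str)
    female = sex == "XX"
    male = sex == "XY"
    if groups is None:
        groups = pd.Series("all", index=acm.cell_ids)
    groups = groups.reindex(acm.cell_ids)
    x_mask = acm.gene_mask("X", exclude_escapees=exclude_escapees)
    auto_mask = acm.gene_mask("autosomal")
    frames = []
    for group in pd.unique(groups.dropna()):
        cells = (groups == group).to_numpy()
        f_cells, m_cells = cells & female, cells & male
        scope = np.where(x_mask, "X", np.where(auto_mask, "autosomal", "other"))
        if f_cells.sum() == 0 or m_cells.sum() == 0:
            frames.append(pd.DataFrame(
                {"group": group, "scope": scope, "ratio": np.nan,
                 "reason": "a sex is missing in this group"}, index=acm.gene_ids))
            continue
        expressed = filter_expressed(expr, expression_rule, cells)
        gene_avg = np.nanmean(expr[:, cells], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = expr[:, cells] / gene_avg[:, None]
            f_mean = np.nanmean(rel[:, female[cells]], axis=1)
            m_mean = np.nanmean(rel[:, male[cells]], axis=1)
            ratio = np.where(expressed & (m_mean > 0), f_mean / m_mean, np.nan)
        frames.append(pd.DataFrame(
            {"group": group, "scope": scope, "ratio": ratio, "reason": None},
            index=acm.gene_ids))
    return pd.concat(frames)
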