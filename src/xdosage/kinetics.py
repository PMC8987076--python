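"""Two-state (telegraph) transcriptional kinetics from allelic counts.

The stationary distribution of the telegraph model is Poisson-Beta:
``x ~ Poisson(k_syn * B)`` with ``B ~ Beta(k_on, k_off)``, where rates
are expressed per mRNA degradation event (degradation rate = 1, the only
identifiable time scale from static counts). ``k_on`` is the burst
frequency and ``k_syn / k_off`` the burst size.

The likelihood marginalizes the Beta-distributed promoter activity by
fixed-order Gauss-Jacobi quadrature, which absorbs the Beta density's
endpoint singularities into the quadrature weight and is therefore
accurate at low ``k_on``/``k_off``. Maximum likelihood uses bounded
Nelder-Mead in log10 parameter space from a factorial-moment start,
mirroring common practice for this model. Fits are filtered on
convergence, parameter bounds, a minimum expected expression level and a
minimum group size (> 20 cells) before any group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, gammaln, logsumexp, roots_jacobi
from statsmodels.stats.multitest import multipletests

from .dosage import percentile_bootstrap_ci

QUADRATURE_ORDER = 50
#: optimizer box in log10 space: k_on, k_off in [1e-3, 1e3], k_syn in [1, 1e4]
LOG10_BOUNDS = ((-3.0, 3.0), (-3.0, 3.0), (0.0, 4.0))
MIN_CELLS = 21          # groups must exceed 20 cells
MIN_EXPECTED_COUNT = 0.01


# ---------------------------------------------------------------------------
# Poisson-Beta pmf
# ---------------------------------------------------------------------------

def _quadrature(k_on: float, k_off: float, order: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """Nodes b_i in (0, 1) and log-weights for E_Beta(k_on, k_off)[f(B)]."""
    t, w = roots_jacobi(order, k_off - 1.0, k_on - 1.0)
    b = 0.5 * (1.0 + t)
    log_w = (np.log(w) - (k_on + k_off - 1.0) * np.log(2.0)
             - betaln(k_on, k_off))
    return b, log_w


def poisson_beta_logpmf(x, k_on: float, k_off: float, k_syn: float,
                        order: int = QUADRATURE_ORDER) -> np.ndarray:
    """Log pmf of the Poisson-Beta (telegraph stationary) distribution."""
    if min(k_on, k_off, k_syn) <= 0:
        raise ValueError("rates must be positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    b, log_w = _quadrature(k_on, k_off, order)
    mu = k_syn * b
    log_pois = (x[None, :] * np.log(mu[:, None]) - mu[:, None]
                - gammaln(x[None, :] + 1.0))
    return logsumexp(log_w[:, None] + log_pois, axis=0)


def poisson_beta_pmf(x, k_on: float, k_off: float, k_syn: float,
                     order: int = QUADRATURE_ORDER) -> np.ndarray:
    """Pmf of the telegraph stationary count distribution.

    ``P(x) = \\int_0^1 Poisson(x; k_syn b) Beta(b; k_on, k_off) db``
    evaluated by Gauss-Jacobi quadrature; sums to 1 over x to within 1e-6.
    """
    return np.exp(poisson_beta_logpmf(x, k_on, k_off, k_syn, order))


def sample_poisson_beta(k_on: float, k_off: float, k_syn: float, size: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws from the model (independent oracle for the pmf)."""
    return rng.poisson(k_syn * rng.beta(k_on, k_off, size=size))


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class BurstKinetics:
    """ML estimate of telegraph kinetics for one gene/allele/group."""

    k_on: float
    k_off: float
    k_syn: float
    loglik: float
    converged: bool
    n_cells_used: int
    filter_pass: bool = False
    filter_reason: str | None = None
    at_bound: bool = False

    @property
    def burst_size(self) -> float:
        return self.k_syn / self.k_off

    @property
    def mean_expression(self) -> float:
        return self.k_syn * self.k_on / (self.k_on + self.k_off)


def _moment_start(counts: np.ndarray) -> np.ndarray:
    """Factorial-moment estimator of (k_on, k_off, k_syn), used as the
    optimizer start; falls back to a generic start when ill-posed."""
    x = counts.astype(float)
    m1 = x.mean()
    m2 = (x * (x - 1)).mean()
    m3 = (x * (x - 1) * (x - 2)).mean()
    fallback = np.array([1.0, 10.0, max(10.0 * max(m1, 0.1), 1.0)])
    if m1 <= 0 or m2 <= 0 or m3 <= 0:
        return fallback
    r1, r2, r3 = m1, m2 / m1, m3 / m2
    denom_common = r1 * r2 - 2.0 * r1 * r3 + r2 * r3
    denom_delta = r1 - 2.0 * r2 + r3
    if denom_common == 0 or denom_delta == 0:
        return fallback
    k_on = 2.0 * r1 * (r3 - r2) / denom_common
    k_off = 2.0 * (r3 - r2) * (r1 - r3) * (r2 - r1) / (denom_common * denom_delta)
    k_syn = (2.0 * r1 * r3 - r1 * r2 - r2 * r3) / denom_delta
    start = np.array([k_on, k_off, k_syn])
    if not np.all(np.isfinite(start)) or np.any(start <= 0):
        return fallback
    return start


def fit_two_state(counts: np.ndarray, min_cells: int = MIN_CELLS,
                  order: int = QUADRATURE_ORDER) -> BurstKinetics:
    """ML telegraph-kinetics fit for one gene's per-cell allelic counts.

    NaN entries (no allelic information) are dropped. Degenerate input
    (all zeros, too few cells) yields a non-converged, filter-failing
    result rather than an exception. Deterministic: fixed quadrature
    order, fixed moment-based start.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[~np.isnan(counts)]
    n = counts.size
    if n < min_cells:
        return BurstKinetics(np.nan, np.nan, np.nan, np.nan, False, n,
                             filter_reason=f"n_cells {n} <= {min_cells - 1}")
    if not np.any(counts > 0):
        return BurstKinetics(np.nan, np.nan, np.nan, np.nan, False, n,
                             filter_reason="all counts zero")
    values, weights = np.unique(counts.astype(np.int64), return_counts=True)
    values = values.astype(float)

    def negloglik(log10_params: np.ndarray) -> float:
        k_on, k_off, k_syn = 10.0 ** log10_params
        lp = poisson_beta_logpmf(values, k_on, k_off, k_syn, order)
        if not np.all(np.isfinite(lp)):
            return 1e12
        return -float(np.dot(weights, lp))

    start = np.log10(_moment_start(counts))
    lo = np.array([b[0] for b in LOG10_BOUNDS])
    hi = np.array([b[1] for b in LOG10_BOUNDS])
    start = np.clip(start, lo + 1e-6, hi - 1e-6)
    res = optimize.minimize(negloglik, start, method="Nelder-Mead",
                            bounds=LOG10_BOUNDS,
                            options={"maxiter": 1000, "xatol": 1e-4,
                                     "fatol": 1e-6})
    k_on, k_off, k_syn = 10.0 ** res.x
    at_bound = bool(np.any(res.x <= lo + 1e-3) or np.any(res.x >= hi - 1e-3))
    return BurstKinetics(float(k_on), float(k_off), float(k_syn),
                         -float(res.fun), bool(res.success), n,
                         at_bound=at_bound)


def filter_fits(fits: "pd.DataFrame | list[BurstKinetics]",
                min_expected: float = MIN_EXPECTED_COUNT,
                min_cells: int = MIN_CELLS) -> pd.DataFrame:
    """Set the pass flag on a table of fits.

    Failure reasons: non-convergence, estimate at an optimizer bound,
    expected expression ``k_syn k_on / (k_on + k_off)`` below the floor,
    or too few cells.
    """
    df = fits if isinstance(fits, pd.DataFrame) else fits_to_frame(fits)
    df = df.copy()
    reasons = []
    for _, row in df.iterrows():
        if isinstance(row.get("filter_reason"), str):
            reason = row["filter_reason"]         # degenerate input, kept as is
        elif np.isnan(row["k_on"]) or not row["converged"]:
            reason = "not converged"
        elif row["at_bound"]:
            reason = "bound"
        elif row["k_syn"] * row["k_on"] / (row["k_on"] + row["k_off"]) < min_expected:
            reason = "low expression"
        elif row["n_cells_used"] < min_cells:
            reason = "too few cells"
        else:
            reason = None
        reasons.append(reason)
    df["filter_reason"] = reasons
    df["filter_pass"] = [r is None for r in reasons]
    return df


def fits_to_frame(fits: list[BurstKinetics], index=None) -> pd.DataFrame:
    rows = [{"k_on": f.k_on, "k_off": f.k_off, "k_syn": f.k_syn,
             "burst_size": f.burst_size, "loglik": f.loglik,
             "converged": f.converged, "n_cells_used": f.n_cells_used,
             "at_bound": f.at_bound, "filter_reason": f.filter_reason}
            for f in fits]
    return pd.DataFrame(rows, index=index)


def fit_gene_panel(counts: np.ndarray, gene_ids=None,
                   min_cells: int = MIN_CELLS,
                   order: int = QUADRATURE_ORDER) -> pd.DataFrame:
    """Fit every row of a genes x cells allelic count matrix and filter."""
    fits = [fit_two_state(counts[g, :], min_cells=min_cells, order=order)
            for g in range(counts.shape[0])]
    return filter_fits(fits_to_frame(fits, index=gene_ids), min_cells=min_cells)


# ---------------------------------------------------------------------------
# group-relative statistics
# ---------------------------------------------------------------------------

@dataclass
class KineticsGroupResult:
    """Burst statistics of a cell group relative to its autosomal median."""

    group: str
    per_gene: pd.DataFrame   # relative k_on and burst size for X genes
    k_on_summary: dict       # median with percentile-bootstrap CI over genes
    burst_size_summary: dict
    n_autosomal: int


def relative_kinetics(fits: pd.DataFrame, gene_annotation: pd.DataFrame,
                      group: str = "", min_autosomal: int = 50,
                      n_boot: int = 1000, seed: int | None = 0
                      ) -> KineticsGroupResult:
    """Divide per-gene burst frequency and size by the group's autosomal
    medians; summarize X genes as median with percentile-bootstrap CI."""
    passing = fits[fits["filter_pass"].astype(bool)]
    chrom = gene_annotation["chrom"].reindex(passing.index).astype(str)
    auto = passing[~chrom.isin(("X", "Y", "MT"))]
    if len(auto) < min_autosomal:
        raise ValueError(
            f"group {group!r}: {len(auto)} passing autosomal fits, "
            f"needs >= {min_autosomal}")
    auto_kon = float(auto["k_on"].median())
    auto_size = float(auto["burst_size"].median())
    rel = passing.copy()
    rel["relative_k_on"] = rel["k_on"] / auto_kon
    rel["relative_burst_size"] = rel["burst_size"] / auto_size
    rel["chrom"] = chrom
    x_rel = rel[rel["chrom"] == "X"]

    def _summary(values: np.ndarray) -> dict:
        point, lo, hi = percentile_bootstrap_ci(values, np.median, n_boot,
                                                seed=seed)
        return {"median": point, "ci_lower": lo, "ci_upper": hi,
                "n_genes": int(values.size)}

    return KineticsGroupResult(
        group=group, per_gene=rel,
        k_on_summary=_summary(x_rel["relative_k_on"].to_numpy()),
        burst_size_summary=_summary(x_rel["relative_burst_size"].to_numpy()),
        n_autosomal=len(auto))


def compare_group_kinetics(result_a: KineticsGroupResult,
                           result_b: KineticsGroupResult,
                           scope: str = "X", min_genes: int = 10) -> pd.DataFrame:
    """Mann-Whitney U comparison of per-gene relative burst frequency and
    burst size between two groups, BH-FDR corrected across the reported
    comparisons."""
    rows = []
    for metric in ("relative_k_on", "relative_burst_size"):
        a = result_a.per_gene.query("chrom == @scope")[metric].dropna().to_numpy()
        b = result_b.per_gene.query("chrom == @scope")[metric].dropna().to_numpy()
        if min(a.size, b.size) < min_genes:
            rows.append({"metric": metric, "statistic": np.nan, "p_value": np.nan,
                         "n_a": a.size, "n_b": b.size,
                         "reason": "too few genes"})
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"metric": metric, "statistic": float(stat),
                     "p_value": float(p), "n_a": a.size, "n_b": b.size,
                     "reason": None})
    df = pd.DataFrame(rows).set_index("metric")
    defined = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if defined.any():
        q[defined.to_numpy()] = multipletests(
            df.loc[defined, "p_value"], method="fdr_bh")[1]
    df["q_value"] = q
    return df
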