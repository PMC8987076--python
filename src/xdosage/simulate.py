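"""Synthetic allele-resolved single-cell count data.

Generates gene x cell x allele UMI-like count matrices with the
statistical structure assumed by the downstream analysis:

* per-gene two-state (telegraph) transcription — stationary counts are
  Poisson-Beta: ``x ~ Poisson(k_syn * B)`` with ``B ~ Beta(k_on, k_off)``
  in units of the mRNA degradation rate;
* X-chromosome inactivation (XCI) with a per-cell silencing degree
  ``d in [0, 1]`` applied to one X allele, imprinted (paternal) or random
  with an Xce-like strain skew;
* elastic X-upregulation (XCU) of the opposite, active X allele: burst
  frequency scaled by ``1 + (phi - 1) * d`` so hyperactivation tracks the
  degree of silencing on the other allele;
* escapee genes that stay biallelic, X-Y ancestral homolog pairs that are
  not compensated in males, XX/XY/XO genotypes, and an Xist-knockout
  scenario in which XCI (and hence female XCU) never initiates;
* library-depth downsampling by binomial thinning and optional allelic
  misassignment noise.

A dilution-series generator mirrors the mock-library calibration design
(pure-strain RNA mixed at fixed fractions, sequenced to a target depth).

Every dataset is returned together with its full ground truth, and
identical config + seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data import AllelicCountMatrix, GroundTruth

DEFAULT_DILUTION_FRACTIONS = (0.0, 0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 0.875, 1.0)


class ConfigurationError(ValueError):
    """Invalid simulation parameter; the message names the field."""


@dataclass
class SimulationConfig:
    """Parameters of the population generator.

    Kinetics priors are log-normal, given as ``(median, log10-sd)`` per
    rate. ``xcu_fold`` is the elastic upregulation factor phi >= 1 reached
    at full XCI. ``xce_skew`` is the probability that the maternal (C57)
    allele is chosen for silencing under random XCI. ``xci_degree`` is the
    distribution of the per-cell silencing degree d, given as a tuple:
    ``("point", v)``, ``("uniform", lo, hi)``, ``("beta", a, b)`` or
    ``("mixture", ((w, spec), ...))``.
    """

    n_cells: int = 500
    n_genes_autosomal: int = 2000
    n_genes_x: int = 200
    n_xy_homologs: int = 0
    escapee_fraction: float = 0.05
    sex_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)  # XX, XY, XO
    xci_mode: str = "random"  # none | imprinted | random | knockout
    xce_skew: float = 0.42
    xci_degree: tuple = ("uniform", 0.0, 1.0)
    xcu_fold: float = 1.6
    xcu_on: str = "burst_frequency"  # "burst_size" is a negative-control mode
    male_xcu: bool = True
    silencing_exponent: float = 1.0
    kinetics_priors: dict = field(default_factory=lambda: {
        "k_on": (0.7, 0.4), "k_off": (5.0, 0.4), "k_syn": (20.0, 0.4)})
    depth_target: float = 10_000.0
    misassignment_rate: float = 0.0
    lineage: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        def _check_prop(name: str, value: float) -> None:
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")

        for name in ("escapee_fraction", "xce_skew", "misassignment_rate"):
            _check_prop(name, getattr(self, name))
        if len(self.sex_mix) != 3 or any(p < 0 for p in self.sex_mix) \
                or not np.isclose(sum(self.sex_mix), 1.0):
            raise ConfigurationError(
                f"sex_mix must be 3 nonnegative proportions summing to 1, got {self.sex_mix}")
        if self.xci_mode not in ("none", "imprinted", "random", "knockout"):
            raise ConfigurationError(f"xci_mode: unknown mode {self.xci_mode!r}")
        if self.xcu_fold < 1.0:
            raise ConfigurationError(f"xcu_fold must be >= 1, got {self.xcu_fold}")
        if self.xcu_on not in ("burst_frequency", "burst_size"):
            raise ConfigurationError(f"xcu_on: unknown target {self.xcu_on!r}")
        if self.depth_target <= 0:
            raise ConfigurationError(f"depth_target must be > 0, got {self.depth_target}")
        if self.n_cells <= 0 or self.n_genes_autosomal <= 0 or self.n_genes_x <= 0:
            raise ConfigurationError("n_cells, n_genes_autosomal, n_genes_x must be > 0")
        if not (0 <= self.n_xy_homologs <= self.n_genes_x):
            raise ConfigurationError("n_xy_homologs must be in [0, n_genes_x]")
        if self.silencing_exponent <= 0:
            raise ConfigurationError("silencing_exponent must be > 0")
        for rate in ("k_on", "k_off", "k_syn"):
            if rate not in self.kinetics_priors:
                raise ConfigurationError(f"kinetics_priors missing {rate}")
            med, sd = self.kinetics_priors[rate]
            if med <= 0 or sd < 0:
                raise ConfigurationError(
                    f"kinetics_priors[{rate}] needs median > 0 and sd >= 0")
        _validate_degree_spec(self.xci_degree)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sex_mix"] = list(self.sex_mix)
        d["xci_degree"] = _degree_spec_to_jsonable(self.xci_degree)
        return d


def _validate_degree_spec(spec) -> None:
    try:
        kind = spec[0]
        if kind == "point":
            (v,) = spec[1:]
            ok = 0.0 <= v <= 1.0
        elif kind == "uniform":
            lo, hi = spec[1:]
            ok = 0.0 <= lo <= hi <= 1.0
        elif kind == "beta":
            a, b = spec[1:]
            ok = a > 0 and b > 0
        elif kind == "mixture":
            (components,) = spec[1:]
            weights = [w for w, _ in components]
            ok = all(w >= 0 for w in weights) and sum(weights) > 0
            for _, sub in components:
                _validate_degree_spec(sub)
        else:
            ok = False
    except (TypeError, ValueError, IndexError):
        ok = False
    if not ok:
        raise ConfigurationError(f"xci_degree: invalid distribution spec {spec!r}")


def _degree_spec_to_jsonable(spec):
    if spec[0] == "mixture":
        return ["mixture", [[w, _degree_spec_to_jsonable(s)] for w, s in spec[1]]]
    return list(spec)


def sample_degree(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` silencing degrees from a distribution spec."""
    kind = spec[0]
    if kind == "point":
        return np.full(n, float(spec[1]))
    if kind == "uniform":
        return rng.uniform(spec[1], spec[2], size=n)
    if kind == "beta":
        return rng.beta(spec[1], spec[2], size=n)
    if kind == "mixture":
        components = spec[1]
        weights = np.array([w for w, _ in components], dtype=float)
        weights /= weights.sum()
        which = rng.choice(len(components), size=n, p=weights)
        out = np.empty(n)
        for i, (_, sub) in enumerate(components):
            idx = which == i
            out[idx] = sample_degree(sub, int(idx.sum()), rng)
        return out
    raise ConfigurationError(f"xci_degree: invalid distribution spec {spec!r}")


def analytic_allelic_mean(k_on: float, k_off: float, k_syn: float,
                          d: float = 0.0, phi: float = 1.6,
                          role: str = "autosomal", *,
                          silencing_exponent: float = 1.0,
                          xcu_on: str = "burst_frequency") -> float:
    """Closed-form stationary mean count of one allele.

    The telegraph stationary mean is ``k_syn * k_on / (k_on + k_off)``;
    the effective rate is scaled by role exactly as in
    :func:`simulate_population`: a silenced non-escapee X allele has
    ``k_on * (1 - d) ** gamma``, the opposite active allele gains
    ``1 + (phi - 1) * d`` on burst frequency (or on burst size in the
    negative-control mode), autosomal/escapee alleles are unscaled.
    """
    if min(k_on, k_off, k_syn) <= 0:
        raise ValueError("rates must be positive")
    gain = 1.0 + (phi - 1.0) * d
    if role == "silenced":
        k_on = k_on * (1.0 - d) ** silencing_exponent
        if k_on == 0.0:
            return 0.0
    elif role == "active":
        if xcu_on == "burst_frequency":
            k_on = k_on * gain
        else:
            k_syn = k_syn * gain
    elif role != "autosomal":
        raise ValueError(f"unknown role {role!r}")
    return k_syn * k_on / (k_on + k_off)


def sample_telegraph_counts(k_on, k_off, k_syn, size,
                            rng: np.random.Generator) -> np.ndarray:
    """Draw stationary telegraph-model counts: Poisson(k_syn * Beta(k_on, k_off))."""
    b = rng.beta(k_on, k_off, size=size)
    return rng.poisson(np.asarray(k_syn) * b)


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------

def _draw_gene_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_auto, n_x, n_hom = cfg.n_genes_autosomal, cfg.n_genes_x, cfg.n_xy_homologs
    gene_ids = ([f"gA{i:05d}" for i in range(n_auto)]
                + [f"gX{i:05d}" for i in range(n_x)]
                + [f"gY{i:05d}" for i in range(n_hom)])
    chrom = (list(np.char.mod("%d", 1 + np.arange(n_auto) % 19))
             + ["X"] * n_x + ["Y"] * n_hom)
    n_genes = len(gene_ids)

    rates = {}
    for rate in ("k_on", "k_off", "k_syn"):
        med, sd = cfg.kinetics_priors[rate]
        base = med * 10.0 ** rng.normal(0.0, sd, size=n_auto + n_x)
        if n_hom:
            # each Y homolog shares its X partner's kinetics (ancestral pair)
            base = np.concatenate([base, base[n_auto:n_auto + n_hom]])
        rates[rate] = base

    escapee = np.zeros(n_genes, dtype=bool)
    xy_homolog = np.zeros(n_genes, dtype=bool)
    if n_hom:
        xy_homolog[n_auto:n_auto + n_hom] = True     # the X-side homologs
        xy_homolog[n_auto + n_x:] = True             # their Y partners
        escapee[n_auto:n_auto + n_hom] = True        # homologs escape XCI
    n_escapee = int(round(cfg.escapee_fraction * n_x))
    free_x = np.arange(n_auto + n_hom, n_auto + n_x)  # X genes not already homologs
    n_extra = max(0, n_escapee - n_hom)
    if n_extra and free_x.size:
        chosen = rng.choice(free_x, size=min(n_extra, free_x.size), replace=False)
        escapee[chosen] = True

    return pd.DataFrame(
        {"chrom": chrom, "k_on": rates["k_on"], "k_off": rates["k_off"],
         "k_syn": rates["k_syn"], "escapee": escapee, "xy_homolog": xy_homolog},
        index=pd.Index(gene_ids, name="gene_id"))


def _draw_cell_table(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    sexes = rng.choice(["XX", "XY", "XO"], size=cfg.n_cells, p=list(cfg.sex_mix))
    d = np.zeros(cfg.n_cells)
    silenced = np.array(["none"] * cfg.n_cells, dtype=object)
    is_xx = sexes == "XX"
    if cfg.xci_mode in ("imprinted", "random"):
        d[is_xx] = sample_degree(cfg.xci_degree, int(is_xx.sum()), rng)
        if cfg.xci_mode == "imprinted":
            silenced[is_xx] = "paternal"
        else:
            mat = rng.random(cfg.n_cells) < cfg.xce_skew
            silenced[is_xx] = np.where(mat[is_xx], "maternal", "paternal")
    # "none" and "knockout" modes leave d = 0: no XCI, hence no female XCU
    return pd.DataFrame(
        {"sex": sexes, "lineage": cfg.lineage, "timepoint": 0, "modality": "rna",
         "true_degree": d, "silenced_allele": silenced},
        index=pd.Index([f"cell{i:05d}" for i in range(cfg.n_cells)], name="cell_id"))


def _kon_scales(cfg: SimulationConfig, genes: pd.DataFrame,
                cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per gene x cell multiplicative scale on k_on (or k_syn) per allele.

    Returns (scale_m, scale_p, gain_m, gain_p): silencing factors enter the
    ``scale`` arrays, XCU gains the ``gain`` arrays so the caller can apply
    the gain to burst frequency or burst size per config.
    """
    n_genes, n_cells = len(genes), len(cells)
    scale_m = np.ones((n_genes, n_cells))
    scale_p = np.ones((n_genes, n_cells))
    gain_m = np.ones((n_genes, n_cells))
    gain_p = np.ones((n_genes, n_cells))

    chrom = genes["chrom"].to_numpy(str)
    is_x = chrom == "X"
    is_y = chrom == "Y"
    escapee = genes["escapee"].to_numpy(bool)
    homolog = genes["xy_homolog"].to_numpy(bool)
    x_scaled = is_x & ~escapee            # genes subject to XCI/XCU
    sex = cells["sex"].to_numpy(str)
    d = cells["true_degree"].to_numpy(float)
    silenced = cells["silenced_allele"].to_numpy(str)
    gamma = cfg.silencing_exponent
    phi = cfg.xcu_fold

    # female XX cells undergoing XCI: silence one allele, tune the other
    for target, sil_scale, act_gain in (
            ("maternal", scale_m, gain_p), ("paternal", scale_p, gain_m)):
        cols = (sex == "XX") & (silenced == target) & (d > 0)
        if cols.any():
            sil_scale[np.ix_(x_scaled, cols)] = (1.0 - d[cols]) ** gamma
            act_gain[np.ix_(x_scaled, cols)] = 1.0 + (phi - 1.0) * d[cols]

    # XY/XO: paternal X structurally absent; single X fully upregulated,
    # except X-Y homologs in males (Y copy keeps their dosage balanced)
    single_x = np.isin(sex, ("XY", "XO"))
    if single_x.any():
        scale_p[np.ix_(is_x, single_x)] = 0.0
        if cfg.male_xcu:
            male_x = is_x & ~homolog
            gain_m[np.ix_(male_x, single_x)] = phi
    # Y genes: paternal-only, XY cells only
    if is_y.any():
        scale_m[is_y, :] = 0.0
        scale_p[np.ix_(is_y, sex != "XY")] = 0.0
    # maternal-only inheritance of X is assumed for XY/XO (X from dam)
    return scale_m, scale_p, gain_m, gain_p


def _draw_allele_counts(genes: pd.DataFrame, scale: np.ndarray, gain: np.ndarray,
                        xcu_on: str, rng: np.random.Generator) -> np.ndarray:
    k_on = genes["k_on"].to_numpy()[:, None] * scale
    k_syn = np.broadcast_to(genes["k_syn"].to_numpy()[:, None], scale.shape).copy()
    if xcu_on == "burst_frequency":
        k_on = k_on * gain
    else:
        k_syn = k_syn * gain
    k_off = np.broadcast_to(genes["k_off"].to_numpy()[:, None], scale.shape)
    counts = np.zeros(scale.shape, dtype=np.int64)
    present = k_on > 0
    b = rng.beta(np.where(present, k_on, 1.0), k_off)
    drawn = rng.poisson(k_syn * b)
    counts[present] = drawn[present]
    return counts


def _misassign(m: np.ndarray, p: np.ndarray, rate: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if rate <= 0:
        return m, p
    m_to_p = rng.binomial(m, rate)
    p_to_m = rng.binomial(p, rate)
    return m - m_to_p + p_to_m, p - p_to_m + m_to_p


def _thin_to_depth(m: np.ndarray, p: np.ndarray, depth_target: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    totals = (m + p).sum(axis=0)
    keep = np.minimum(1.0, depth_target / np.maximum(totals, 1))
    m = rng.binomial(m, keep[None, :])
    p = rng.binomial(p, keep[None, :])
    return m, p


def simulate_population(config: SimulationConfig) -> tuple[AllelicCountMatrix, GroundTruth]:
    """Simulate an allele-resolved single-cell population with ground truth.

    Draw order under the single seeded generator stream: gene kinetics and
    escapee assignment; cell sex, silenced allele, silencing degree;
    maternal counts; paternal counts; allelic misassignment; depth thinning.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = _draw_gene_table(config, rng)
    cells = _draw_cell_table(config, rng)
    scale_m, scale_p, gain_m, gain_p = _kon_scales(config, genes, cells)

    maternal = _draw_allele_counts(genes, scale_m, gain_m, config.xcu_on, rng)
    paternal = _draw_allele_counts(genes, scale_p, gain_p, config.xcu_on, rng)
    maternal, paternal = _misassign(maternal, paternal, config.misassignment_rate, rng)
    maternal, paternal = _thin_to_depth(maternal, paternal, config.depth_target, rng)
    total = maternal + paternal

    gene_annotation = genes[["chrom", "escapee", "xy_homolog"]].copy()
    cell_annotation = cells[["sex", "lineage", "timepoint", "modality"]].copy()
    acm = AllelicCountMatrix(maternal.astype(float), paternal.astype(float),
                             total, gene_annotation, cell_annotation)
    truth = GroundTruth(genes=genes.copy(), cells=cells.copy(), config=config)
    return acm, truth


# ---------------------------------------------------------------------------
# dilution series
# ---------------------------------------------------------------------------

def simulate_dilution_series(fractions: Sequence[float] = DEFAULT_DILUTION_FRACTIONS,
                             depth: int = 100_000, n_genes: int = 2000,
                             seed: int = 0,
                             abundance_log10_sd: float = 1.0
                             ) -> tuple[AllelicCountMatrix, GroundTruth]:
    """Simulate pure-strain RNA mixtures at known maternal (C57) fractions.

    One pseudo-bulk sample per fraction: per-gene abundances are drawn once
    (log-normal over genes), each sample draws ``depth`` reads multinomially
    over genes and splits each gene's reads binomially with maternal
    probability equal to the spiked fraction.
    """
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions list is empty")
    if any(not (0.0 <= f <= 1.0) for f in fractions):
        raise ValueError("fractions must be in [0, 1]")
    if depth <= 0 or n_genes <= 0:
        raise ValueError("depth and n_genes must be > 0")
    rng = np.random.default_rng(seed)

    abundance = 10.0 ** rng.normal(0.0, abundance_log10_sd, size=n_genes)
    props = abundance / abundance.sum()
    n_x = max(1, n_genes // 20)  # a minority of genes annotated X-linked
    chrom = np.array(["X"] * n_x + ["1"] * (n_genes - n_x))

    maternal = np.empty((n_genes, len(fractions)), dtype=np.int64)
    paternal = np.empty_like(maternal)
    for j, frac in enumerate(fractions):
        totals = rng.multinomial(depth, props)
        mat = rng.binomial(totals, frac)
        maternal[:, j] = mat
        paternal[:, j] = totals - mat

    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    sample_ids = pd.Index([f"mix_{100 * f:g}pctC57" for f in fractions], name="cell_id")
    gene_annotation = pd.DataFrame({"chrom": chrom}, index=gene_ids)
    cell_annotation = pd.DataFrame(
        {"sex": "XX", "lineage": "dilution", "timepoint": 0, "modality": "rna",
         "true_fraction": fractions}, index=sample_ids)
    acm = AllelicCountMatrix(maternal.astype(float), paternal.astype(float),
                             maternal + paternal, gene_annotation,
                             cell_annotation.drop(columns="true_fraction"))
    truth = GroundTruth(
        genes=pd.DataFrame({"chrom": chrom, "abundance": props}, index=gene_ids),
        cells=cell_annotation)
    return acm, truth


def subsample_depth(acm: AllelicCountMatrix, depth: float,
                    seed: int = 0) -> AllelicCountMatrix:
    """Binomially thin a dataset to a lower mean depth (calibration curves)."""
    rng = np.random.default_rng(seed)
    m = np.nan_to_num(acm.maternal).astype(np.int64)
    p = np.nan_to_num(acm.paternal).astype(np.int64)
    m, p = _thin_to_depth(m, p, depth, rng)
    return AllelicCountMatrix(m.astype(float), p.astype(float), m + p,
                              acm.gene_annotation.copy(), acm.cell_annotation.copy())
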