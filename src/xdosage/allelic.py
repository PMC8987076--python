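"""Per-cell allelic statistics: reference ratios, XCI state, completion,
allelic expression scaling, trimmed-mean dosage and expression filters.

The allelic reference ratio of a cell is the maternal (C57) share of
allelically informative X-linked counts, computed on summed counts after
excluding the most highly expressed X genes (top 10% within the cell) so
a single dominant gene cannot drive the chromosome-level call. Cells are
classed by the ratio r into XCI states — biallelic XaXa for r in
(0.4, 0.6), semi-inactive XaXs / XsXa for [0.6, 0.9) and its mirror,
fully inactive XaXi / XiXa beyond 0.9 / below 0.1 — and XCI completion is
|0.5 - r| / 0.5, the degree of monoallelic skew (0 = balanced,
1 = monoallelic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import AllelicCountMatrix

DEFAULT_EXCLUDE_TOP_FRAC = 0.10
DEFAULT_MIN_INFORMATIVE = 10
DEFAULT_TRIM = 0.20


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def counts_per_million(counts: np.ndarray) -> np.ndarray:
    """Depth-normalize a genes x cells count matrix to counts per million.

    For UMI data this is the TPM-equivalent (no gene-length bias to remove).
    All-zero cells map to zero columns.
    """
    counts = np.asarray(counts, dtype=float)
    depth = np.nansum(counts, axis=0)
    scale = np.divide(1e6, depth, out=np.zeros_like(depth), where=depth > 0)
    return counts * scale[None, :]


def tpm_from_lengths(counts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Length-normalized TPM: reads per kilobase, rescaled to 1e6 per cell."""
    counts = np.asarray(counts, dtype=float)
    rpk = counts / (np.asarray(lengths, dtype=float)[:, None] / 1e3)
    denom = rpk.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return rpk / np.where(denom > 0, denom, np.nan) * 1e6


def allelic_ratio_matrix(acm: AllelicCountMatrix) -> np.ndarray:
    """Per gene x cell maternal fraction of allelic counts (NaN if uninformative)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = acm.maternal + acm.paternal
        return np.where(denom > 0, acm.maternal / denom, np.nan)


# ---------------------------------------------------------------------------
# reference ratio and XCI state
# ---------------------------------------------------------------------------

def compute_reference_ratio(acm: AllelicCountMatrix, cell: int | str,
                            scope: str = "X",
                            exclude_top_frac: float = DEFAULT_EXCLUDE_TOP_FRAC,
                            min_informative: int = DEFAULT_MIN_INFORMATIVE
                            ) -> tuple[float, int]:
    """Maternal reference ratio of one cell over a chromosome scope.

    Returns ``(ratio, n_informative)``; ratio is NaN when fewer than
    ``min_informative`` genes carry allelic counts. Genes are ranked by the
    cell's total expression within the scope and the top
    ``exclude_top_frac`` are removed before summing counts.
    """
    if isinstance(cell, str):
        cell = acm.cell_ids.get_loc(cell)
    mask = acm.gene_mask(scope)
    if not mask.any():
        raise ValueError(f"empty gene scope {scope!r}")
    m = acm.maternal[mask, cell]
    p = acm.paternal[mask, cell]
    tot = np.asarray(acm.total, dtype=float)[mask, cell]
    informative = np.nan_to_num(m) + np.nan_to_num(p) > 0
    n_informative = int(informative.sum())
    if n_informative < min_informative:
        return np.nan, n_informative
    m, p, tot = m[informative], p[informative], tot[informative]
    n_drop = int(np.floor(exclude_top_frac * m.size))
    if n_drop:
        keep = np.argsort(tot, kind="stable")[: m.size - n_drop]
        m, p = m[keep], p[keep]
    denom = np.nansum(m) + np.nansum(p)
    if denom == 0:
        return np.nan, n_informative
    return float(np.nansum(m) / denom), n_informative


def reference_ratios(acm: AllelicCountMatrix, scope: str = "X",
                     exclude_top_frac: float = DEFAULT_EXCLUDE_TOP_FRAC,
                     min_informative: int = DEFAULT_MIN_INFORMATIVE) -> pd.DataFrame:
    """Reference ratio and informative gene count for every cell."""
    rows = [compute_reference_ratio(acm, j, scope, exclude_top_frac, min_informative)
            for j in range(acm.n_cells)]
    return pd.DataFrame(rows, index=acm.cell_ids,
                        columns=["ratio", "n_informative"])


def classify_xci_state(r) -> "str | np.ndarray":
    """Map a maternal reference ratio to an XCI state label.

    Interval rules (half-open exactly as printed, so boundary values fall
    in the more-skewed class): (0.4, 0.6) -> XaXa; [0.6, 0.9) -> XaXs;
    >= 0.9 -> XaXi; mirrored (0.1, 0.4] -> XsXa; <= 0.1 -> XiXa;
    undefined (NaN) -> undetermined.
    """
    arr = np.asarray(r, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    defined = ~np.isnan(arr)
    if ((arr[defined] < 0) | (arr[defined] > 1)).any():
        raise ValueError("reference ratio outside [0, 1]")
    out = np.full(arr.shape, "undetermined", dtype=object)
    out[defined & (arr > 0.4) & (arr < 0.6)] = "XaXa"
    out[defined & (arr >= 0.6) & (arr < 0.9)] = "XaXs"
    out[defined & (arr >= 0.9)] = "XaXi"
    out[defined & (arr > 0.1) & (arr <= 0.4)] = "XsXa"
    out[defined & (arr <= 0.1)] = "XiXa"
    return str(out[0]) if scalar else out


def xci_completion(r):
    """Degree of XCI completion |0.5 - r| / 0.5 (allele-label symmetric)."""
    arr = np.asarray(r, dtype=float)
    out = np.abs(0.5 - arr) / 0.5
    return float(out) if arr.ndim == 0 else out


def cell_states(acm: AllelicCountMatrix, scope: str = "X",
                exclude_top_frac: float = DEFAULT_EXCLUDE_TOP_FRAC,
                min_informative: int = DEFAULT_MIN_INFORMATIVE) -> pd.DataFrame:
    """Per-cell allelic state table: ratio, XCI state, completion, n_informative."""
    tbl = reference_ratios(acm, scope, exclude_top_frac, min_informative)
    tbl["xci_state"] = classify_xci_state(tbl["ratio"].to_numpy())
    tbl["xci_completion"] = xci_completion(tbl["ratio"].to_numpy())
    tbl["n_informative"] = tbl["n_informative"].astype(int)
    return tbl[["ratio", "xci_state", "xci_completion", "n_informative"]]


# ---------------------------------------------------------------------------
# allelic expression
# ---------------------------------------------------------------------------

def scale_allelic_expression(total_expr: np.ndarray, ratios: np.ndarray
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Split normalized total expression into alleles by per-gene-cell ratios.

    maternal = total * ratio, paternal = total * (1 - ratio); entries with
    undefined (NaN) ratios are undefined on both alleles.
    """
    total_expr = np.asarray(total_expr, dtype=float)
    ratios = np.asarray(ratios, dtype=float)
    defined = ~np.isnan(ratios)
    if ((ratios[defined] < 0) | (ratios[defined] > 1)).any():
        raise ValueError("allelic ratio outside [0, 1]")
    maternal = total_expr * ratios
    paternal = total_expr * (1.0 - ratios)
    return maternal, paternal


def fill_missing_allelic(maternal: np.ndarray, paternal: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-fill undefined allelic values where the other allele is detected.

    An undefined entry becomes 0 iff the opposite allele has a detected
    (> 0) value; both-undefined entries stay undefined. Idempotent.
    """
    maternal = np.array(maternal, dtype=float)
    paternal = np.array(paternal, dtype=float)
    m_nan, p_nan = np.isnan(maternal), np.isnan(paternal)
    maternal[m_nan & ~p_nan & (np.nan_to_num(paternal) > 0)] = 0.0
    paternal[p_nan & ~m_nan & (np.nan_to_num(maternal) > 0)] = 0.0
    return maternal, paternal


def fill_missing_allelic_matrix(acm: AllelicCountMatrix) -> AllelicCountMatrix:
    """Apply the zero-fill rule to a dataset's allelic count layers."""
    out = acm.copy()
    out.maternal, out.paternal = fill_missing_allelic(out.maternal, out.paternal)
    return out


def cell_dosage(expr: np.ndarray, gene_mask: np.ndarray,
                trim: float = DEFAULT_TRIM) -> np.ndarray:
    """Robust per-cell expression: symmetric trimmed mean over a gene set.

    ``trim`` is the fraction removed from each tail. NaN entries (genes
    without allelic information in that cell) are dropped per cell before
    trimming; a cell whose effective gene count cannot survive trimming is
    returned as NaN.
    """
    if not (0.0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    expr = np.asarray(expr, dtype=float)[np.asarray(gene_mask, dtype=bool), :]
    if expr.shape[0] == 0:
        raise ValueError("empty gene set")
    out = np.full(expr.shape[1], np.nan)
    for j in range(expr.shape[1]):
        vals = expr[:, j]
        vals = vals[~np.isnan(vals)]
        if vals.size * (1.0 - 2.0 * trim) < 1.0:
            continue
        out[j] = stats.trim_mean(vals, trim)
    return out


def filter_expressed(expr: np.ndarray, rule: str = "mean_gt_zero",
                     cells: np.ndarray | None = None) -> np.ndarray:
    """Boolean gene mask of expressed genes over a cell group.

    ``mean_gt_zero``: group mean expression > 0 (the dataset-level
    detection rule); ``tpm_gt_one``: group mean normalized expression > 1
    (the ratio-analysis rule). These are the only built-in rules.
    """
    expr = np.asarray(expr, dtype=float)
    if cells is not None:
        expr = expr[:, np.asarray(cells, dtype=bool)]
    if expr.shape[1] == 0:
        raise ValueError("empty cell group")
    means = np.nanmean(expr, axis=1)
    if rule == "mean_gt_zero":
        return means > 0
    if rule == "tpm_gt_one":
        return means > 1
    raise ValueError(f"unknown expression rule {rule!r}")


def allelic_expression(acm: AllelicCountMatrix, zero_fill: bool = True
                       ) -> dict[str, np.ndarray]:
    """Normalized total and allelic expression layers for a dataset.

    Total counts are CPM-normalized (length-normalized TPM when the gene
    annotation provides lengths); allelic layers are the total scaled by
    per-gene-cell allelic ratios, with the zero-fill rule applied to the
    ratios' source counts first when ``zero_fill`` is set.
    """
    if "length" in acm.gene_annotation.columns and \
            acm.gene_annotation["length"].notna().all():
        total = tpm_from_lengths(acm.total, acm.gene_annotation["length"].to_numpy())
    else:
        total = counts_per_million(np.asarray(acm.total, dtype=float))
    work = fill_missing_allelic_matrix(acm) if zero_fill else acm
    ratios = allelic_ratio_matrix(work)
    maternal, paternal = scale_allelic_expression(total, ratios)
    # a zero total measurement is a zero allelic measurement, not missing
    zero_total = np.asarray(acm.total) == 0
    maternal[zero_total] = 0.0
    paternal[zero_total] = 0.0
    return {"total": total, "maternal": maternal, "paternal": paternal}
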