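"""Core data container for allele-resolved count matrices.

The central object is :class:`AllelicCountMatrix`: genes x cells count
matrices split by parental allele (maternal = C57 reference in the
C57xCAST cross, paternal = CAST), together with the total (allelic +
unassignable) counts and gene/cell annotation tables.

Allelic entries may be *undefined* (no informative reads covering a
strain polymorphism): these are stored as NaN in the float allelic
matrices and are distinct from an observed zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SEXES = ("XX", "XY", "XO")

#: XCI-state labels: each X allele is active (a), semi-inactive (s) or
#: inactive (i); maternal allele written first.
XCI_STATES = ("XaXa", "XaXs", "XaXi", "XsXa", "XiXa", "undetermined")


class ValidationError(ValueError):
    """Raised when matrices and annotations do not form a coherent dataset."""


@dataclass
class AllelicCountMatrix:
    """Genes x cells allelic count matrices plus annotations.

    Parameters
    ----------
    maternal, paternal
        Float arrays of shape (n_genes, n_cells). NaN marks an undefined
        allelic observation; all defined values are nonnegative counts.
    total
        Integer array of total counts, entrywise >= maternal + paternal
        where both alleles are defined (unassignable reads may exceed the
        allelic sum).
    gene_annotation
        Indexed by gene id. Required column ``chrom``; optional boolean
        columns ``escapee`` and ``xy_homolog``, optional ``length``.
    cell_annotation
        Indexed by cell id. Required column ``sex`` in {XX, XY, XO};
        optional ``lineage``, ``timepoint``, ``modality``.
    """

    maternal: np.ndarray
    paternal: np.ndarray
    total: np.ndarray
    gene_annotation: pd.DataFrame
    cell_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        self.maternal = np.asarray(self.maternal, dtype=float)
        self.paternal = np.asarray(self.paternal, dtype=float)
        self.total = np.asarray(self.total)
        self.validate()

    # -- basic properties -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.maternal.shape[0]

    @property
    def n_cells(self) -> int:
        return self.maternal.shape[1]

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_annotation.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_annotation.index

    def allele(self, which: str) -> np.ndarray:
        """Return the counts layer for ``maternal``, ``paternal`` or ``total``."""
        try:
            return {"maternal": self.maternal,
                    "paternal": self.paternal,
                    "total": self.total}[which]
        except KeyError:
            raise ValueError(f"unknown allele layer {which!r}") from None

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        shp = self.maternal.shape
        if self.paternal.shape != shp or self.total.shape != shp:
            raise ValidationError(
                f"matrix shapes disagree: maternal {self.maternal.shape}, "
                f"paternal {self.paternal.shape}, total {self.total.shape}")
        if len(self.gene_annotation) != shp[0]:
            raise ValidationError(
                f"gene annotation has {len(self.gene_annotation)} rows for "
                f"{shp[0]} genes")
        if len(self.cell_annotation) != shp[1]:
            raise ValidationError(
                f"cell annotation has {len(self.cell_annotation)} rows for "
                f"{shp[1]} cells")
        if "chrom" not in self.gene_annotation.columns:
            raise ValidationError("gene annotation lacks 'chrom' column")
        if "sex" not in self.cell_annotation.columns:
            raise ValidationError("cell annotation lacks 'sex' column")
        bad_sex = set(self.cell_annotation["sex"]) - set(SEXES)
        if bad_sex:
            raise ValidationError(f"unknown sex labels: {sorted(bad_sex)}")
        for name, arr in (("maternal", self.maternal), ("paternal", self.paternal)):
            vals = arr[~np.isnan(arr)]
            if vals.size and vals.min() < 0:
                raise ValidationError(f"negative counts in {name} matrix")
        if self.total.min() < 0:
            raise ValidationError("negative counts in total matrix")
        both = ~np.isnan(self.maternal) & ~np.isnan(self.paternal)
        if both.any():
            excess = (self.maternal + self.paternal)[both] - self.total[both]
            if excess.max() > 1e-9:
                raise ValidationError(
                    "maternal + paternal exceeds total counts for "
                    f"{int((excess > 1e-9).sum())} entries")
        chroms = set(self.gene_annotation["chrom"].astype(str))
        if "X" not in chroms:
            raise ValidationError("annotation contains no X-linked gene")
        if not (chroms - {"X", "Y", "MT"}):
            raise ValidationError("annotation contains no autosomal gene")

    # -- gene scopes ------------------------------------------------------

    def gene_mask(self, scope: str, exclude_escapees: bool = False,
                  exclude_xy_homologs: bool = False) -> np.ndarray:
        """Boolean mask over genes for a chromosome scope.

        ``scope`` is ``"X"``, ``"Y"`` or ``"autosomal"``. chrY and chrM
        never enter the X or autosomal scopes. Genes named/flagged Xist
        are excluded from the X scope (Xi-expressed, would invert ratios).
        """
        chrom = self.gene_annotation["chrom"].astype(str).to_numpy()
        if scope == "X":
            mask = chrom == "X"
            names = self.gene_annotation.index.astype(str).str.lower()
            mask &= np.asarray(names != "xist")
            if "is_xist" in self.gene_annotation.columns:
                mask &= ~self.gene_annotation["is_xist"].fillna(False).to_numpy(bool)
        elif scope == "Y":
            mask = chrom == "Y"
        elif scope == "autosomal":
            mask = ~np.isin(chrom, ("X", "Y", "MT"))
        else:
            raise ValueError(f"unknown scope {scope!r}")
        if exclude_escapees and "escapee" in self.gene_annotation.columns:
            mask &= ~self.gene_annotation["escapee"].fillna(False).to_numpy(bool)
        if exclude_xy_homologs and "xy_homolog" in self.gene_annotation.columns:
            mask &= ~self.gene_annotation["xy_homolog"].fillna(False).to_numpy(bool)
        return mask

    def copy(self) -> "AllelicCountMatrix":
        return AllelicCountMatrix(
            self.maternal.copy(), self.paternal.copy(), self.total.copy(),
            self.gene_annotation.copy(), self.cell_annotation.copy())


@dataclass
class GroundTruth:
    """True generative state of a simulated dataset.

    ``genes``: per-gene table with true kinetics per allele
    (k_on/k_off/k_syn), chromosome, escapee and homolog flags.
    ``cells``: per-cell table with sex, lineage, true silencing degree
    ``d`` and the identity of the silenced allele.
    """

    genes: pd.DataFrame
    cells: pd.DataFrame
    config: "object | None" = field(default=None, repr=False)
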