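"""Dataset serialization and configuration files.

On disk a dataset is a directory with one MatrixMarket file per layer
(``maternal.mtx``, ``paternal.mtx``, ``total.mtx``) plus ``genes.tsv``
and ``cells.tsv`` annotation tables, or equivalently wide TSV matrices
(``maternal.tsv`` ...) with gene rows and cell columns. Undefined
allelic entries are stored as -1 in the allelic layers (MatrixMarket
integer fields cannot carry NaN) and restored to NaN on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .data import AllelicCountMatrix, GroundTruth, ValidationError

_LAYERS = ("maternal", "paternal", "total")


def _encode_allelic(arr: np.ndarray) -> np.ndarray:
    out = np.array(arr, dtype=float)
    out[np.isnan(out)] = -1.0
    return out.astype(np.int64)


def _decode_allelic(arr: np.ndarray) -> np.ndarray:
    out = np.asarray(arr, dtype=float)
    out[out < 0] = np.nan
    return out


def write_dataset(acm: AllelicCountMatrix, outdir: str | Path,
                  fmt: str = "mtx") -> Path:
    """Write a dataset directory in MatrixMarket (``mtx``) or wide-TSV form."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layers = {"maternal": _encode_allelic(acm.maternal),
              "paternal": _encode_allelic(acm.paternal),
              "total": np.asarray(acm.total, dtype=np.int64)}
    for name, mat in layers.items():
        if fmt == "mtx":
            spio.mmwrite(outdir / f"{name}.mtx", sparse.coo_matrix(mat))
        elif fmt == "tsv":
            pd.DataFrame(mat, index=acm.gene_ids, columns=acm.cell_ids) \
                .to_csv(outdir / f"{name}.tsv", sep="\t")
        else:
            raise ValueError(f"unknown format {fmt!r}")
    acm.gene_annotation.to_csv(outdir / "genes.tsv", sep="\t")
    acm.cell_annotation.to_csv(outdir / "cells.tsv", sep="\t")
    return outdir


def read_dataset(path: str | Path) -> AllelicCountMatrix:
    """Read a dataset directory (either serialization dialect).

    Raises :class:`ValidationError` naming up to the first five offending
    identifiers when matrices and annotations disagree.
    """
    path = Path(path)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(path / "cells.tsv", sep="\t", index_col=0)
    layers = {}
    for name in _LAYERS:
        mtx, tsv = path / f"{name}.mtx", path / f"{name}.tsv"
        if mtx.exists():
            layers[name] = np.asarray(spio.mmread(mtx).todense())
        elif tsv.exists():
            df = pd.read_csv(tsv, sep="\t", index_col=0)
            bad = [g for g in df.index if g not in genes.index][:5]
            if bad or len(df) != len(genes):
                raise ValidationError(
                    f"{name}.tsv gene ids disagree with genes.tsv; "
                    f"first offenders: {bad or list(genes.index[:5])}")
            layers[name] = df.to_numpy()
        else:
            raise FileNotFoundError(f"no {name}.mtx or {name}.tsv under {path}")
    shape = layers["total"].shape
    if shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix shape {shape} does not match {len(genes)} genes x "
            f"{len(cells)} cells; first gene ids: {list(genes.index[:5])}")
    return AllelicCountMatrix(
        _decode_allelic(layers["maternal"]), _decode_allelic(layers["paternal"]),
        layers["total"].astype(np.int64), genes, cells)


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t")
    truth.cells.to_csv(outdir / "truth_cells.tsv", sep="\t")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_config_echo(config_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    return loaded


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str,
                index: bool = True) -> None:
    """Write a tidy TSV result table stamped with the run's config hash."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)
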