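"""Generate the reference synthetic populations used by the downstream
analyses and write them as dataset directories under results/.

Scenarios: naive biallelic females (no XCI), graded random XCI (the
tuning scenario), an Xist-knockout population that never initiates XCI,
and a mixed-sex population with imprinted XCI.
"""

from pathlib import Path

from xdosage import SimulationConfig, simulate_population, write_dataset
from xdosage.io import write_config_echo, write_ground_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "datasets"

SCENARIOS = {
    "naive_xaxa": SimulationConfig(n_cells=300, xci_mode="none", seed=10),
    "graded_rxci": SimulationConfig(n_cells=400, xci_mode="random", seed=11),
    "xist_knockout": SimulationConfig(n_cells=300, xci_mode="knockout", seed=12),
    "mixed_sex_ixci": SimulationConfig(
        n_cells=400, sex_mix=(0.5, 0.4, 0.1), xci_mode="imprinted",
        n_xy_homologs=8, xci_degree=("point", 1.0), seed=13),
}


def main() -> None:
    for name, cfg in SCENARIOS.items():
        acm, truth = simulate_population(cfg)
        outdir = OUT / name
        write_dataset(acm, outdir)
        write_ground_truth(truth, outdir)
        write_config_echo(cfg.to_dict(), outdir / "config.yaml")
        depth = acm.total.sum(axis=0).mean()
        print(f"{name}: {acm.n_genes} genes x {acm.n_cells} cells, "
              f"mean depth {depth:,.0f}")


if __name__ == "__main__":
    main()
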