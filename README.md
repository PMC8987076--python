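# xdosage

Allele-resolved analysis of X-chromosome dosage compensation in
single-cell RNA-seq data: per-cell X-inactivation (XCI) state calling,
quantification of elastic X-upregulation (XCU), tuning-model regression
and transcriptional burst-kinetics inference — plus a fully
ground-truthed synthetic data generator so the entire pipeline can be
exercised and validated without any external datasets.

## The scientific problem

Female mammalian cells silence one X chromosome (XCI) while both sexes
hyperactivate the remaining active X allele (XCU) to balance X dosage
against diploid autosomes. Total (nonallelic) expression measurements
cannot separate the two processes: silencing of one allele and
upregulation of the other cancel at the chromosome level. With
allele-resolved counts from a hybrid cross (maternal C57 x paternal
CAST), the two effects can be measured per allele and per cell:

* **Allelic reference ratio** — per cell, the maternal share of
  allelically informative X-linked counts,
  `r = sum(maternal) / sum(maternal + paternal)`, computed after
  excluding the top 10% expressed X genes in that cell. Cells are
  classed by `r` into XCI states: XaXa for `r` in (0.4, 0.6), XaXs for
  [0.6, 0.9), XaXi for r >= 0.9, and the mirrored XsXa / XiXa states.
  XCI completion is `|0.5 - r| / 0.5`.
* **Same-active-allele fold change** — pseudobulk, gene-wise expression
  of the *same* allele compared between XCI-state groups; the direct
  measurement of XCU on the active X.
* **Tuning regression** — per-cell trimmed-mean allelic X expression
  regressed on the cell's maternal X-fraction. A linear relationship
  with opposite slopes per allele is the signature of *elastic* XCU:
  upregulation proportional to the degree of silencing on the other
  allele, not an on/off switch.
* **Burst kinetics** — per-gene allelic counts are fit with the
  two-state (telegraph) model whose stationary distribution is
  Poisson-Beta: `x ~ Poisson(k_syn * B)`, `B ~ Beta(k_on, k_off)` (rates
  per mRNA degradation event). Burst frequency is `k_on`, burst size
  `k_syn / k_off`. XCU manifests as increased burst frequency at
  unchanged burst size.

The generator simulates all of this forward: per-gene telegraph
transcription with log-normal kinetics, per-cell silencing degree `d`
(imprinted or random XCI with Xce-like strain skew), elastic gain
`1 + (phi - 1) d` on the active allele's burst frequency, escapee genes,
X-Y homolog pairs, XX/XY/XO genotypes, an Xist-knockout mode, binomial
depth thinning and allelic misassignment — returning complete ground
truth for every cell and gene.

## Worked example

```python
from xdosage import (SimulationConfig, simulate_population,
                     same_allele_fold_change, tuning_fit)
from xdosage.allelic import allelic_expression, cell_states

cfg = SimulationConfig(
    n_cells=1000, xci_mode="imprinted",
    xci_degree=("mixture", ((0.5, ("point", 0.0)), (0.5, ("point", 1.0)))),
    seed=21)
acm, truth = simulate_population(cfg)

layers = allelic_expression(acm)   # CPM total + allelic expression layers
states = cell_states(acm)          # per-cell ratio, XCI state, completion
print(states["xci_state"].value_counts().to_dict())

in_a = (states["xci_state"] == "XaXa").to_numpy()
in_b = (states["xci_state"] == "XaXi").to_numpy()
fc = same_allele_fold_change(layers["maternal"], acm, in_a, in_b)
print(f"X-gene median fold: {fc.x_median:.2f}  "
      f"autosomal: {fc.autosomal_median:.2f}  Wilcoxon p: {fc.wilcoxon_p:.1e}")

fit = tuning_fit(layers["maternal"], acm, states["ratio"].to_numpy())
print(f"tuning slope {fit.slope:+.0f}, adjusted R^2 {fit.adj_r_squared:.2f}")
```

prints

```
{'XaXi': 530, 'XaXa': 470}
X-gene median fold: 1.46  autosomal: 1.04  Wilcoxon p: 6.4e-33
tuning slope +139, adjusted R^2 0.84
```

Half the simulated cells completed XCI and are called XaXi; the
maternal (active) allele of X-linked genes rises ~1.5-fold from the
biallelic XaXa state into XaXi while autosomal genes stay flat (the
small autosomal shift is library-depth reallocation after one X allele
goes quiet), and allelic X dosage tracks the maternal X-fraction
linearly — elastic tuning. The fold sits below the generator's
`phi = 1.6` because a burst-frequency gain saturates the telegraph
stationary mean; see `docs/methods.md`.

## Command line and analysis scripts

Every stage is also a CLI subcommand over dataset directories
(MatrixMarket or TSV matrices plus annotation tables):

```sh
xdosage simulate --out data/sim --seed 3
xdosage classify data/sim --out states.tsv
xdosage foldchange data/sim --group-a XaXa --group-b XaXi --allele maternal
xdosage tuning data/sim
xdosage kinetics data/sim --min-cells 21
xdosage run --config pipeline.yaml     # full pipeline + JSON manifest
```

The numbered scripts under `analysis/` run the complete study on
synthetic data — `01` simulates the scenario populations, `02` calls
XCI states, `03` measures the XCU fold change, `04` fits the tuning
model and escapee comparison, `05` infers burst kinetics and the
frequency-not-size signature, `06` calibrates the dilution series —
each printing its findings and writing tables under `results/`.

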