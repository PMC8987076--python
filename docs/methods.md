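# Methods

## Model

Transcription of each gene copy follows the two-state (telegraph)
model: the promoter switches on at rate `k_on`, off at rate `k_off`,
and synthesizes mRNA at rate `k_syn` while on; transcripts decay at
rate 1, which fixes the time unit — static counts identify rates only
relative to mRNA turnover. The stationary count distribution is
Poisson-Beta,

    x ~ Poisson(k_syn * B),   B ~ Beta(k_on, k_off),

with mean `k_syn * k_on / (k_on + k_off)`, burst frequency `k_on` and
burst size `k_syn / k_off`.

X-chromosome regulation is layered on top per cell. A female (XX) cell
carries a silencing degree `d in [0, 1]` on one X allele; the silenced
allele's burst frequency is scaled by `(1 - d)` (an exponent on
`(1 - d)` is exposed for asymmetric-loss experiments, default 1), and
the opposite, active allele gains `1 + (phi - 1) * d` on burst
frequency — elastic upregulation proportional to silencing, with
`phi = 1.6` at completion. XY and XO cells lack the paternal X
structurally and carry the full gain `phi` on their single X (toggleable),
except X-Y ancestral homolog genes, whose active Y copy already
balances dosage and which therefore receive no gain in males. Escapee
genes stay biallelic and unscaled. In the knockout mode (Xist ablation)
`d = 0` everywhere, so no silencing and — because the gain is a
function of `d` — no female upregulation either: hyperactivation only
ever arises as a response to dosage imbalance.

A deliberate consequence of placing the gain on burst frequency is that
the *expression* fold of the active allele is
`phi (k_on + k_off) / (phi k_on + k_off) < phi`: the telegraph mean
saturates in `k_on`. At the default priors the median X-gene expression
fold at `phi = 1.6` is about 1.49 before, and about 1.5 after,
depth-normalization effects. A config switch (`xcu_on="burst_size"`)
scales `k_syn` instead, which is linear in the mean; it exists for
negative controls — e.g. with `phi = 2` and full silencing it conserves
total X output exactly, the cleanest setting for demonstrating that
nonallelic X:A ratios mask allelic tuning.

## Generator defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| `n_genes_autosomal`, `n_genes_x` | 2000, 200 | order of detected genes in deep single-cell data, at the X/autosome proportion of the mouse genome |
| `kinetics_priors` (median, log10-sd) | k_on 0.7, k_off 5, k_syn 20; sd 0.4 | log-normal rates yielding sparse, bursty UMI-scale counts (per-gene-allele means ~1-10) |
| `xcu_fold` (phi) | 1.6 | the observed magnitude of X-upregulation at the RNA level |
| `escapee_fraction` | 0.05 | minority of X genes biallelic under XCI |
| `xce_skew` | 0.42 | probability the maternal (C57) allele is silenced under random XCI; the direction (preferential C57 inactivation) is established, the magnitude is a documented placeholder, not a measured value |
| `xci_degree` | uniform(0, 1) | asynchronously progressing random XCI across a population |
| `depth_target` | 10,000 | realistic UMI count per cell; thinning is binomial per entry (read subsampling), requiring the raw simulated output (~13k at defaults) to exceed it |
| `misassignment_rate` | 0 | allelic read misassignment available as noise, off by default |

All draws flow from one seeded generator in documented order (gene
kinetics, escapee choice; cell sex, silenced allele, degree; maternal
counts, paternal counts; misassignment; thinning), so identical config
and seed are bit-identical.

What the generator does **not** emulate: gene length and positional
effects (normalized expression is counts-per-million; length-normalized
TPM is used only when the annotation supplies lengths), cell-cycle and
doublet artifacts, technical dropout beyond binomial thinning,
unassignable reads (simulated totals always equal maternal + paternal),
and any spatial or pseudotemporal structure. Passing tests therefore
demonstrate correctness of the estimators under the stated generative
model, not robustness to every artifact of real libraries.

## Estimators

**Reference ratio and XCI state.** Per cell, summed maternal over
summed allelic counts across informative X genes (counts, not a mean of
per-gene ratios), after removing the top 10% of informative genes
ranked by that cell's total expression within the scope — the ranking
is per cell, and `floor(0.1 n)` genes are removed. Cells with fewer
than 10 informative X genes are undetermined. Interval boundaries are
half-open exactly as stated above (`r = 0.6` is XaXs, `r = 0.4` XsXa).
chrY and chrM genes never enter X or autosomal scopes; a gene named or
flagged Xist is excluded from the X scope since it is expressed from
the *inactive* allele.

**Allelic expression.** Total counts are CPM-normalized; allelic layers
are total times the per-gene-cell allelic ratio, after the zero-fill
rule (an undefined allelic value becomes 0 iff the other allele is
detected; both-undefined stays undefined). A zero total is a zero
allelic measurement, not a missing one — leaving it undefined would
condition pseudobulk means on detection and bias fold changes upward at
UMI sparsity.

**Dosage statistics.** X:A ratios aggregate expressed genes
(`mean CPM > 1` by default) per cell and divide by the autosomal
aggregate; the default aggregator is the median, with `mean` for
binary-like accessibility scores and a 20% `trimmed_mean` for sparse
allelic layers, where per-cell medians of small integer counts
degenerate. The bootstrap background draws 1000 random autosomal gene
sets of the X-set's size; note the X panel itself is a single draw from
(approximately) that background distribution, so single-dataset
exceedance claims carry panel-level luck — comparisons should pool
panels or contrast cell groups within one panel. Fold changes are
pseudobulk per-gene mean ratios between XCI-state groups of at least
21 cells, with escapees excluded and a one-sample Wilcoxon signed-rank
test on X-gene log2 folds (a size-matched X-vs-autosome Mann-Whitney
variant is provided). The tuning fit is OLS of per-cell 20% trimmed-mean
allelic X expression on the maternal X-fraction, with per-gene Pearson
correlations; escapees vs other X genes are compared on those
correlations by a two-sample Kolmogorov-Smirnov test. All group
summaries are medians with percentile-bootstrap 95% CIs (1000
resamples, seeded).

**Kinetics.** The Poisson-Beta likelihood marginalizes promoter
activity by fixed-order Gauss-Jacobi quadrature (order 50), which
absorbs the Beta endpoint singularities into the quadrature weight; the
pmf is exactly normalized by construction. Maximization uses bounded
Nelder-Mead in log10 space (`k_on, k_off` in [1e-3, 1e3], `k_syn` in
[1, 1e4]) from a factorial-moment start, with a generic fallback when
moments are ill-posed; given counts, the fit is deterministic. Fits are
filtered on convergence, bound-hitting, expected expression >= 0.01 and
group size > 20 cells. Per-gene estimates sit on a flat `k_off`/`k_syn`
likelihood ridge (a fitted point can beat the truth in likelihood at
n = 5000 cells), so single-gene burst-size estimates carry ~15%
sampling spread; group statistics therefore use medians over gene
panels relative to each group's autosomal medians, compared across
groups by Mann-Whitney with Benjamini-Hochberg correction.

## Numerical and design choices

* Allele labels are metadata ("maternal" is the C57 reference of the
  cross); every statistic is label-symmetric.
* Ties and boundaries: interval endpoints as above; the top-10%
  exclusion uses a stable sort so ties resolve deterministically.
* Degenerate inputs return flagged, undefined-with-reason results
  (never exceptions) wherever the spec of the operation is statistical:
  all-zero genes, undetermined cells, zero autosomal aggregates,
  degenerate regressors.
* The dilution-series generator draws per-gene abundances once
  (log-normal, 1 dex), then multinomial reads per sample and binomial
  allelic splits at the spiked fraction — recovery is limited purely by
  counting noise, matching its role as a calibration benchmark.
* Problem sizes in tests and analysis scripts (e.g. 2200 genes x 1000
  cells x 20 seeds for fold-change recovery; 320 genes x 3000 cells for
  the kinetic signature) were chosen as the smallest designs at which
  the respective group statistics are stable, as documented above.

## Known limitations

* Rates are identified only relative to mRNA decay; comparisons across
  groups assume equal decay (supported for X vs autosomes in
  expression-matched transcripts, but an assumption here).
* The linear-in-`d` silencing and gain forms are modeling choices; the
  within-cell functional form of partial silencing is not established.
* Per-gene kinetic confidence intervals are out of scope; only
  group-level bootstrap CIs are reported.
* The classifier's interval rules inherit the reference ratio's
  sampling noise: near-boundary cells (e.g. `d` near 0.2) are assigned
  stochastically between adjacent states at realistic depth.
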