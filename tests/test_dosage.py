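"""X:A ratios, bootstrap backgrounds, fold changes, tuning regression,
escapee/homolog tests, female:male ratios and bootstrap summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xdosage import (SimulationConfig, analytic_allelic_mean,
                     bootstrap_xa_ratio, escapee_tuning_test,
                     female_male_ratio, group_summary, homolog_dosage_test,
                     same_allele_fold_change, simulate_population, tuning_fit,
                     xa_ratio)
from xdosage.allelic import allelic_expression, cell_states
from xdosage.data import AllelicCountMatrix


def _expr_matrix(x_values, auto_values):
    """Constant-per-gene expression with given X and autosomal levels."""
    n_cells = 3
    vals = np.concatenate([x_values, auto_values])
    expr = np.tile(vals[:, None], (1, n_cells))
    genes = pd.DataFrame(
        {"chrom": ["X"] * len(x_values) + ["1"] * len(auto_values)},
        index=[f"g{i}" for i in range(len(vals))])
    cells = pd.DataFrame({"sex": ["XX"] * n_cells},
                         index=[f"c{i}" for i in range(n_cells)])
    acm = AllelicCountMatrix(expr, expr, 2 * expr, genes, cells)
    return expr, acm


class TestXaRatio:
    def test_toy_arithmetic(self):
        expr, acm = _expr_matrix(np.full(25, 5.0), np.full(40, 10.0))
        ratios = xa_ratio(expr, acm, min_genes=20)
        assert np.allclose(ratios, 0.5)

    def test_exchangeable_genes_give_unity(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(2, 50, 600)
        expr, acm = _expr_matrix(vals[:200], vals[200:])
        ratios = xa_ratio(expr, acm)
        assert np.allclose(ratios, np.median(vals[:200]) / np.median(vals[200:]))
        assert np.nanmedian(ratios) == pytest.approx(1.0, abs=0.15)

    def test_single_x_male_matches_generator_means(self):
        """An XY cell's allelic X:A under full XCU approaches the analytic
        ratio of upregulated-X to per-allele autosomal telegraph means
        (mean aggregation: per-cell medians of small counts are discrete)."""
        cfg = SimulationConfig(n_cells=300, n_genes_autosomal=800,
                               n_genes_x=150, escapee_fraction=0.0,
                               sex_mix=(0.0, 1.0, 0.0), xci_mode="none",
                               depth_target=1e9, seed=9)
        acm, truth = simulate_population(cfg)
        g = truth.genes
        mat = np.asarray(acm.maternal, float)
        expected_x = np.mean([
            analytic_allelic_mean(r.k_on, r.k_off, r.k_syn, 1.0, cfg.xcu_fold,
                                  "active")
            for r in g[g.chrom == "X"].itertuples()])
        expected_a = np.mean([
            analytic_allelic_mean(r.k_on, r.k_off, r.k_syn)
            for r in g[g.chrom != "X"].itertuples()])
        ratios = xa_ratio(mat, acm, aggregation="mean",
                          expression_rule="mean_gt_zero")
        assert np.nanmedian(ratios) == pytest.approx(expected_x / expected_a,
                                                     rel=0.05)

    def test_unknown_aggregation_errors(self):
        expr, acm = _expr_matrix(np.full(25, 5.0), np.full(40, 10.0))
        with pytest.raises(ValueError, match="aggregation"):
            xa_ratio(expr, acm, aggregation="mode")


class TestBootstrapXaRatio:
    def test_background_median_near_one(self):
        rng = np.random.default_rng(3)
        vals = rng.gamma(2, 50, 800)
        expr, acm = _expr_matrix(vals[:100], vals[100:])
        out = bootstrap_xa_ratio(expr, acm, 0, n_boot=500, seed=0)
        assert out["background_median"] == pytest.approx(1.0, abs=0.1)

    def test_xcu_cells_exceed_background(self):
        """Allelic X:A of fully inactivated cells lies above the autosomal
        background's 97.5% quantile in the majority of cells. The X gene
        panel is a single draw whose level the background is built to
        calibrate, so cells are pooled over independent panels."""
        n_above = n_cells = 0
        for seed in range(300, 306):
            cfg = SimulationConfig(n_cells=30, xci_mode="random",
                                   xci_degree=("point", 1.0), seed=seed)
            acm, _ = simulate_population(cfg)
            layers = allelic_expression(acm)
            states = cell_states(acm)
            xaxi = np.flatnonzero((states["xci_state"] == "XaXi").to_numpy())
            for j in xaxi:
                out = bootstrap_xa_ratio(layers["maternal"], acm, int(j),
                                         n_boot=200,
                                         aggregation="trimmed_mean", seed=1)
                n_above += out["observed"] > out["background_q975"]
                n_cells += 1
        assert n_cells >= 60
        assert n_above > n_cells / 2

    def test_insufficient_autosomal_errors(self):
        expr, acm = _expr_matrix(np.full(50, 5.0), np.full(30, 5.0))
        with pytest.raises(ValueError, match="autosomal"):
            bootstrap_xa_ratio(expr, acm, 0)


class TestFoldChange:
    def test_identity_groups_give_unit_folds(self, small_random_xci):
        acm, _ = small_random_xci
        layers = allelic_expression(acm)
        cells = np.zeros(acm.n_cells, bool)
        cells[:50] = True
        fc = same_allele_fold_change(layers["maternal"], acm, cells, cells,
                                     min_cells=20)
        ok = fc.per_gene["fold"].dropna()
        assert np.allclose(ok, 1.0)
        assert fc.x_median == pytest.approx(1.0)

    def test_no_xcu_control_is_flat(self):
        cfg = SimulationConfig(
            n_cells=500, n_genes_autosomal=800, n_genes_x=150, xcu_fold=1.0,
            xci_mode="imprinted",
            xci_degree=("mixture", ((0.5, ("point", 0.0)),
                                    (0.5, ("point", 1.0)))),
            seed=12)
        acm, _ = simulate_population(cfg)
        layers = allelic_expression(acm)
        states = cell_states(acm)
        in_a = (states["xci_state"] == "XaXa").to_numpy()
        in_b = (states["xci_state"] == "XaXi").to_numpy()
        fc = same_allele_fold_change(layers["maternal"], acm, in_a, in_b)
        # losing one X allele without compensation reallocates library depth,
        # shifting X and autosomal folds by the same factor: their ratio is 1
        assert fc.x_median / fc.autosomal_median == pytest.approx(1.0, abs=0.06)

    def test_recovers_analytic_fold_under_xcu(self, small_random_xci):
        """Measured X-gene median fold matches the closed-form prediction
        from the generator's own kinetics (the independent oracle)."""
        acm, truth = small_random_xci
        layers = allelic_expression(acm)
        states = cell_states(acm)
        in_a = (states["xci_state"] == "XaXa").to_numpy()
        in_b = (states["xci_state"] == "XaXi").to_numpy()
        fc = same_allele_fold_change(layers["maternal"], acm, in_a, in_b)
        g = truth.genes
        xg = g[(g.chrom == "X") & ~g.escapee]
        predicted = np.median([
            analytic_allelic_mean(r.k_on, r.k_off, r.k_syn, 1.0, 1.6, "active")
            / analytic_allelic_mean(r.k_on, r.k_off, r.k_syn, 0.0, 1.6, "active")
            for r in xg.itertuples()])
        assert fc.x_median == pytest.approx(predicted, rel=0.08)
        assert fc.autosomal_median == pytest.approx(1.0, abs=0.06)
        assert fc.wilcoxon_p < 1e-6

    def test_small_group_errors_with_name(self, small_random_xci):
        acm, _ = small_random_xci
        layers = allelic_expression(acm)
        few = np.zeros(acm.n_cells, bool)
        few[:5] = True
        many = ~few
        with pytest.raises(ValueError, match="XaXa"):
            same_allele_fold_change(layers["maternal"], acm, few, many)


class TestTuningFit:
    def test_noiseless_linear_relationship(self):
        rng = np.random.default_rng(0)
        n_cells, n_x, n_auto = 60, 30, 40
        frac = np.linspace(0.05, 0.95, n_cells)
        genes = pd.DataFrame({"chrom": ["X"] * n_x + ["1"] * n_auto},
                             index=[f"g{i}" for i in range(n_x + n_auto)])
        cells = pd.DataFrame({"sex": ["XX"] * n_cells},
                             index=[f"c{i}" for i in range(n_cells)])
        expr = np.vstack([np.tile(10 + 20 * frac, (n_x, 1)),
                          rng.gamma(5, 2, (n_auto, n_cells))])
        acm = AllelicCountMatrix(expr, expr, 2 * expr, genes, cells)
        fit = tuning_fit(expr, acm, frac)
        assert fit.adj_r_squared > 0.999
        assert fit.slope == pytest.approx(20.0, rel=1e-6)
        assert (fit.gene_correlations.dropna() > 0.99).all()

    def test_opposite_slopes_per_allele(self, graded_rxci):
        acm, _ = graded_rxci
        layers = allelic_expression(acm)
        frac = cell_states(acm)["ratio"].to_numpy()
        fm = tuning_fit(layers["maternal"], acm, frac, allele="maternal")
        fp = tuning_fit(layers["paternal"], acm, frac, allele="paternal")
        assert fm.slope > 0 > fp.slope
        assert fm.adj_r_squared > 0.5 and fp.adj_r_squared > 0.5

    def test_shuffled_fraction_has_no_signal(self, graded_rxci):
        acm, _ = graded_rxci
        layers = allelic_expression(acm)
        frac = cell_states(acm)["ratio"].to_numpy()
        rng = np.random.default_rng(99)
        fit = tuning_fit(layers["maternal"], acm, rng.permutation(frac))
        assert fit.adj_r_squared <= 0.05

    def test_degenerate_fraction_flagged(self, graded_rxci):
        acm, _ = graded_rxci
        layers = allelic_expression(acm)
        fit = tuning_fit(layers["maternal"], acm,
                         np.full(acm.n_cells, 0.5))
        assert not fit.defined
        assert "degenerate" in fit.reason


class TestEscapeeTuning:
    def test_random_flags_are_null(self, graded_rxci):
        acm, _ = graded_rxci
        layers = allelic_expression(acm)
        frac = cell_states(acm)["ratio"].to_numpy()
        fit = tuning_fit(layers["maternal"], acm, frac)
        rng = np.random.default_rng(5)
        flags = pd.Series(rng.random(len(fit.gene_correlations)) < 0.2,
                          index=fit.gene_correlations.index)
        out = escapee_tuning_test(fit, flags)
        assert out["p_value"] > 0.01

    def test_true_escapees_match_other_genes(self, graded_rxci):
        """Escapees simulated to tune like other X genes: no detectable
        difference (the null result on real data)."""
        acm, truth = graded_rxci
        layers = allelic_expression(acm)
        frac = cell_states(acm)["ratio"].to_numpy()
        fit = tuning_fit(layers["total"], acm, frac)
        flags = truth.genes["escapee"]
        out = escapee_tuning_test(fit, flags)
        assert out["p_value"] > 0.05

    def test_flat_escapees_detected(self):
        """Escapees simulated as non-tuning separate clearly in the
        gene-wise correlation distributions (power check)."""
        rng = np.random.default_rng(7)
        cors_tuning = rng.uniform(0.5, 0.95, 100)
        cors_flat = rng.normal(0.0, 0.1, 20)
        from xdosage.dosage import TuningFit
        fit = TuningFit("maternal", 1, 0, 0.9, 1e-10, 100,
                        pd.Series(np.concatenate([cors_tuning, cors_flat]),
                                  index=[f"g{i}" for i in range(120)]))
        flags = pd.Series([False] * 100 + [True] * 20, index=fit.gene_correlations.index)
        out = escapee_tuning_test(fit, flags)
        assert out["p_value"] < 1e-6

    def test_too_few_escapees_flagged(self, graded_rxci):
        acm, _ = graded_rxci
        layers = allelic_expression(acm)
        frac = cell_states(acm)["ratio"].to_numpy()
        fit = tuning_fit(layers["maternal"], acm, frac)
        flags = pd.Series(False, index=fit.gene_correlations.index)
        flags.iloc[0] = True
        out = escapee_tuning_test(fit, flags)
        assert np.isnan(out["p_value"]) and "escapee" in out["reason"]


class TestHomologDosage:
    def test_symmetric_null(self):
        rng = np.random.default_rng(1)
        out = homolog_dosage_test({"males": 0.5 + rng.normal(0, 0.05, 80)})
        assert out.loc["males", "p_value"] > 0.05

    def test_female_xcu_detected(self):
        rng = np.random.default_rng(2)
        ratios = 0.75 + rng.normal(0, 0.1, 200)
        out = homolog_dosage_test({"females": ratios})
        assert out.loc["females", "p_value"] < 1e-6
        assert out.loc["females", "median_ratio"] > 0.5

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            homolog_dosage_test({})


class TestFemaleMale:
    def _mixed_population(self, xci_degree, seed):
        cfg = SimulationConfig(n_cells=600, n_genes_autosomal=700,
                               n_genes_x=150, escapee_fraction=0.0,
                               sex_mix=(0.5, 0.5, 0.0), xci_mode="imprinted",
                               xci_degree=xci_degree, seed=seed)
        return simulate_population(cfg)

    def test_xaxa_females_vs_males_match_generator_means(self):
        """Biallelic females against upregulated single-X males: the X-gene
        ratio equals the closed-form 2 m(k) / m(phi-scaled k) per gene."""
        acm, truth = self._mixed_population(("point", 0.0), seed=14)
        layers = allelic_expression(acm)
        tbl = female_male_ratio(layers["total"], acm)
        g = truth.genes
        xg = g[g.chrom == "X"]
        predicted = np.median([
            2 * analytic_allelic_mean(r.k_on, r.k_off, r.k_syn)
            / analytic_allelic_mean(r.k_on, r.k_off, r.k_syn, 1.0, 1.6,
                                    "active")
            for r in xg.itertuples()])
        x_med = tbl[tbl.scope == "X"]["ratio"].median()
        auto_med = tbl[tbl.scope == "autosomal"]["ratio"].median()
        assert x_med == pytest.approx(predicted, rel=0.1)
        assert auto_med == pytest.approx(1.0, abs=0.05)

    def test_inactivated_females_vs_males_balanced(self):
        """Fully inactivated females and males are both monoallelic
        hyperactive: X-gene female:male ratio near 1."""
        acm, _ = self._mixed_population(("point", 1.0), seed=15)
        layers = allelic_expression(acm)
        tbl = female_male_ratio(layers["total"], acm)
        x_med = tbl[tbl.scope == "X"]["ratio"].median()
        assert x_med == pytest.approx(1.0, abs=0.1)

    def test_missing_sex_reported(self):
        cfg = SimulationConfig(n_cells=80, n_genes_autosomal=150,
                               n_genes_x=40, sex_mix=(1.0, 0.0, 0.0), seed=2)
        acm, _ = simulate_population(cfg)
        layers = allelic_expression(acm)
        tbl = female_male_ratio(layers["total"], acm)
        assert tbl["ratio"].isna().all()
        assert (tbl["reason"] == "a sex is missing in this group").all()


class TestGroupSummary:
    def test_constant_input_zero_width(self):
        out = group_summary(np.full(20, 3.3), seed=0)
        assert out["point"] == out["ci_lower"] == out["ci_upper"] == 3.3

    def test_two_point_sample_endpoints_enumerable(self):
        out = group_summary(np.array([1.0, 9.0, 1.0]), seed=1)
        boot_support = {1.0, 5.0, 9.0}
        assert out["ci_lower"] in boot_support and out["ci_upper"] in boot_support

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            group_summary(np.array([]))

    def test_reproducible_under_seed(self):
        vals = np.random.default_rng(0).normal(size=50)
        assert group_summary(vals, seed=11) == group_summary(vals, seed=11)
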