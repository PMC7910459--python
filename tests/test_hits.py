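"""The dual t/RRA test, multiple-testing handling, filters, validation
assay arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pairscreen as ps
from pairscreen.hits import (EssentialGeneSet, adjust_and_call,
                             call_single_gene_depletion,
                             competitive_assay_residual, filter_hits,
                             pair_t_test, pair_t_table)


class TestPairT:
    def test_symmetric_residuals_give_zero(self):
        t, p = pair_t_test([-1.0, 0.0, 1.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_variance_flagged_not_raised(self):
        t, p = pair_t_test([-1.0, -1.0, -1.0, -1.0])
        assert np.isnan(t) and np.isnan(p)
        t, p = pair_t_test([0.5, -0.5])  # n < 3
        assert np.isnan(t)

    def test_matches_brute_force_formula(self):
        """t equals mean/sqrt(var/(n-1)) with unbiased variance, to 1e-12,
        on random vectors; p is two-sided with n-1 df."""
        rng = np.random.default_rng(8)
        for n in (3, 10, 225):
            for _ in range(20):
                r = rng.normal(-0.3, 1.2, n)
                t, p = pair_t_test(r)
                mean = sum(r) / n
                var = sum((x - mean) ** 2 for x in r) / (n - 1)
                t_ref = mean / np.sqrt(var / (n - 1))
                assert t == pytest.approx(t_ref, abs=1e-12)
                assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), n - 1),
                                          abs=1e-12)

    def test_relation_to_conventional_one_sample_t(self):
        """The printed statistic is the conventional t shrunk by
        sqrt((n-1)/n) — the var/(n-1) denominator is slightly
        conservative."""
        rng = np.random.default_rng(9)
        r = rng.normal(0, 1, 50)
        t, _ = pair_t_test(r)
        t_conv = stats.ttest_1samp(r, 0.0).statistic
        assert t == pytest.approx(t_conv * np.sqrt(49 / 50), rel=1e-12)

    def test_null_p_values_uniform_monte_carlo(self):
        """On iid N(0,1) residual sets (n=225, 10,000 repeats) the p-values
        are uniform by KS once the statistic is rescaled to its exact
        null (the n-1 denominator shrinks t by sqrt((n-1)/n))."""
        rng = np.random.default_rng(10)
        n, reps = 225, 10_000
        X = rng.normal(size=(reps, n))
        mean = X.mean(axis=1)
        var = X.var(axis=1, ddof=1)
        t_paper = mean / np.sqrt(var / (n - 1))
        t_exact = t_paper * np.sqrt(n / (n - 1))
        p = 2 * stats.t.sf(np.abs(t_exact), n - 1)
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestAdjustAndCall:
    def _tables(self, t_p, rra_p, means=None):
        idx = [f"P{i}" for i in range(len(t_p))]
        means = means if means is not None else [-1.0] * len(t_p)
        t = pd.DataFrame({"n_residuals": 100, "mean_adjusted_residual": means,
                          "t_stat": -5.0, "t_p": t_p},
                         index=pd.Index(idx, name="gene_pair"))
        r = pd.DataFrame({"n": 100, "k": 10, "rho": 0.01, "p": rra_p},
                         index=pd.Index(idx, name="gene_pair"))
        return t, r

    def test_bonferroni_arithmetic(self):
        t, r = self._tables([0.0005] + [0.5] * 99, [0.0001] + [0.5] * 99)
        out = adjust_and_call(t, r)
        assert out.loc[0, "t_p_adj"] == pytest.approx(0.05)
        assert bool(out.loc[0, "is_hit"])

    def test_single_test_significance_is_not_a_hit(self):
        t, r = self._tables([0.5, 0.00001], [0.00001, 0.5])
        out = adjust_and_call(t, r)
        assert not out["is_hit"].any()
        assert bool(out.loc[0, "significant_rra"])
        assert bool(out.loc[1, "significant_t"])

    def test_positive_mean_blocks_hit(self):
        t, r = self._tables([1e-6], [1e-6], means=[+0.5])
        out = adjust_and_call(t, r)
        assert not out["is_hit"].any()

    def test_m_equal_one_adjustment_is_identity(self):
        t, r = self._tables([0.03], [0.04])
        out = adjust_and_call(t, r)
        assert out.loc[0, "t_p_adj"] == pytest.approx(0.03)
        assert out.loc[0, "rra_p_adj"] == pytest.approx(0.04)

    def test_insufficient_residuals_flagged(self):
        t, r = self._tables([np.nan, 0.001], [0.001, 0.001])
        out = adjust_and_call(t, r)
        assert out.loc[0, "filter_reason"] == "insufficient_residuals"
        assert not bool(out.loc[0, "is_hit"])

    def test_mismatched_universe_rejected(self):
        t, r = self._tables([0.5], [0.5])
        r.index = pd.Index(["OTHER"], name="gene_pair")
        with pytest.raises(ValueError, match="universe"):
            adjust_and_call(t, r)


class TestEssentialFilter:
    def test_hit_with_essential_member_filtered(self):
        results = pd.DataFrame({
            "gene_pair": ["AKT1|AKT2", "CNOT7|CNOT8"],
            "n_residuals": 100, "mean_adjusted_residual": -1.0,
            "t_stat": -8.0, "t_p": 1e-8, "t_p_adj": 1e-6,
            "rra_rho": 0.001, "rra_p": 1e-4, "rra_p_adj": 1e-2,
            "significant_t": True, "significant_rra": True,
            "is_hit": True, "filter_reason": "none"})
        ess = EssentialGeneSet({"AKT1": "internal_day14"})
        out = filter_hits(results, ess)
        assert not bool(out.loc[0, "is_hit"])
        assert out.loc[0, "filter_reason"] == "essential_gene_in_pair"
        assert bool(out.loc[1, "is_hit"])
        # statistics retained
        assert out.loc[0, "t_stat"] == -8.0

    def test_empty_essential_set_is_noop(self):
        results = pd.DataFrame({"gene_pair": ["A|B"], "n_residuals": 10,
                                "mean_adjusted_residual": -1.0,
                                "t_stat": -3.0, "t_p": 0.01,
                                "t_p_adj": 0.01, "rra_rho": 0.1,
                                "rra_p": 0.1, "rra_p_adj": 0.1,
                                "significant_t": True,
                                "significant_rra": False, "is_hit": False,
                                "filter_reason": "none"})
        out = filter_hits(results, EssentialGeneSet())
        pd.testing.assert_frame_equal(out, results)

    def test_external_list_provenance(self):
        ess = EssentialGeneSet({"G1": "internal_day14"})
        ess.merge_external({"G2", "G1"})
        assert ess.provenance == {"G1": "internal_day14",
                                  "G2": "external_list"}


class TestSingleGeneDepletion:
    def test_strongly_lethal_gene_flagged(self):
        """A gene with f=-3 (all others 0) is flagged from day-14 singles
        across seeds."""
        found = 0
        for seed in range(5):
            cfg = ps.SimulationConfig(n_pairs=12, guides_per_gene=3,
                                      frac_sl=0.0, fitness_sd=0.0,
                                      frac_lethal_genes=0.0, seed=800 + seed)
            lib, eff = ps.simulate_truth(cfg)
            eff.gene_fitness["G0000A"] = -3.0
            counts = ps.simulate_counts(lib, eff, cfg)
            model = ps.PairedScreen(counts, lib)
            fc14 = model.fold_changes(14)
            ess = call_single_gene_depletion(fc14, lib, n_perm=2000,
                                             seed=seed)
            if ess.provenance.get("G0000A") == "internal_day14":
                found += 1
            assert len(ess.genes - {"G0000A"}) <= 1  # near-no false flags
        assert found == 5

    def test_null_simulation_rarely_flags(self):
        empty = 0
        for seed in range(5):
            cfg = ps.SimulationConfig(n_pairs=10, guides_per_gene=3,
                                      frac_sl=0.0, fitness_sd=0.0,
                                      frac_lethal_genes=0.0, seed=900 + seed)
            lib, eff, counts = ps.simulate_screen(cfg)
            fc14 = ps.PairedScreen(counts, lib).fold_changes(14)
            ess = call_single_gene_depletion(fc14, lib, n_perm=2000,
                                             seed=seed)
            if not ess.genes:
                empty += 1
        assert empty >= 4

    def test_external_list_always_included(self, small_screen):
        _, lib, _, counts, _ = small_screen
        fc14 = ps.PairedScreen(counts, lib).fold_changes(14)
        ess = call_single_gene_depletion(fc14, lib, n_perm=200, seed=0,
                                         external={"XRCC1"})
        assert ess.provenance["XRCC1"] == "external_list"


class TestCompetitiveAssay:
    def test_proportional_change_gives_zero(self):
        t0 = {"untransduced": 0.25, "a": 0.25, "b": 0.25, "double": 0.25}
        t1 = dict(t0)
        assert competitive_assay_residual(t0, t1) == pytest.approx(0.0)

    def test_fourfold_extra_depletion_gives_minus_two(self):
        t0 = {"untransduced": 0.25, "a": 0.25, "b": 0.25, "double": 0.25}
        # singles unchanged, double depleted 4-fold relative to untransduced
        t1 = {"untransduced": 1 / 3.25, "a": 1 / 3.25, "b": 1 / 3.25,
              "double": 0.25 / 3.25}
        assert competitive_assay_residual(t0, t1) == pytest.approx(-2.0)

    def test_additive_construction_recovers_interaction(self):
        """Fractions built from growth rates with eps=-1 yield residual -1."""
        fa, fb, eps = -0.5, -0.8, -1.0
        t0 = {"untransduced": 0.25, "a": 0.25, "b": 0.25, "double": 0.25}
        w = {"untransduced": 1.0, "a": 2 ** fa, "b": 2 ** fb,
             "double": 2 ** (fa + fb + eps)}
        tot = sum(0.25 * v for v in w.values())
        t1 = {k: 0.25 * v / tot for k, v in w.items()}
        assert competitive_assay_residual(t0, t1) == pytest.approx(eps)

    def test_input_validation(self):
        t0 = {"untransduced": 0.25, "a": 0.25, "b": 0.25, "double": 0.25}
        bad = {"untransduced": 0.5, "a": 0.5, "b": 0.2, "double": 0.2}
        with pytest.raises(ValueError, match="sum to 1"):
            competitive_assay_residual(t0, bad)
        zero = {"untransduced": 0.5, "a": 0.5, "b": 0.0, "double": 0.0}
        with pytest.raises(ValueError, match="sum to 1|zero"):
            competitive_assay_residual(t0, zero)


def test_pair_t_table_groups_by_pair(small_screen):
    _, _, _, _, res = small_screen
    table = pair_t_table(res.residual_table.df)
    assert set(table.index) == set(res.residual_table.df["gene_pair"])
    assert (table["n_residuals"] >= 3).all()
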