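"""Two-way ANOVA decomposition, BH-FDR, Levene, Shapiro, and the prefilter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crhnet import anova
from crhnet.synthetic import SyntheticConfig, generate_ratio_matrix

from conftest import make_ratio_matrix


class TestTwoWayAnova:
    def test_hand_computed_toy_decomposition(self):
        """2-time x 2-dye design, n=2 per cell, cell means (0, 0, 1, 1) by
        time: SS hand-computed from the eight printed numbers."""
        # time t1: cells (0, 0); time t2: cells (1, 1); zero noise
        vals = np.array([[0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0, 1.0]])
        time = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        dye = np.array(["treated_cy3", "treated_cy3", "treated_cy5",
                        "treated_cy5"] * 2)
        t = anova.two_way_anova(vals, time, dye, with_interaction=True)
        ss = t.attrs["ss"]
        # grand mean 0.5; SS_time = 8 * 0.25 = 2; all else 0
        assert ss["time"][0] == pytest.approx(2.0, abs=1e-12)
        assert ss["dye"][0] == pytest.approx(0.0, abs=1e-12)
        assert ss["interaction"][0] == pytest.approx(0.0, abs=1e-12)
        assert ss["residual"][0] == pytest.approx(0.0, abs=1e-12)
        assert bool(t["degenerate"][0])          # zero residual variance
        assert np.isnan(t["p_time"][0])

    def test_constant_gene_flagged_degenerate(self):
        m = make_ratio_matrix(np.full((1, 30), 3.14))
        t = anova.two_way_anova(m.matrix(), m.time, m.dye)
        assert bool(t["degenerate"][0])
        assert np.isnan(t["p_time"][0]) and np.isnan(t["p_interaction"][0])

    def test_ss_conservation(self):
        rng = np.random.default_rng(0)
        m = make_ratio_matrix(rng.normal(size=(200, 30)))
        for with_int in (True, False):
            t = anova.two_way_anova(m.matrix(), m.time, m.dye, with_int)
            ss = t.attrs["ss"]
            parts = ss["time"] + ss["dye"] + ss["residual"]
            if with_int:
                parts = parts + ss["interaction"]
            np.testing.assert_allclose(parts, ss["total"], atol=1e-8)

    def test_degrees_of_freedom(self):
        rng = np.random.default_rng(1)
        m = make_ratio_matrix(rng.normal(size=(5, 30)))
        with_int = anova.two_way_anova(m.matrix(), m.time, m.dye, True)
        no_int = anova.two_way_anova(m.matrix(), m.time, m.dye, False)
        assert with_int.attrs["df"] == {
            "time": 4, "dye": 1, "interaction": 4, "residual": 20
        }
        assert no_int.attrs["df"]["residual"] == 24

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(2)
        m = make_ratio_matrix(rng.normal(size=(2000, 30)))
        t = anova.two_way_anova(m.matrix(), m.time, m.dye, False)
        assert stats.kstest(t["p_time"], "uniform").pvalue > 0.01

    def test_unbalanced_design_rejected(self):
        vals = np.zeros((1, 8))
        time = np.array([1, 1, 1, 2, 2, 2, 2, 2])
        dye = np.array(["treated_cy3", "treated_cy5"] * 4)
        with pytest.raises(ValueError, match="balanced"):
            anova.two_way_anova(vals, time, dye)


class TestBhFdr:
    def test_step_up_hand_example(self):
        # p(i) * m / i then cumulative min from the top: all become 0.05
        np.testing.assert_allclose(
            anova.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05
        )

    def test_single_and_saturated(self):
        assert anova.bh_fdr([0.03])[0] == pytest.approx(0.03)
        np.testing.assert_allclose(anova.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_excluded_from_m(self):
        q = anova.bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], anova.bh_fdr([0.01, 0.02]))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, pvals, rnd):
        p = np.array(pvals)
        perm = np.array(rnd.sample(range(p.size), p.size))
        q_perm = anova.bh_fdr(p[perm])
        q = anova.bh_fdr(p)
        np.testing.assert_allclose(q_perm, q[perm])
        assert (q >= p - 1e-15).all()


class TestLevene:
    def test_identical_groups_statistic_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        stat, p = anova.levene_trimmed(
            np.r_[a, a[::-1]], np.r_[np.zeros(6), np.ones(6)]
        )
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_scale_shift_matches_deviation_score_anova(self):
        """Group B = 10x group A: the statistic equals a hand-built one-way
        F on absolute deviations from the trimmed group means."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=6)
        b = 10 * rng.normal(size=6)
        vals = np.r_[a, b]
        groups = np.r_[np.zeros(6), np.ones(6)]
        stat, p = anova.levene_trimmed(vals, groups, trim=0.25)

        def trimmed_mean(x):
            return stats.trim_mean(x, 0.25)

        dev = np.r_[np.abs(a - trimmed_mean(a)), np.abs(b - trimmed_mean(b))]
        f_oracle, p_oracle = stats.f_oneway(dev[:6], dev[6:])
        assert stat == pytest.approx(f_oracle, rel=1e-10)
        assert p == pytest.approx(p_oracle, rel=1e-10)

    def test_trim_zero_reduces_to_plain_levene(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=12)
        groups = np.r_[np.zeros(6), np.ones(6)]
        stat, _ = anova.levene_trimmed(vals, groups, trim=0.0)
        ref, _ = stats.levene(vals[:6], vals[6:], center="mean")
        assert stat == pytest.approx(ref, rel=1e-12)

    def test_zero_spread_handled(self):
        vals = np.r_[np.ones(6), np.ones(6)]
        stat, p = anova.levene_trimmed(
            vals, np.r_[np.zeros(6), np.ones(6)]
        )
        assert (stat, p) == (0.0, 1.0)


class TestShapiro:
    def test_null_level(self):
        rng = np.random.default_rng(5)
        m = make_ratio_matrix(rng.normal(size=(1000, 30)))
        out = anova.shapiro_per_gene(m)
        assert (out["p"] > 0.05).mean() > 0.90

    def test_bimodal_vector_rejected(self):
        m = make_ratio_matrix(np.r_[np.zeros(15), np.ones(15)][None, :])
        out = anova.shapiro_per_gene(m)
        assert out["p"][0] < 0.001
        assert out.attrs["n_below_001"] == 1

    def test_constant_vector_flagged(self):
        m = make_ratio_matrix(np.full((1, 30), 2.0))
        out = anova.shapiro_per_gene(m)
        assert bool(out["degenerate"][0]) and np.isnan(out["p"][0])
        assert out.attrs["n_below_001"] == 0


class TestPrefilter:
    def test_interaction_genes_excluded_and_de_preselected(self):
        cfg = SyntheticConfig(
            n_spots=400, n_de_genes=20, n_interaction_genes=50,
            de_effect=1.25, interaction_effect=0.75, noise_sd=0.25, seed=6,
        )
        matrix, truth = generate_ratio_matrix(cfg)
        res = anova.prefilter(matrix)
        excluded = set(res.excluded.index)
        recall = len(excluded & set(truth.interaction_genes)) / 50
        assert recall >= 0.90
        assert set(truth.de_genes) <= set(res.preselected.index)
        # invariant: preselected and excluded sets are disjoint
        assert not excluded & set(res.preselected.index)

    def test_null_exclusion_rate_matches_alpha(self):
        rates = []
        for seed in range(5):
            cfg = SyntheticConfig(n_spots=400, n_de_genes=0, seed=seed)
            matrix, _ = generate_ratio_matrix(cfg)
            res = anova.prefilter(matrix, interaction_alpha=0.01)
            rates.append(len(res.excluded) / 400)
        se = np.sqrt(0.01 * 0.99 / (400 * 5))
        assert abs(np.mean(rates) - 0.01) < 2.5 * se + 1e-3

    def test_zero_alpha_excludes_nothing(self):
        cfg = SyntheticConfig(n_spots=50, n_interaction_genes=10, seed=7)
        matrix, _ = generate_ratio_matrix(cfg)
        res = anova.prefilter(matrix, interaction_alpha=0.0)
        assert len(res.excluded) == 0
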