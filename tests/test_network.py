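"""PCA biplot and the shrinkage graphical Gaussian model."""

import numpy as np
import pandas as pd
import pytest

from crhnet.network import (
    build_network,
    dynamic_weights,
    edge_significance,
    infer_network,
    pca_biplot,
    shrinkage_pcor,
)
from crhnet.synthetic import (
    DEFAULT_PLANTED_EDGES,
    SyntheticConfig,
    generate_ratio_matrix,
)


def frame(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )


class TestPca:
    def test_rank_one_matrix_single_component(self):
        m = frame(np.outer([1, 2, 3], [1, -1, 2, 0]))
        res = pca_biplot(m)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_mirror_profiles_opposite_scores(self):
        x = np.array([1.0, 2.0, 0.5, -1.0, 0.0, 3.0])
        res = pca_biplot(frame(np.vstack([x, -x, x * 2])))
        s = res.scores["PC1"]
        assert s["g0"] * s["g1"] < 0

    def test_matches_hand_svd_oracle(self):
        rng = np.random.default_rng(0)
        m = frame(rng.normal(size=(4, 6)))
        res = pca_biplot(m)
        Xc = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        np.testing.assert_allclose(
            np.abs(res.scores.to_numpy()), np.abs(U * s), atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(res.loadings.to_numpy()), np.abs(Vt.T), atol=1e-10
        )
        np.testing.assert_allclose(res.reconstruct(), Xc, atol=1e-8)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pca_biplot(frame(np.ones((3, 4))))


class TestDynamicWeights:
    def test_reference_grid_matches_hand_trapezoid(self):
        """Weights on the (1,3,6,12,24) h grid equal the hand-computed
        trapezoid-rule vector (1, 2.5, 4.5, 9, 6)/23 per time point."""
        t = np.repeat([1.0, 3.0, 6.0, 12.0, 24.0], 6)
        w = dynamic_weights(t)
        per_time = np.array([1.0, 2.5, 4.5, 9.0, 6.0]) / 23.0
        np.testing.assert_allclose(
            w, np.repeat(per_time / 6, 6), rtol=1e-12
        )
        assert w.sum() == pytest.approx(1.0)

    def test_late_interval_outweighs_early(self):
        t = np.array([1.0, 3.0, 6.0, 12.0, 24.0])
        w = dynamic_weights(t)
        assert w[4] > w[1]

    def test_single_time_point_uniform(self):
        with pytest.warns(UserWarning, match="single"):
            w = dynamic_weights([2.0, 2.0, 2.0, 2.0])
        np.testing.assert_allclose(w, 0.25)


class TestShrinkagePcor:
    def test_three_gene_chain_conditional_independence(self):
        """Population corr [[1,.6,.36],[.6,1,.6],[.36,.6,1]] has
        pcor(0,2|1) = 0 (3x3 inversion oracle); the shrinkage estimate
        converges to it at n = 10000."""
        corr = np.array([[1, 0.6, 0.36], [0.6, 1, 0.6], [0.36, 0.6, 1]])
        omega = np.linalg.inv(corr)
        d = np.sqrt(np.diag(omega))
        assert -omega[0, 2] / (d[0] * d[2]) == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(1)
        X = rng.multivariate_normal(np.zeros(3), corr, size=10000).T
        pc = shrinkage_pcor(frame(X))
        assert abs(pc.iloc[0, 2]) < 0.05
        assert pc.iloc[0, 1] > 0.3 and pc.iloc[1, 2] > 0.3

    def test_matches_independent_partial_corr_oracle(self):
        """With shrinkage forced off, pcor equals pingouin's estimate."""
        import pingouin as pg

        rng = np.random.default_rng(2)
        X = rng.normal(size=(4, 200))
        X[1] += 0.5 * X[0]
        X[2] += 0.5 * X[1]
        df = pd.DataFrame(X.T, columns=list("abcd"))
        pc = shrinkage_pcor(frame(X), shrinkage=0.0)
        for i, j, rest in [(0, 1, ["c", "d"]), (1, 2, ["a", "d"])]:
            ref = pg.partial_corr(
                df, x="abcd"[i], y="abcd"[j], covar=rest
            )["r"].iloc[0]
            assert pc.iloc[i, j] == pytest.approx(ref, abs=1e-6)

    def test_two_gene_pcor_equals_shrunk_correlation(self):
        # with no conditioning set the partial correlation is just the
        # (shrunk) correlation
        rng = np.random.default_rng(30)
        X = rng.normal(size=(2, 40))
        X[1] += X[0]
        pc = shrinkage_pcor(frame(X), shrinkage=0.2)
        r = np.corrcoef(X)[0, 1]
        assert pc.iloc[0, 1] == pytest.approx(0.8 * r, abs=1e-10)

    def test_full_shrinkage_zeroes_everything(self):
        rng = np.random.default_rng(3)
        pc = shrinkage_pcor(frame(rng.normal(size=(5, 30))), shrinkage=1.0)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(pc.to_numpy()[off], 0.0, atol=1e-12)

    def test_shrinkage_monotonically_attenuates(self):
        rng = np.random.default_rng(4)
        X = frame(rng.normal(size=(5, 30)))
        lams = [0.0, 0.3, 0.6, 0.9]
        mags = [
            np.abs(shrinkage_pcor(X, shrinkage=l).to_numpy()
                   [~np.eye(5, dtype=bool)]).max()
            for l in lams
        ]
        assert all(a >= b for a, b in zip(mags, mags[1:]))

    def test_symmetric_bounded(self):
        rng = np.random.default_rng(5)
        pc = shrinkage_pcor(frame(rng.normal(size=(8, 30)))).to_numpy()
        np.testing.assert_allclose(pc, pc.T, atol=1e-12)
        assert (np.abs(pc) <= 1.0 + 1e-12).all()


class TestEdgeSignificance:
    def test_zero_pcor_p_one_and_monotone(self):
        vals = np.eye(5)
        vals[0, 1] = vals[1, 0] = 0.0
        vals[0, 2] = vals[2, 0] = 0.3
        vals[0, 3] = vals[3, 0] = 0.6
        vals[0, 4] = vals[4, 0] = 0.9
        p = edge_significance(frame(vals), kappa=25.0)
        assert p.iloc[0, 1] == pytest.approx(1.0)
        assert p.iloc[0, 1] > p.iloc[0, 2] > p.iloc[0, 3] > p.iloc[0, 4]

    def test_null_type_one_error_calibrated(self):
        """Edge-wise false positive rate at p < 0.05 stays near 0.05 on
        independent genes (11 genes, 30 samples)."""
        rng = np.random.default_rng(6)
        hits = total = 0
        for _ in range(150):
            X = frame(rng.normal(size=(11, 30)))
            pc = shrinkage_pcor(X)
            pv = edge_significance(pc, n_samples=30)
            iu = np.triu_indices(11, 1)
            hits += (pv.to_numpy()[iu] < 0.05).sum()
            total += len(iu[0])
        assert abs(hits / total - 0.05) < 0.02

    def test_few_edges_fallback(self):
        vals = np.eye(3)
        with pytest.warns(UserWarning, match="kappa"):
            p = edge_significance(frame(vals), n_samples=30)
        assert p.attrs["kappa"] == 29.0


class TestBuildNetwork:
    def test_conjunctive_filter(self):
        pc = np.eye(4)
        pv = np.ones((4, 4))
        pc[0, 1] = pc[1, 0] = 0.5; pv[0, 1] = pv[1, 0] = 0.01   # kept
        pc[0, 2] = pc[2, 0] = 0.5; pv[0, 2] = pv[2, 0] = 0.2    # p too big
        pc[1, 3] = pc[3, 1] = 0.2; pv[1, 3] = pv[3, 1] = 0.001  # pcor small
        net = build_network(frame(pc), frame(pv))
        assert net.edge_set() == {frozenset(("g0", "g1"))}
        assert set(net.unconnected) == {"g2", "g3"}

    def test_all_zero_pcor_edgeless(self):
        net = build_network(frame(np.eye(5)), frame(np.ones((5, 5))))
        assert len(net.edges) == 0
        assert net.unconnected == [f"g{i}" for i in range(5)]
        assert net.to_networkx().number_of_nodes() == 5

    def test_planted_network_recovered_with_signs(self):
        cfg = SyntheticConfig(
            n_spots=10, n_de_genes=0, network_genes=10, noise_sd=0.0,
            seed=7,
        )
        matrix, truth = generate_ratio_matrix(cfg)
        net = infer_network(matrix.values, time_points=matrix.time)
        found = net.edge_set()
        true_edges = {frozenset((a, b)) for a, b, _p in truth.edge_list}
        recall = len(found & true_edges) / len(true_edges)
        assert recall >= 0.6
        # the planted negative edge keeps its sign when recovered
        neg = [(a, b) for a, b, p in truth.edge_list if p < 0][0]
        hit = net.edges[
            (net.edges["gene_i"].isin(neg)) & (net.edges["gene_j"].isin(neg))
        ]
        if len(hit):
            assert (hit["sign"] == "-").all()
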