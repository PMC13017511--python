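"""TF-TF association networks: consolidation, Spearman, glasso, null FDR."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfatlas import simulate
from tfatlas.assoc import (AssociationGraph, ConsolidatedNetwork,
                           consolidate, default_lambda_grid,
                           fit_association_graph, filter_regulatees,
                           glasso_path, nearest_psd, null_shuffle_fdr,
                           select_lambda, spearman_tf_tf,
                           shrunken_ecdf_transform, PathPoint)
from tfatlas.grn import RegulatoryNetwork


def _net(sample, rows):
    tfs = sorted({r[0] for r in rows} | {r[1] for r in rows})
    return RegulatoryNetwork(
        sample=sample,
        node_weight=pd.Series(1.0, index=tfs),
        edges=pd.DataFrame(rows, columns=["tf", "gene", "w"]))


class TestConsolidate:
    def test_single_sample_identity(self):
        nets = {"s1": _net("s1", [("T1", "G1", 0.4), ("T1", "G2", 0.6)])}
        cn = consolidate(nets, ["s1"], ["T1"])
        assert cn.weights.loc["T1", "G1"] == pytest.approx(0.4)
        assert cn.weights.loc["T1", "G2"] == pytest.approx(0.6)

    def test_absent_edge_counts_as_zero(self):
        nets = {"s1": _net("s1", [("T1", "G1", 0.4)]),
                "s2": _net("s2", [("T1", "G2", 0.8)])}
        cn = consolidate(nets, ["s1", "s2"], ["T1"])
        assert cn.weights.loc["T1", "G1"] == pytest.approx(0.2)
        assert cn.weights.loc["T1", "G2"] == pytest.approx(0.4)

    def test_three_sample_elementwise_mean(self):
        rng = np.random.default_rng(0)
        nets = {}
        frames = []
        for s in ("s1", "s2", "s3"):
            rows = [("T1", f"G{j}", rng.random()) for j in range(4)]
            rows += [("T2", f"G{j}", rng.random()) for j in range(4)]
            nets[s] = _net(s, rows)
            frames.append(nets[s].edges.set_index(["tf", "gene"])["w"])
        cn = consolidate(nets, list(nets), ["T1", "T2"])
        oracle = pd.concat(frames, axis=1).fillna(0).mean(axis=1)
        for (tf, g), v in oracle.items():
            assert cn.weights.loc[tf, g] == pytest.approx(v)

    def test_empty_tf_set_rejected(self):
        nets = {"s1": _net("s1", [("T1", "G1", 0.4)])}
        with pytest.raises(ValueError, match="tf_set"):
            consolidate(nets, ["s1"], [])


class TestFilterRegulatees:
    def test_constant_column_dropped(self):
        w = pd.DataFrame({"G1": [2.0, 2.0, 2.0], "G2": [0.0, 5.0, 10.0]},
                         index=["T1", "T2", "T3"])
        out = filter_regulatees(ConsolidatedNetwork("c", w))
        assert list(out.weights.columns) == ["G2"]

    def test_sd_exactly_one_dropped(self):
        # sample sd of (1, 2, 3) is exactly 1: the rule is <=, so dropped
        w = pd.DataFrame({"G1": [1.0, 2.0, 3.0], "G2": [0.0, 5.0, 10.0]},
                         index=["T1", "T2", "T3"])
        out = filter_regulatees(ConsolidatedNetwork("c", w), sd_min=1.0)
        assert "G1" not in out.weights.columns

    def test_all_dropped_advises_rescaling(self):
        w = pd.DataFrame({"G1": [0.1, 0.2, 0.3]}, index=["T1", "T2", "T3"])
        with pytest.raises(ValueError, match="rescale"):
            filter_regulatees(ConsolidatedNetwork("c", w))

    def test_survivors_match_oracle(self):
        rng = np.random.default_rng(1)
        w = pd.DataFrame(rng.exponential(2.0, size=(6, 30)),
                         index=[f"T{i}" for i in range(6)],
                         columns=[f"G{j}" for j in range(30)])
        out = filter_regulatees(ConsolidatedNetwork("c", w), sd_min=1.5)
        expected = [g for g in w.columns if w[g].std(ddof=1) > 1.5]
        assert list(out.weights.columns) == expected


class TestSpearman:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(2)
        w = pd.DataFrame(rng.exponential(1.0, size=(4, 50)))
        rho, _ = spearman_tf_tf(ConsolidatedNetwork("c", w), min_common=10)
        np.testing.assert_allclose(np.diag(rho.to_numpy()), 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        base = pd.DataFrame(rng.exponential(1.0, size=(4, 60)))
        rho1, _ = spearman_tf_tf(ConsolidatedNetwork("c", base),
                                 min_common=10)
        for f in (np.exp, lambda x: x ** 3):
            rho2, _ = spearman_tf_tf(
                ConsolidatedNetwork("c", pd.DataFrame(f(base.to_numpy()))),
                min_common=10)
            np.testing.assert_allclose(rho1.to_numpy(), rho2.to_numpy(),
                                       atol=1e-12)

    def test_perfect_monotone_pair(self):
        x = np.linspace(0.1, 3.0, 40)
        w = pd.DataFrame([x, np.exp(x)], index=["T1", "T2"])
        rho, _ = spearman_tf_tf(ConsolidatedNetwork("c", w), min_common=10)
        assert rho.loc["T1", "T2"] == pytest.approx(1.0)

    def test_matches_pairwise_oracle_with_zeros(self):
        rng = np.random.default_rng(4)
        w = rng.exponential(1.0, size=(4, 80))
        w[rng.random(w.shape) < 0.3] = 0.0
        cn = ConsolidatedNetwork("c", pd.DataFrame(w))
        rho, flag = spearman_tf_tf(cn, min_common=10)
        for i in range(4):
            for j in range(i + 1, 4):
                common = (w[i] > 0) & (w[j] > 0)
                if common.sum() < 10:
                    assert flag.iloc[i, j]
                    assert rho.iloc[i, j] == 0.0
                else:
                    expected = stats.spearmanr(w[i, common],
                                               w[j, common]).statistic
                    assert rho.iloc[i, j] == pytest.approx(expected)

    def test_low_support_flagged(self):
        w = pd.DataFrame([[1.0, 2.0, 0.0, 0.0],
                          [0.0, 0.0, 3.0, 4.0]], index=["T1", "T2"])
        rho, flag = spearman_tf_tf(ConsolidatedNetwork("c", w),
                                   min_common=2)
        assert flag.loc["T1", "T2"]
        assert rho.loc["T1", "T2"] == 0.0


class TestNearestPsd:
    def test_psd_input_unchanged(self):
        m = pd.DataFrame(np.array([[1.0, 0.3], [0.3, 1.0]]))
        out = nearest_psd(m)
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy(),
                                   atol=1e-12)

    def test_indefinite_becomes_psd_unit_diag(self):
        # pairwise-complete style matrix that is not PSD
        m = np.array([[1.0, 0.9, -0.9],
                      [0.9, 1.0, 0.9],
                      [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(m).min() < 0
        out = nearest_psd(m)
        assert np.linalg.eigvalsh(out).min() >= -1e-12
        np.testing.assert_allclose(np.diag(out), 1.0)

    def test_identity_fixed_point(self):
        out = nearest_psd(np.eye(4))
        np.testing.assert_allclose(out, np.eye(4))


def _block_correlation():
    """Exact population correlation of a 6-var precision with two blocks."""
    theta, labels = simulate.block_precision(6, 2, 0.3)
    sigma = np.linalg.inv(theta)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d), theta


class TestGlassoPath:
    def test_identity_covariance_gives_no_edges(self):
        path = glasso_path(np.eye(5), np.geomspace(1.0, 0.01, 10))
        assert all(p.density == 0.0 for p in path)

    def test_density_monotone_along_path(self):
        S, _ = _block_correlation()
        lambdas = np.geomspace(0.6, 0.005, 25)
        path = glasso_path(S, lambdas)
        dens = [p.density for p in path]  # lambda decreasing -> density up
        assert all(dens[i] <= dens[i + 1] + 1e-12
                   for i in range(len(dens) - 1))

    def test_planted_support_recovered_at_suitable_lambda(self):
        S, theta_true = _block_correlation()
        path = glasso_path(S, np.geomspace(0.5, 0.01, 30))
        true_support = np.abs(theta_true) > 1e-12
        hit = any(
            ((np.abs(p.precision) > 1e-8) == true_support).all()
            for p in path)
        assert hit

    def test_kkt_certificate(self):
        """The estimate satisfies the penalized-likelihood stationarity
        conditions: Theta^-1 - S equals lambda on active off-diagonals
        (with the sign of Theta), is within lambda elsewhere, and matches
        S on the diagonal."""
        S, _ = _block_correlation()
        lam = 0.1
        theta = glasso_path(S, np.array([lam]))[0].precision
        W = np.linalg.inv(theta)
        G = W - S
        n = S.shape[0]
        for i in range(n):
            assert G[i, i] == pytest.approx(0.0, abs=5e-3)
            for j in range(n):
                if i == j:
                    continue
                if abs(theta[i, j]) > 1e-8:
                    assert G[i, j] == pytest.approx(
                        lam * np.sign(theta[i, j]), abs=5e-3)
                else:
                    assert abs(G[i, j]) <= lam + 5e-3

    def test_non_psd_input_rejected(self):
        m = np.array([[1.0, 0.9, -0.9],
                      [0.9, 1.0, 0.9],
                      [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="nearest_psd"):
            glasso_path(m, np.array([0.1]))


def _fake_path(lambdas, densities):
    return [PathPoint(lambda_=l, precision=np.eye(2), density=d)
            for l, d in zip(lambdas, densities)]


class TestSelectLambda:
    def test_flat_shelf_at_target_chosen(self):
        lambdas = np.geomspace(1.0, 0.01, 12)
        densities = [0.0, 0.0, 0.05, 0.15, 0.15, 0.15, 0.15, 0.3, 0.4,
                     0.45, 0.5, 0.55]
        point = select_lambda(_fake_path(lambdas, densities), 0.15)
        assert point.density == 0.15

    def test_geometric_decay_falls_back_with_warning(self):
        lambdas = np.geomspace(1.0, 0.01, 10)
        densities = list(np.linspace(0.01, 0.5, 10))
        with pytest.warns(UserWarning, match="no plateau"):
            point = select_lambda(_fake_path(lambdas, densities), 0.15)
        assert point.density == min(densities,
                                    key=lambda d: abs(d - 0.15))

    def test_single_point_path(self):
        point = select_lambda(_fake_path([0.1], [0.2]), 0.15)
        assert point.lambda_ == 0.1


class TestFitAssociationGraph:
    def test_independent_rows_stay_sparse(self):
        W, _ = simulate.generate_consolidated_weights(20, 2000, 1, 1e-4,
                                                      seed=5)
        g = fit_association_graph(ConsolidatedNetwork("null", W))
        assert g.density < 0.02

    def test_duplicate_tf_row_connected(self):
        rng = np.random.default_rng(6)
        W, _ = simulate.generate_consolidated_weights(6, 300, 1, 1e-4,
                                                      seed=6)
        W.loc["Tf0001_copy"] = W.loc["Tf0001"].to_numpy()
        g = fit_association_graph(ConsolidatedNetwork("dup", W))
        pairs = set(map(tuple, g.edges[["tf_a", "tf_b"]].to_numpy()))
        assert (("Tf0001", "Tf0001_copy") in pairs
                or ("Tf0001_copy", "Tf0001") in pairs)

    def test_blocks_dominate_edges(self):
        W, labels = simulate.generate_consolidated_weights(30, 2000, 5, 0.1,
                                                           seed=7)
        g = fit_association_graph(ConsolidatedNetwork("blocks", W))
        lab = dict(zip(W.index, labels))
        within = sum(lab[a] == lab[b]
                     for a, b in zip(g.edges["tf_a"], g.edges["tf_b"]))
        assert len(g.edges) > 0
        assert within / len(g.edges) >= 0.90

    def test_no_self_edges_and_symmetric_support(self):
        W, _ = simulate.generate_consolidated_weights(10, 500, 2, 0.2,
                                                      seed=8)
        g = fit_association_graph(ConsolidatedNetwork("x", W))
        assert (g.edges["tf_a"] != g.edges["tf_b"]).all()
        # the precision matrix behind the support must be symmetric
        np.testing.assert_allclose(g.precision, g.precision.T, atol=1e-8)


class TestNullShuffle:
    def test_shuffle_preserves_row_multisets(self):
        W, _ = simulate.generate_consolidated_weights(5, 200, 1, 1e-4,
                                                      seed=9)
        cn = ConsolidatedNetwork("c", W)
        rng = np.random.default_rng(0)
        M = cn.weights.to_numpy().copy()
        for i in range(M.shape[0]):
            M[i] = M[i, rng.permutation(M.shape[1])]
        for i in range(M.shape[0]):
            np.testing.assert_allclose(np.sort(M[i]),
                                       np.sort(cn.weights.to_numpy()[i]))

    def test_zero_replicates_empty(self):
        W, _ = simulate.generate_consolidated_weights(5, 100, 1, 1e-4,
                                                      seed=10)
        counts, mean = null_shuffle_fdr(ConsolidatedNetwork("c", W), 0.3,
                                        n_null=0)
        assert counts == [] and np.isnan(mean)


class TestShrunkenEcdf:
    def test_row_monotone_map(self):
        rng = np.random.default_rng(11)
        w = pd.DataFrame(rng.exponential(1.0, size=(3, 40)))
        z = shrunken_ecdf_transform(w)
        for i in range(3):
            order_w = np.argsort(w.iloc[i].to_numpy())
            order_z = np.argsort(z.iloc[i].to_numpy())
            np.testing.assert_array_equal(order_w, order_z)

    def test_unit_variance_rows(self):
        rng = np.random.default_rng(12)
        w = pd.DataFrame(rng.exponential(1.0, size=(3, 200)))
        z = shrunken_ecdf_transform(w)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-9)
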