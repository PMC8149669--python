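"""PCNM eigenfunctions, forward selection, VPA, random-forest importance."""

import numpy as np
import pandas as pd
import pytest

from mycobeta.drivers import (
    forward_select,
    pcnm,
    rf_importance,
    variation_partition,
)


def sign_changes(v: np.ndarray) -> int:
    s = np.sign(v)
    s = s[s != 0]
    return int(np.sum(s[:-1] * s[1:] < 0))


class TestPcnm:
    def test_transect_eigenvectors_are_sinusoid_like(self):
        # on a regular transect, eigenvector k oscillates with k sign changes
        coords = np.column_stack([np.arange(20.0), np.zeros(20)])
        eig = pcnm(coords)
        for k in range(5):
            assert sign_changes(eig.vectors[:, k]) == k + 1

    def test_three_collinear_points_match_dense_eigen_oracle(self):
        # distances (1, 1, 2); truncation t = 1; the 2 entry becomes 4
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        eig = pcnm(coords)
        assert eig.truncation == pytest.approx(1.0)
        d = np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
        j = np.eye(3) - np.ones((3, 3)) / 3
        b = -0.5 * j @ (d**2) @ j
        vals = np.sort(np.linalg.eigvalsh(b))[::-1]
        np.testing.assert_allclose(eig.eigenvalues, vals[vals > 1e-8], atol=1e-8)

    def test_orthogonality_and_centering(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 100, size=(25, 2))
        eig = pcnm(coords)
        g = eig.vectors.T @ eig.vectors
        np.testing.assert_allclose(g - np.diag(np.diag(g)), 0.0, atol=1e-8)
        np.testing.assert_allclose(eig.vectors.mean(axis=0), 0.0, atol=1e-8)
        assert eig.vectors.shape[1] < len(coords)

    def test_duplicate_coordinates_advise_jitter(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="jitter"):
            pcnm(coords)


class TestForwardSelect:
    def test_planted_signal_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            C = rng.normal(size=(45, 6))
            y = 2 * C[:, 0] + rng.normal(0, 0.1, 45)
            hits += forward_select(y, C, n_perm=199, seed=seed) == [0]
        assert hits >= 18

    def test_pure_noise_selects_nothing(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            C = rng.normal(size=(45, 6))
            y = rng.normal(size=45)
            empty += forward_select(y, C, n_perm=199, seed=seed) == []
        assert empty >= 17  # global gate holds ~95% of null runs

    def test_identical_candidate_selected(self):
        y = np.random.default_rng(5).normal(size=30)
        assert forward_select(y, y[:, None], n_perm=199, seed=0) == [0]

    def test_dataframe_labels_returned(self):
        rng = np.random.default_rng(7)
        C = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        y = 3 * C["b"].to_numpy() + rng.normal(0, 0.1, 40)
        assert forward_select(y, C, n_perm=199, seed=0) == ["b"]

    def test_never_selects_more_than_n_minus_2(self):
        rng = np.random.default_rng(8)
        n = 8
        C = rng.normal(size=(n, 12))
        y = C[:, :10].sum(axis=1)
        sel = forward_select(y, C, n_perm=99, seed=0)
        assert len(sel) <= n - 2


class TestVariationPartition:
    def test_orthogonal_components_recovered(self):
        rng = np.random.default_rng(0)
        n = 60
        e = rng.normal(size=n); e -= e.mean(); e /= np.linalg.norm(e)
        s = rng.normal(size=n); s -= (s @ e) * e; s -= s.mean(); s /= np.linalg.norm(s)
        vp = variation_partition(e + s, e[:, None], s[:, None], n_perm=199, seed=1)
        assert vp.pure_env == pytest.approx(0.5, abs=0.05)
        assert vp.pure_space == pytest.approx(0.5, abs=0.05)
        assert vp.shared == pytest.approx(0.0, abs=0.05)
        assert vp.p_env <= 0.05 and vp.p_space <= 0.05

    def test_duplicated_predictors_all_shared(self):
        rng = np.random.default_rng(1)
        n = 50
        X = rng.normal(size=(n, 2))
        y = X @ [1.0, -1.0] + rng.normal(0, 0.2, n)
        # env and space carry the same information (noisy copies to avoid
        # exact collinearity within each set)
        vp = variation_partition(
            y, X + rng.normal(0, 1e-6, X.shape), X + rng.normal(0, 1e-6, X.shape),
            n_perm=199, seed=2,
        )
        assert vp.pure_env == pytest.approx(0.0, abs=0.02)
        assert vp.pure_space == pytest.approx(0.0, abs=0.02)
        assert vp.shared > 0.8

    def test_constant_response_all_zero(self):
        rng = np.random.default_rng(2)
        vp = variation_partition(
            np.ones(30), rng.normal(size=(30, 2)), rng.normal(size=(30, 2)),
            n_perm=99, seed=0,
        )
        assert (vp.pure_env, vp.shared, vp.pure_space) == (0, 0, 0)
        assert vp.p_env == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        n = 45
        E = rng.normal(size=(n, 3))
        S = rng.normal(size=(n, 2))
        y = E[:, 0] + 0.5 * S[:, 1] + rng.normal(0, 0.5, n)
        vp = variation_partition(y, E, S, n_perm=99, seed=1)
        assert vp.pure_env + vp.shared + vp.pure_space + vp.residual == pytest.approx(
            1.0, abs=1e-8
        )

    def test_rank_deficient_predictors_rejected(self):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(30, 2))
        E = np.column_stack([E, E[:, 0]])
        with pytest.raises(ValueError, match="rank-deficient"):
            variation_partition(rng.normal(size=30), E, rng.normal(size=(30, 2)))

    def test_null_permutation_pvalues_roughly_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(100):
            y = rng.normal(size=30)
            E = rng.normal(size=(30, 2))
            S = rng.normal(size=(30, 2))
            vp = variation_partition(y, E, S, n_perm=199, seed=rng)
            pvals.append(vp.p_env)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRfImportance:
    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(45, 10))
        y = 10 * X[:, 3] + rng.normal(size=45)
        r = rf_importance(y, X, n_trees=100, n_perm=99, seed=0, compute_pd=False)
        assert r.table.iloc[3]["rank"] == 1
        assert r.table.iloc[3]["p"] <= 0.05

    def test_null_response_mostly_nonsignificant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(45, 10))
        y = rng.permutation(10 * X[:, 3] + rng.normal(size=45))
        r = rf_importance(y, X, n_trees=60, n_perm=99, seed=1, compute_pd=False)
        assert (r.table["p"] <= 0.05).sum() <= 2

    def test_ranking_invariant_to_column_order(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 6))
        y = 5 * X[:, 0] - 3 * X[:, 4] + rng.normal(0, 0.5, 50)
        r1 = rf_importance(y, X, n_trees=150, n_perm=0, seed=3, compute_pd=False)
        perm = [4, 0, 5, 1, 3, 2]
        r2 = rf_importance(y, X[:, perm], n_trees=150, n_perm=0, seed=3, compute_pd=False)
        top1 = r1.table.index[r1.table["rank"] == 1][0]
        top2 = r2.table.index[r2.table["rank"] == 1][0]
        assert perm[int(top2[1:])] == int(top1[1:])

    def test_partial_dependence_monotone_for_linear_signal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 4))
        y = 4 * X[:, 1] + rng.normal(0, 0.3, 60)
        r = rf_importance(y, X, n_trees=150, n_perm=0, seed=4, pd_points=25)
        grid, preds = r.partial_dependence["x1"]
        assert len(grid) == 25
        # strictly increasing trend up to forest noise: compare ends
        assert preds[-1] > preds[0]
        assert np.corrcoef(grid, preds)[0, 1] > 0.95

    def test_constant_response_warns_all_null(self, caplog):
        import logging

        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        with caplog.at_level(logging.WARNING):
            r = rf_importance(np.ones(30), X, n_trees=30, n_perm=19, seed=0, compute_pd=False)
        np.testing.assert_allclose(r.table["importance"], 0.0, atol=1e-12)
        assert (r.table["p"] > 0.9).all()
        assert any("constant response" in rec.message for rec in caplog.records)

    def test_importance_units_are_rss_decrease(self):
        # a single-split tree on a perfectly separable predictor decreases
        # RSS by about n * var(y); importances should be on that scale
        rng = np.random.default_rng(5)
        x = np.repeat([0.0, 1.0], 30)
        y = np.repeat([0.0, 10.0], 30) + rng.normal(0, 0.01, 60)
        X = np.column_stack([x, rng.normal(size=60)])
        r = rf_importance(y, X, n_trees=50, n_perm=0, seed=1, compute_pd=False)
        assert r.table.iloc[0]["importance"] == pytest.approx(60 * 25.0, rel=0.2)

    def test_too_few_plots_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            rf_importance(np.ones(5), np.ones((5, 3)), n_trees=10, n_perm=0)
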