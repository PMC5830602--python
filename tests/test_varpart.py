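"""Hellinger transform, RDA, forward selection, variation partitioning."""

import numpy as np
import pandas as pd
import pytest

from nestshore.varpart import (
    forward_select,
    hellinger,
    partial_rda_test,
    rda_r2,
    variation_partition,
)


class TestHellinger:
    def test_hand_values(self):
        out = hellinger(np.array([[1.0, 3.0]]))
        assert out[0, 0] == pytest.approx(0.5)
        assert out[0, 1] == pytest.approx(np.sqrt(0.75))
        assert np.allclose(hellinger(np.array([[5.0, 0.0, 0.0]])), [[1, 0, 0]])

    def test_rows_unit_sum_of_squares(self, rng):
        Y = rng.integers(0, 20, size=(10, 6)).astype(float)
        Y[:, 0] += 1  # no all-zero rows
        H = hellinger(Y)
        assert np.allclose((H**2).sum(axis=1), 1.0)

    def test_all_zero_row_names_site(self):
        Y = pd.DataFrame([[1, 2], [0, 0]], index=["good", "empty"], columns=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            hellinger(Y)

    def test_reapplication_warns(self):
        H = hellinger(np.array([[1.0, 3.0], [2.0, 2.0]]))
        with pytest.warns(UserWarning, match="unit-norm"):
            hellinger(H)


class TestRdaR2:
    def test_perfect_fit(self, rng):
        x = rng.normal(size=(10, 1))
        r2, r2adj, f = rda_r2(x, x)
        assert r2 == pytest.approx(1.0) and r2adj == pytest.approx(1.0)

    def test_orthogonal_predictor_gives_negative_adjusted(self):
        Y = np.array([[1.0], [-1.0], [1.0], [-1.0], [1.0], [-1.0]])
        X = np.array([[1.0], [1.0], [-1.0], [-1.0], [1.0], [-1.0]])
        X -= X.mean()
        # make exactly orthogonal to Y
        X = X - (X.T @ Y) / (Y.T @ Y) * Y
        r2, r2adj, _ = rda_r2(Y, X)
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert r2adj < 0

    def test_matches_hat_matrix_oracle(self, rng):
        n, p, m = 12, 5, 2
        Y = rng.normal(size=(n, p))
        X = rng.normal(size=(n, m))
        Yc = Y - Y.mean(0)
        Xc = X - X.mean(0)
        H = Xc @ np.linalg.inv(Xc.T @ Xc) @ Xc.T
        r2_oracle = float(((H @ Yc) ** 2).sum() / (Yc**2).sum())
        r2, r2adj, f = rda_r2(Y, X)
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)
        assert r2adj == pytest.approx(1 - (1 - r2_oracle) * (n - 1) / (n - m - 1), abs=1e-10)

    def test_collinear_predictors_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X = np.hstack([X, X[:, :1]])
        with pytest.raises(ValueError, match="rank-deficient"):
            rda_r2(rng.normal(size=(10, 3)), X)


class TestPartialRda:
    def test_empty_conditioning_reduces_to_plain_f(self, rng):
        Y = rng.normal(size=(14, 6))
        X = rng.normal(size=(14, 2))
        _, _, f_plain = rda_r2(Y, X)
        t = partial_rda_test(Y, X, None, n_perm=99, seed=1)
        assert t.f == pytest.approx(f_plain, rel=1e-9)

    def test_x_in_span_of_w_rejected(self, rng):
        W = rng.normal(size=(12, 2))
        with pytest.raises(ValueError, match="span"):
            partial_rda_test(rng.normal(size=(12, 4)), W[:, :1], W, n_perm=99, seed=0)

    def test_detects_true_effect(self, rng):
        X = rng.normal(size=(20, 1))
        Y = X @ rng.normal(size=(1, 5)) + 0.1 * rng.normal(size=(20, 5))
        t = partial_rda_test(Y, X, None, n_perm=199, seed=3)
        assert t.p <= 0.01


class TestVariationPartition:
    def test_fraction_identities_on_random_fixtures(self, rng):
        for _ in range(5):
            Y = rng.normal(size=(16, 8))
            E = pd.DataFrame(rng.normal(size=(16, 3)))
            S = pd.DataFrame(rng.normal(size=(16, 2)), columns=["m1", "m2"])
            r = variation_partition(Y, E, S, n_perm=49, seed=0)
            assert r.a + r.b + r.c + r.d == pytest.approx(1.0, abs=1e-12)
            assert r.a + r.b == pytest.approx(r.r2adj_env, abs=1e-12)
            assert r.c + r.b == pytest.approx(r.r2adj_space, abs=1e-12)

    def test_perfect_env_fit_no_space(self, rng):
        E = pd.DataFrame(rng.normal(size=(10, 1)), columns=["e"])
        Y = E.to_numpy() @ np.ones((1, 4))
        r = variation_partition(Y, E, None, n_perm=49, seed=0)
        assert r.a == pytest.approx(1.0)
        assert r.b == pytest.approx(0.0) and r.c == pytest.approx(0.0)
        assert r.d == pytest.approx(0.0, abs=1e-10)

    def test_identical_sets_share_everything(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["v1", "v2"])
        Y = rng.normal(size=(12, 5))
        r = variation_partition(Y, X, X.copy(), n_perm=49, seed=0)
        assert r.a == pytest.approx(0.0, abs=1e-10)
        assert r.c == pytest.approx(0.0, abs=1e-10)
        assert r.b == pytest.approx(r.r2adj_env, abs=1e-10)


class TestForwardSelect:
    def test_pure_noise_candidate_rarely_selected(self, rng):
        empty = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            Y = r.normal(size=(15, 6))
            cand = pd.DataFrame(r.normal(size=(15, 1)), columns=["noise"])
            steps = forward_select(Y, cand, alpha=0.05, n_perm=199, seed=seed)
            empty += not steps
        assert empty >= 16  # ~95% expected under the null

    def test_perfect_candidate_selected_then_stops(self, rng):
        x = rng.normal(size=(12, 1))
        Y = np.hstack([x, 2 * x])
        cand = pd.DataFrame(np.hstack([x, rng.normal(size=(12, 1))]), columns=["x1", "junk"])
        steps = forward_select(Y, cand, n_perm=199, seed=4)
        assert [s.variable for s in steps] == ["x1"]

    def test_first_step_matches_best_subset_oracle(self, rng):
        cand = pd.DataFrame(rng.normal(size=(14, 3)), columns=["a", "b", "c"])
        # all three candidates carry signal so the global model dominates
        Y = cand.to_numpy() @ rng.normal(size=(3, 5)) + 0.3 * rng.normal(size=(14, 5))
        from nestshore.varpart import rda_r2 as _r2

        best = max(cand.columns, key=lambda c: _r2(Y, cand[[c]])[0])
        steps = forward_select(Y, cand, alpha=1.01, n_perm=99, seed=5)
        assert steps and steps[0].variable == best

    def test_no_candidates_empty_selection(self, rng):
        assert forward_select(rng.normal(size=(10, 3)), pd.DataFrame(index=range(10))) == []
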