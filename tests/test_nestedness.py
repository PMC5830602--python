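"""NODF, matrix temperature, FF nulls, gradient battery, site cover."""

import numpy as np
import pandas as pd
import pytest

from nestshore.datamodel import PresenceMatrix
from nestshore.nestedness import (
    ff_null,
    matrix_temperature,
    min_site_cover,
    nestedness_test,
    nodf,
    nodf_matrix,
    pack_matrix,
    rank_matrix,
    run_gradient_battery,
    temperature_matrix,
)

# reference values computed with an independent implementation of both
# metrics (vegan 2.7); temperature packing breaks ties at random there, so
# its reference is an envelope over tie-break realisations
FIX_A = np.array(
    [[1, 0, 0, 1, 1, 0, 0, 1, 0], [1, 0, 0, 0, 0, 0, 0, 1, 1],
     [1, 1, 0, 1, 0, 1, 1, 1, 1], [0, 1, 1, 1, 0, 0, 0, 1, 0],
     [0, 1, 0, 1, 0, 1, 1, 0, 1], [0, 0, 1, 0, 0, 0, 1, 1, 0]], dtype=np.int8)
FIX_B = np.array(
    [[1, 0, 0, 1, 1, 0, 0, 1], [1, 1, 0, 0, 1, 1, 0, 1],
     [0, 1, 0, 0, 0, 0, 1, 0], [1, 1, 1, 0, 1, 1, 1, 0],
     [1, 0, 0, 0, 0, 1, 0, 0], [0, 0, 0, 0, 1, 0, 0, 1],
     [0, 1, 0, 1, 0, 0, 0, 1], [0, 1, 0, 1, 1, 1, 1, 0]], dtype=np.int8)
FIX_C = np.array(
    [[1, 0, 0, 0, 0, 1, 1], [1, 0, 0, 0, 0, 0, 0], [0, 0, 1, 0, 0, 0, 1],
     [0, 0, 0, 1, 0, 0, 1], [1, 0, 1, 1, 0, 1, 0], [1, 0, 1, 0, 0, 1, 0],
     [0, 0, 1, 0, 0, 1, 0], [1, 1, 0, 1, 1, 0, 0], [0, 1, 0, 1, 0, 1, 0],
     [0, 0, 0, 1, 0, 0, 1]], dtype=np.int8)


def nodf_oracle(M):
    """Literal pairwise enumeration of the NODF definition."""
    nr, nc = M.shape
    rf, cf = M.sum(1), M.sum(0)
    total = 0.0
    for i in range(nr):
        for j in range(i + 1, nr):
            if rf[i] > rf[j] > 0:
                total += (M[i] & M[j]).sum() / rf[j]
    for i in range(nc):
        for j in range(i + 1, nc):
            if cf[i] > cf[j] > 0:
                total += (M[:, i] & M[:, j]).sum() / cf[j]
    return 100 * total / (nr * (nr - 1) / 2 + nc * (nc - 1) / 2)


class TestNodf:
    def test_perfectly_nested_is_100(self):
        M = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0]], dtype=np.int8)
        assert nodf_matrix(M) == pytest.approx(100.0)

    def test_equal_fill_identity_is_zero(self):
        assert nodf_matrix(np.eye(2, dtype=np.int8)) == 0.0

    def test_hand_pairwise_enumeration(self):
        M = np.array([[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 1, 0]], dtype=np.int8)[:, :3]
        assert nodf_matrix(M) == pytest.approx((100 + 100 + 0 + 100 + 100 + 0) / 6)

    @pytest.mark.parametrize("fix,expected", [(FIX_A, 22.38562), (FIX_B, 29.25595), (FIX_C, 20.9596)])
    def test_reference_implementation_values(self, fix, expected):
        assert nodf_matrix(fix) == pytest.approx(expected, abs=1e-4)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            shape = rng.integers(2, 9, size=2)
            M = (rng.random(shape) < rng.uniform(0.2, 0.8)).astype(np.int8)
            assert nodf_matrix(M) == pytest.approx(nodf_oracle(M), abs=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            nodf_matrix(np.ones((1, 4), dtype=np.int8))


class TestTemperature:
    def test_perfect_staircase_is_zero(self):
        for n in (4, 7):
            M = np.tril(np.ones((n, n), dtype=np.int8))
            assert temperature_matrix(M, pack=True) == pytest.approx(0.0, abs=1e-9)

    def test_all_ones_degenerate_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert temperature_matrix(np.ones((3, 3), dtype=np.int8)) == 0.0

    def test_checkerboard_is_hot(self):
        C = (np.indices((6, 6)).sum(0) % 2).astype(np.int8)
        t = temperature_matrix(C, pack=True)
        assert t > 50
        assert t == pytest.approx(87.3058, abs=0.01)  # frozen regression value

    @pytest.mark.parametrize(
        "fix,lo,hi",
        [(FIX_A, 42.22, 44.49), (FIX_B, 37.83, 42.13), (FIX_C, 39.86, 46.98)],
    )
    def test_within_reference_tiebreak_envelope(self, fix, lo, hi):
        assert lo <= temperature_matrix(fix, pack=True) <= hi

    def test_packing_never_increases_temperature_of_staircase_noise(self, rng):
        M = np.tril(np.ones((8, 8), dtype=np.int8))
        M[rng.integers(0, 8, 3), rng.integers(0, 8, 3)] ^= 1
        M = M[M.sum(1) > 0][:, M[M.sum(1) > 0].sum(0) > 0]
        if min(M.shape) >= 2 and 0 < M.sum() < M.size:
            packed = temperature_matrix(M, pack=True)
            given = temperature_matrix(M, pack=False)
            assert packed <= given + 1e-9


class TestFFNull:
    def test_unique_margin_matrix_reproduced_exactly(self):
        M = np.array([[1, 1], [1, 0]], dtype=np.int8)
        for s in ff_null(M, n=20, seed=1):
            assert (s == M).all()

    def test_margins_preserved_every_draw(self, rng):
        M = (rng.random((10, 18)) < 0.35).astype(np.int8)
        rf, cf = M.sum(1), M.sum(0)
        for s in ff_null(M, n=200, seed=2):
            assert (s.sum(1) == rf).all() and (s.sum(0) == cf).all()

    def test_deterministic_under_seed(self, rng):
        M = (rng.random((8, 12)) < 0.4).astype(np.int8)
        a = np.stack(list(ff_null(M, n=10, seed=33)))
        b = np.stack(list(ff_null(M, n=10, seed=33)))
        assert (a == b).all()

    def test_swap_engine_preserves_margins(self, rng):
        M = (rng.random((6, 9)) < 0.5).astype(np.int8)
        rf, cf = M.sum(1), M.sum(0)
        for s in ff_null(M, n=50, algorithm="swap", seed=3):
            assert (s.sum(1) == rf).all() and (s.sum(0) == cf).all()

    def test_column_frequency_order_is_invariant(self, rng):
        M = (rng.random((9, 14)) < 0.4).astype(np.int8)
        order = np.argsort(-M.sum(0), kind="stable")
        for s in ff_null(M, n=30, seed=4):
            assert (np.argsort(-s.sum(0), kind="stable") == order).all()


class TestRankedMatrix:
    def test_drops_empty_rows_and_columns(self):
        inc = pd.DataFrame(
            [[1, 0, 0], [0, 0, 0], [1, 1, 0]],
            index=["a", "b", "c"], columns=["x", "y", "z"],
        )
        rm = rank_matrix(PresenceMatrix(inc))
        assert rm.dropped_rows == ("b",) and rm.dropped_cols == ("z",)
        assert rm.shape == (2, 2)

    def test_default_order_is_decreasing_richness(self):
        inc = pd.DataFrame(
            [[1, 0, 0], [1, 1, 1], [1, 1, 0]],
            index=["poor", "rich", "mid"], columns=["x", "y", "z"],
        )
        rm = rank_matrix(PresenceMatrix(inc))
        assert rm.row_labels == ("rich", "mid", "poor")

    def test_explicit_gradient_order_kept(self):
        inc = pd.DataFrame([[1, 0], [1, 1]], index=["a", "b"], columns=["x", "y"])
        rm = rank_matrix(PresenceMatrix(inc), row_order=("a", "b"), ordering="BI_desc")
        assert rm.row_labels == ("a", "b") and rm.ordering == "BI_desc"


class TestNestednessTest:
    def test_z_formula_and_p_bounds(self, rng):
        M = (rng.random((8, 20)) < 0.4).astype(np.int8)
        inc = pd.DataFrame(M, index=[f"s{i}" for i in range(8)],
                           columns=[f"p{j}" for j in range(20)])
        res = nestedness_test(rank_matrix(PresenceMatrix(inc)), "NODF", n=300, seed=5)
        # internal consistency of the z formula
        assert res.z == pytest.approx((res.observed - res.null_mean) / res.null_sd)
        assert 0 < res.p_one_tailed <= 1

    def test_degenerate_null_flagged(self):
        inc = pd.DataFrame([[1, 1], [1, 0]], index=["a", "b"], columns=["x", "y"])
        res = nestedness_test(rank_matrix(PresenceMatrix(inc)), "NODF", n=50, seed=6)
        assert res.degenerate and np.isnan(res.z)
        assert res.p_one_tailed == pytest.approx(1.0)  # all ties

    def test_directions_of_the_two_metrics_disagree_on_same_deviation(self, rng):
        # NODF above null mean reads nested; T above null mean reads anti-nested
        M = (rng.random((10, 25)) < 0.35).astype(np.int8)
        inc = pd.DataFrame(M, index=[f"s{i}" for i in range(10)],
                           columns=[f"p{j}" for j in range(25)])
        rm = rank_matrix(PresenceMatrix(inc))
        rn = nestedness_test(rm, "NODF", n=200, seed=7)
        rt = nestedness_test(rm, "T", n=200, seed=7)
        if rn.z > 0.5 and rt.z > 0.5:
            assert rn.direction != rt.direction


@pytest.fixture(scope="module")
def battery_inputs():
    from nestshore import datamodel as dm
    from nestshore.morphodynamics import gradient_rankings
    from nestshore.synthetic import ScenarioConfig, generate

    ds = generate(ScenarioConfig(scenario="MIXED", seed=21, n_sites=10, n_species=30))
    pooled = dm.pool_periods(ds.fall, ds.spring)
    presences = {
        "fall": dm.to_presence(ds.fall),
        "spring": dm.to_presence(ds.spring),
        "pooled": dm.to_presence(pooled),
    }
    return presences, gradient_rankings(ds.env)


class TestBattery:
    def test_emits_24_rows_and_is_deterministic(self, battery_inputs):
        presences, rankings = battery_inputs
        t1 = run_gradient_battery(presences, rankings, n_rand=60, seed=9)
        t2 = run_gradient_battery(presences, rankings, n_rand=60, seed=9)
        assert len(t1) == 24  # 3 period sets x 4 orderings x 2 metrics
        assert set(t1["metric"]) == {"NODF", "T"}
        pd.testing.assert_frame_equal(t1, t2)

    def test_different_seed_changes_nulls_not_observed(self, battery_inputs):
        presences, rankings = battery_inputs
        t1 = run_gradient_battery(presences, rankings, n_rand=60, seed=9)
        t3 = run_gradient_battery(presences, rankings, n_rand=60, seed=10)
        assert (t1["obs"] == t3["obs"]).all()
        assert (t1["exp"] != t3["exp"]).any()


class TestMinSiteCover:
    def test_perfectly_nested_needs_one_site(self):
        M = np.tril(np.ones((6, 6), dtype=np.int8))[::-1]
        k, frac, exact = min_site_cover(M)
        assert k == 1 and exact

    def test_diagonal_needs_all_sites(self):
        k, frac, exact = min_site_cover(np.eye(5, dtype=np.int8))
        assert k == 5 and frac == 1.0 and exact

    def test_matches_exhaustive_enumeration(self, rng):
        import itertools

        for _ in range(5):
            M = (rng.random((8, 15)) < 0.3).astype(np.int8)
            M = M[:, M.sum(0) > 0]
            if M.shape[1] < 2:
                continue
            k, _, exact = min_site_cover(M)
            assert exact
            brute = None
            for r in range(1, 9):
                for combo in itertools.combinations(range(8), r):
                    if M[list(combo)].max(axis=0).min() == 1:
                        brute = r
                        break
                if brute:
                    break
            assert k == brute

    def test_greedy_fallback_flagged_inexact(self, rng):
        M = (rng.random((30, 40)) < 0.2).astype(np.int8)
        M = M[:, M.sum(0) > 0]
        k, frac, exact = min_site_cover(M, exact_limit=10)
        assert not exact and 1 <= k <= 30
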