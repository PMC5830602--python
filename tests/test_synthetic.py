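"""Generator contracts: determinism, gradient structure, scenario archetypes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nestshore import datamodel as dm
from nestshore.morphodynamics import gradient_rankings
from nestshore.nestedness import nodf, rank_matrix
from nestshore.synthetic import (
    Scenario,
    ScenarioConfig,
    generate,
    generate_env,
    generate_sites,
    write_dataset,
)


def test_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(n_sites=2, seed=1)
    with pytest.raises(ValueError):
        ScenarioConfig(seed=1, spatial_range_km=0)
    cfg = ScenarioConfig(scenario="env_only".upper(), seed=1)
    assert cfg.scenario is Scenario.ENV_ONLY and cfg.space_effect == 0.0


def test_sites_deterministic_and_separated():
    cfg = ScenarioConfig(seed=42, n_sites=3)
    _, c1 = generate_sites(cfg)
    _, c2 = generate_sites(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    d = np.diff(c1["coast_km"])
    assert (d > 0).all()


def test_full_dataset_bit_identical_under_seed():
    a = generate(ScenarioConfig(scenario="MIXED", seed=9, n_sites=8, n_species=25))
    b = generate(ScenarioConfig(scenario="MIXED", seed=9, n_sites=8, n_species=25))
    pd.testing.assert_frame_equal(a.env, b.env)
    pd.testing.assert_frame_equal(a.fall.counts, b.fall.counts)
    pd.testing.assert_frame_equal(a.spring.counts, b.spring.counts)
    c = generate(ScenarioConfig(scenario="MIXED", seed=10, n_sites=8, n_species=25))
    assert not a.fall.counts.equals(c.fall.counts)


class TestEnvironment:
    def test_bi_within_requested_range(self):
        for seed in range(5):
            ds = generate(ScenarioConfig(scenario="ENV_ONLY", seed=seed))
            lo, hi = ds.config.bi_range
            assert ds.env["beach_index"].between(lo - 1e-9, hi + 1e-9).all()

    def test_space_only_environment_is_constant(self):
        ds = generate(ScenarioConfig(scenario="SPACE_ONLY", seed=4))
        assert ds.env["beach_index"].nunique() == 1
        assert ds.env["slope_ratio"].std() == pytest.approx(0.0, abs=1e-12)

    def test_bi_slope_rank_correlation_negative(self):
        # steeper beaches are more reflective by construction
        rhos = []
        for seed in range(20):
            _, coords = generate_sites(ScenarioConfig(seed=seed))
            env = generate_env(coords, ScenarioConfig(seed=seed))
            rhos.append(spearmanr(env["beach_index"], env["slope_ratio"]).statistic)
        assert np.mean(rhos) < -0.9

    def test_env_only_bi_decorrelated_from_position(self):
        rhos = []
        for seed in range(30):
            cfg = ScenarioConfig(scenario="ENV_ONLY", seed=seed)
            _, coords = generate_sites(cfg)
            env = generate_env(coords, cfg)
            rhos.append(spearmanr(coords["coast_km"], env["beach_index"]).statistic)
        assert abs(np.mean(rhos)) < 0.25


class TestCommunity:
    def test_nested_noiseless_is_perfectly_nested_under_bi_order(self):
        # every strictly-decreasing pair overlaps completely, so NODF hits
        # the maximum attainable for the margins (tied identical columns
        # score 0 under the strict-decrease rule, so 100 itself is out of
        # reach whenever species outnumber occupancy levels)
        ds = generate(ScenarioConfig(scenario="NESTED", seed=3, nested_noise=0.0))
        for m in (ds.fall, dm.pool_periods(ds.fall, ds.spring)):
            rk = gradient_rankings(ds.env)["BI_desc"]
            rm = rank_matrix(dm.to_presence(m), row_order=rk.order)
            M = rm.matrix
            for i in range(M.shape[0] - 1):  # poorer rows are strict subsets
                assert (M[i + 1] <= M[i]).all()
            rf, cf = M.sum(1), M.sum(0)
            nr, nc = M.shape
            strict_rows = sum(rf[i] > rf[j] for i in range(nr) for j in range(i + 1, nr))
            strict_cols = sum(cf[i] > cf[j] for i in range(nc) for j in range(i + 1, nc))
            max_nodf = 100.0 * (strict_rows + strict_cols) / (
                nr * (nr - 1) / 2 + nc * (nc - 1) / 2)
            assert nodf(rm) == pytest.approx(max_nodf)
            assert rf.tolist() == sorted(rf, reverse=True)  # richness tracks BI

    def test_mean_count_monotone_in_mean_abundance(self):
        means = []
        for ma in (0.3, 0.9, 2.7):
            ds = generate(ScenarioConfig(scenario="MIXED", seed=6, mean_abundance=ma))
            means.append(ds.fall.counts.to_numpy().mean())
        assert means[0] < means[1] < means[2]

    def test_turnover_optima_equally_spaced(self):
        ds = generate(ScenarioConfig(scenario="TURNOVER", seed=2))
        opt = np.array(ds.truth.species_optima)
        assert np.allclose(np.diff(opt), np.diff(opt)[0])
        assert ds.truth.expected_nestedness == "anti-nested"

    def test_periods_are_distinct_draws_from_shared_intensity(self):
        ds = generate(ScenarioConfig(scenario="MIXED", seed=8))
        assert not ds.fall.counts.equals(ds.spring.counts)
        # shared intensities leave a cell-level association across periods
        a = np.log1p(ds.fall.counts.to_numpy().ravel())
        b = np.log1p(ds.spring.counts.to_numpy().ravel())
        rho = spearmanr(a, b).statistic
        assert rho > 0.2


def test_write_dataset_roundtrip(tmp_path):
    ds = generate(ScenarioConfig(scenario="MIXED", seed=12, n_sites=6, n_species=15))
    write_dataset(ds, tmp_path)
    for f in ("sites.csv", "env.csv", "community_fall.csv", "community_spring.csv", "truth.json"):
        assert (tmp_path / f).exists()
    back = dm.read_community(tmp_path / "community_fall.csv", period="fall")
    pd.testing.assert_frame_equal(back.counts, ds.fall.counts)
    env = dm.read_env(tmp_path / "env.csv")
    assert list(env.index) == list(ds.env.index)
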