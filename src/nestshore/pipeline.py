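"""End-to-end orchestration: environment -> BI -> pooling check -> dbMEM ->
forward selection -> variation partitioning -> NMDS -> nestedness battery ->
richness correlations, with seeded reproducibility and CSV/JSON artifacts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import datamodel as dm
from . import dissimilarity as ds
from . import morphodynamics as morpho
from . import nestedness as nest
from . import spatial
from . import varpart as vp

log = logging.getLogger("nestshore")

ENV_PREDICTORS = ["slope_ratio", "width_m", "beach_index", "mean_diameter_phi"]


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    n: int
    r: float
    t: float
    p: float


def pearson(x, y, labels: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation with the t-based two-tailed p (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    t = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf
    return CorrelationResult(pair=labels, n=n, r=float(r), t=float(t), p=float(p))


def scenario_varpart(ds, n_perm: int = 199, seed: int = 0) -> vp.VarPartResult:
    """Forward selection + variation partitioning on a synthetic dataset.

    The in-memory analogue of the varpart stage of :func:`run_all`; used by
    recovery studies that score whether the generator's dominant fraction
    ([a] vs [c]) is identified.
    """
    pooled = dm.pool_periods(ds.fall, ds.spring)
    Y = vp.hellinger(pooled.counts.loc[:, (pooled.counts != 0).any(axis=0)])
    E_cand = ds.env[ENV_PREDICTORS]
    D = spatial.distance_matrix(ds.coords[["latitude", "longitude"]].to_numpy())
    basis = spatial.dbmem(D, site_order=tuple(pooled.sites))
    S_cand = pd.DataFrame(basis.vectors, index=pooled.sites, columns=basis.names())
    s1, s2, s3 = _child_seeds(seed, 3)
    env_steps = vp.forward_select(Y, E_cand, n_perm=n_perm, seed=s1)
    mem_steps = vp.forward_select(Y, S_cand, n_perm=n_perm, seed=s2)
    E = E_cand[[s.variable for s in env_steps]] if env_steps else None
    S = S_cand[[s.variable for s in mem_steps]] if mem_steps else None
    return vp.variation_partition(Y, E, S, n_perm=n_perm, seed=s3)


def scenario_nestedness(ds, metric: str = "NODF", n_rand: int = 300, seed: int = 0,
                        ordering: str = "BI_desc"):
    """Gradient-ordered nestedness test on a synthetic dataset (pooled periods)."""
    pooled = dm.pool_periods(ds.fall, ds.spring)
    ranking = morpho.gradient_rankings(ds.env)[ordering]
    rm = nest.rank_matrix(dm.to_presence(pooled), row_order=ranking.order, ordering=ordering)
    return nest.nestedness_test(rm, metric=metric, n=n_rand, seed=seed)


@dataclass
class RunConfig:
    """Paths, parameters and per-stage toggles for a full pipeline run."""

    community_fall: str
    community_spring: str
    sites: str
    env: str
    out_dir: str
    seed: int
    tide_range_m: float = morpho.DEFAULT_TIDE_RANGE_M
    n_perm: int = 10000
    n_rand: int = 1000
    forward_n_perm: int = 999
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "morphodynamics": True,
            "procrustes": True,
            "varpart": True,
            "nmds": True,
            "nestedness": True,
            "correlations": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        stages = raw.pop("stages", None)
        cfg = cls(**raw)
        if stages:
            cfg.stages.update(stages)
        for key in ("community_fall", "community_spring", "sites", "env"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")
        return cfg


def _child_seeds(master: int, n: int) -> list[int]:
    rng = np.random.default_rng(master)
    return [int(s) for s in rng.integers(2**31 - 1, size=n)]


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; writes artifacts under ``out_dir`` and
    returns the in-memory results keyed by stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(
        ("procrustes", "varpart_select", "varpart", "nmds", "nestedness"),
        _child_seeds(config.seed, 5),
    ))
    results: dict = {}

    fall = dm.read_community(config.community_fall, period="fall")
    spring = dm.read_community(config.community_spring, period="spring")
    pooled = dm.pool_periods(fall, spring)
    sites = pd.read_csv(config.sites, index_col="site_id")
    env = dm.read_env(config.env)

    if config.stages.get("morphodynamics", True):
        log.info("stage: morphodynamics")
        env_bi = morpho.add_beach_index(env, config.tide_range_m)
        env_bi["state"] = [
            morpho.classify_state(b, w).value
            for b, w in zip(env_bi["beach_index"], env_bi["width_m"])
        ]
        env_bi.to_csv(out / "env_bi.csv")
        results["env_bi"] = env_bi
    else:
        env_bi = morpho.add_beach_index(env, config.tide_range_m)

    if config.stages.get("procrustes", True):
        log.info("stage: procrustes pooling check")
        pr = ds.period_procrustes(fall.counts, spring.counts, n_perm=999, seed=seeds["procrustes"])
        (out / "procrustes.json").write_text(json.dumps(
            {"m2": pr.m2, "correlation": pr.correlation, "p": pr.p, "n_perm": pr.n_perm}, indent=1))
        results["procrustes"] = pr

    if config.stages.get("varpart", True):
        log.info("stage: dbMEM + forward selection + variation partitioning")
        coords = sites[["latitude", "longitude"]].loc[pooled.sites].to_numpy()
        D = spatial.distance_matrix(coords)
        basis = spatial.dbmem(D, site_order=tuple(pooled.sites))
        mem_df = pd.DataFrame(basis.vectors, index=pooled.sites, columns=basis.names())
        mem_df.to_csv(out / "mem.csv")
        Y = vp.hellinger(pooled.counts.loc[:, (pooled.counts != 0).any(axis=0)])
        E_cand = env_bi.loc[pooled.sites, ENV_PREDICTORS]
        sel_seeds = _child_seeds(seeds["varpart_select"], 2)
        env_steps = vp.forward_select(Y, E_cand, n_perm=config.forward_n_perm, seed=sel_seeds[0])
        mem_steps = vp.forward_select(Y, mem_df, n_perm=config.forward_n_perm, seed=sel_seeds[1])
        E = E_cand[[s.variable for s in env_steps]] if env_steps else None
        S = mem_df[[s.variable for s in mem_steps]] if mem_steps else None
        res = vp.variation_partition(Y, E, S, n_perm=config.n_perm, seed=seeds["varpart"])
        trace = pd.DataFrame(
            [{"component": comp, "variable": s.variable, "cum_r2": s.cum_r2,
              "cum_r2adj": s.cum_r2adj, "F": s.f, "p": s.p}
             for comp, steps in (("environmental", env_steps), ("spatial", mem_steps))
             for s in steps]
        )
        trace.to_csv(out / "forward_selection.csv", index=False)
        (out / "varpart.json").write_text(json.dumps({
            "a": round(res.a, 6), "b": round(res.b, 6), "c": round(res.c, 6),
            "d": round(res.d, 6), "F_a": res.f_a, "p_a": res.p_a,
            "F_c": res.f_c, "p_c": res.p_c, "n_perm": res.n_perm,
            "env_vars": list(res.env_vars), "space_vars": list(res.space_vars),
            "dbmem_threshold_km": basis.threshold_km,
        }, indent=1, default=float))
        results["varpart"] = res
        results["mem"] = basis
        results["forward_selection"] = trace

    if config.stages.get("nmds", True):
        log.info("stage: Bray-Curtis / NMDS")
        D_bc = ds.bray_curtis(pooled.counts.to_numpy())
        ord_res = ds.nmds(D_bc, k=2, seed=seeds["nmds"])
        conf = pd.DataFrame(ord_res.configuration, index=pooled.sites, columns=["NMDS1", "NMDS2"])
        conf.to_csv(out / "nmds_config.csv")
        (out / "nmds.json").write_text(json.dumps(
            {"stress": ord_res.stress, "n_starts": ord_res.n_starts,
             "converged": ord_res.converged}, indent=1))
        results["nmds"] = ord_res

    if config.stages.get("nestedness", True):
        log.info("stage: gradient nestedness battery")
        rankings = morpho.gradient_rankings(env_bi)
        presences = {
            "fall": dm.to_presence(fall),
            "spring": dm.to_presence(spring),
            "pooled": dm.to_presence(pooled),
        }
        table4 = nest.run_gradient_battery(
            presences, rankings, n_rand=config.n_rand, seed=seeds["nestedness"])
        table4.to_csv(out / "table_nestedness.csv", index=False)
        pooled_inc = presences["pooled"].incidence
        observed = dm.PresenceMatrix(pooled_inc.loc[:, pooled_inc.sum(axis=0) > 0])
        k, frac, exact = nest.min_site_cover(observed)
        (out / "site_cover.json").write_text(json.dumps(
            {"k": k, "fraction": frac, "exact": exact}, indent=1))
        results["nestedness"] = table4
        results["site_cover"] = (k, frac, exact)

    if config.stages.get("correlations", True):
        log.info("stage: richness correlations (site x period resolution)")
        rows = []
        rich = pd.concat([dm.richness(fall), dm.richness(spring)])
        for var in ("beach_index", "slope_ratio", "mean_diameter_phi", "width_m"):
            v = pd.concat([env_bi.loc[fall.sites, var], env_bi.loc[spring.sites, var]])
            c = pearson(v.to_numpy(), rich.to_numpy(), labels=(var, "richness"))
            rows.append({"variable": var, "n": c.n, "r": round(c.r, 4),
                         "t": round(c.t, 4), "p": round(c.p, 4)})
        corr = pd.DataFrame(rows)
        corr.to_csv(out / "richness_correlations.csv", index=False)
        excl = dm.exclusive_species(pooled)
        pd.Series({g: len(s) for g, s in excl.items()}, name="n_exclusive").rename_axis(
            "site_id").to_csv(out / "exclusive_species.csv")
        results["correlations"] = corr
        results["exclusive"] = excl

    return results
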