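"""Nestedness metrics under gradient orderings with fixed-fixed null models.

A metacommunity is *nested* when species-poor sites hold subsets of the
species found at species-rich sites. Two classic metrics are implemented:

* NODF ("nestedness metric based on overlap and decreasing fill"):
  averages, over ordered row pairs and column pairs with strictly
  decreasing marginal totals, the percentage of the later line's presences
  shared with the earlier line. 0 = no nestedness, 100 = perfect.
* Matrix temperature T: disorder of the incidence matrix relative to the
  isocline of perfect nestedness for the same fill, 0 (perfectly nested)
  to 100 degrees. Uses the Rodriguez-Girones & Santamaria parametrization
  (Umax = 0.04145).

Observed values are compared with a fixed-fixed (FF) null model that
preserves every row and column total, sampled by the curveball algorithm.
Site (row) order can be an explicit morphodynamic gradient so the test asks
whether nestedness arises *along that gradient*; columns are always ranked
by decreasing species frequency, which FF nulls preserve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numba
import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .datamodel import PresenceMatrix

UMAX = 0.04145


# ---------------------------------------------------------------------------
# ranked matrices

@dataclass
class RankedMatrix:
    """Presence matrix with explicit row and column orders applied.

    Rows follow the supplied gradient (or decreasing richness); columns are
    ordered by decreasing frequency with ties broken by species id. Empty
    rows and columns are dropped and recorded.
    """

    matrix: np.ndarray  # rows/cols already permuted, int8
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    ordering: str
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def rank_matrix(
    pm: PresenceMatrix, row_order: tuple[str, ...] | list[str] | None = None,
    ordering: str = "richness_desc",
) -> RankedMatrix:
    """Apply a row ordering and the decreasing-frequency column ordering.

    ``row_order=None`` ranks sites by decreasing richness (ties by site id);
    otherwise ``row_order`` is an explicit permutation of the site ids.
    """
    inc = pm.incidence
    dropped_rows = tuple(str(s) for s in inc.index[inc.sum(axis=1) == 0])
    dropped_cols = tuple(str(s) for s in inc.columns[inc.sum(axis=0) == 0])
    inc = inc.loc[inc.sum(axis=1) > 0, inc.sum(axis=0) > 0]
    if row_order is None:
        rf = inc.sum(axis=1)
        rows = sorted(inc.index, key=lambda s: (-rf[s], str(s)))
    else:
        rows = [s for s in row_order if s in inc.index]
        missing = set(inc.index) - set(rows)
        if missing:
            raise ValueError(f"row_order does not cover sites: {sorted(missing)}")
    cf = inc.sum(axis=0)
    cols = sorted(inc.columns, key=lambda s: (-cf[s], str(s)))
    sub = inc.loc[rows, cols]
    return RankedMatrix(
        matrix=sub.to_numpy(dtype=np.int8),
        row_labels=tuple(map(str, rows)),
        col_labels=tuple(map(str, cols)),
        ordering=ordering,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
    )


# ---------------------------------------------------------------------------
# NODF

def nodf_matrix(M: np.ndarray) -> float:
    """NODF of a 0/1 matrix in its given row and column order."""
    M = np.asarray(M)
    nr, nc = M.shape
    if nr < 2 or nc < 2:
        raise ValueError("NODF needs at least 2 rows and 2 columns")
    rf = M.sum(axis=1)
    cf = M.sum(axis=0)
    Mf = M.astype(float)
    # rows: overlap of each ordered pair (earlier i, later j), counted when
    # fill strictly decreases
    O = Mf @ Mf.T
    iu = np.triu_indices(nr, 1)
    dec = rf[iu[0]] > rf[iu[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        row_scores = np.where(dec & (rf[iu[1]] > 0), O[iu] / rf[iu[1]], 0.0)
    C = Mf.T @ Mf
    ju = np.triu_indices(nc, 1)
    decc = cf[ju[0]] > cf[ju[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        col_scores = np.where(decc & (cf[ju[1]] > 0), C[ju] / cf[ju[1]], 0.0)
    denom = nr * (nr - 1) / 2 + nc * (nc - 1) / 2
    return float(100.0 * (row_scores.sum() + col_scores.sum()) / denom)


def nodf(rm: RankedMatrix) -> float:
    return nodf_matrix(rm.matrix)


def _nodf_pair_weights(rf: np.ndarray, cf: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Constant NODF pair weights for a family of matrices sharing margins.

    W[i, j] = 1/fill(j) for ordered pairs with strictly decreasing fill,
    else 0; NODF = 100 * (sum(O * Wr) + sum(C * Wc)) / n_pairs where O and
    C are the row/column overlap matrices.
    """
    nr, nc = len(rf), len(cf)
    Wr = np.zeros((nr, nr))
    iu = np.triu_indices(nr, 1)
    dec = (rf[iu[0]] > rf[iu[1]]) & (rf[iu[1]] > 0)
    Wr[iu[0][dec], iu[1][dec]] = 1.0 / rf[iu[1][dec]]
    Wc = np.zeros((nc, nc))
    ju = np.triu_indices(nc, 1)
    decc = (cf[ju[0]] > cf[ju[1]]) & (cf[ju[1]] > 0)
    Wc[ju[0][decc], ju[1][decc]] = 1.0 / cf[ju[1][decc]]
    denom = nr * (nr - 1) / 2 + nc * (nc - 1) / 2
    return Wr, Wc, denom


def _nodf_on_stack(samples: np.ndarray, Wr: np.ndarray, Wc: np.ndarray, denom: float) -> np.ndarray:
    """NODF for a (k, nr, nc) stack of matrices sharing the same margins."""
    S = samples.astype(np.float32)
    out = np.empty(len(S))
    step = max(1, int(2e7 // (S.shape[2] * S.shape[2] + 1)))
    for lo in range(0, len(S), step):
        chunk = S[lo:lo + step]
        O = chunk @ chunk.transpose(0, 2, 1)
        C = chunk.transpose(0, 2, 1) @ chunk
        out[lo:lo + step] = (
            (O * Wr[None]).sum(axis=(1, 2)) + (C * Wc[None]).sum(axis=(1, 2))
        )
    return 100.0 * out / denom


# ---------------------------------------------------------------------------
# matrix temperature

def _rank_first(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n, ties broken by position (deterministic)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(x) + 1)
    return ranks.astype(float)


def _rank_average(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    return rankdata(x)


def _colpack(x: np.ndarray, rr: np.ndarray) -> np.ndarray:
    ind = np.tile(rr[:, None], (1, x.shape[1]))
    s = -((x * ind) ** 2).sum(axis=0)
    t = -((x.shape[0] - (1 - x) * ind + 1) ** 2).sum(axis=0)
    return _rank_first(s + t)


def _rowpack(x: np.ndarray, cr: np.ndarray) -> np.ndarray:
    ind = np.tile(cr[None, :], (x.shape[0], 1))
    s = -((x * ind) ** 2).sum(axis=1)
    t = -((x.shape[1] - (1 - x) * ind + 1) ** 2).sum(axis=1)
    return _rank_first(s + t)


def pack_matrix(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Iteratively re-rank rows and columns to maximise nested packing.

    Returns (packed matrix, row permutation, column permutation). The
    procedure alternates row/column re-ranking eight times; ties break by
    current position, so packing is deterministic.
    """
    M = np.asarray(M, dtype=float)
    nr, nc = M.shape
    if nc >= nr:
        i = _rank_average(-M.sum(axis=1))
    else:
        j = _rank_average(-M.sum(axis=0))
        i = _rowpack(M, j)
    for _ in range(8):
        j = _colpack(M, i)
        i = _rowpack(M, j)
    if nc < nr:
        j = _colpack(M, i)
    rperm = np.argsort(i, kind="stable")
    cperm = np.argsort(j, kind="stable")
    return M[np.ix_(rperm, cperm)].astype(np.int8), rperm, cperm


def _isocline_p(fill: float) -> float:
    def fillfun_area(p: float) -> float:
        return quad(lambda x: 1 - (1 - (1 - x) ** p) ** (1 / p), 0, 1, limit=200)[0] - fill

    lo, hi = 1e-6, 20.0
    # area is decreasing in p; expand the bracket downward if needed
    while fillfun_area(hi) > 0 and hi < 1e6:
        hi *= 2
    while fillfun_area(lo) < 0 and lo > 1e-12:
        lo /= 2
    return brentq(fillfun_area, lo, hi, xtol=1e-12)


def _temperature_surface(nr: int, nc: int, fill: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell squared normalized distance to the isocline and its sign.

    Returns (u2, sign) where sign > 0 marks cells above the isocline
    (presences there are unexpected) and sign < 0 cells below (absences
    there are unexpected).
    """
    p = _isocline_p(fill)

    def fillfun(x: float) -> float:
        return 1 - (1 - (1 - x) ** p) ** (1 / p)

    r = (np.arange(1, nr + 1) - 0.5) / nr
    c = (np.arange(1, nc + 1) - 0.5) / nc
    dis = np.tile(r[:, None], (1, nc))
    totdis = 1 - np.abs(r[:, None] - c[None, :])
    out = np.empty((nr, nc))
    cache: dict[float, float] = {}
    for i in range(nr):
        for j in range(nc):
            a = c[j] - r[i]
            key = round(a, 12)
            if key not in cache:
                cache[key] = brentq(lambda x: fillfun(x) - a - x, 0.0, 1.0, xtol=1e-12)
            out[i, j] = cache[key]
    u = (dis - out) / totdis
    return u**2, np.sign(u)


def temperature_matrix(M: np.ndarray, pack: bool = True) -> float:
    """Matrix temperature T in [0, 100] of a 0/1 matrix.

    ``pack=True`` re-sorts rows and columns to the most packed arrangement
    first (the classic definition); ``pack=False`` scores the matrix in its
    given (gradient) order. Degenerate fills (all zeros or all ones) return
    0 with a warning.
    """
    M = np.asarray(M)
    nr, nc = M.shape
    if nr < 2 or nc < 2:
        raise ValueError("temperature needs at least 2 rows and 2 columns")
    fill = M.sum() / M.size
    if fill in (0.0, 1.0):
        warnings.warn("degenerate fill; temperature defined as 0")
        return 0.0
    if pack:
        M, _, _ = pack_matrix(M)
    u2, sign = _temperature_surface(nr, nc, fill)
    contrib = np.where(((sign > 0) & (M == 1)) | ((sign < 0) & (M == 0)), u2, 0.0)
    return float(100.0 * contrib.sum() / (nr * nc) / UMAX)


def matrix_temperature(rm: RankedMatrix, ordering: str = "pack") -> float:
    if ordering not in ("pack", "gradient"):
        raise ValueError("ordering must be 'pack' or 'gradient'")
    return temperature_matrix(rm.matrix, pack=(ordering == "pack"))


# ---------------------------------------------------------------------------
# fixed-fixed null model

@numba.njit(cache=False)
def _curveball_chain(M: np.ndarray, n: int, thin: int, burn_in: int, seed: int) -> np.ndarray:
    """Run the curveball Markov chain in place, emitting n samples.

    One trade: pick two distinct rows, pool the species unique to each,
    reshuffle the pool between them (fixed per-row quota). Preserves both
    margins; the stationary distribution is uniform on the fixed-margin
    state space.
    """
    nr, nc = M.shape
    out = np.empty((n, nr, nc), dtype=np.int8)
    buf = np.empty(nc, dtype=np.int64)
    # xorshift64* stream; all state arithmetic stays in uint64
    state = np.uint64(seed) * np.uint64(2862933555777941757) + np.uint64(3037000493)
    mult = np.uint64(2685821657736338717)
    total = burn_in + n * thin
    emitted = 0
    for step in range(total):
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        i = np.int64(((state * mult) >> np.uint64(33)) % np.uint64(nr))
        state ^= state >> np.uint64(12)
        state ^= state << np.uint64(25)
        state ^= state >> np.uint64(27)
        j = np.int64(((state * mult) >> np.uint64(33)) % np.uint64(nr - 1))
        if j >= i:
            j += 1
        la = 0
        for k in range(nc):
            if M[i, k] == 1 and M[j, k] == 0:
                buf[la] = k
                la += 1
        lb = 0
        for k in range(nc):
            if M[j, k] == 1 and M[i, k] == 0:
                buf[la + lb] = k
                lb += 1
        if la > 0 and lb > 0:
            # Fisher-Yates over the pooled exclusives
            for k in range(la + lb - 1, 0, -1):
                state ^= state >> np.uint64(12)
                state ^= state << np.uint64(25)
                state ^= state >> np.uint64(27)
                r = np.int64(((state * mult) >> np.uint64(33)) % np.uint64(k + 1))
                tmp = buf[k]
                buf[k] = buf[r]
                buf[r] = tmp
            for k in range(la):
                M[i, buf[k]] = 1
                M[j, buf[k]] = 0
            for k in range(la, la + lb):
                M[i, buf[k]] = 0
                M[j, buf[k]] = 1
        if step >= burn_in and (step - burn_in + 1) % thin == 0:
            out[emitted] = M
            emitted += 1
    return out


def _swap_trade(M: np.ndarray, rng: np.random.Generator) -> None:
    """One attempted 2x2 checkerboard swap (in place)."""
    nr, nc = M.shape
    r = rng.choice(nr, size=2, replace=False)
    c = rng.choice(nc, size=2, replace=False)
    sub = M[np.ix_(r, c)]
    if sub[0, 0] == sub[1, 1] and sub[0, 1] == sub[1, 0] and sub[0, 0] != sub[0, 1]:
        M[np.ix_(r, c)] = sub[::-1]


def ff_null(
    M: np.ndarray,
    n: int = 1000,
    algorithm: str = "curveball",
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int | None = None,
) -> Iterator[np.ndarray]:
    """Stream of ``n`` fixed-fixed null matrices (row and column totals
    preserved exactly).

    The curveball algorithm trades species between random row pairs; the
    chain burns in for ``burn_in`` trades (default 10 x fill) and emits a
    sample every ``thin`` trades (default fill). ``algorithm='swap'`` uses
    classic 2x2 checkerboard swaps instead.
    """
    M = np.asarray(M).astype(np.int8)
    nr, nc = M.shape
    fill = int(M.sum())
    if burn_in is None:
        burn_in = 10 * max(fill, 1)
    if thin is None:
        thin = max(fill, 1)
    rng = np.random.default_rng(seed)
    if algorithm == "curveball":
        chain_seed = int(rng.integers(1, 2**62))
        samples = _curveball_chain(M.copy(), n, thin, burn_in, chain_seed)
        yield from samples
    elif algorithm == "swap":
        cur = M.copy()
        for _ in range(burn_in):
            _swap_trade(cur, rng)
        for _ in range(n):
            for _ in range(thin):
                _swap_trade(cur, rng)
            yield cur.copy()
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# tests and battery

@dataclass
class NestednessResult:
    """Observed metric vs its fixed-fixed null distribution."""

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # nan when null_sd == 0
    p_one_tailed: float
    direction: str  # "nested" | "anti-nested"
    n_rand: int
    null_model: str = "FF"
    seed: int | None = None
    ordering: str = "richness_desc"
    period: str = "pooled"
    degenerate: bool = False


def _metric_values_on_nulls(
    rm: RankedMatrix, metrics: tuple[str, ...], n: int, seed: int | None,
    algorithm: str = "curveball",
) -> dict[str, np.ndarray]:
    """Evaluate metrics over one shared FF null stream (margin-preserving,
    so the frequency-based column order stays valid for every draw)."""
    rf = rm.matrix.sum(axis=1)
    cf = rm.matrix.sum(axis=0)
    samples = np.stack(list(ff_null(rm.matrix, n=n, seed=seed, algorithm=algorithm)))
    assert (samples.sum(axis=2) == rf).all() and (samples.sum(axis=1) == cf).all(), \
        "FF null failed to preserve margins"
    vals: dict[str, np.ndarray] = {}
    if "NODF" in metrics:
        Wr, Wc, denom = _nodf_pair_weights(rf, cf)
        vals["NODF"] = _nodf_on_stack(samples, Wr, Wc, denom)
    if "T" in metrics:
        nr, nc = rm.shape
        u2, sign = _temperature_surface(nr, nc, rm.matrix.sum() / rm.matrix.size)
        pos = np.where(sign > 0, u2, 0.0)
        neg = np.where(sign < 0, u2, 0.0)
        # presences right of the isocline + absences left of it
        contrib = (samples * pos[None]).sum(axis=(1, 2)) + ((1 - samples) * neg[None]).sum(axis=(1, 2))
        vals["T"] = 100.0 * contrib / (nr * nc) / UMAX
    return vals


def _summarize(metric: str, obs: float, nulls: np.ndarray, seed, ordering, period) -> NestednessResult:
    mu = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
    if sd > 0:
        z = (obs - mu) / sd
        degenerate = False
    else:
        z = np.nan
        degenerate = True
    # direction of the observed deviation
    deviation_up = obs >= mu
    if metric == "NODF":
        direction = "nested" if deviation_up else "anti-nested"
    else:  # temperature: low = nested
        direction = "anti-nested" if deviation_up else "nested"
    if deviation_up:
        count = int((nulls >= obs).sum())
    else:
        count = int((nulls <= obs).sum())
    p = (count + 1) / (len(nulls) + 1)
    return NestednessResult(
        metric=metric, observed=float(obs), null_mean=mu, null_sd=sd,
        z=float(z) if not degenerate else np.nan, p_one_tailed=float(p),
        direction=direction, n_rand=len(nulls), seed=seed,
        ordering=ordering, period=period, degenerate=degenerate,
    )


def nestedness_test(
    rm: RankedMatrix, metric: str = "NODF", n: int = 1000, seed: int | None = None,
    period: str = "pooled",
) -> NestednessResult:
    """Observed metric vs FF nulls: z-score (obs - mean)/sd and a one-tailed
    empirical p in the observed direction."""
    if metric == "NODF":
        obs = nodf(rm)
    elif metric == "T":
        obs = matrix_temperature(rm, ordering="gradient")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    nulls = _metric_values_on_nulls(rm, (metric,), n, seed)[metric]
    return _summarize(metric, obs, nulls, seed, rm.ordering, period)


def run_gradient_battery(
    presences: dict[str, PresenceMatrix],
    rankings: dict[str, "object"],
    metrics: tuple[str, ...] = ("NODF", "T"),
    n_rand: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One nestedness test per (period x ordering x metric).

    ``presences`` maps period label -> PresenceMatrix (typically fall,
    spring, pooled); ``rankings`` maps ordering name -> GradientRanking.
    Null streams are shared between metrics within a (period, ordering)
    cell. Returns a long table: period, ordering, metric, obs, exp, sd, z,
    p, direction.
    """
    rows = []
    master = np.random.default_rng(seed)
    for period, pm in presences.items():
        for oname, ranking in rankings.items():
            child_seed = int(master.integers(2**31 - 1))
            rm = rank_matrix(pm, row_order=ranking.order, ordering=oname)
            obs = {m: (nodf(rm) if m == "NODF" else matrix_temperature(rm, "gradient")) for m in metrics}
            nulls = _metric_values_on_nulls(rm, tuple(metrics), n_rand, child_seed)
            for m in metrics:
                res = _summarize(m, obs[m], nulls[m], child_seed, oname, period)
                rows.append(
                    dict(period=period, ordering=oname, metric=m, obs=res.observed,
                         exp=res.null_mean, sd=res.null_sd, z=res.z, p=res.p_one_tailed,
                         direction=res.direction)
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# minimal site cover

def min_site_cover(pm: PresenceMatrix | np.ndarray, exact_limit: int = 25) -> tuple[int, float, bool]:
    """Minimum number of sites whose union of presences covers all species.

    A high required fraction (> ~40% of sites) diagnoses a turnover-
    dominated, anti-nested dataset. Exact branch-and-bound for up to
    ``exact_limit`` sites; greedy upper bound (flagged inexact) beyond.
    Returns (k, fraction of sites, exact?).
    """
    M = pm.incidence.to_numpy() if isinstance(pm, PresenceMatrix) else np.asarray(pm)
    if M.size == 0:
        raise ValueError("empty matrix")
    if (M.sum(axis=0) == 0).any():
        raise ValueError("species with zero occurrences; drop them first")
    n = M.shape[0]
    masks = [int("".join(map(str, row[::-1])), 2) for row in M.astype(int)]
    full = 0
    for m in masks:
        full |= m

    def greedy() -> int:
        cov, k = 0, 0
        remaining = list(masks)
        while cov != full:
            best = max(remaining, key=lambda m: bin(m & ~cov & full).count("1"))
            cov |= best
            k += 1
        return k

    ub = greedy()
    if n > exact_limit:
        return ub, ub / n, False

    species_cols = [int(c) for c in range(M.shape[1])]
    covers = {c: [i for i in range(n) if M[i, c]] for c in species_cols}
    best_k = ub

    def dfs(cov: int, used: int, chosen: int) -> None:
        nonlocal best_k
        if cov == full:
            best_k = min(best_k, chosen)
            return
        if chosen + 1 >= best_k:
            return
        # branch on the uncovered species with fewest covering sites
        target = min(
            (c for c in species_cols if not (cov >> c) & 1),
            key=lambda c: len(covers[c]),
        )
        for i in covers[target]:
            if (used >> i) & 1:
                continue
            dfs(cov | masks[i], used | (1 << i), chosen + 1)

    dfs(0, 0, 0)
    return best_k, best_k / n, True
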