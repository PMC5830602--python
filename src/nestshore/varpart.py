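"""Hellinger transformation, RDA with adjusted R2, forward selection with
double stopping, partial-RDA permutation tests, and two-component variation
partitioning.

Variation partitioning decomposes the explained variance of a (Hellinger-
transformed) community matrix into the pure environmental fraction [a], the
spatially structured environmental fraction [b] (shared), the pure spatial
fraction [c], and the residual [d], using adjusted R2 from redundancy
analysis:

    a = R2adj(E+S) - R2adj(S)
    c = R2adj(E+S) - R2adj(E)
    b = R2adj(E) + R2adj(S) - R2adj(E+S)
    d = 1 - R2adj(E+S)

[a] and [c] are testable fractions; their significance is assessed by
permutation of reduced-model residuals (Freedman-Lane).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _as_array(X) -> np.ndarray:
    A = np.asarray(X, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    return A


def hellinger(Y) -> np.ndarray:
    """Square root of relative abundance per row.

    y'_ij = sqrt(y_ij / sum_j y_ij). Errors on negative entries or an
    all-zero row; warns when rows already have unit sum of squares (the
    transform is not idempotent, so re-application is usually a mistake).
    """
    A = _as_array(Y)
    if (A < 0).any():
        raise ValueError("abundances must be non-negative")
    sums = A.sum(axis=1)
    if (sums == 0).any():
        i = int(np.flatnonzero(sums == 0)[0])
        name = Y.index[i] if isinstance(Y, pd.DataFrame) else i
        raise ValueError(f"all-zero row for site {name!r}")
    if np.allclose((A**2).sum(axis=1), 1.0, atol=1e-8):
        warnings.warn("rows already unit-norm; input may already be Hellinger-transformed")
    out = np.sqrt(A / sums[:, None])
    if isinstance(Y, pd.DataFrame):
        return pd.DataFrame(out, index=Y.index, columns=Y.columns)
    return out


def _center(A: np.ndarray) -> np.ndarray:
    return A - A.mean(axis=0, keepdims=True)


def _fit_r2(Yc: np.ndarray, Xc: np.ndarray) -> float:
    """R2 of multivariate least squares of centered Y on centered X."""
    if Xc.shape[1] == 0:
        return 0.0
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    ss_tot = float((Yc**2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return float((fitted**2).sum()) / ss_tot


def rda_r2(Y, X) -> tuple[float, float, float]:
    """Redundancy analysis fit: returns (R2, adjusted R2, pseudo-F).

    R2 sums squared fitted values over all response columns relative to the
    total (centered) sum of squares; the adjustment is Ezekiel's
    1 - (1 - R2)(n - 1)/(n - m - 1) with m = number of predictors.
    """
    Yc = _center(_as_array(Y))
    Xc = _center(_as_array(X))
    n, m = Xc.shape
    if m > 0:
        rank = np.linalg.matrix_rank(Xc)
        if rank < m:
            raise ValueError(f"predictor matrix rank-deficient (rank {rank} < {m} columns)")
    if n <= m + 1:
        raise ValueError(f"need n > m + 1 (n={n}, m={m})")
    r2 = _fit_r2(Yc, Xc)
    r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
    if m == 0:
        return 0.0, 0.0, np.nan
    if 1.0 - r2 < 1e-14:
        return r2, r2adj, np.inf  # perfect fit
    f = (r2 / m) / ((1.0 - r2) / (n - m - 1))
    return r2, r2adj, f


def _residualize(A: np.ndarray, Wc: np.ndarray) -> np.ndarray:
    """Residuals of centered A on centered W (A already centered)."""
    if Wc.shape[1] == 0:
        return A
    coef, *_ = np.linalg.lstsq(Wc, A, rcond=None)
    return A - Wc @ coef


def _partial_f(Yc: np.ndarray, Xc: np.ndarray, Wc: np.ndarray) -> float:
    """Pseudo-F for the added effect of X given covariates W."""
    n = Yc.shape[0]
    mx, mw = Xc.shape[1], Wc.shape[1]
    Yr = _residualize(Yc, Wc)
    Xr = _residualize(Xc, Wc)
    coef, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
    fitted = Xr @ coef
    ss_x = float((fitted**2).sum())
    ss_res = float(((Yr - fitted) ** 2).sum())
    df_res = n - mw - mx - 1
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_res < 1e-14 * max(ss_x, 1.0):
        return np.inf
    return (ss_x / mx) / (ss_res / df_res)


@dataclass
class PartialRDATest:
    r2adj: float  # semipartial adjusted R2 of the tested fraction
    f: float
    p: float
    n_perm: int


def partial_rda_test(Y, X, W=None, n_perm: int = 10000, seed: int | None = None) -> PartialRDATest:
    """Permutation test for the added effect of X conditioned on W.

    With W empty this is a plain RDA test permuting rows of Y. Otherwise
    reduced-model (Freedman-Lane) permutation: residuals of Y ~ W are
    permuted, re-attached to the reduced-model fit, and the partial
    pseudo-F recomputed. p = (exceedances + 1)/(n_perm + 1).
    """
    Yc = _center(_as_array(Y))
    Xc = _center(_as_array(X))
    Wc = _center(_as_array(W)) if W is not None and _as_array(W).shape[1] > 0 else np.empty((Yc.shape[0], 0))
    if n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse")
    if Xc.shape[1] == 0:
        raise ValueError("X has no columns")
    Xr = _residualize(Xc, Wc)
    # rank relative to the scale of X itself: residualizing a column of W
    # leaves numerical dust, not signal
    if np.linalg.norm(Xr) < 1e-8 * max(np.linalg.norm(Xc), 1e-30):
        raise ValueError("X lies in the span of W; partial effect undefined")
    n = Yc.shape[0]
    f_obs = _partial_f(Yc, Xc, Wc)
    # semipartial adjusted R2 (fraction attributable to X beyond W)
    _, r2adj_full, _ = rda_r2(Yc, np.hstack([Wc, Xc]))
    if Wc.shape[1] > 0:
        _, r2adj_red, _ = rda_r2(Yc, Wc)
    else:
        r2adj_red = 0.0
    frac = r2adj_full - r2adj_red

    rng = np.random.default_rng(seed)
    if Wc.shape[1] > 0:
        coef, *_ = np.linalg.lstsq(Wc, Yc, rcond=None)
        fitted_red = Wc @ coef
        resid_red = Yc - fitted_red
    else:
        fitted_red = np.zeros_like(Yc)
        resid_red = Yc
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Ystar = fitted_red + resid_red[perm]
        if _partial_f(_center(Ystar), Xc, Wc) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PartialRDATest(r2adj=float(frac), f=float(f_obs), p=float(p), n_perm=n_perm)


@dataclass
class ForwardStep:
    variable: str
    cum_r2: float
    cum_r2adj: float
    f: float
    p: float


def forward_select(
    Y,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[ForwardStep]:
    """Forward selection with the double stopping criterion.

    At each step the candidate giving the largest partial fit (conditioned
    on the already-selected set) is tested by permutation; selection stops
    when (i) that candidate's p exceeds ``alpha`` or (ii) the cumulative
    adjusted R2 would exceed the adjusted R2 of the global model containing
    all candidates. Returns the selection trace in order of entry.
    """
    # constant candidates can never explain variance; drop them up front
    keep = [
        c for c in candidates.columns
        if np.asarray(candidates[c], dtype=float).std()
        > 1e-12 * (1.0 + np.abs(np.asarray(candidates[c], dtype=float).mean()))
    ]
    candidates = candidates[keep]
    if candidates.shape[1] == 0:
        return []
    Yc = _center(_as_array(Y))
    # global reference model: rank-tolerant (collinear candidate sets are
    # legal here; the adjustment uses the effective rank)
    Xg = _center(_as_array(candidates))
    rank_g = int(np.linalg.matrix_rank(Xg))
    n = Yc.shape[0]
    if n <= rank_g + 1:
        raise ValueError("too few sites for the global model")
    r2_g = _fit_r2(Yc, Xg)
    global_r2adj = 1.0 - (1.0 - r2_g) * (n - 1) / (n - rank_g - 1)
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    steps: list[ForwardStep] = []
    remaining = list(candidates.columns)
    while remaining:
        Wsel = candidates[selected] if selected else None
        best_var, best_r2 = None, -np.inf
        for var in remaining:
            trial = candidates[selected + [var]]
            try:
                r2, _, _ = rda_r2(Yc, trial)
            except ValueError:  # collinear with already-selected set
                continue
            if r2 > best_r2:
                best_var, best_r2 = var, r2
        if best_var is None:
            break
        test = partial_rda_test(
            Yc, candidates[[best_var]], Wsel, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        if test.p > alpha:
            break
        r2, r2adj, f = rda_r2(Yc, candidates[selected + [best_var]])
        if r2adj > global_r2adj + 1e-10:
            break
        selected.append(best_var)
        remaining.remove(best_var)
        steps.append(ForwardStep(variable=str(best_var), cum_r2=r2, cum_r2adj=r2adj, f=test.f, p=test.p))
    return steps


@dataclass
class VarPartResult:
    """Adjusted-R2 fractions [a], [b], [c], [d] plus tests for [a] and [c]."""

    a: float
    b: float
    c: float
    d: float
    f_a: float = np.nan
    p_a: float = np.nan
    f_c: float = np.nan
    p_c: float = np.nan
    env_vars: tuple[str, ...] = ()
    space_vars: tuple[str, ...] = ()
    n_perm: int = 0
    r2adj_env: float = 0.0
    r2adj_space: float = 0.0
    r2adj_both: float = 0.0
    notes: list[str] = field(default_factory=list)


def variation_partition(Y, E=None, S=None, n_perm: int = 10000, seed: int | None = None) -> VarPartResult:
    """Two-component variation partitioning with permutation tests.

    E and S are DataFrames (or arrays) of selected environmental and
    spatial predictors; either may be empty/None. Fractions satisfy
    a + b + c + d = 1 by construction.
    """
    Yc = _center(_as_array(Y))
    Edf = pd.DataFrame(E) if E is not None else pd.DataFrame(index=range(Yc.shape[0]))
    Sdf = pd.DataFrame(S) if S is not None else pd.DataFrame(index=range(Yc.shape[0]))
    me, ms = Edf.shape[1], Sdf.shape[1]
    rng = np.random.default_rng(seed)

    def _r2adj_tolerant(X: np.ndarray) -> float:
        # the E+S union may be collinear (shared structure); adjust by
        # effective rank rather than rejecting
        Xc = _center(X)
        rank = int(np.linalg.matrix_rank(Xc))
        n = Yc.shape[0]
        if n <= rank + 1:
            raise ValueError("too few sites for the combined model")
        r2 = _fit_r2(Yc, Xc)
        return 1.0 - (1.0 - r2) * (n - 1) / (n - rank - 1)

    re_adj = rda_r2(Yc, Edf)[1] if me else 0.0
    rs_adj = rda_r2(Yc, Sdf)[1] if ms else 0.0
    if me and ms:
        res_adj = _r2adj_tolerant(np.hstack([_as_array(Edf), _as_array(Sdf)]))
    else:
        res_adj = re_adj if me else rs_adj

    a = res_adj - rs_adj
    c = res_adj - re_adj
    b = re_adj + rs_adj - res_adj
    d = 1.0 - res_adj
    out = VarPartResult(
        a=a, b=b, c=c, d=d,
        env_vars=tuple(map(str, Edf.columns)), space_vars=tuple(map(str, Sdf.columns)),
        n_perm=n_perm, r2adj_env=re_adj, r2adj_space=rs_adj, r2adj_both=res_adj,
    )
    if me:
        try:
            t = partial_rda_test(Yc, Edf, Sdf if ms else None, n_perm=n_perm,
                                 seed=int(rng.integers(2**31 - 1)))
            out.f_a, out.p_a = t.f, t.p
        except ValueError as e:
            out.notes.append(f"[a] test degenerate: {e}")
    else:
        out.notes.append("no environmental predictors; [a] untested")
    if ms:
        try:
            t = partial_rda_test(Yc, Sdf, Edf if me else None, n_perm=n_perm,
                                 seed=int(rng.integers(2**31 - 1)))
            out.f_c, out.p_c = t.f, t.p
        except ValueError as e:
            out.notes.append(f"[c] test degenerate: {e}")
    else:
        out.notes.append("no spatial predictors; [c] untested")
    return out
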