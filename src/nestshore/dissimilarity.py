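"""Bray-Curtis dissimilarity, non-metric multidimensional scaling, and
Procrustes/PROTEST comparison of ordination configurations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio.stats.ordination import pcoa as _pcoa
from sklearn.manifold import smacof


def bray_curtis(counts, transform: str = "log1p") -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity between sites.

    Counts are log(x+1)-transformed by default to down-weight dominant
    species; pass ``transform=None`` for raw abundances. A pair of
    all-zero rows is assigned dissimilarity 0 with a warning.
    """
    A = np.asarray(counts, dtype=float)
    if (A < 0).any():
        raise ValueError("counts must be non-negative")
    if transform == "log1p":
        A = np.log1p(A)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    zero_rows = A.sum(axis=1) == 0
    if zero_rows.sum() >= 2:
        warnings.warn("multiple all-zero rows; their pairwise dissimilarity is set to 0")
    with np.errstate(invalid="ignore"):
        D = squareform(pdist(A, metric="braycurtis"))
    D = np.nan_to_num(D, nan=0.0)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class OrdinationResult:
    configuration: np.ndarray  # n x k, centered at origin
    stress: float  # Kruskal stress-1
    n_starts: int
    converged: bool
    seed: int | None


def nmds(
    D: np.ndarray,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Runs ``n_starts`` random initialisations plus one metric (PCoA) start
    and keeps the lowest-stress configuration. Stress is the 0-1 ratio
    sqrt(sum (dhat - d*)^2 / sum dhat^2).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} sites")
    common = dict(
        n_components=k, metric=False, max_iter=max_iter, eps=tol,
        normalized_stress=True,
    )
    best_conf, best_stress = None, np.inf
    conf, stress = smacof(D, init=None, n_init=n_starts, random_state=seed, **common)
    if stress < best_stress:
        best_conf, best_stress = conf, stress
    # metric-scaling start: classical scaling coordinates of D
    init = _metric_start(D, k)
    conf, stress = smacof(D, init=init, n_init=1, random_state=seed, **common)
    if stress < best_stress:
        best_conf, best_stress = conf, stress
    best_conf = best_conf - best_conf.mean(axis=0, keepdims=True)
    return OrdinationResult(
        configuration=best_conf,
        stress=float(best_stress),
        n_starts=n_starts + 1,
        converged=bool(np.isfinite(best_stress)),
        seed=seed,
    )


def _metric_start(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0, None)
    return evecs[:, order] * np.sqrt(lam)[None, :]


def pcoa_coordinates(D: np.ndarray, k: int | None = None) -> np.ndarray:
    """Principal-coordinates configuration of a dissimilarity matrix."""
    n = D.shape[0]
    if k is None:
        k = min(n - 1, 10)
    res = _pcoa(_SkbioDM(D), number_of_dimensions=k)
    return res.samples.to_numpy()[:, :k]


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p: float
    n_perm: int
    seed: int | None


def procrustes_protest(
    conf_a: np.ndarray, conf_b: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> ProcrustesResult:
    """Symmetric Procrustes comparison with a PROTEST permutation test.

    Both configurations are centered and scaled to unit trace; the optimal
    rotation (reflections allowed) gives the residual m2, and
    correlation = sqrt(1 - m2). The null permutes the rows of the second
    configuration; p = (count(m2_perm <= m2_obs) + 1)/(n_perm + 1).
    """
    A = np.asarray(conf_a, dtype=float)
    B = np.asarray(conf_b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if A.shape[1] != B.shape[1]:
        k = min(A.shape[1], B.shape[1])
        A, B = A[:, :k], B[:, :k]
    _, _, m2 = _procrustes(A, B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        _, _, m2p = _procrustes(A, B[perm])
        if m2p <= m2:
            count += 1
    p = (count + 1) / (n_perm + 1)
    corr = float(np.sqrt(max(0.0, 1.0 - m2)))
    return ProcrustesResult(m2=float(m2), correlation=corr, p=float(p), n_perm=n_perm, seed=seed)


def period_procrustes(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, n_perm: int = 999, seed: int | None = None
) -> ProcrustesResult:
    """PROTEST between the PCoA configurations of two periods' Bray-Curtis
    matrices — the pooling-justification check."""
    if list(counts_a.index) != list(counts_b.index):
        raise ValueError("periods must cover the same sites in the same order")
    Da = bray_curtis(counts_a.to_numpy())
    Db = bray_curtis(counts_b.to_numpy())
    return procrustes_protest(pcoa_coordinates(Da), pcoa_coordinates(Db), n_perm=n_perm, seed=seed)
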