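"""Distance-based Moran eigenvector maps (dbMEM).

Pipeline: geographic distance matrix -> truncation threshold (longest edge
of the minimum spanning tree, i.e. the longest distance connecting two
neighbouring sites) -> truncated matrix where distances beyond the
threshold are replaced by 4x the threshold -> Gower double-centering of
-1/2 D*^2 -> eigendecomposition. Eigenvectors with positive eigenvalues are
the spatial predictors; early ones (largest eigenvalues) model broad-scale
structure, later ones fine-scale structure. Moran's I is reported per
eigenvector using binary within-threshold connectivity weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree

EARTH_RADIUS_KM = 6371.0088


@dataclass
class MEMBasis:
    """Spatial eigenvectors: columns unit-norm, zero-mean, eigenvalues descending."""

    vectors: np.ndarray  # n x k
    eigenvalues: np.ndarray  # k, positive, descending
    morans_i: np.ndarray  # k
    threshold_km: float
    site_order: tuple[str, ...]

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def names(self) -> list[str]:
        return [f"dbMEM{i + 1}" for i in range(self.k)]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def distance_matrix(coords: np.ndarray, method: str = "haversine") -> np.ndarray:
    """Pairwise site distances in km.

    ``coords`` is (n, 2): latitude/longitude decimal degrees for
    ``haversine`` (default), or already-projected planar km for
    ``euclidean``.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sites")
    if method == "haversine":
        lat = coords[:, 0][:, None]
        lon = coords[:, 1][:, None]
        D = haversine_km(lat, lon, coords[:, 0][None, :], coords[:, 1][None, :])
    elif method == "euclidean":
        diff = coords[:, None, :] - coords[None, :, :]
        D = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def truncation_threshold(D: np.ndarray) -> float:
    """Longest edge of the minimum spanning tree over the complete graph on D."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    mst = minimum_spanning_tree(D).toarray()
    return float(mst.max())


def dbmem(D: np.ndarray, thr: float | None = None, eps: float = 1e-9,
          site_order: tuple[str, ...] | None = None) -> MEMBasis:
    """Build the dbMEM basis from a distance matrix.

    Distances above ``thr`` are replaced by ``4 * thr``; the result is
    Gower-centered (A = -1/2 D*^2, double-centered) and eigendecomposed.
    Only eigenvectors with eigenvalue > eps * max eigenvalue are retained
    (positive spatial autocorrelation models). Column signs are normalised
    so each vector's first nonzero loading is positive.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if thr is None:
        thr = truncation_threshold(D)
    if thr <= 0:
        raise ValueError("threshold must be positive")
    Dstar = np.where(D <= thr, D, 4.0 * thr)
    np.fill_diagonal(Dstar, 0.0)
    A = -0.5 * Dstar**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > eps * evals.max()
    if not keep.any():
        raise ValueError("no positive eigenvalues; degenerate configuration")
    evals, evecs = evals[keep], evecs[:, keep]
    for j in range(evecs.shape[1]):
        nz = np.flatnonzero(np.abs(evecs[:, j]) > 1e-12)
        if nz.size and evecs[nz[0], j] < 0:
            evecs[:, j] = -evecs[:, j]
    W = connectivity_weights(D, thr)
    mi = np.array([morans_i(evecs[:, j], W) for j in range(evecs.shape[1])])
    if site_order is None:
        site_order = tuple(str(i) for i in range(n))
    return MEMBasis(
        vectors=evecs,
        eigenvalues=evals,
        morans_i=mi,
        threshold_km=float(thr),
        site_order=tuple(site_order),
    )


def connectivity_weights(D: np.ndarray, thr: float) -> np.ndarray:
    """Binary neighbour weights: w_ij = 1 iff d_ij <= thr, i != j."""
    W = ((D <= thr) & (D > 0)).astype(float)
    # sites at identical positions still count as neighbours
    same = (D == 0) & ~np.eye(D.shape[0], dtype=bool)
    W[same] = 1.0
    return W


def morans_i(v: np.ndarray, W: np.ndarray) -> float:
    """Moran's spatial autocorrelation of vector v under weight matrix W."""
    v = np.asarray(v, dtype=float)
    v = v - v.mean()
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("all-zero weight matrix")
    n = v.size
    num = float(v @ W @ v)
    den = float(v @ v)
    return (n / s0) * num / den
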