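"""Beach Index, morphodynamic state classification, and gradient rankings.

The Beach Index (BI) summarises a beach's position on the
reflective-to-dissipative continuum:

    BI = log10( Mz * TR / S )

where ``Mz`` is the mean grain diameter expressed as (phi + 1), ``TR`` is
the maximum spring tide range in metres, and ``S`` is the beach slope as a
ratio (rise/run). Higher BI means more dissipative (flatter, finer sand,
wider surf zone). Published environment tables in this literature print the
slope column as the ratio itself; that ratio is the operative S here, which
is what makes recomputed BI agree with published values.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

DEFAULT_TIDE_RANGE_M = 2.0


class BeachState(str, Enum):
    REFLECTIVE = "reflective"
    INTERMEDIATE = "intermediate"
    DISSIPATIVE = "dissipative"


@dataclass(frozen=True)
class Thresholds:
    """BI cut-offs for state classification (closed-left convention)."""

    reflective_max: float = 2.0
    dissipative_min: float = 2.55

    def __post_init__(self) -> None:
        if not self.reflective_max < self.dissipative_min:
            raise ValueError("reflective_max must be < dissipative_min")


#: Ordering names -> (env column, ascending?) placing the most
#: dissipative-like site first.
GRADIENT_ORDERINGS: dict[str, tuple[str, bool]] = {
    "BI_desc": ("beach_index", False),
    "grain_phi_desc": ("mean_diameter_phi", False),
    "slope_asc": ("slope_ratio", True),
    "width_desc": ("width_m", False),
}


def beach_index(
    mz_phi: float | np.ndarray,
    slope_ratio: float | np.ndarray,
    tide_range_m: float = DEFAULT_TIDE_RANGE_M,
) -> float | np.ndarray:
    """Beach Index, dimensionless on a log10 scale.

    ``mz_phi`` is the mean grain diameter in phi units; the formula uses
    Mz = mz_phi + 1. Raises on a non-positive log argument.
    """
    mz = np.asarray(mz_phi, dtype=float) + 1.0
    s = np.asarray(slope_ratio, dtype=float)
    if tide_range_m <= 0:
        raise ValueError("tide_range_m must be positive")
    if np.any(s <= 0):
        raise ValueError("slope_ratio must be strictly positive")
    arg = mz * tide_range_m / s
    if np.any(arg <= 0):
        raise ValueError("non-positive argument to log10 (check mz_phi > -1)")
    out = np.log10(arg)
    return float(out) if out.ndim == 0 else out


def add_beach_index(env: pd.DataFrame, tide_range_m: float = DEFAULT_TIDE_RANGE_M) -> pd.DataFrame:
    """Return a copy of the env table with a computed ``beach_index`` column."""
    out = env.copy()
    out["beach_index"] = beach_index(
        out["mean_diameter_phi"].to_numpy(), out["slope_ratio"].to_numpy(), tide_range_m
    )
    return out


def classify_state(
    bi: float, width_m: float | None = None, thresholds: Thresholds = Thresholds()
) -> BeachState:
    """Classify a site as reflective/intermediate/dissipative from its BI.

    Boundaries belong to the lower class. ``width_m`` is accepted because
    field classifications also weigh width qualitatively, but the default
    rule is driven by BI alone.
    """
    if bi < thresholds.reflective_max:
        return BeachState.REFLECTIVE
    if bi > thresholds.dissipative_min:
        return BeachState.DISSIPATIVE
    return BeachState.INTERMEDIATE


@dataclass(frozen=True)
class GradientRanking:
    """An explicit site permutation, most dissipative-like first."""

    name: str
    order: tuple[str, ...]
    key_values: tuple[float, ...]


def gradient_rankings(env: pd.DataFrame) -> dict[str, GradientRanking]:
    """The four morphodynamic site rankings used to order nestedness matrices.

    Rankings: decreasing BI, decreasing grain size (phi), increasing slope,
    decreasing width. Ties break by site_id lexical order (stable).
    """
    if "beach_index" not in env.columns:
        env = add_beach_index(env)
    out: dict[str, GradientRanking] = {}
    for name, (col, ascending) in GRADIENT_ORDERINGS.items():
        if env[col].isna().any():
            bad = env.index[env[col].isna()][0]
            raise ValueError(f"missing {col} for site {bad!r}")
        sub = env[[col]].copy()
        sub["_site"] = sub.index.astype(str)
        sub = sub.sort_values([col, "_site"], ascending=[ascending, True], kind="mergesort")
        out[name] = GradientRanking(
            name=name,
            order=tuple(sub.index),
            key_values=tuple(float(v) for v in sub[col]),
        )
    return out
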