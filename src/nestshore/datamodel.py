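"""Core containers and CSV I/O for site-by-species community data.

The central object is :class:`CommunityMatrix`, a thin wrapper around a
pandas DataFrame with sites on the rows and species on the columns, holding
non-negative integer counts. Everything downstream (ordination, variation
partitioning, nestedness) consumes either this object or its binarized
counterpart :class:`PresenceMatrix`.

Site order is file order; no stage re-sorts rows implicitly. Gradient
orderings used by the nestedness battery are explicit permutations produced
by :mod:`nestshore.morphodynamics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ENV_COLUMNS = [
    "width_m",
    "slope_ratio",
    "mean_diameter_phi",
    "sorting_phi",
    "caco3_pct",
    "om_pct",
]


class ValidationError(ValueError):
    """Raised when an input table violates a schema invariant."""


@dataclass(frozen=True)
class SiteRecord:
    """A sampled beach sector with its position and sampling period."""

    site_id: str
    beach_name: str
    latitude: float
    longitude: float
    period: str = "pooled"

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"latitude out of range for {self.site_id!r}: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"longitude out of range for {self.site_id!r}: {self.longitude}")


@dataclass
class CommunityMatrix:
    """Site-by-species abundance table (integer counts >= 0)."""

    counts: pd.DataFrame
    period: str = "pooled"

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate site ids: {dups}")
        if df.columns.duplicated().any():
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate species ids: {dups}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if arr.size:
            if (arr < 0).any():
                i, j = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative count at site {df.index[i]!r}, species {df.columns[j]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at site {df.index[i]!r}, species {df.columns[j]!r}"
                )
        self.counts = df.astype(np.int64)

    @property
    def sites(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_csv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "site_id"
        out.to_csv(path)


@dataclass
class PresenceMatrix:
    """Binary incidence matrix with cached marginal totals.

    ``fill`` is the number of presences; ``row_fills``/``col_fills`` are the
    marginal totals (site richness and species frequency respectively).
    """

    incidence: pd.DataFrame
    period: str = "pooled"
    all_zero: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        arr = self.incidence.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("incidence entries must be 0/1")
        self.incidence = self.incidence.astype(np.int8)
        self.all_zero = bool(arr.size == 0 or arr.sum() == 0)

    @property
    def sites(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def fill(self) -> int:
        return int(self.incidence.to_numpy().sum())

    @property
    def row_fills(self) -> pd.Series:
        return self.incidence.sum(axis=1)

    @property
    def col_fills(self) -> pd.Series:
        return self.incidence.sum(axis=0)


def _clean_key(k: object) -> str:
    return str(k).strip()


def read_community(path: str | Path, layout: str = "wide", period: str = "pooled") -> CommunityMatrix:
    """Read a community matrix from CSV.

    ``layout='wide'``: first column is ``site_id``, remaining columns are
    species. ``layout='long'``: columns ``site_id, species, count`` (and
    optionally ``period``); duplicate (site, species) rows are summed and
    missing cells become 0.
    """
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.map(_clean_key)
        df.columns = df.columns.map(_clean_key)
        return CommunityMatrix(df, period=period)
    if layout == "long":
        raw = pd.read_csv(path)
        required = {"site_id", "species", "count"}
        if not required.issubset(raw.columns):
            raise ValidationError(f"long layout needs columns {sorted(required)}")
        raw["site_id"] = raw["site_id"].map(_clean_key)
        raw["species"] = raw["species"].map(_clean_key)
        wide = raw.pivot_table(
            index="site_id", columns="species", values="count", aggfunc="sum", fill_value=0
        )
        wide = wide.loc[raw["site_id"].unique(), :]
        wide.columns.name = None
        return CommunityMatrix(wide, period=period)
    raise ValueError(f"unknown layout {layout!r}")


def read_sites(path: str | Path) -> list[SiteRecord]:
    df = pd.read_csv(path)
    recs = [
        SiteRecord(
            site_id=_clean_key(r.site_id),
            beach_name=_clean_key(getattr(r, "beach", getattr(r, "beach_name", r.site_id))),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
        )
        for r in df.itertuples()
    ]
    ids = [r.site_id for r in recs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate site ids in sites table")
    return recs


def read_env(path: str | Path) -> pd.DataFrame:
    """Read the per-site environment table; validates positivity constraints."""
    df = pd.read_csv(path, index_col="site_id")
    df.index = df.index.map(_clean_key)
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"env table missing columns {missing}")
    if (df["width_m"] <= 0).any() or (df["slope_ratio"] <= 0).any():
        raise ValidationError("width_m and slope_ratio must be strictly positive")
    for col in ("caco3_pct", "om_pct"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValidationError(f"{col} must lie in [0, 100]")
    if df.index.duplicated().any():
        raise ValidationError("duplicate site ids in env table")
    return df


def pool_periods(m_a: CommunityMatrix, m_b: CommunityMatrix) -> CommunityMatrix:
    """Sum two period matrices element-wise over the union of species.

    Both matrices must cover the same sites; species sets may differ
    (absent species count as 0).
    """
    if set(m_a.sites) != set(m_b.sites):
        only_a = sorted(set(m_a.sites) - set(m_b.sites))
        only_b = sorted(set(m_b.sites) - set(m_a.sites))
        raise ValidationError(f"site sets differ: only in first {only_a}, only in second {only_b}")
    species = list(dict.fromkeys(m_a.species + m_b.species))
    a = m_a.counts.reindex(columns=species, fill_value=0)
    b = m_b.counts.reindex(index=m_a.sites, columns=species, fill_value=0)
    return CommunityMatrix(a + b, period="pooled")


def to_presence(m: CommunityMatrix) -> PresenceMatrix:
    return PresenceMatrix((m.counts > 0).astype(np.int8), period=m.period)


def richness(m: CommunityMatrix) -> pd.Series:
    """Number of species with count > 0 at each site."""
    return (m.counts > 0).sum(axis=1)


def total_richness(m: CommunityMatrix) -> int:
    return int(((m.counts > 0).any(axis=0)).sum())


def exclusive_species(
    m: CommunityMatrix, grouping: dict[str, str] | None = None
) -> dict[str, set[str]]:
    """Species whose every presence falls within a single group of sites.

    ``grouping`` maps site_id -> group label (e.g. sectors of the same beach
    share a label). Default: each site is its own group. Species absent
    everywhere are assigned to no group.
    """
    if grouping is None:
        grouping = {s: s for s in m.sites}
    missing = [s for s in m.sites if s not in grouping]
    if missing:
        raise ValidationError(f"sites missing from grouping: {missing}")
    pres = m.counts > 0
    groups = sorted(set(grouping[s] for s in m.sites))
    out: dict[str, set[str]] = {g: set() for g in groups}
    for sp in m.species:
        where = [grouping[s] for s in m.sites if pres.loc[s, sp]]
        if where and len(set(where)) == 1:
            out[where[0]].add(sp)
    return out
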