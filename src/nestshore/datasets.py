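"""Bundled study inputs: the 14-sector sandy-beach system (SE Brazil coast).

The community data for this system are not public, but the per-sector
environmental characterisation (width, slope, grain size, sorting, CaCO3,
organic matter, Beach Index) and the sector coordinates are published
values and small; they are embedded here so morphodynamic and spatial
stages can run against real inputs.

``slope_ratio`` is the slope expressed as a ratio (rise/run). ``published_bi``
is the Beach Index value as printed in the source table; recomputing BI from
grain size and slope with a 2.0 m spring tide range reproduces it within
+/-0.02 for 13 of the 14 sectors (the Sahy sector prints 2.13 where the
formula gives ~2.01; the discrepancy is in the source and left as-is).
"""

from __future__ import annotations

import pandas as pd

# site_id: width_m, slope_ratio, mean_diameter_phi, sorting_phi, caco3_pct, om_pct, published_bi
_ENV_ROWS = {
    "Sahy": (50, 0.064, 2.29, 0.63, 2.38, 0.44, 2.13),
    "Baleia": (140, 0.023, 2.65, 0.39, 7.33, 0.49, 2.50),
    "Palmeiras": (80, 0.021, 3.42, 0.34, 3.39, 1.20, 2.62),
    "Flecheiras 1": (80, 0.035, 2.69, 0.77, 2.49, 1.09, 2.32),
    "Flecheiras 2": (55, 0.047, 3.09, 0.68, 3.89, 1.07, 2.24),
    "Cidade 1": (115, 0.020, 2.89, 0.69, 4.33, 0.74, 2.59),
    "Cidade 2": (35, 0.040, 1.43, 0.90, 1.47, 0.48, 2.08),
    "Cidade 3": (60, 0.018, 2.25, 0.96, 2.88, 0.53, 2.55),
    "Cidade 4": (50, 0.032, 2.32, 1.07, 2.32, 0.59, 2.32),
    "Camaroeiro": (50, 0.028, 2.43, 0.95, 3.21, 0.43, 2.39),
    "Fazenda 1": (100, 0.016, 3.21, 0.29, 4.08, 0.43, 2.72),
    "Fazenda 2": (140, 0.013, 3.20, 0.29, 1.18, 0.48, 2.81),
    "Toque-Toque": (40, 0.105, 1.14, 0.85, 4.33, 0.22, 1.61),
    "Picinguaba": (25, 0.100, 0.94, 0.67, 0.35, 0.32, 1.59),
}

# site_id: (deg, min, sec) S latitude, (deg, min, sec) W longitude.
# Fazenda 1 is printed at 45deg51'22"W in the source map caption, which would
# place it ~100 km from its own sector pair (Fazenda 2) and from Picinguaba,
# its documented neighbour; 44deg51'22"W is used as the evident intent.
_COORD_ROWS = {
    "Sahy": ((23, 46, 30), (45, 41, 40)),
    "Baleia": ((23, 46, 28), (45, 40, 31)),
    "Palmeiras": ((23, 41, 38), (45, 25, 46)),
    "Flecheiras 1": ((23, 38, 37), (45, 25, 23)),
    "Flecheiras 2": ((23, 38, 15), (45, 25, 11)),
    "Cidade 1": ((23, 37, 24), (45, 24, 21)),
    "Cidade 2": ((23, 37, 22), (45, 24, 2)),
    "Cidade 3": ((23, 37, 3), (45, 23, 57)),
    "Cidade 4": ((23, 37, 31), (45, 23, 54)),
    "Camaroeiro": ((23, 37, 40), (45, 23, 49)),
    "Fazenda 1": ((23, 21, 31), (44, 51, 22)),
    "Fazenda 2": ((23, 22, 1), (44, 50, 20)),
    "Toque-Toque": ((23, 50, 4), (45, 30, 39)),
    "Picinguaba": ((23, 22, 39), (44, 50, 17)),
}


def _dms(d: int, m: int, s: int) -> float:
    return d + m / 60.0 + s / 3600.0


def study_environment() -> pd.DataFrame:
    """Environment table for the 14 sectors, indexed by site_id."""
    df = pd.DataFrame.from_dict(
        _ENV_ROWS,
        orient="index",
        columns=[
            "width_m",
            "slope_ratio",
            "mean_diameter_phi",
            "sorting_phi",
            "caco3_pct",
            "om_pct",
            "published_bi",
        ],
    )
    df.index.name = "site_id"
    return df


def study_coordinates() -> pd.DataFrame:
    """Decimal-degree coordinates (southern/western hemisphere: negative)."""
    rows = {
        site: (-_dms(*lat), -_dms(*lon)) for site, (lat, lon) in _COORD_ROWS.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["latitude", "longitude"])
    df.index.name = "site_id"
    return df
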