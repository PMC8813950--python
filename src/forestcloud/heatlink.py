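"""Linking the cloud effect to sensible-heat differences.

Whether forests enhance or inhibit clouds tracks the sign of the sensible
heat difference between forest and adjacent non-forest (ΔH, W/m²): higher
sensible heating over forest favors convective cloud enhancement, lower
heating drives a mesoscale circulation whose subsiding branch over forest
inhibits clouds. This module provides the pieces that quantify the
relationship:

* extraction of the dominant (modal) land-cover pair of a window,
* look-up of ΔH for that pair in a conversion table keyed per coarse cell,
* daytime (8:00–16:00, endpoints inclusive) means of hourly flux series,
* matching of paired flux sites to the 1°-aggregated effect map with the
  documented exclusions (missing ΔCloud; ΔH outliers above 200 W/m²),
* geometric-mean (reduced major axis) regression and Spearman rank
  correlation of ΔCloud on ΔH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridField
from .surface import SurfaceClass, SurfaceClassMap
from .windows import EffectMap, Window

__all__ = [
    "ConversionTable",
    "SitePair",
    "RankRegressionResult",
    "DELTA_H_OUTLIER",
    "DAYTIME_HOURS",
    "dominant_pair",
    "lookup_delta_h",
    "daytime_mean_h",
    "match_site_pair",
    "gm_regression",
    "rank_correlation",
]

DELTA_H_OUTLIER = 200.0           # W/m²; pairs beyond this are excluded
DAYTIME_HOURS = tuple(range(8, 17))  # 8:00–16:00 inclusive, 9 hours


@dataclass
class ConversionTable:
    """ΔH (W/m²) keyed by (forest class, non-forest class) per coarse cell.

    ``cell_entries`` maps ``(cell_i, cell_j)`` — floor(lat / resolution),
    floor(lon / resolution) — to per-pair values; ``global_entries`` holds
    location-independent fallbacks. Missing keys yield ``None``, never 0.
    """

    resolution: float = 1.0
    global_entries: dict[tuple[int, int], float] = field(default_factory=dict)
    cell_entries: dict[tuple[int, int], dict[tuple[int, int], float]] = \
        field(default_factory=dict)
    provenance: str = "synthetic"

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        return (int(np.floor(lat / self.resolution)),
                int(np.floor(lon / self.resolution)))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"cell_i": ci, "cell_j": cj, "forest_class": f,
                 "nonforest_class": n, "delta_h": v}
                for (ci, cj), pairs in self.cell_entries.items()
                for (f, n), v in pairs.items()]
        rows += [{"cell_i": np.nan, "cell_j": np.nan, "forest_class": f,
                  "nonforest_class": n, "delta_h": v}
                 for (f, n), v in self.global_entries.items()]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, resolution: float = 1.0,
                 provenance: str = "satellite-like") -> "ConversionTable":
        df = pd.read_csv(path)
        table = cls(resolution=resolution, provenance=provenance)
        for _, row in df.iterrows():
            key = (int(row["forest_class"]), int(row["nonforest_class"]))
            if pd.isna(row.get("cell_i", np.nan)):
                table.global_entries[key] = float(row["delta_h"])
            else:
                cell = (int(row["cell_i"]), int(row["cell_j"]))
                table.cell_entries.setdefault(cell, {})[key] = float(row["delta_h"])
        return table


@dataclass
class SitePair:
    """One paired forest / non-forest flux site record."""

    pair_id: int
    forest_lat: float
    forest_lon: float
    nonforest_lat: float
    nonforest_lon: float
    delta_h: float                    # daytime mean, W/m²
    delta_cloud: float | None = None  # matched from the 1° effect map
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class RankRegressionResult:
    gm_slope: float
    gm_intercept: float
    spearman_rho: float
    p_value: float


def dominant_pair(
    window: Window, classmap: SurfaceClassMap, landcover: GridField
) -> tuple[int, int] | None:
    """Modal land-cover class among the window's unchanged forest pixels and
    among its unchanged non-forest pixels; ties break to the smallest code.
    Returns ``None`` when either class is empty."""
    out = []
    for cls in (SurfaceClass.UNCHANGED_FOREST, SurfaceClass.UNCHANGED_NONFOREST):
        sel = classmap.where(cls)[window.rows, window.cols] \
            & ~landcover.mask[window.rows, window.cols]
        codes = landcover.values[window.rows, window.cols][sel].astype(int)
        if codes.size == 0:
            return None
        cats, counts = np.unique(codes, return_counts=True)
        out.append(int(cats[np.argmax(counts)]))  # sorted cats → smallest wins ties
    return out[0], out[1]


def lookup_delta_h(
    pair: tuple[int, int], lat: float, lon: float, table: ConversionTable
) -> float | None:
    """ΔH for a land-conversion pair at the enclosing coarse cell.

    Exact-key lookup; a missing key is ``None`` (a typed missing value),
    never zero. Cell-specific entries take precedence over global ones.
    """
    cell = table.cell_of(lat, lon)
    value = table.cell_entries.get(cell, {}).get(pair)
    if value is None:
        value = table.global_entries.get(pair)
    return value


def daytime_mean_h(hourly_h: Sequence[float]) -> float:
    """Mean sensible heat over local hours 8–16 inclusive (9 values)."""
    series = np.asarray(hourly_h, dtype=float)
    if series.size != 24:
        raise ValueError("hourly series must have 24 entries")
    return float(series[list(DAYTIME_HOURS)].mean())


def match_site_pair(pair: SitePair, effect_map: EffectMap) -> SitePair:
    """Attach the effect-map value at the midpoint of the two sites.

    The effect map should be the 1° aggregation built without the elevation
    filter and water buffer. A pair is excluded (flag + reason, values
    untouched) when the midpoint cell is nodata or |ΔH| exceeds the outlier
    bound.
    """
    mid_lat = 0.5 * (pair.forest_lat + pair.nonforest_lat)
    mid_lon = 0.5 * (pair.forest_lon + pair.nonforest_lon)
    g = effect_map.delta
    res = g.resolution
    i = int(np.floor((mid_lat - (g.lat[0] - res / 2)) / res))
    j = int(np.floor((mid_lon - (g.lon[0] - res / 2)) / res))
    out = SitePair(**{**pair.__dict__})
    inside = 0 <= i < g.shape[0] and 0 <= j < g.shape[1]
    if not inside or g.mask[i, j]:
        out.excluded, out.exclusion_reason = True, "missing delta_cloud"
        return out
    out.delta_cloud = float(g.values[i, j])
    if abs(out.delta_h) > DELTA_H_OUTLIER:
        out.excluded, out.exclusion_reason = True, "delta_h outlier"
    return out


def gm_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Geometric-mean (reduced major axis) regression of y on x.

    slope = sign(r) · sd(y) / sd(x); intercept = ȳ − slope · x̄. Symmetric
    under axis exchange: slope_xy · slope_yx = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in a regression variable")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = np.sign(r) * sy / sx if r != 0 else sy / sx
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-tailed t-approximation p value.

    Pearson correlation of (average-tie) ranks, as computed by
    ``scipy.stats.spearmanr``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired samples for a finite p")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def site_pairs_to_frame(pairs: Sequence[SitePair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])
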