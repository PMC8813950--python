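"""Moving-window space-for-time estimator of forest effects on cloud cover.

The potential effect of forests at a location is the difference in mean
cloud-cover fraction between unchanged forest and unchanged non-forest
pixels inside a small moving window,

    ΔCloud = Cloud_forest − Cloud_nonforest ,

positive for cloud enhancement over forest, negative for inhibition. The
actual effect of forest loss compares forest-loss pixels against unchanged
forest instead,

    ΔCloud_loss = Cloud_loss − Cloud_forest .

Windows (default 9 × 9 pixels, centers 5 pixels apart) are placed only
where land change occurred, ensuring proximity of the compared pixels to
real transitions; windows over complex terrain (elevation s.d. > 100 m) or
without enough pixels of either class are rejected, and water pixels plus a
one-pixel buffer are excluded from both classes. Retained samples are
aggregated to a coarser display grid (default 0.5°) for mapping and all
summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import GridField, GridStack, GeometryError
from .surface import SurfaceClass, SurfaceClassMap, buffer_water_mask

__all__ = [
    "WindowSpec",
    "Window",
    "WindowSample",
    "LossSample",
    "Rejection",
    "EffectMap",
    "place_windows",
    "window_effect",
    "actual_effect",
    "elevation_filter",
    "potential_effects",
    "actual_effects",
    "aggregate_to_display",
    "sign_fractions",
    "latitudinal_profile",
    "seasonal_max_month",
    "diurnal_max_hour",
    "samples_to_frame",
]


@dataclass(frozen=True)
class WindowSpec:
    """Geometry and filters of the window search."""

    size: int = 9                  # odd window edge, pixels
    step: int = 5                  # center-to-center distance, pixels
    min_count_forest: int = 3
    min_count_nonforest: int = 3
    min_count_loss: int = 3
    elev_sd_max: float = 100.0     # m

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("window size must be odd and >= 3")
        if not 1 <= self.step <= self.size:
            raise ValueError("step must lie in [1, size]")
        if min(self.min_count_forest, self.min_count_nonforest,
               self.min_count_loss) < 1:
            raise ValueError("minimum class counts must be >= 1")


@dataclass(frozen=True)
class Window:
    """Index ranges of one fully interior window plus its center."""

    row0: int
    col0: int
    size: int
    center_lat: float
    center_lon: float

    @property
    def rows(self) -> slice:
        return slice(self.row0, self.row0 + self.size)

    @property
    def cols(self) -> slice:
        return slice(self.col0, self.col0 + self.size)


@dataclass
class WindowSample:
    """One paired forest / non-forest comparison (Cloud or any field)."""

    center_lat: float
    center_lon: float
    mean_forest: float
    mean_nonforest: float
    delta: float
    n_forest: int
    n_nonforest: int
    elevation_sd: float | None = None
    window: Window | None = None


@dataclass
class LossSample:
    """One paired forest-loss / unchanged-forest comparison."""

    center_lat: float
    center_lon: float
    mean_loss: float
    mean_forest: float
    delta_loss: float
    n_loss: int
    n_forest: int
    elevation_sd: float | None = None
    window: Window | None = None


@dataclass(frozen=True)
class Rejection:
    """Typed window rejection (not an exception)."""

    reason: str
    window: Window | None = None


@dataclass
class EffectMap:
    """Display-grid mean effect and per-cell sample count."""

    delta: GridField
    count: np.ndarray

    @property
    def valid(self) -> np.ndarray:
        return ~self.delta.mask


def place_windows(classmap: SurfaceClassMap, spec: WindowSpec = WindowSpec(),
                  trigger: np.ndarray | None = None) -> list[Window]:
    """Enumerate fully interior windows on the step lattice, keeping those
    that contain at least one changed pixel.

    The change trigger defaults to the classifier's change magnitude
    exceeding its change threshold (net forest change > 0.05); a boolean
    ``trigger`` field overrides it.
    """
    labels = classmap.labels
    n_lat, n_lon = labels.shape
    if n_lat < spec.size or n_lon < spec.size:
        return []
    if trigger is None:
        trigger = classmap.change_magnitude() > classmap.config.change_threshold
    half = spec.size // 2
    out: list[Window] = []
    for r in range(half, n_lat - half, spec.step):
        for c in range(half, n_lon - half, spec.step):
            r0, c0 = r - half, c - half
            if np.any(trigger[r0:r0 + spec.size, c0:c0 + spec.size]):
                out.append(Window(r0, c0, spec.size,
                                  float(labels.lat[r]), float(labels.lon[c])))
    return out


def elevation_filter(window: Window, elevation: GridField,
                     spec: WindowSpec = WindowSpec()) -> bool:
    """True (pass) iff the elevation s.d. over unmasked window pixels is
    within ``elev_sd_max``; an all-nodata window fails."""
    block = elevation.values[window.rows, window.cols]
    mask = elevation.mask[window.rows, window.cols]
    vals = block[~mask]
    if vals.size == 0:
        return False
    return float(np.std(vals)) <= spec.elev_sd_max


def _elev_sd(window: Window, elevation: GridField) -> float:
    block = elevation.values[window.rows, window.cols]
    vals = block[~elevation.mask[window.rows, window.cols]]
    return float(np.std(vals)) if vals.size else float("nan")


def _class_mean(fld: GridField, window: Window, sel: np.ndarray,
                exclude: np.ndarray) -> tuple[float, int]:
    use = sel[window.rows, window.cols] \
        & ~exclude[window.rows, window.cols] \
        & ~fld.mask[window.rows, window.cols]
    vals = fld.values[window.rows, window.cols][use]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)


def window_effect(
    window: Window,
    classmap: SurfaceClassMap,
    fld: GridField,
    water_buffer: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    elevation: GridField | None = None,
) -> WindowSample | Rejection:
    """Potential effect in one window: forest minus non-forest mean of ``fld``.

    Returns a :class:`Rejection` when either class has fewer unmasked pixels
    than the configured minimum or when the elevation filter fails.
    """
    exclude = (water_buffer.values.astype(bool) if water_buffer is not None
               else np.zeros(fld.shape, dtype=bool))
    elev_sd = None
    if elevation is not None:
        if not elevation_filter(window, elevation, spec):
            return Rejection("elevation_sd", window)
        elev_sd = _elev_sd(window, elevation)
    mf, nf = _class_mean(fld, window,
                         classmap.where(SurfaceClass.UNCHANGED_FOREST), exclude)
    mn, nn = _class_mean(fld, window,
                         classmap.where(SurfaceClass.UNCHANGED_NONFOREST), exclude)
    if nf < spec.min_count_forest:
        return Rejection("min_count_forest", window)
    if nn < spec.min_count_nonforest:
        return Rejection("min_count_nonforest", window)
    return WindowSample(window.center_lat, window.center_lon,
                        mf, mn, mf - mn, nf, nn, elev_sd, window)


def actual_effect(
    window: Window,
    classmap: SurfaceClassMap,
    fld: GridField,
    water_buffer: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    elevation: GridField | None = None,
) -> LossSample | Rejection:
    """Actual effect in one window: forest-loss minus unchanged-forest mean."""
    exclude = (water_buffer.values.astype(bool) if water_buffer is not None
               else np.zeros(fld.shape, dtype=bool))
    elev_sd = None
    if elevation is not None:
        if not elevation_filter(window, elevation, spec):
            return Rejection("elevation_sd", window)
        elev_sd = _elev_sd(window, elevation)
    ml, nl = _class_mean(fld, window,
                         classmap.where(SurfaceClass.FOREST_LOSS), exclude)
    mf, nf = _class_mean(fld, window,
                         classmap.where(SurfaceClass.UNCHANGED_FOREST), exclude)
    if nl < spec.min_count_loss:
        return Rejection("min_count_loss", window)
    if nf < spec.min_count_forest:
        return Rejection("min_count_forest", window)
    return LossSample(window.center_lat, window.center_lon,
                      ml, mf, ml - mf, nl, nf, elev_sd, window)


def _run(windows, effect_fn):
    samples, rejections = [], []
    for w in windows:
        res = effect_fn(w)
        (samples if not isinstance(res, Rejection) else rejections).append(res)
    return samples, rejections


def potential_effects(
    classmap: SurfaceClassMap,
    fld: GridField,
    elevation: GridField | None = None,
    water_mask: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    windows: Sequence[Window] | None = None,
) -> tuple[list[WindowSample], list[Rejection]]:
    """Place windows and compute the potential effect in each."""
    if windows is None:
        windows = place_windows(classmap, spec)
    buf = buffer_water_mask(water_mask) if water_mask is not None else None
    return _run(windows, lambda w: window_effect(
        w, classmap, fld, buf, spec, elevation))


def actual_effects(
    classmap: SurfaceClassMap,
    fld: GridField,
    elevation: GridField | None = None,
    water_mask: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    windows: Sequence[Window] | None = None,
) -> tuple[list[LossSample], list[Rejection]]:
    """Place windows and compute the actual (loss) effect in each."""
    if windows is None:
        windows = place_windows(classmap, spec)
    buf = buffer_water_mask(water_mask) if water_mask is not None else None
    return _run(windows, lambda w: actual_effect(
        w, classmap, fld, buf, spec, elevation))


# ---------------------------------------------------------------------------
# Display aggregation and summaries
# ---------------------------------------------------------------------------

def _sample_delta(s) -> float:
    return s.delta if isinstance(s, WindowSample) else s.delta_loss


def aggregate_to_display(
    samples: Sequence[WindowSample | LossSample],
    display_resolution: float = 0.5,
    extent: tuple[float, float, float, float] | None = None,
) -> EffectMap:
    """Bin window samples to a coarse display grid (unweighted cell means).

    Binning is half-open ``[edge, edge + res)``; cells without samples are
    nodata. ``extent`` is ``(south, north, west, east)`` in cell-edge terms
    and defaults to the bounding box of the sample centers snapped outward
    to the display lattice.
    """
    if not samples:
        raise ValueError("no samples to aggregate")
    res = display_resolution
    lats = np.array([s.center_lat for s in samples])
    lons = np.array([s.center_lon for s in samples])
    deltas = np.array([_sample_delta(s) for s in samples])
    if extent is None:
        south = np.floor(lats.min() / res) * res
        north = np.ceil((lats.max() + 1e-12) / res) * res
        west = np.floor(lons.min() / res) * res
        east = np.ceil((lons.max() + 1e-12) / res) * res
    else:
        south, north, west, east = extent
    n_lat = max(1, int(round((north - south) / res)))
    n_lon = max(1, int(round((east - west) / res)))
    total = np.zeros((n_lat, n_lon))
    count = np.zeros((n_lat, n_lon), dtype=int)
    ri = np.floor((lats - south) / res).astype(int)
    ci = np.floor((lons - west) / res).astype(int)
    keep = (ri >= 0) & (ri < n_lat) & (ci >= 0) & (ci < n_lon)
    np.add.at(total, (ri[keep], ci[keep]), deltas[keep])
    np.add.at(count, (ri[keep], ci[keep]), 1)
    mask = count == 0
    mean = np.where(mask, 0.0, total / np.maximum(count, 1))
    fld = GridField(
        values=mean,
        lat=south + res * (np.arange(n_lat) + 0.5),
        lon=west + res * (np.arange(n_lon) + 0.5),
        resolution=res, mask=mask, variable="delta_cloud", units="1",
    )
    return EffectMap(delta=fld, count=count)


def sign_fractions(effect_map: EffectMap,
                   zero_positive: bool = True) -> tuple[float, float]:
    """Percent of valid display cells with positive (enhancement) and
    negative (inhibition) effect; zeros count as positive by default."""
    vals = effect_map.delta.values[effect_map.valid]
    if vals.size == 0:
        return float("nan"), float("nan")
    pos = vals > 0 if not zero_positive else vals >= 0
    p = 100.0 * np.mean(pos)
    return float(p), float(100.0 - p)


def latitudinal_profile(
    effect_map: EffectMap, band_width_deg: float = 1.0
) -> pd.DataFrame:
    """Per-latitude-band mean of positive and of negative effects.

    Returns a frame indexed by band south edge with columns
    ``enhancement`` / ``inhibition`` (NaN where the band has no cells of
    that sign) and the matching sample counts.
    """
    fld = effect_map.delta
    valid = effect_map.valid
    lat2d = np.broadcast_to(fld.lat[:, None], fld.shape)
    band = np.floor(lat2d / band_width_deg) * band_width_deg
    rows = []
    for b in np.unique(band):
        sel = (band == b) & valid
        vals = fld.values[sel]
        pos, neg = vals[vals >= 0], vals[vals < 0]
        rows.append({
            "band": float(b),
            "enhancement": float(pos.mean()) if pos.size else np.nan,
            "n_enhancement": int(pos.size),
            "inhibition": float(neg.mean()) if neg.size else np.nan,
            "n_inhibition": int(neg.size),
        })
    return pd.DataFrame(rows).set_index("band")


def seasonal_max_month(monthly_delta: Sequence[float],
                       snowfree_months: Iterable[int] | None = None) -> int:
    """Month (1–12) with the largest |ΔCloud| among snow-free months.

    ``monthly_delta`` is a 12-entry series (NaN = gap); ties break to the
    earliest month.
    """
    series = np.asarray(monthly_delta, dtype=float)
    if series.size != 12:
        raise ValueError("monthly series must have 12 entries")
    allowed = set(range(1, 13)) if snowfree_months is None else set(snowfree_months)
    best, best_mag = None, -np.inf
    for m in range(1, 13):
        v = series[m - 1]
        if m not in allowed or np.isnan(v):
            continue
        if abs(v) > best_mag:
            best, best_mag = m, abs(v)
    if best is None:
        raise ValueError("no snow-free month with data")
    return best


def diurnal_max_hour(hourly_delta_utc: Sequence[float], lon: float) -> int:
    """Local hour of the maximum-magnitude effect.

    The 24-entry UTC series is shifted by ``round(lon / 15)`` hours to local
    solar time; the local hour with the largest |ΔCloud| wins, ties breaking
    to the earliest local hour.
    """
    series = np.asarray(hourly_delta_utc, dtype=float)
    if series.size != 24:
        raise ValueError("hourly series must have 24 entries")
    shift = int(round(lon / 15.0))
    local = np.full(24, np.nan)
    for h_utc in range(24):
        local[(h_utc + shift) % 24] = series[h_utc]
    best, best_mag = None, -np.inf
    for h in range(24):
        v = local[h]
        if np.isnan(v):
            continue
        if abs(v) > best_mag:
            best, best_mag = h, abs(v)
    if best is None:
        raise ValueError("empty hourly series")
    return best


def samples_to_frame(samples: Sequence[WindowSample | LossSample]) -> pd.DataFrame:
    """Flat table (one row per window) for CSV export."""
    rows = []
    for s in samples:
        if isinstance(s, WindowSample):
            rows.append({
                "center_lat": s.center_lat, "center_lon": s.center_lon,
                "mean_forest": s.mean_forest, "mean_nonforest": s.mean_nonforest,
                "delta": s.delta, "n_forest": s.n_forest,
                "n_nonforest": s.n_nonforest, "elevation_sd": s.elevation_sd,
            })
        else:
            rows.append({
                "center_lat": s.center_lat, "center_lon": s.center_lon,
                "mean_loss": s.mean_loss, "mean_forest": s.mean_forest,
                "delta_loss": s.delta_loss, "n_loss": s.n_loss,
                "n_forest": s.n_forest, "elevation_sd": s.elevation_sd,
            })
    return pd.DataFrame(rows)
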