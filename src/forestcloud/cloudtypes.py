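"""ISCCP cloud-type classification and per-type forest effects.

Cloud observations are sorted into the nine ISCCP types on a 3 × 3 grid of
cloud-top pressure (high / mid / low, boundaries 440 and 680 hPa) versus
optical depth (thin / medium / thick, boundaries 3.6 and 23):

            τ ≤ 3.6        3.6 < τ ≤ 23     τ > 23
  CTP ≤ 440   1 cirrus       2 cirrostratus   3 deep convection
  440–680     4 altocumulus  5 altostratus    6 nimbostratus
  CTP > 680   7 cumulus      8 stratocumulus  9 stratus

Types 3, 7 and 8 are convective; 7 and 8 are shallow convective. Per-type
fractional covers sum to the total cloud fraction pixel by pixel, so the
window difference of each type sums exactly to the total effect; the
dominant type of a cell is the one sharing the total effect's sign with the
largest magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .grid import GridField
from .surface import SurfaceClassMap
from .windows import (
    EffectMap, Rejection, Window, WindowSpec, aggregate_to_display,
    place_windows, window_effect,
)
from .surface import buffer_water_mask

__all__ = [
    "CloudTypeScheme",
    "TYPE_NAMES",
    "TypeEffectRecord",
    "classify_isccp",
    "per_type_effects",
    "dominant_type",
    "convective_dominance_fraction",
]

TYPE_NAMES = {
    1: "cirrus", 2: "cirrostratus", 3: "deep convection",
    4: "altocumulus", 5: "altostratus", 6: "nimbostratus",
    7: "cumulus", 8: "stratocumulus", 9: "stratus",
}


@dataclass(frozen=True)
class CloudTypeScheme:
    """Boundaries and groupings of the 3×3 ISCCP type grid."""

    ctp_boundaries: tuple[float, float] = (440.0, 680.0)   # hPa
    tau_boundaries: tuple[float, float] = (3.6, 23.0)
    convective: frozenset[int] = frozenset({3, 7, 8})
    shallow_convective: frozenset[int] = frozenset({7, 8})

    def __post_init__(self) -> None:
        if not (self.ctp_boundaries[0] < self.ctp_boundaries[1]):
            raise ValueError("ctp boundaries must increase")
        if not (self.tau_boundaries[0] < self.tau_boundaries[1]):
            raise ValueError("tau boundaries must increase")


def classify_isccp(ctp, tau, scheme: CloudTypeScheme = CloudTypeScheme()):
    """Map cloud-top pressure (hPa) and optical depth to type codes 1–9.

    Accepts scalars or arrays. Boundary values fall into the
    higher-altitude (lower CTP) and thinner (lower τ) bins. NaN in either
    input propagates as NaN.
    """
    ctp = np.asarray(ctp, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(ctp[~np.isnan(ctp)] <= 0):
        raise ValueError("cloud-top pressure must be positive")
    if np.any(tau[~np.isnan(tau)] < 0):
        raise ValueError("optical depth must be non-negative")
    c1, c2 = scheme.ctp_boundaries
    t1, t2 = scheme.tau_boundaries
    alt = np.where(ctp <= c1, 0, np.where(ctp <= c2, 1, 2))   # high/mid/low
    thick = np.where(tau <= t1, 0, np.where(tau <= t2, 1, 2))
    code = (3 * alt + thick + 1).astype(float)
    code = np.where(np.isnan(ctp) | np.isnan(tau), np.nan, code)
    if code.ndim == 0:
        v = float(code)
        return int(v) if not np.isnan(v) else float("nan")
    return code


@dataclass
class TypeEffectRecord:
    """Per-type ΔCloud vector for one display cell (indices 1–9)."""

    per_type: np.ndarray          # shape (9,)
    total: float

    def __post_init__(self) -> None:
        self.per_type = np.asarray(self.per_type, dtype=float)
        if self.per_type.shape != (9,):
            raise ValueError("per-type vector must have 9 entries")


def per_type_effects(
    type_cover: Mapping[int, GridField],
    total_cloud: GridField,
    classmap: SurfaceClassMap,
    elevation: GridField | None = None,
    water_mask: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    display_resolution: float = 0.5,
    windows: Sequence[Window] | None = None,
) -> tuple[dict[tuple[float, float], TypeEffectRecord], EffectMap]:
    """Window estimator applied to each type's cover field.

    ``type_cover`` maps ISCCP codes to per-type fractional cover fields; the
    nine covers must sum to the total cloud fraction at every unmasked pixel
    (tolerance 1e-6). Returns per-display-cell records plus the total-effect
    map; the sum identity Σ_type ΔCloud_type = ΔCloud_total is exact by
    linearity of class means.
    """
    zero = total_cloud.like(np.zeros(total_cloud.shape))
    covers = {c: type_cover.get(c, zero) for c in range(1, 10)}
    total_sum = np.zeros(total_cloud.shape)
    for c in range(1, 10):
        total_sum += covers[c].values
    ok = ~total_cloud.mask
    if np.any(np.abs(total_sum[ok] - total_cloud.values[ok]) > 1e-6):
        raise ValueError("per-type covers do not sum to the total cloud fraction")

    if windows is None:
        windows = place_windows(classmap, spec)
    buf = buffer_water_mask(water_mask) if water_mask is not None else None

    per_type_samples: dict[int, list] = {c: [] for c in range(1, 10)}
    total_samples = []
    for w in windows:
        st = window_effect(w, classmap, total_cloud, buf, spec, elevation)
        if isinstance(st, Rejection):
            continue
        scs = [window_effect(w, classmap, covers[c], buf, spec)
               for c in range(1, 10)]
        if any(isinstance(sc, Rejection) for sc in scs):
            continue
        total_samples.append(st)
        for c, sc in zip(range(1, 10), scs):
            per_type_samples[c].append(sc)
    if not total_samples:
        return {}, None

    res = display_resolution
    lats = [s.center_lat for s in total_samples]
    lons = [s.center_lon for s in total_samples]
    extent = (np.floor(min(lats) / res) * res,
              np.ceil((max(lats) + 1e-12) / res) * res,
              np.floor(min(lons) / res) * res,
              np.ceil((max(lons) + 1e-12) / res) * res)
    total_map = aggregate_to_display(total_samples, res, extent)
    type_maps = {c: aggregate_to_display(per_type_samples[c], res, extent)
                 for c in range(1, 10)}

    records: dict[tuple[float, float], TypeEffectRecord] = {}
    g = total_map.delta
    for i, j in np.argwhere(total_map.valid):
        vec = np.array([type_maps[c].delta.values[i, j] for c in range(1, 10)])
        records[(float(g.lat[i]), float(g.lon[j]))] = TypeEffectRecord(
            vec, float(g.values[i, j]))
    return records, total_map


def dominant_type(record: TypeEffectRecord) -> int | None:
    """Type sharing the total effect's sign with the largest magnitude.

    Returns ``None`` when no type shares the sign (or the total is zero);
    ties break to the smallest type code.
    """
    if record.total == 0 or not np.isfinite(record.total):
        return None
    sign = np.sign(record.total)
    best, best_mag = None, -np.inf
    for c in range(1, 10):
        v = record.per_type[c - 1]
        if np.sign(v) != sign:
            continue
        if abs(v) > best_mag:
            best, best_mag = c, abs(v)
    return best


def convective_dominance_fraction(
    dominant: Mapping[tuple[float, float], int | None],
    scheme: CloudTypeScheme = CloudTypeScheme(),
) -> tuple[float, float]:
    """Percent of cells dominated by convective and by shallow-convective
    types, over cells with a dominant type."""
    codes = [c for c in dominant.values() if c is not None]
    if not codes:
        return float("nan"), float("nan")
    conv = 100.0 * sum(c in scheme.convective for c in codes) / len(codes)
    shallow = 100.0 * sum(c in scheme.shallow_convective for c in codes) / len(codes)
    return conv, shallow
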