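"""Attribution of the cloud effect to tree cover versus orography.

Because forests preferentially sit on higher, rougher terrain, part of any
forest/non-forest cloud difference can be orographic rather than vegetative.
Within each moving window the cloud field is regressed on tree cover and
elevation,

    Cloud = S_tree · tree + S_ele · elevation + c ,

giving local sensitivities. Multiplying each sensitivity by the window's
forest-minus-non-forest difference in the matching driver yields the two
components

    ΔCloud_tree = S_tree · ΔTree ,      ΔCloud_ele = S_ele · ΔEle ,

whose sum reconstructs ΔCloud when the linear model holds. Sensitivities and
differences are averaged to the display grid before the multiplication, and
each display cell is then assigned one of five attribution classes by
comparing signs and magnitudes of the components against the original
ΔCloud.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .grid import GridField
from .surface import SurfaceClassMap
from .windows import (
    EffectMap, Rejection, Window, WindowSample, WindowSpec,
    aggregate_to_display, window_effect,
)

__all__ = [
    "AttributionClass",
    "SensitivityRecord",
    "AttributionRecord",
    "fit_window_sensitivities",
    "decompose",
    "classify_attribution",
    "reconstruction_explained",
    "attribute_scene",
    "AttributionResult",
]

MIN_REGRESSION_PIXELS = 4  # one more than the number of fitted parameters


class AttributionClass(Enum):
    TREE_PLUS = "Tree+"
    TREE_MINUS = "Tree-"
    ORO_PLUS = "Orography+"
    ORO_MINUS = "Orography-"
    OTHER = "Other"


@dataclass
class SensitivityRecord:
    """Per-window OLS sensitivities of cloud to tree cover and elevation."""

    s_tree: float     # cloud fraction per unit tree-cover fraction
    s_ele: float      # cloud fraction per meter
    intercept: float  # unused downstream
    window: Window | None = None


@dataclass
class AttributionRecord:
    delta_cloud: float
    delta_cloud_tree: float
    delta_cloud_ele: float
    attribution: AttributionClass


def fit_window_sensitivities(
    cloud: GridField,
    tree: GridField,
    elevation: GridField,
    window: Window,
) -> SensitivityRecord | Rejection:
    """OLS fit of cloud on (tree, elevation, 1) over one window's pixels.

    Rejected when fewer than four unmasked pixels remain, when tree cover is
    zero everywhere in the window, or when the design matrix is rank
    deficient (e.g. constant elevation).
    """
    sl_r, sl_c = window.rows, window.cols
    use = ~(cloud.mask[sl_r, sl_c] | tree.mask[sl_r, sl_c]
            | elevation.mask[sl_r, sl_c])
    y = cloud.values[sl_r, sl_c][use].astype(float)
    t = tree.values[sl_r, sl_c][use].astype(float)
    e = elevation.values[sl_r, sl_c][use].astype(float)
    if y.size < MIN_REGRESSION_PIXELS:
        return Rejection("too_few_pixels", window)
    if np.all(t == 0):
        return Rejection("zero_tree_cover", window)
    X = np.column_stack([t, e, np.ones_like(t)])
    # Column scaling keeps the rank test meaningful when elevation values
    # are numerically large compared with fractions.
    scale = np.maximum(np.abs(X).max(axis=0), 1e-30)
    if np.linalg.matrix_rank(X / scale, tol=1e-10) < 3:
        return Rejection("rank_deficient", window)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SensitivityRecord(float(coef[0]), float(coef[1]), float(coef[2]),
                             window)


def decompose(record: SensitivityRecord, delta_tree: float,
              delta_ele: float) -> tuple[float, float]:
    """Component cloud differences: sensitivities times driver differences."""
    return record.s_tree * delta_tree, record.s_ele * delta_ele


def classify_attribution(delta_cloud: float, delta_cloud_tree: float,
                         delta_cloud_ele: float) -> AttributionClass:
    """Dominant-factor classification of one cell.

    If both components share ΔCloud's sign the larger-magnitude one
    dominates (exact ties break to tree cover); if only one shares the sign
    it dominates; if neither does — or ΔCloud is exactly zero — the cell is
    OTHER. The sign of ΔCloud sets the +/− variant.
    """
    if delta_cloud == 0 or not np.isfinite(delta_cloud):
        return AttributionClass.OTHER
    sign = np.sign(delta_cloud)
    tree_same = np.sign(delta_cloud_tree) == sign
    ele_same = np.sign(delta_cloud_ele) == sign
    if tree_same and ele_same:
        dominant = ("tree" if abs(delta_cloud_tree) >= abs(delta_cloud_ele)
                    else "ele")
    elif tree_same:
        dominant = "tree"
    elif ele_same:
        dominant = "ele"
    else:
        return AttributionClass.OTHER
    if dominant == "tree":
        return AttributionClass.TREE_PLUS if sign > 0 else AttributionClass.TREE_MINUS
    return AttributionClass.ORO_PLUS if sign > 0 else AttributionClass.ORO_MINUS


def reconstruction_explained(original: Sequence[float],
                             reconstructed: Sequence[float],
                             method: str = "r2") -> float:
    """How much of the original ΔCloud the reconstruction explains.

    ``r2`` (default) is the coefficient of determination of original against
    reconstructed (squared Pearson correlation); ``abs_ratio`` is the
    alternative Σ|reconstructed| / Σ|original|.
    """
    x = np.asarray(original, dtype=float)
    y = np.asarray(reconstructed, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if method == "abs_ratio":
        denom = np.abs(x).sum()
        return float(np.abs(y).sum() / denom) if denom else float("nan")
    if method != "r2":
        raise ValueError("method must be 'r2' or 'abs_ratio'")
    if np.allclose(x, y):
        return 1.0
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


# ---------------------------------------------------------------------------
# Display-grid attribution pipeline
# ---------------------------------------------------------------------------

@dataclass
class AttributionResult:
    """Display-grid attribution of the potential cloud effect."""

    delta_cloud: EffectMap
    delta_cloud_tree: GridField
    delta_cloud_ele: GridField
    classes: GridField            # AttributionClass codes, 0 = nodata
    records: list[AttributionRecord]
    explained: float
    class_percent: dict[str, float]


_CLASS_CODE = {c: i + 1 for i, c in enumerate(AttributionClass)}


def _mean_map(samples: list[tuple[float, float, float]], res: float,
              extent) -> EffectMap:
    sams = [WindowSample(la, lo, v, 0.0, v, 1, 1) for la, lo, v in samples]
    return aggregate_to_display(sams, res, extent)


def attribute_scene(
    classmap: SurfaceClassMap,
    cloud_mean: GridField,
    tree: GridField,
    elevation: GridField,
    water_mask: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    display_resolution: float = 0.5,
    windows: Sequence[Window] | None = None,
    explained_method: str = "r2",
) -> AttributionResult:
    """Full attribution: per-window sensitivities and driver differences,
    display-grid averaging, decomposition, and five-class map."""
    from .surface import buffer_water_mask
    from .windows import place_windows

    if windows is None:
        windows = place_windows(classmap, spec)
    buf = buffer_water_mask(water_mask) if water_mask is not None else None

    cloud_s, tree_s, ele_s, sens = [], [], [], []
    for w in windows:
        dc = window_effect(w, classmap, cloud_mean, buf, spec, elevation)
        if isinstance(dc, Rejection):
            continue
        dt = window_effect(w, classmap, tree, buf, spec)
        de = window_effect(w, classmap, elevation, buf, spec)
        fit = fit_window_sensitivities(cloud_mean, tree, elevation, w)
        if isinstance(dt, Rejection) or isinstance(de, Rejection) \
                or isinstance(fit, Rejection):
            continue
        cloud_s.append((w.center_lat, w.center_lon, dc.delta))
        tree_s.append((w.center_lat, w.center_lon, dt.delta))
        ele_s.append((w.center_lat, w.center_lon, de.delta))
        sens.append((w.center_lat, w.center_lon, fit.s_tree, fit.s_ele))
    if not cloud_s:
        raise ValueError("no windows survived the attribution filters")

    res = display_resolution
    lats = [s[0] for s in cloud_s]
    lons = [s[1] for s in cloud_s]
    south = np.floor(min(lats) / res) * res
    north = np.ceil((max(lats) + 1e-12) / res) * res
    west = np.floor(min(lons) / res) * res
    east = np.ceil((max(lons) + 1e-12) / res) * res
    extent = (south, north, west, east)

    dc_map = _mean_map(cloud_s, res, extent)
    dt_map = _mean_map(tree_s, res, extent)
    de_map = _mean_map(ele_s, res, extent)
    st_map = _mean_map([(la, lo, st) for la, lo, st, _ in sens], res, extent)
    se_map = _mean_map([(la, lo, se) for la, lo, _, se in sens], res, extent)

    valid = dc_map.valid & dt_map.valid & st_map.valid
    g = dc_map.delta
    comp_tree = np.where(valid, st_map.delta.values * dt_map.delta.values, 0.0)
    comp_ele = np.where(valid, se_map.delta.values * de_map.delta.values, 0.0)
    codes = np.zeros(g.shape, dtype=np.int64)
    records: list[AttributionRecord] = []
    orig, recon = [], []
    for i, j in np.argwhere(valid):
        rec = AttributionRecord(
            float(g.values[i, j]), float(comp_tree[i, j]),
            float(comp_ele[i, j]),
            classify_attribution(float(g.values[i, j]),
                                 float(comp_tree[i, j]),
                                 float(comp_ele[i, j])),
        )
        records.append(rec)
        codes[i, j] = _CLASS_CODE[rec.attribution]
        orig.append(rec.delta_cloud)
        recon.append(rec.delta_cloud_tree + rec.delta_cloud_ele)
    explained = (reconstruction_explained(orig, recon, explained_method)
                 if len(orig) >= 3 else float("nan"))
    n = max(len(records), 1)
    class_percent = {
        c.value: 100.0 * sum(r.attribution is c for r in records) / n
        for c in AttributionClass
    }
    return AttributionResult(
        delta_cloud=dc_map,
        delta_cloud_tree=g.like(comp_tree, mask=~valid,
                                variable="delta_cloud_tree"),
        delta_cloud_ele=g.like(comp_ele, mask=~valid,
                               variable="delta_cloud_ele"),
        classes=g.like(codes, mask=np.zeros_like(valid),
                       variable="attribution_class", units="class"),
        records=records, explained=explained, class_percent=class_percent,
    )
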