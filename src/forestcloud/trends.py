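"""Annual loss-effect series, trend fitting, and the scale experiment.

Over a hotspot region the actual effect of forest loss is tracked year by
year: for each year the yearly mean cloud field is run through the window
estimator (forest-loss minus unchanged-forest) and the retained samples are
averaged over display cells whose forest-loss fraction exceeds 0.05. The
annual series is paired with the progressive tree-cover deficit

    ΔTree_year = (Tree2000_loss − Tree2000_forest)
                 − Σ_{2001}^{year} (Treeloss_loss − Treeloss_forest) ,

which declines as loss accumulates in the loss pixels. A linear OLS trend
in percent per year, its two-tailed p value, and the total change
(slope × inclusive year count, 17 for 2002–2018) summarize each region.

The scale experiment re-runs the whole estimator after aggregating the
scene to coarser resolutions (mean for continuous fields, majority for
land cover), quantifying how the spatial coverage of cloud inhibition —
a mesoscale feature — shrinks as resolution coarsens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GridField, GridStack, aggregate_major, aggregate_mean
from .surface import (
    ClassifierConfig, SurfaceClass, SurfaceClassMap, classify_pixels,
    compute_change,
)
from .windows import (
    WindowSpec, actual_effects, aggregate_to_display, potential_effects,
    sign_fractions,
)

__all__ = [
    "HOTSPOT_REGIONS",
    "AnnualSeries",
    "TrendResult",
    "ScaleRunConfig",
    "delta_tree_series",
    "annual_effect_series",
    "fit_trend",
    "rescale_experiment",
]

#: Named hotspot bounding boxes (lon_min, lon_max, lat_min, lat_max).
HOTSPOT_REGIONS: dict[str, tuple[float, float, float, float]] = {
    "amazon": (-70.0, -50.0, -16.0, -5.0),
    "indonesia": (95.0, 120.0, -5.0, 5.0),
    "southeast_us": (-97.0, -75.0, 30.0, 40.0),
    "east_siberia": (110.0, 140.0, 50.0, 65.0),
}


@dataclass
class AnnualSeries:
    """Regional yearly mean ΔCloud_loss and tree-cover deficit."""

    years: list[int]
    delta_cloud_loss: list[float]     # fraction
    delta_tree: list[float] | None = None
    n_samples: list[int] | None = None
    region: str = "region"

    def as_frame(self) -> pd.DataFrame:
        d = {"year": self.years, "delta_cloud_loss": self.delta_cloud_loss}
        if self.delta_tree is not None:
            d["delta_tree"] = self.delta_tree
        if self.n_samples is not None:
            d["n_samples"] = self.n_samples
        return pd.DataFrame(d).set_index("year")


@dataclass
class TrendResult:
    """Linear trend of an annual effect series, in percent per year."""

    slope: float          # %/year
    intercept: float      # %
    p_value: float        # two-tailed t-test on the slope
    total_change: float   # % over the inclusive year span
    n_years: int


def delta_tree_series(
    tree2000_loss: float,
    tree2000_forest: float,
    yearly_loss_loss: Mapping[int, float],
    yearly_loss_forest: Mapping[int, float],
    years: Sequence[int],
) -> dict[int, float]:
    """Tree-cover difference (loss minus unchanged forest) through time.

    The baseline difference is reduced by the accumulated excess loss in the
    loss pixels, so ΔTree declines as clearing progresses.
    """
    base = tree2000_loss - tree2000_forest
    out: dict[int, float] = {}
    acc = 0.0
    first = min(min(years), 2001)
    for y in range(first, max(years) + 1):
        acc += yearly_loss_loss.get(y, 0.0) - yearly_loss_forest.get(y, 0.0)
        if y in years:
            out[y] = base - acc
    return out


def annual_effect_series(
    cloud_yearly: GridStack,
    classmap: SurfaceClassMap,
    accumulated_loss: GridField,
    region: tuple[float, float, float, float] | None = None,
    elevation: GridField | None = None,
    water_mask: GridField | None = None,
    spec: WindowSpec = WindowSpec(),
    display_resolution: float = 0.5,
    loss_fraction_min: float = 0.05,
    region_name: str = "region",
    tree2000: GridField | None = None,
    yearly_loss: Mapping[int, GridField] | None = None,
) -> AnnualSeries:
    """Yearly mean ΔCloud_loss over qualifying display cells of a region.

    A display cell qualifies when it lies inside the region box and its
    mean forest-loss fraction exceeds ``loss_fraction_min``. When baseline
    tree cover and the yearly loss stacks are supplied, the matching
    ΔTree series over the same pixel classes is attached.
    """
    g = classmap.labels
    if region is None:
        region = (float(g.lon[0] - g.resolution), float(g.lon[-1] + g.resolution),
                  float(g.lat[0] - g.resolution), float(g.lat[-1] + g.resolution))
    lon_min, lon_max, lat_min, lat_max = region

    res = display_resolution
    # per-display-cell mean loss fraction, keyed by (floor(lat/res), floor(lon/res))
    la2d = np.broadcast_to(accumulated_loss.lat[:, None], accumulated_loss.shape)
    lo2d = np.broadcast_to(accumulated_loss.lon[None, :], accumulated_loss.shape)
    keys = np.stack([np.floor(la2d / res), np.floor(lo2d / res)], axis=-1)
    loss_by_cell: dict[tuple[float, float], float] = {}
    flat_keys = keys.reshape(-1, 2)
    flat_vals = accumulated_loss.values.reshape(-1)
    for key in np.unique(flat_keys, axis=0):
        sel = (flat_keys[:, 0] == key[0]) & (flat_keys[:, 1] == key[1])
        loss_by_cell[(key[0], key[1])] = float(flat_vals[sel].mean())
    years, means, counts = [], [], []
    for y in cloud_yearly.time:
        samples, _ = actual_effects(classmap, cloud_yearly[y], elevation,
                                    water_mask, spec)
        keep = [s for s in samples
                if lon_min <= s.center_lon < lon_max
                and lat_min <= s.center_lat < lat_max]
        if not keep:
            continue
        emap = aggregate_to_display(keep, res)
        vals, ok = [], emap.valid
        for i, j in np.argwhere(ok):
            la, lo = emap.delta.lat[i], emap.delta.lon[j]
            cell = (np.floor(la / res), np.floor(lo / res))
            if loss_by_cell.get(cell, 0.0) > loss_fraction_min:
                vals.append(emap.delta.values[i, j])
        if vals:
            years.append(int(y))
            means.append(float(np.mean(vals)))
            counts.append(len(vals))
    if not years:
        raise ValueError("no qualifying display cells in the region")

    dtree = None
    if tree2000 is not None and yearly_loss is not None:
        loss_sel = classmap.where(SurfaceClass.FOREST_LOSS)
        forest_sel = classmap.where(SurfaceClass.UNCHANGED_FOREST)
        inbox = (
            (g.lon[None, :] >= lon_min) & (g.lon[None, :] < lon_max)
            & (g.lat[:, None] >= lat_min) & (g.lat[:, None] < lat_max)
        )
        loss_sel, forest_sel = loss_sel & inbox, forest_sel & inbox
        if loss_sel.any() and forest_sel.any():
            series = delta_tree_series(
                float(tree2000.values[loss_sel].mean()),
                float(tree2000.values[forest_sel].mean()),
                {y: float(f.values[loss_sel].mean())
                 for y, f in yearly_loss.items()},
                {y: float(f.values[forest_sel].mean())
                 for y, f in yearly_loss.items()},
                years,
            )
            dtree = [series[y] for y in years]
    return AnnualSeries(years, means, dtree, counts, region_name)


def fit_trend(series: AnnualSeries) -> TrendResult:
    """OLS trend of the annual effect (converted to percent) on year.

    ``total_change`` is slope × the inclusive year count of the series
    (e.g. 17 for 2002–2018); the p value is the two-tailed t-test on the
    slope, NaN for degenerate (constant or too-short) series.
    """
    years = np.asarray(series.years, dtype=float)
    pct = np.asarray(series.delta_cloud_loss, dtype=float) * 100.0
    if years.size < 3:
        raise ValueError("need at least 3 years for a trend")
    n_years = int(years.max() - years.min()) + 1
    res = stats.linregress(years, pct)
    slope = float(res.slope)
    p = float(res.pvalue)
    if np.allclose(pct, pct[0]):
        slope = 0.0
        p = float("nan")
    return TrendResult(slope, float(res.intercept), p,
                       slope * n_years, n_years)


# ---------------------------------------------------------------------------
# Scale-dependency experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleRunConfig:
    """One resolution of the rescale experiment with two window settings."""

    target_resolution: float
    window_specs: tuple[WindowSpec, WindowSpec]
    display_resolution: float = 1.0


DEFAULT_SCALE_RUNS: tuple[ScaleRunConfig, ...] = (
    ScaleRunConfig(0.05, (WindowSpec(9, 5), WindowSpec(11, 5))),
    ScaleRunConfig(0.1, (WindowSpec(9, 5), WindowSpec(5, 3))),
    ScaleRunConfig(0.25, (WindowSpec(5, 3), WindowSpec(7, 3))),
    ScaleRunConfig(0.5, (WindowSpec(5, 3), WindowSpec(3, 1))),
    ScaleRunConfig(1.0, (WindowSpec(3, 1), WindowSpec(5, 1))),
)


def rescale_experiment(
    scene,
    configs: Sequence[ScaleRunConfig] = DEFAULT_SCALE_RUNS,
    classifier: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Re-estimate the potential effect at coarser resolutions.

    For every target resolution the cloud, tree, loss, gain and water
    fields are block-mean aggregated, land cover is majority-aggregated,
    the classifier and window estimator are re-run with each of the two
    window settings, and the enhancement / inhibition percentages are
    tabulated.
    """
    base_res = scene.tree2000.resolution
    cloud = scene.cloud_yearly.mean()
    rows = []
    for cfg in configs:
        factor = cfg.target_resolution / base_res
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"target resolution {cfg.target_resolution} is not a "
                f"multiple of the scene resolution {base_res}")
        factor = int(round(factor))
        if scene.tree2000.shape[0] % factor or scene.tree2000.shape[1] % factor:
            raise ValueError("aggregation factor does not divide the grid")
        tree_c = aggregate_mean(scene.tree2000, factor)
        gain_c = aggregate_mean(scene.gain, factor)
        loss_c = {y: aggregate_mean(f, factor)
                  for y, f in scene.yearly_loss.items()}
        lc_c = aggregate_major(scene.landcover, factor)
        cloud_c = aggregate_mean(cloud, factor)
        elev_c = aggregate_mean(scene.elevation, factor)
        water_c = aggregate_major(scene.water_mask, factor)
        turnover, net = compute_change(tree_c, loss_c, gain_c)
        cmap = classify_pixels(tree_c, turnover, net, lc_c, classifier)
        for k, spec in enumerate(cfg.window_specs):
            samples, rejections = potential_effects(
                cmap, cloud_c, elev_c, water_c, spec)
            if samples:
                emap = aggregate_to_display(samples, cfg.display_resolution)
                enh, inh = sign_fractions(emap)
            else:
                enh = inh = float("nan")
            rows.append({
                "resolution": cfg.target_resolution,
                "window_size": spec.size,
                "window_step": spec.step,
                "n_samples": len(samples),
                "n_rejected": len(rejections),
                "percent_enhancement": enh,
                "percent_inhibition": inh,
            })
    return pd.DataFrame(rows)
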