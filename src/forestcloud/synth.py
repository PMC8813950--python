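"""Synthetic scene generator with known ground truth.

Builds complete gridded scenes — elevation, baseline tree cover, patchy yearly
forest loss, land cover, water, and cloud stacks linearly coupled to tree
cover and elevation — so the whole moving-window pipeline can be exercised
and its estimates checked against the generative parameters.

The generative model for cloud cover in year ``y`` is

    cloud_y = clip( b0 + S_tree * tree_y + S_ele * elevation
                    + spatial_noise + interannual_noise_y , 0, 1 )

where ``tree_y`` is baseline tree cover minus the loss accumulated through
``y``. ``S_tree`` (cloud fraction per unit tree-cover fraction) may take a
different sign in different longitude bands, emulating regions where forests
enhance clouds (positive coupling, sensible-heat driven convection) versus
regions where mesoscale subsidence over forest inhibits them (negative
coupling). The spatial noise is one correlated field shared by all years;
the interannual noise is one scalar per year shared by the whole scene.

Everything is a pure function of the seed: the same :class:`SceneConfig`
reproduces a scene bit-exactly.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .grid import GridField, GridStack, write_raster, write_stack

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_random_field",
    "generate_scene",
    "fixture_scene_config",
    "LC_WATER",
    "LC_EVERGREEN_BROADLEAF",
    "LC_GRASSLAND",
    "LC_WETLAND",
    "LC_CROPLAND",
    "LC_SNOW_ICE",
    "EXCLUDED_NONFOREST_CLASSES",
]

# Compact IGBP-style land-cover vocabulary.
LC_WATER = 0
LC_EVERGREEN_BROADLEAF = 2
LC_GRASSLAND = 10
LC_WETLAND = 11
LC_CROPLAND = 12
LC_SNOW_ICE = 15
#: Non-forest classes excluded from the "unchanged non-forest" pool.
EXCLUDED_NONFOREST_CLASSES = frozenset({LC_WATER, LC_WETLAND, LC_SNOW_ICE})


@dataclass
class SceneConfig:
    """Generative parameters of a synthetic scene.

    Units: cloud quantities are fractions in [0, 1]; ``S_tree_true`` is cloud
    fraction per unit tree-cover fraction; ``S_ele_true`` is cloud fraction
    per meter; lengths are grid cells; ``delta_h`` values are W/m².
    """

    n_lat: int = 96
    n_lon: int = 96
    resolution: float = 0.05
    origin_lat: float = -10.0
    origin_lon: float = 20.0
    years: tuple[int, int] = (2002, 2018)
    months: tuple[int, ...] = tuple(range(1, 13))
    seed: int = 0

    # linear cloud model
    S_tree_true: float = 0.05
    S_ele_true: float = 1e-4
    b0: float = 0.45
    #: optional longitude-band values overriding S_tree_true (west → east)
    s_tree_regions: tuple[float, ...] | None = None
    #: optional patchy coupling (background, patch value, patch correlation
    #: length in cells, patch area fraction) — small blobs of one sign inside
    #: a background of the other, emulating sub-window mesoscale inhibition
    s_tree_patch: tuple[float, float, float, float] | None = None
    noise_sd_spatial: float = 0.02
    noise_sd_interannual: float = 0.01
    correlation_length: float = 3.0

    # land surface
    tree_correlation_length: float = 8.0
    elevation_mean: float = 300.0
    elevation_sd: float = 40.0
    elevation_correlation_length: float = 20.0
    loss_patch_count: int = 12
    loss_patch_size: int = 25
    loss_rate_per_year: float = 0.03
    water_fraction: float = 0.02
    snow_months_by_latitude: Mapping[float, Sequence[int]] = field(
        default_factory=lambda: {55.0: (11, 12, 1, 2, 3)}
    )

    # seasonal / diurnal modulation of the tree coupling
    seasonal_amplitude: float = 0.5
    seasonal_peak_month: int = 7
    diurnal_peak_hour_utc: int = 12

    # optional extras
    include_monthly: bool = True
    include_hourly: bool = False
    include_cloud_types: bool = False

    # sensible-heat table: ΔH = heat_per_sensitivity · local S_tree (+ jitter)
    heat_per_sensitivity: float = 1000.0
    heat_jitter_sd: float = 5.0
    delta_h_by_pair: Mapping[tuple[int, int], float] | None = None

    def __post_init__(self) -> None:
        for name in ("b0", "water_fraction", "loss_rate_per_year"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.noise_sd_spatial < 0 or self.noise_sd_interannual < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.years[1] < self.years[0]:
            raise ValueError("years range must be inclusive and ordered")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def loss_years(self) -> list[int]:
        return list(range(2001, self.years[1] + 1))

    def s_tree_map(self, lon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel tree-coupling map (bands or patches if configured)."""
        if self.s_tree_patch is not None:
            base, patch, corr, frac = self.s_tree_patch
            fld = generate_random_field(self.seed + 1_000_003, shape, corr, 1.0)
            thr = np.quantile(fld.values, 1.0 - frac)
            return np.where(fld.values > thr, patch, base)
        if self.s_tree_regions is None:
            return np.full(shape, self.S_tree_true)
        bands = np.asarray(self.s_tree_regions, dtype=float)
        idx = np.minimum(
            (np.arange(lon.size) * len(bands)) // lon.size, len(bands) - 1
        )
        return np.broadcast_to(bands[idx], shape).copy()


@dataclass
class SyntheticScene:
    """Generated rasters plus the ground-truth config that made them."""

    elevation: GridField
    tree2000: GridField
    yearly_loss: dict[int, GridField]
    gain: GridField
    landcover: GridField
    water_mask: GridField
    snow_flags: dict[int, GridField]          # month -> boolean flag field
    cloud_monthly: GridStack | None
    cloud_yearly: GridStack
    s_tree_field: GridField                   # per-pixel true tree coupling
    cloud_hourly: GridStack | None = None
    type_cover: dict[int, GridField] | None = None   # ISCCP code -> cover
    type_total: GridField | None = None              # total the covers sum to
    ctp: GridField | None = None
    tau: GridField | None = None
    conversion_table: "object | None" = None  # heatlink.ConversionTable
    truth: SceneConfig | None = None

    def accumulated_loss(self, through_year: int | None = None) -> GridField:
        """Total loss fraction accumulated from 2001 through ``through_year``."""
        years = sorted(self.yearly_loss)
        if through_year is not None:
            years = [y for y in years if y <= through_year]
        total = np.zeros(self.tree2000.shape)
        for y in years:
            total += self.yearly_loss[y].values
        return self.tree2000.like(total, variable="loss_fraction")

    def tree_in_year(self, year: int) -> GridField:
        tree = self.tree2000.values - self.accumulated_loss(year).values
        return self.tree2000.like(np.clip(tree, 0.0, 1.0))

    def tree_multiyear_mean(self) -> GridField:
        """Tree cover averaged over the cloud years — the driver field that
        co-varies with the multiyear mean cloud fraction."""
        years = list(self.cloud_yearly.time)
        stack = np.mean([self.tree_in_year(y).values for y in years], axis=0)
        return self.tree2000.like(stack)


def generate_random_field(
    seed: int, shape: tuple[int, int], correlation_length: float, sd: float
) -> GridField:
    """Zero-mean spatially correlated Gaussian random field.

    White noise smoothed by a Gaussian kernel of scale ``correlation_length``
    (cells), then re-centered and rescaled so the sample mean is exactly 0 and
    the sample standard deviation exactly ``sd``. ``correlation_length = 0``
    gives plain white noise; ``sd = 0`` gives the zero field.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if correlation_length < 0:
        raise ValueError("correlation_length must be >= 0")
    n_lat, n_lon = shape
    lat = (np.arange(n_lat) + 0.5) * 1.0
    lon = (np.arange(n_lon) + 0.5) * 1.0
    if sd == 0:
        vals = np.zeros(shape)
    else:
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal(shape)
        if correlation_length > 0:
            vals = ndimage.gaussian_filter(vals, sigma=correlation_length, mode="wrap")
        vals = vals - vals.mean()
        s = vals.std()
        vals = vals * (sd / s) if s > 0 else vals
    return GridField(values=vals, lat=lat, lon=lon, resolution=1.0,
                     variable="noise", units="1")


def _axes(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    lat = cfg.origin_lat + cfg.resolution * (np.arange(cfg.n_lat) + 0.5)
    lon = cfg.origin_lon + cfg.resolution * (np.arange(cfg.n_lon) + 0.5)
    return lat, lon


def _correlated(rng: np.random.Generator, cfg: SceneConfig,
                corr: float, sd: float = 1.0) -> np.ndarray:
    sub = int(rng.integers(0, 2**31 - 1))
    return generate_random_field(sub, (cfg.n_lat, cfg.n_lon), corr, sd).values


def _grow_patch(forest: np.ndarray, start: tuple[int, int], size: int,
                taken: np.ndarray) -> list[tuple[int, int]]:
    """Grow a contiguous blob of up to ``size`` forest pixels by BFS."""
    n_lat, n_lon = forest.shape
    pix: list[tuple[int, int]] = []
    q: deque[tuple[int, int]] = deque([start])
    seen = {start}
    while q and len(pix) < size:
        i, j = q.popleft()
        if not forest[i, j] or taken[i, j]:
            continue
        pix.append((i, j))
        taken[i, j] = True
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n_lat and 0 <= nj < n_lon and (ni, nj) not in seen:
                seen.add((ni, nj))
                q.append((ni, nj))
    return pix


def generate_scene(cfg: SceneConfig) -> SyntheticScene:
    """Generate a full synthetic scene from its config (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    lat, lon = _axes(cfg)
    shape = (cfg.n_lat, cfg.n_lon)

    def make(values, variable, units="1", mask=None):
        return GridField(values=values, lat=lat, lon=lon,
                         resolution=cfg.resolution, mask=mask,
                         variable=variable, units=units)

    # --- land surface -----------------------------------------------------
    elev = cfg.elevation_mean + cfg.elevation_sd * _correlated(
        rng, cfg, cfg.elevation_correlation_length)
    elev = np.clip(elev, 0.0, None)
    elevation = make(elev, "elevation", "m")

    g = _correlated(rng, cfg, cfg.tree_correlation_length)
    tree = np.clip(0.5 + 0.45 * np.tanh(2.5 * g), 0.0, 1.0)
    tree2000 = make(tree, "tree_fraction")

    w = _correlated(rng, cfg, cfg.tree_correlation_length)
    if cfg.water_fraction >= 1.0:
        water = np.ones(shape, dtype=bool)
    elif cfg.water_fraction > 0:
        water = w > np.quantile(w, 1.0 - cfg.water_fraction)
    else:
        water = np.zeros(shape, dtype=bool)
    water_mask = make(water.astype(float), "water_mask")

    crop_split = _correlated(rng, cfg, cfg.tree_correlation_length)
    lc = np.where(tree > 0.5, LC_EVERGREEN_BROADLEAF,
                  np.where(crop_split > 0, LC_CROPLAND, LC_GRASSLAND))
    lc = np.where(water, LC_WATER, lc)
    landcover = make(lc.astype(np.int64), "landcover", "class")

    # --- forest loss patches ---------------------------------------------
    forest = (tree > 0.5) & ~water
    loss_years = cfg.loss_years
    patch_pixels: list[tuple[int, int]] = []
    if cfg.loss_patch_count > 0:
        cand = np.argwhere(forest)
        if cand.size == 0:
            raise ValueError("loss patches requested but scene has no forest")
        taken = np.zeros(shape, dtype=bool)
        order = rng.permutation(len(cand))
        placed = 0
        for k in order:
            if placed >= cfg.loss_patch_count:
                break
            i, j = map(int, cand[k])
            if taken[i, j]:
                continue
            pix = _grow_patch(forest, (i, j), cfg.loss_patch_size, taken)
            if pix:
                patch_pixels.extend(pix)
                placed += 1
    yearly_loss: dict[int, GridField] = {}
    cum = np.zeros(shape)
    patch_arr = np.zeros(shape, dtype=bool)
    for i, j in patch_pixels:
        patch_arr[i, j] = True
    for y in loss_years:
        step = np.zeros(shape)
        room = np.clip(tree - cum, 0.0, None)
        step[patch_arr] = np.minimum(cfg.loss_rate_per_year, room[patch_arr])
        yearly_loss[y] = make(step, "loss_fraction")
        cum += step
    gain = make(np.zeros(shape), "gain_fraction")

    # --- cloud stacks -----------------------------------------------------
    s_tree = cfg.s_tree_map(lon, shape)
    s_tree_field = make(s_tree, "s_tree_true", "cloud fraction / tree fraction")
    spatial_noise = _correlated(rng, cfg, cfg.correlation_length,
                                cfg.noise_sd_spatial)
    years = cfg.year_list
    inter = (rng.standard_normal(len(years)) * cfg.noise_sd_interannual
             if cfg.noise_sd_interannual > 0 else np.zeros(len(years)))

    snow_flags: dict[int, GridField] = {}
    for m in range(1, 13):
        flag = np.zeros(shape, dtype=bool)
        for thr, months in cfg.snow_months_by_latitude.items():
            if m in tuple(months):
                flag |= np.abs(lat)[:, None] >= float(thr)
        snow_flags[m] = make(flag.astype(float), "snow_flag")

    cum_by_year: dict[int, np.ndarray] = {}
    running = np.zeros(shape)
    for y in loss_years:
        running = running + yearly_loss[y].values
        cum_by_year[y] = running.copy()

    yearly_fields, monthly_fields, monthly_labels = [], [], []
    for k, y in enumerate(years):
        tree_y = np.clip(tree - cum_by_year.get(y, 0.0), 0.0, 1.0)
        base = cfg.b0 + s_tree * tree_y + cfg.S_ele_true * elev \
            + spatial_noise + inter[k]
        yearly_fields.append(make(np.clip(base, 0.0, 1.0), "cloud_fraction"))
        for m in (cfg.months if cfg.include_monthly else ()):
            wgt = 1.0 + cfg.seasonal_amplitude * np.cos(
                2 * np.pi * (m - cfg.seasonal_peak_month) / 12.0)
            vals = np.clip(cfg.b0 + s_tree * wgt * tree_y
                           + cfg.S_ele_true * elev + spatial_noise + inter[k],
                           0.0, 1.0)
            snow = snow_flags[m].values.astype(bool)
            monthly_fields.append(make(vals, "cloud_fraction", mask=snow))
            monthly_labels.append((y, m))
    cloud_yearly = GridStack(yearly_fields, list(years))
    cloud_monthly = (GridStack(monthly_fields, monthly_labels)
                     if cfg.include_monthly else None)

    cloud_hourly = None
    if cfg.include_hourly:
        tree_end = np.clip(tree - running, 0.0, 1.0)
        hf, hl = [], []
        for h in range(24):
            wgt = max(0.0, np.cos(2 * np.pi * (h - cfg.diurnal_peak_hour_utc) / 24.0))
            vals = np.clip(cfg.b0 + s_tree * (0.5 + wgt) * tree_end
                           + cfg.S_ele_true * elev, 0.0, 1.0)
            hf.append(make(vals, "cloud_fraction"))
            hl.append(h)
        cloud_hourly = GridStack(hf, hl)

    # --- cloud-type covers (optional) -------------------------------------
    type_cover = type_total = ctp = tau = None
    if cfg.include_cloud_types:
        tree_mean = np.clip(
            tree - np.mean([cum_by_year[y] for y in years], axis=0), 0.0, 1.0)
        raw_total = cfg.b0 + s_tree * tree_mean + cfg.S_ele_true * elev \
            + spatial_noise
        total = np.clip(raw_total, 0.0, 1.0)
        # Split total cover into three physically tagged components whose
        # window differences isolate the generative terms: the tree-coupled
        # part is shallow-convective (stratocumulus), the orographic part
        # cirrus, the baseline stratus.  Constant shifts keep covers >= 0
        # without touching any forest/non-forest difference.
        conv = s_tree * tree_mean
        conv = conv - conv.min() + 0.02
        oro = cfg.S_ele_true * elev
        oro = oro - oro.min() + 0.02
        rest = raw_total - conv - oro
        rest = rest - min(0.0, rest.min())
        raw_sum = conv + oro + rest
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(raw_sum > 0, total / raw_sum, 0.0)
        covers = {8: conv * scale, 1: oro * scale, 9: rest * scale}
        type_cover = {
            code: make(covers.get(code, np.zeros(shape)),
                       f"cloud_type_{code}_cover")
            for code in range(1, 10)
        }
        type_total = make(total, "cloud_fraction")
        dominant = np.where(
            (covers[8] >= covers[1]) & (covers[8] >= covers[9]), 8,
            np.where(covers[1] >= covers[9], 1, 9))
        ctp = make(np.where(dominant == 1, 300.0, 900.0), "cloud_top_pressure",
                   "hPa")
        tau = make(np.where(dominant == 8, 10.0,
                            np.where(dominant == 1, 1.0, 2.0)),
                   "cloud_optical_depth")

    # --- sensible-heat conversion table ------------------------------------
    from .heatlink import ConversionTable  # local import avoids a cycle

    table_res = 1.0
    if cfg.delta_h_by_pair is not None:
        table = ConversionTable(resolution=table_res,
                                global_entries=dict(cfg.delta_h_by_pair),
                                cell_entries={}, provenance="synthetic")
    else:
        cell_entries: dict[tuple[int, int], dict[tuple[int, int], float]] = {}
        ci_of = np.floor(lat / table_res).astype(int)
        cj_of = np.floor(lon / table_res).astype(int)
        for ci in np.unique(ci_of):
            for cj in np.unique(cj_of):
                sel = np.ix_(ci_of == ci, cj_of == cj)
                s_local = float(s_tree[sel].mean())
                jitter = float(rng.normal(0.0, cfg.heat_jitter_sd)) \
                    if cfg.heat_jitter_sd > 0 else 0.0
                dh = cfg.heat_per_sensitivity * s_local + jitter
                cell_entries[(int(ci), int(cj))] = {
                    (LC_EVERGREEN_BROADLEAF, LC_CROPLAND): dh,
                    (LC_EVERGREEN_BROADLEAF, LC_GRASSLAND): dh,
                }
        table = ConversionTable(resolution=table_res, global_entries={},
                                cell_entries=cell_entries,
                                provenance="synthetic")

    return SyntheticScene(
        elevation=elevation, tree2000=tree2000, yearly_loss=yearly_loss,
        gain=gain, landcover=landcover, water_mask=water_mask,
        snow_flags=snow_flags, cloud_monthly=cloud_monthly,
        cloud_yearly=cloud_yearly, s_tree_field=s_tree_field,
        cloud_hourly=cloud_hourly, type_cover=type_cover,
        type_total=type_total, ctp=ctp, tau=tau,
        conversion_table=table, truth=cfg,
    )


def fixture_scene_config(**overrides) -> SceneConfig:
    """Small (64×64, 5-year) scene used throughout the test suite."""
    defaults = dict(n_lat=64, n_lon=64, years=(2002, 2006), seed=7,
                    loss_patch_count=6, loss_patch_size=16)
    defaults.update(overrides)
    return SceneConfig(**defaults)


def save_scene(scene: SyntheticScene, outdir: str | Path) -> None:
    """Serialize a scene to GeoTIFF/NetCDF files plus a YAML manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("elevation", "tree2000", "gain", "landcover", "water_mask"):
        write_raster(getattr(scene, name), outdir / f"{name}.tif")
    loss_stack = GridStack(
        [scene.yearly_loss[y] for y in sorted(scene.yearly_loss)],
        sorted(scene.yearly_loss))
    write_stack(loss_stack, outdir / "yearly_loss.nc")
    write_stack(scene.cloud_yearly, outdir / "cloud_yearly.nc")
    if scene.cloud_monthly is not None:
        write_stack(scene.cloud_monthly, outdir / "cloud_monthly.nc")
    if scene.cloud_hourly is not None:
        write_stack(scene.cloud_hourly, outdir / "cloud_hourly.nc")
    manifest = {"config": _config_to_dict(scene.truth)} if scene.truth else {}
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def _config_to_dict(cfg: SceneConfig) -> dict:
    d = {}
    for k, v in cfg.__dict__.items():
        if isinstance(v, tuple):
            v = list(v)
        elif isinstance(v, Mapping):
            v = {str(kk): list(vv) if isinstance(vv, (tuple, list)) else vv
                 for kk, vv in v.items()}
        d[k] = v
    return d
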