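"""Core gridded data model: geographic raster fields, stacks, aggregation, IO.

Every stage of the pipeline exchanges :class:`GridField` objects — 2-D arrays
of a single variable on a regular geographic (lat/lon) grid with cell-center
coordinates — and :class:`GridStack` objects, which are time-indexed sequences
of fields sharing one geometry.

Conventions
-----------
* Latitude axes run south → north, longitude west → east, both strictly
  evenly spaced; coordinates label cell centers.
* The grid extent is half-open ``[south, north) × [west, east)`` in cell-edge
  terms, so a cell with center ``(lat, lon)`` covers
  ``[lat - res/2, lat + res/2) × [lon - res/2, lon + res/2)``.
* Nodata is carried as a boolean mask (``True`` = missing); array values under
  the mask are unspecified.
* Fraction-valued variables (cloud cover, tree cover, loss, gain) live in
  ``[0, 1]`` on unmasked cells.

IO
--
Single 2-D fields round-trip through GeoTIFF (georeferencing stored in the
standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags); stacks
round-trip through CF-style NetCDF with ``lat``/``lon``/``time`` dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import xarray as xr

__all__ = [
    "GridField",
    "GridStack",
    "GeometryError",
    "aggregate_mean",
    "aggregate_major",
    "read_raster",
    "write_raster",
    "read_stack",
    "write_stack",
]

_AXIS_TOL = 1e-9
#: Variables whose unmasked values must lie in [0, 1].
FRACTION_VARIABLES = frozenset(
    {"cloud_fraction", "tree_fraction", "loss_fraction", "gain_fraction"}
)

GEOTIFF_NODATA = -9999.0


class GeometryError(ValueError):
    """Raised when grids disagree in shape, axes or resolution."""


def _check_axis(axis: np.ndarray, resolution: float, name: str) -> None:
    if axis.ndim != 1 or axis.size == 0:
        raise GeometryError(f"{name} axis must be a non-empty 1-D array")
    if axis.size > 1:
        steps = np.diff(axis)
        if not np.all(steps > 0):
            raise GeometryError(f"{name} axis must be strictly increasing")
        if np.any(np.abs(steps - resolution) > _AXIS_TOL):
            raise GeometryError(
                f"{name} axis spacing deviates from resolution {resolution!r}"
            )


@dataclass
class GridField:
    """A single georeferenced 2-D variable.

    Parameters
    ----------
    values
        2-D array, shape ``(n_lat, n_lon)``; row ``i`` sits at ``lat[i]``.
    lat, lon
        Cell-center coordinates in degrees, strictly increasing, evenly
        spaced at ``resolution``.
    resolution
        Cell size in degrees (> 0).
    mask
        Boolean nodata mask, ``True`` where the cell is missing.
    variable, units
        Name + units tag (e.g. ``("cloud_fraction", "1")``,
        ``("elevation", "m")``).
    """

    values: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    resolution: float
    mask: np.ndarray | None = None
    variable: str = "field"
    units: str = "1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("values must be 2-D")
        if self.resolution <= 0:
            raise GeometryError("resolution must be positive")
        _check_axis(self.lat, self.resolution, "lat")
        _check_axis(self.lon, self.resolution, "lon")
        if self.values.shape != (self.lat.size, self.lon.size):
            raise GeometryError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.lat.size}, {self.lon.size})"
            )
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise GeometryError("mask shape does not match values")
        if self.variable in FRACTION_VARIABLES and self.values.size:
            valid = self.values[~self.mask]
            if valid.size and (valid.min() < -_AXIS_TOL or valid.max() > 1 + _AXIS_TOL):
                raise ValueError(
                    f"fraction variable {self.variable!r} outside [0, 1]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "GridField") -> bool:
        return (
            self.shape == other.shape
            and abs(self.resolution - other.resolution) <= _AXIS_TOL
            and np.allclose(self.lat, other.lat, atol=_AXIS_TOL)
            and np.allclose(self.lon, other.lon, atol=_AXIS_TOL)
        )

    def require_same_geometry(self, other: "GridField") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch between {self.variable!r} and {other.variable!r}"
            )

    def masked_values(self) -> np.ndarray:
        """Values with nodata replaced by NaN (float output)."""
        out = self.values.astype(float, copy=True)
        out[self.mask] = np.nan
        return out

    def like(self, values: np.ndarray, mask: np.ndarray | None = None,
             variable: str | None = None, units: str | None = None) -> "GridField":
        """New field on this geometry with different values."""
        return GridField(
            values=values,
            lat=self.lat.copy(),
            lon=self.lon.copy(),
            resolution=self.resolution,
            mask=self.mask.copy() if mask is None else mask,
            variable=self.variable if variable is None else variable,
            units=self.units if units is None else units,
        )


@dataclass
class GridStack:
    """Time-indexed sequence of :class:`GridField` sharing one geometry.

    ``time`` labels may be years (int), ``(year, month)`` tuples, or
    hours-of-day; they must be unique and sorted.
    """

    fields: list[GridField]
    time: list

    def __post_init__(self) -> None:
        if len(self.fields) != len(self.time):
            raise ValueError("one time label per field required")
        if not self.fields:
            raise ValueError("empty stack")
        first = self.fields[0]
        for f in self.fields[1:]:
            first.require_same_geometry(f)
        if len(set(map(tuple_or_scalar, self.time))) != len(self.time):
            raise ValueError("time labels must be unique")
        if sorted(self.time) != list(self.time):
            raise ValueError("time labels must be sorted")

    def __len__(self) -> int:
        return len(self.fields)

    def __getitem__(self, label) -> GridField:
        return self.fields[self.time.index(label)]

    @property
    def geometry(self) -> GridField:
        return self.fields[0]

    def mean(self, labels: Iterable | None = None) -> GridField:
        """Per-pixel mean over (a subset of) the stack, ignoring nodata.

        A pixel is nodata in the result only if it is nodata in every
        selected slice.
        """
        sel = list(self.time) if labels is None else list(labels)
        arrs = []
        for lab in sel:
            arrs.append(self[lab].masked_values())
        cube = np.stack(arrs)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(cube, axis=0)
        mask = np.all(np.isnan(cube), axis=0)
        out[mask] = np.nan
        g = self.geometry
        return g.like(np.where(mask, 0.0, out), mask=mask)


def tuple_or_scalar(t):
    return tuple(t) if isinstance(t, (list, tuple)) else t


# ---------------------------------------------------------------------------
# Aggregation primitives
# ---------------------------------------------------------------------------

def _coarse_axis(axis: np.ndarray, factor: int) -> np.ndarray:
    return axis.reshape(-1, factor).mean(axis=1)


def _check_factor(fld: GridField, factor: int) -> None:
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    n_lat, n_lon = fld.shape
    if n_lat % factor or n_lon % factor:
        raise GeometryError(
            f"factor {factor} does not divide grid dimensions {fld.shape}"
        )


def aggregate_mean(fld: GridField, factor: int) -> GridField:
    """Block-mean aggregation to a ``factor``-times coarser grid.

    Each coarse cell is the mean of its ``factor × factor`` fine cells,
    ignoring nodata; the coarse cell is nodata only when all constituents
    are nodata.
    """
    factor = int(factor)
    if factor == 1:
        return fld.like(fld.values.copy())
    _check_factor(fld, factor)
    n_lat, n_lon = fld.shape
    vals = fld.masked_values().reshape(
        n_lat // factor, factor, n_lon // factor, factor
    )
    with np.errstate(invalid="ignore"):
        out = np.nanmean(vals, axis=(1, 3))
    mask = np.all(np.isnan(vals), axis=(1, 3))
    return GridField(
        values=np.where(mask, 0.0, out),
        lat=_coarse_axis(fld.lat, factor),
        lon=_coarse_axis(fld.lon, factor),
        resolution=fld.resolution * factor,
        mask=mask,
        variable=fld.variable,
        units=fld.units,
    )


def aggregate_major(fld: GridField, factor: int) -> GridField:
    """Majority (modal-category) aggregation for categorical fields.

    Ties break to the smallest category code; an all-nodata block is nodata.
    """
    factor = int(factor)
    if factor == 1:
        return fld.like(fld.values.copy())
    _check_factor(fld, factor)
    codes = np.asarray(fld.values)
    if not np.issubdtype(codes.dtype, np.integer):
        if not np.all(codes[~fld.mask] == np.round(codes[~fld.mask])):
            raise ValueError("aggregate_major requires integer category codes")
        codes = codes.astype(np.int64)
    n_lat, n_lon = fld.shape
    nb_lat, nb_lon = n_lat // factor, n_lon // factor
    blocks = codes.reshape(nb_lat, factor, nb_lon, factor).transpose(0, 2, 1, 3)
    bmask = fld.mask.reshape(nb_lat, factor, nb_lon, factor).transpose(0, 2, 1, 3)
    out = np.zeros((nb_lat, nb_lon), dtype=codes.dtype)
    omask = np.zeros((nb_lat, nb_lon), dtype=bool)
    for i in range(nb_lat):
        for j in range(nb_lon):
            vals = blocks[i, j][~bmask[i, j]]
            if vals.size == 0:
                omask[i, j] = True
                continue
            cats, counts = np.unique(vals, return_counts=True)
            # np.unique sorts categories, so argmax returns the smallest
            # code among maximal counts — the documented tie-break.
            out[i, j] = cats[np.argmax(counts)]
    return GridField(
        values=out,
        lat=_coarse_axis(fld.lat, factor),
        lon=_coarse_axis(fld.lon, factor),
        resolution=fld.resolution * factor,
        mask=omask,
        variable=fld.variable,
        units=fld.units,
    )


# ---------------------------------------------------------------------------
# IO — GeoTIFF for single fields, NetCDF for stacks
# ---------------------------------------------------------------------------

def write_raster(fld: GridField, path: str | Path, format: str = "GeoTIFF") -> None:
    """Write a single field to GeoTIFF or a single-slice NetCDF file."""
    fmt = format.lower()
    if fmt == "geotiff":
        _write_geotiff(fld, Path(path))
    elif fmt == "netcdf":
        _field_to_dataset(fld).to_netcdf(Path(path), engine="scipy")
    else:
        raise ValueError(f"unknown raster format {format!r}")


def read_raster(path: str | Path, format: str = "GeoTIFF") -> GridField:
    fmt = format.lower()
    if fmt == "geotiff":
        return _read_geotiff(Path(path))
    if fmt == "netcdf":
        with xr.open_dataset(Path(path), engine="scipy") as ds:
            return _dataset_to_field(ds)
    raise ValueError(f"unknown raster format {format!r}")


def _write_geotiff(fld: GridField, path: Path) -> None:
    # GeoTIFF rows run north → south; flip our south → north layout.
    vals = fld.values.astype(np.float64, copy=True)
    vals[fld.mask] = GEOTIFF_NODATA
    vals = vals[::-1]
    res = fld.resolution
    west_edge = fld.lon[0] - res / 2
    north_edge = fld.lat[-1] + res / 2
    extratags = [
        (33550, "d", 3, (res, res, 0.0)),                      # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, west_edge, north_edge, 0.0)),  # ModelTiepoint
        (42113, "s", 0, str(GEOTIFF_NODATA)),                  # GDAL_NODATA
    ]
    tifffile.imwrite(
        path,
        vals,
        extratags=extratags,
        description=f"{fld.variable} [{fld.units}]",
        metadata=None,  # keep the description tag free for variable/units
    )


def _read_geotiff(path: Path) -> GridField:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray()[::-1].astype(np.float64)
        tags = {t.code: t.value for t in page.tags.values()}
    if 33550 not in tags or 33922 not in tags:
        raise GeometryError(f"{path} lacks GeoTIFF georeferencing tags")
    res_x, res_y = tags[33550][0], tags[33550][1]
    if abs(res_x - res_y) > _AXIS_TOL:
        raise GeometryError("anisotropic cells are not supported")
    west_edge, north_edge = tags[33922][3], tags[33922][4]
    nodata = float(tags.get(42113, GEOTIFF_NODATA))
    n_lat, n_lon = vals.shape
    lon = west_edge + res_x * (np.arange(n_lon) + 0.5)
    lat = north_edge - res_y * (n_lat - np.arange(n_lat) - 0.5)
    mask = vals == nodata
    vals = np.where(mask, 0.0, vals)
    desc = tags.get(270, "field [1]")
    variable, _, units = desc.partition(" [")
    return GridField(
        values=vals, lat=lat, lon=lon, resolution=res_x, mask=mask,
        variable=variable or "field", units=units.rstrip("]") or "1",
    )


def _field_to_dataset(fld: GridField) -> xr.Dataset:
    data = fld.masked_values()
    da = xr.DataArray(
        data, dims=("lat", "lon"), coords={"lat": fld.lat, "lon": fld.lon},
        name=fld.variable, attrs={"units": fld.units, "_FillValue_policy": "NaN"},
    )
    ds = da.to_dataset()
    ds.attrs["resolution"] = fld.resolution
    return ds


def _dataset_to_field(ds: xr.Dataset) -> GridField:
    name = list(ds.data_vars)[0]
    da = ds[name]
    vals = np.asarray(da.values, dtype=float)
    mask = np.isnan(vals)
    return GridField(
        values=np.where(mask, 0.0, vals),
        lat=np.asarray(da["lat"].values),
        lon=np.asarray(da["lon"].values),
        resolution=float(ds.attrs.get(
            "resolution", np.diff(da["lat"].values).mean() if da["lat"].size > 1 else 1.0
        )),
        mask=mask,
        variable=name,
        units=str(da.attrs.get("units", "1")),
    )


def write_stack(stack: GridStack, path: str | Path) -> None:
    """Write a stack as CF-style NetCDF (dims time, lat, lon).

    Tuple time labels ``(year, month)`` are encoded as ``year * 100 + month``.
    """
    g = stack.geometry
    encoded = [
        lab[0] * 100 + lab[1] if isinstance(lab, (tuple, list)) else lab
        for lab in stack.time
    ]
    cube = np.stack([f.masked_values() for f in stack.fields])
    da = xr.DataArray(
        cube, dims=("time", "lat", "lon"),
        coords={"time": encoded, "lat": g.lat, "lon": g.lon},
        name=g.variable, attrs={"units": g.units},
    )
    ds = da.to_dataset()
    ds.attrs["resolution"] = g.resolution
    ds.attrs["time_encoding"] = (
        "yearmonth" if isinstance(stack.time[0], (tuple, list)) else "plain"
    )
    ds.to_netcdf(Path(path), engine="scipy")


def read_stack(path: str | Path) -> GridStack:
    with xr.open_dataset(Path(path), engine="scipy") as ds:
        name = list(ds.data_vars)[0]
        da = ds[name].load()
        res = float(ds.attrs["resolution"])
        encoding = ds.attrs.get("time_encoding", "plain")
        units = str(da.attrs.get("units", "1"))
    lat = np.asarray(da["lat"].values)
    lon = np.asarray(da["lon"].values)
    fields, labels = [], []
    for k, t in enumerate(np.asarray(da["time"].values)):
        vals = np.asarray(da.values[k], dtype=float)
        mask = np.isnan(vals)
        fields.append(GridField(
            values=np.where(mask, 0.0, vals), lat=lat, lon=lon,
            resolution=res, mask=mask, variable=name, units=units,
        ))
        t = int(t)
        labels.append((t // 100, t % 100) if encoding == "yearmonth" else t)
    return GridStack(fields=fields, time=labels)
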