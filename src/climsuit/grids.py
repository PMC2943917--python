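"""Raster data model, grid I/O, aggregation, point extraction and bioclim derivation.

The :class:`Grid` is the universal spatial carrier of the package: a 2-D array of
cell values on a regular, axis-aligned, square-celled lattice with an explicit
nodata sentinel.  Row 0 is the northernmost row.  ``origin`` is the map
coordinate of the *outer* corner of the top-left cell (i.e. the north-west
corner of the raster), so the centre of cell ``(r, c)`` sits at
``(x0 + (c + 0.5) * cell_size, y0 - (r + 0.5) * cell_size)``.

Two grids are *aligned* iff origin, cell size and shape match exactly; every
multi-layer operation in the package requires alignment.

Supported file formats are single-band GeoTIFF (via :mod:`tifffile`, using the
standard ModelPixelScale / ModelTiepoint / GDAL_NODATA tags) and the ESRI
ASCII grid (``.asc``) plain-text format.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical order of the ten bioclimatic predictors used throughout the package.
BIOCLIM_NAMES: tuple[str, ...] = (
    "MTEMP",   # annual mean temperature (degC)
    "TEMPR",   # mean monthly (diurnal) temperature range (degC)
    "ISO",     # isothermality: TEMPR / annual temperature range (ratio in (0, 1])
    "TEMPS",   # temperature seasonality: SD of monthly mean temperature (degC)
    "MTWM",    # max temperature of the warmest month (degC)
    "MTCM",    # min temperature of the coldest month (degC)
    "PREC",    # annual precipitation (mm)
    "PRECS",   # precipitation seasonality: CV of monthly precipitation (percent)
    "PWQ",     # precipitation of the wettest quarter (mm)
    "PDQ",     # precipitation of the driest quarter (mm)
)

DEFAULT_NODATA = -9999.0


class GridFormatError(ValueError):
    """Raised when a raster file cannot be parsed as the named format."""


@dataclass
class Grid:
    """A georeferenced 2-D raster layer.

    Parameters
    ----------
    values : ndarray
        2-D array of cell values (float).  ``nodata`` cells carry the sentinel.
    origin : tuple of float
        ``(x, y)`` of the outer (north-west) corner of the top-left cell.
    cell_size : float
        Positive cell edge length in map units (cells are square).
    nodata : float
        Sentinel marking missing cells; excluded from every statistic and
        every sampling pool.
    crs_label : str
        Free-text tag describing the coordinate reference system.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = DEFAULT_NODATA
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("Grid values must be a 2-D array with at least one cell")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        self.cell_size = float(self.cell_size)

    # -- basic geometry -------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data (not nodata, not NaN)."""
        if math.isnan(self.nodata):
            return ~np.isnan(self.values)
        return (self.values != self.nodata) & ~np.isnan(self.values)

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.origin == other.origin
            and self.cell_size == other.cell_size
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def contains(self, x: float, y: float) -> bool:
        """Half-open extent membership: x in [x_min, x_max), y in (y_min, y_max]."""
        x0, y0 = self.origin
        return (x0 <= x < x0 + self.ncols * self.cell_size) and (
            y0 - self.nrows * self.cell_size < y <= y0
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Return ``(row, col)`` of the cell containing a point.

        Membership is half-open: a point belongs to cell ``(r, c)`` iff
        ``x in [x_left, x_right)`` and ``y in (y_bottom, y_top]``, so points on
        shared edges resolve unambiguously to one cell.
        """
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        t = (y0 - y) / self.cell_size
        row = int(math.ceil(t)) - 1 if t > 0 else 0
        return row, col

    def with_values(self, values: np.ndarray) -> "Grid":
        """A new grid on the same geometry carrying ``values``."""
        return replace(self, values=np.asarray(values, dtype=float))

    def __eq__(self, other: object) -> bool:  # value equality, used in tests
        if not isinstance(other, Grid):
            return NotImplemented
        return (
            self.aligned_with(other)
            and (math.isnan(self.nodata) and math.isnan(other.nodata)
                 or self.nodata == other.nodata)
            and np.array_equal(self.values, other.values)
        )


def require_aligned(*grids: Grid) -> None:
    """Raise with both geotransforms printed when any pair of grids misaligns."""
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise ValueError(
                "grids are not aligned: "
                f"(origin={ref.origin}, cell_size={ref.cell_size}, shape={ref.shape})"
                f" vs (origin={g.origin}, cell_size={g.cell_size}, shape={g.shape})"
            )


# ----------------------------------------------------------------------
# File I/O
# ----------------------------------------------------------------------

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".txt"):
        return "esri_ascii"
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    raise ValueError(f"cannot infer raster format from extension {suffix!r}")


def read_grid(path: str | Path, format: str | None = None) -> Grid:
    """Read a single-band raster as a :class:`Grid`.

    ``format`` is ``"geotiff"`` or ``"esri_ascii"``; when omitted it is
    inferred from the file extension.
    """
    fmt = _infer_format(path, format)
    if fmt == "esri_ascii":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_grid(grid: Grid, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`Grid` to disk as GeoTIFF or ESRI ASCII."""
    fmt = _infer_format(path, format)
    if fmt == "esri_ascii":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _read_ascii(path: str | Path) -> Grid:
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines):
        parts = lines[pos].split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(
                    f"{path}: malformed ESRI ASCII header value for {parts[0]!r}: {parts[1]!r}"
                ) from exc
            pos += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing ESRI ASCII header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = "\n".join(lines[pos:])
    try:
        values = np.array(body.split(), dtype=float) if body.strip() else np.array([])
    except ValueError as exc:
        raise GridFormatError(f"{path}: unparseable ESRI ASCII data block") from exc
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: ESRI ASCII data block has {values.size} values, "
            f"expected nrows*ncols = {nrows * ncols}"
        )
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return Grid(values.reshape(nrows, ncols), origin, cell, nodata=nodata)


def _write_ascii(grid: Grid, path: str | Path) -> None:
    x0, y0 = grid.origin
    yll = y0 - grid.nrows * grid.cell_size
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {x0:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.10g}" for v in row))
            fh.write("\n")


_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(grid: Grid, path: str | Path) -> None:
    import tifffile

    x0, y0 = grid.origin
    cs = grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, f"{grid.nodata:.10g}"),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float64), extratags=extratags)


def _read_geotiff(path: str | Path) -> Grid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            scale = (tags[_TAG_MODEL_PIXEL_SCALE].value
                     if _TAG_MODEL_PIXEL_SCALE in tags else None)
            tie = (tags[_TAG_MODEL_TIEPOINT].value
                   if _TAG_MODEL_TIEPOINT in tags else None)
            nodata_tag = (tags[_TAG_GDAL_NODATA].value
                          if _TAG_GDAL_NODATA in tags else None)
    except Exception as exc:
        raise GridFormatError(f"{path}: not a readable TIFF file: {exc}") from exc
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster, got shape {values.shape}")
    if scale is None or tie is None:
        raise GridFormatError(
            f"{path}: missing GeoTIFF georeferencing tags (ModelPixelScale/ModelTiepoint)"
        )
    sx, sy = scale[:2]
    i, j, _, x, y, _ = tie[:6]
    # tie point maps raster corner (i, j) to map (x, y); recover the NW corner
    origin = (x - j * sx, y + i * sy)
    nodata = DEFAULT_NODATA
    if nodata_tag is not None:
        nodata = float(str(nodata_tag).strip("\x00 "))
    if not np.isclose(sx, sy):
        raise GridFormatError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
    return Grid(values, origin, float(sx), nodata=nodata)


# ----------------------------------------------------------------------
# Aggregation
# ----------------------------------------------------------------------

def aggregate(grid: Grid, factor: int) -> Grid:
    """Block-mean aggregation to a coarser resolution.

    Each output cell is the mean of its ``factor x factor`` block of input
    cells, ignoring nodata; a block that is entirely nodata becomes nodata.
    Ragged edge blocks average whatever cells are available.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"aggregation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return grid.with_values(grid.values.copy())
    nr = math.ceil(grid.nrows / factor)
    nc = math.ceil(grid.ncols / factor)
    valid = grid.valid_mask()
    vals = np.where(valid, grid.values, 0.0)
    out = np.full((nr, nc), grid.nodata, dtype=float)
    for r in range(nr):
        for c in range(nc):
            rs, cs_ = slice(r * factor, (r + 1) * factor), slice(c * factor, (c + 1) * factor)
            n = valid[rs, cs_].sum()
            if n:
                out[r, c] = vals[rs, cs_].sum() / n
    return Grid(out, grid.origin, grid.cell_size * factor,
                nodata=grid.nodata, crs_label=grid.crs_label)


# ----------------------------------------------------------------------
# Point sets
# ----------------------------------------------------------------------

@dataclass
class PointSet:
    """A set of georeferenced points with an id per point.

    ``role`` tags whether the set is used for model training or testing, and
    ``period`` which range (modern or historical) it was drawn from.
    """

    ids: list[str]
    x: np.ndarray
    y: np.ndarray
    role: str = "train"       # train | test
    period: str = "modern"    # modern | historical
    seed: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == self.x.size == self.y.size):
            raise ValueError("ids, x and y must have equal length")

    def __len__(self) -> int:
        return len(self.ids)


def write_points(points: PointSet, path: str | Path) -> None:
    pd.DataFrame({"id": points.ids, "x": points.x, "y": points.y}).to_csv(path, index=False)


def read_points(path: str | Path, role: str = "train", period: str = "modern") -> PointSet:
    df = pd.read_csv(path)
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: point file must have columns id,x,y (missing {col!r})")
    return PointSet(ids=[str(i) for i in df["id"]], x=df["x"].to_numpy(),
                    y=df["y"].to_numpy(), role=role, period=period)


# ----------------------------------------------------------------------
# Multi-layer containers
# ----------------------------------------------------------------------

@dataclass
class MonthlyClimate:
    """Twelve aligned monthly grids each of tmin, tmax (degC) and prec (mm/month)."""

    tmin: list[Grid]
    tmax: list[Grid]
    prec: list[Grid]

    def __post_init__(self) -> None:
        if not (len(self.tmin) == len(self.tmax) == len(self.prec) == 12):
            raise ValueError("MonthlyClimate requires 12 grids per variable")
        require_aligned(*self.tmin, *self.tmax, *self.prec)
        valid = self.valid_mask()
        for lo, hi in zip(self.tmin, self.tmax):
            bad = valid & (hi.values < lo.values)
            if bad.any():
                raise ValueError("tmax < tmin at some cells")
        for p in self.prec:
            if (valid & (p.values < 0)).any():
                raise ValueError("negative precipitation at some cells")

    @property
    def grid(self) -> Grid:
        return self.tmin[0]

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.grid.shape, dtype=bool)
        for g in (*self.tmin, *self.tmax, *self.prec):
            m &= g.valid_mask()
        return m


@dataclass
class BioclimStack:
    """The ten named bioclimatic predictor layers on a shared grid geometry."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        if set(self.layers) != set(BIOCLIM_NAMES):
            raise ValueError(
                f"BioclimStack requires exactly the layers {BIOCLIM_NAMES}, "
                f"got {sorted(self.layers)}"
            )
        require_aligned(*self.layers.values())

    @property
    def grid(self) -> Grid:
        return self.layers[BIOCLIM_NAMES[0]]

    @property
    def names(self) -> tuple[str, ...]:
        return BIOCLIM_NAMES

    def valid_mask(self) -> np.ndarray:
        m = np.ones(self.grid.shape, dtype=bool)
        for g in self.layers.values():
            m &= g.valid_mask()
        return m

    def array(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stacked (n_layers, nrows, ncols) array in canonical layer order."""
        names = tuple(names) if names is not None else BIOCLIM_NAMES
        return np.stack([self.layers[n].values for n in names])


def extract(stack: BioclimStack, points: PointSet) -> pd.DataFrame:
    """Extract the ten predictor values at each point's cell.

    Returns a DataFrame with columns ``id``, the ten layer names, and a
    boolean ``valid`` flag.  A point whose cell has nodata in any layer is
    flagged invalid (and the count logged); callers exclude invalid rows.
    A point outside the grid extent raises, naming the point id.
    """
    g = stack.grid
    rows = np.empty(len(points), dtype=int)
    cols = np.empty(len(points), dtype=int)
    for i, (pid, x, y) in enumerate(zip(points.ids, points.x, points.y)):
        if not g.contains(x, y):
            raise ValueError(f"point {pid!r} at ({x}, {y}) falls outside the grid extent")
        rows[i], cols[i] = g.cell_of(x, y)
    data = {"id": list(points.ids)}
    valid = np.ones(len(points), dtype=bool)
    for name in BIOCLIM_NAMES:
        layer = stack.layers[name]
        vals = layer.values[rows, cols]
        valid &= layer.valid_mask()[rows, cols]
        data[name] = vals
    df = pd.DataFrame(data)
    df["valid"] = valid
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("extract: %d of %d points fall on nodata cells and are flagged invalid",
                       n_bad, len(points))
    return df


# ----------------------------------------------------------------------
# Bioclim derivation
# ----------------------------------------------------------------------

def derive_bioclim(monthly: MonthlyClimate) -> BioclimStack:
    """Derive the ten bioclimatic predictors from monthly climate.

    Per cell, with monthly mean temperature ``m_i = (tmax_i + tmin_i) / 2``:

    - MTEMP: mean of ``m_i`` over the 12 months
    - TEMPR: mean of ``tmax_i - tmin_i``
    - ISO:   TEMPR / (max tmax - min tmin), the 0-1 isothermality ratio
    - TEMPS: population standard deviation of ``m_i``
    - MTWM / MTCM: max monthly tmax / min monthly tmin
    - PREC:  annual precipitation sum
    - PRECS: 100 * population SD / mean of monthly precipitation (0 when the
      mean is 0)
    - PWQ / PDQ: max / min precipitation total over the twelve wrap-around
      consecutive three-month quarters (Dec-Jan-Feb included)

    ISO and TEMPS are reported on their natural scales (ratio and degC); the
    x100 integer packing used by some distributed climate products is a
    storage artifact and is not applied.  Cells with an annual temperature
    range of zero get ISO = nodata (logged).
    """
    tmin = np.stack([g.values for g in monthly.tmin])   # (12, nr, nc)
    tmax = np.stack([g.values for g in monthly.tmax])
    prec = np.stack([g.values for g in monthly.prec])
    valid = monthly.valid_mask()
    ref = monthly.grid
    nodata = ref.nodata

    m = (tmax + tmin) / 2.0
    mtemp = m.mean(axis=0)
    tempr = (tmax - tmin).mean(axis=0)
    annual_range = tmax.max(axis=0) - tmin.min(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        iso = np.where(annual_range > 0, tempr / np.where(annual_range > 0, annual_range, 1.0),
                       nodata)
    n_zero_range = int((valid & (annual_range == 0)).sum())
    if n_zero_range:
        logger.warning("derive_bioclim: %d cells have zero annual temperature range; "
                       "ISO set to nodata there", n_zero_range)
    temps = m.std(axis=0)                       # population SD over the 12 months
    mtwm = tmax.max(axis=0)
    mtcm = tmin.min(axis=0)
    ptot = prec.sum(axis=0)
    pmean = prec.mean(axis=0)
    psd = prec.std(axis=0)
    precs = np.where(pmean > 0, 100.0 * psd / np.where(pmean > 0, pmean, 1.0), 0.0)
    # wrap-around quarters: 12 windows of 3 consecutive months
    quarters = np.stack([prec[[i % 12, (i + 1) % 12, (i + 2) % 12]].sum(axis=0)
                         for i in range(12)])
    pwq = quarters.max(axis=0)
    pdq = quarters.min(axis=0)

    arrays = {"MTEMP": mtemp, "TEMPR": tempr, "ISO": iso, "TEMPS": temps,
              "MTWM": mtwm, "MTCM": mtcm, "PREC": ptot, "PRECS": precs,
              "PWQ": pwq, "PDQ": pdq}
    layers = {}
    for name, arr in arrays.items():
        out = np.where(valid, arr, nodata)
        if name == "ISO":
            out = np.where(valid & (annual_range == 0), nodata, out)
        layers[name] = ref.with_values(out)
    return BioclimStack(layers)
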