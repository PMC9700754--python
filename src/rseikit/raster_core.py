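"""Grid data model and raster I/O.

A :class:`Grid` is a single-band, north-up raster with square cells on a
projected coordinate system.  Values are held as float64 with ``NaN`` marking
missing cells internally; a finite sentinel (``nodata``) is used on disk.
GeoTIFF files are read and written through :mod:`tifffile`, carrying
georeferencing in the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint)
plus the GDAL nodata tag; the CRS label travels in the image description.

All imagery arriving from different products is brought onto one template
grid with :func:`align_to` (the analysis assumes a single shared CRS — the
source products are projected to one UTM zone upstream), and multi-date
imagery is reduced to a per-pixel temporal median with QA rejection by
:func:`temporal_median_composite`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "DEFAULT_NODATA",
    "Grid",
    "RasterStack",
    "CategoricalGrid",
    "read_raster",
    "write_raster",
    "align_to",
    "temporal_median_composite",
]

#: Finite sentinel written to disk for missing float cells.
DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes used for georeferencing round-trips.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterIOError(IOError):
    """Raised when a raster file cannot be read or written."""


class MultiBandError(RasterIOError):
    """Raised when a single-band raster is expected but the file has more."""


@dataclasses.dataclass
class Grid:
    """Single-band, north-up raster with square cells.

    Pixel (row 0, col 0) is the north-west corner; ``origin_x``/``origin_y``
    are the map coordinates of the grid's top-left corner.  A cell value
    refers to the whole cell; cell (r, c) covers the half-open box
    ``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]``.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = "EPSG:32650"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("Grid values must be a 2-D array with >=1 row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        # Normalize the on-disk sentinel to NaN internally.
        if np.isfinite(self.nodata):
            self.values = np.where(self.values == self.nodata, np.nan, self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        """1-D array of non-nodata cell values."""
        return self.values[self.valid_mask]

    def co_registered(self, other: "Grid | CategoricalGrid") -> bool:
        return (
            self.shape == other.shape
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
            and self.cell_size == other.cell_size
            and self.crs_label == other.crs_label
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of every cell centre, each shaped like values."""
        nr, nc = self.shape
        xs = self.origin_x + (np.arange(nc) + 0.5) * self.cell_size
        ys = self.origin_y - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray) -> "Grid":
        """New Grid sharing this grid's georeferencing."""
        return Grid(
            values=np.asarray(values, dtype=np.float64),
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            crs_label=self.crs_label,
            nodata=self.nodata,
        )


@dataclasses.dataclass
class CategoricalGrid:
    """Integer-coded raster (e.g. land-cover classes) with a legend."""

    codes: np.ndarray
    legend: Mapping[int, str]
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 1.0
    crs_label: str = "EPSG:32650"
    nodata: int = -1

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("CategoricalGrid codes must be integers")
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D")
        present = set(np.unique(self.codes[self.codes != self.nodata]).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"codes missing from legend: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata

    def co_registered(self, other: "Grid | CategoricalGrid") -> bool:
        return Grid.co_registered(self, other)  # type: ignore[arg-type]

    def as_grid(self) -> Grid:
        """Float view (codes, nodata -> NaN) sharing the georeferencing."""
        vals = self.codes.astype(np.float64)
        vals[self.codes == self.nodata] = np.nan
        return Grid(vals, self.origin_x, self.origin_y, self.cell_size,
                    self.crs_label, DEFAULT_NODATA)


class RasterStack:
    """Ordered list of co-registered grids with unique names."""

    def __init__(self, layers: Sequence[Grid], names: Sequence[str] | None = None):
        layers = list(layers)
        if not layers:
            raise ValueError("RasterStack requires at least one layer")
        if names is None:
            names = [f"layer_{i}" for i in range(len(layers))]
        names = list(names)
        if len(names) != len(layers):
            raise ValueError("one name per layer required")
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        ref = layers[0]
        for name, g in zip(names, layers):
            if not ref.co_registered(g):
                raise ValueError(f"layer {name!r} is not co-registered with the first layer")
        self.layers = layers
        self.names = names

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self) -> Iterator[Grid]:
        return iter(self.layers)

    def __getitem__(self, key: int | str) -> Grid:
        if isinstance(key, str):
            return self.layers[self.names.index(key)]
        return self.layers[key]

    def as_array(self) -> np.ndarray:
        """(n_layers, rows, cols) float array with NaN nodata."""
        return np.stack([g.values for g in self.layers])


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def read_raster(path: str | Path) -> Grid:
    """Read a single-band GeoTIFF into a Grid.

    Raises :class:`MultiBandError` for multi-band files and
    :class:`RasterIOError` for unreadable/non-TIFF input.  Nodata is taken
    from the GDAL nodata tag when present, else :data:`DEFAULT_NODATA`.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"no such file: {path}")
    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise RasterIOError(f"cannot read {path} as a GeoTIFF: {exc}") from exc
    with tf:
        page = tf.pages[0]
        nbands = page.samplesperpixel if page.samplesperpixel else 1
        if len(tf.pages) > 1:
            nbands = max(nbands, len(tf.pages))
        if nbands > 1:
            raise MultiBandError(
                f"{path} has {nbands} bands; expected a single-band raster"
            )
        values = page.asarray().astype(np.float64)
        tags = page.tags
        cell = 1.0
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            cell = float(sx)
            if abs(float(sy) - cell) > 1e-9 * max(cell, 1.0):
                raise RasterIOError(f"{path}: non-square cells are not supported")
        ox = oy = 0.0
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            # (i, j, k, x, y, z) ties raster point (i, j) to map (x, y).
            ox = float(tp[3]) - float(tp[0]) * cell
            oy = float(tp[4]) + float(tp[1]) * cell
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value))
        crs = "unknown"
        if 270 in tags and tags[270].value:
            crs = str(tags[270].value)
    return Grid(values, ox, oy, cell, crs, nodata)


def write_raster(grid: Grid, path: str | Path) -> None:
    """Write a Grid to a single-band GeoTIFF (round-trips via read_raster)."""
    path = Path(path)
    out = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, 12, 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, 12, 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, 2, None, repr(grid.nodata)),
    ]
    try:
        tifffile.imwrite(path, out, extratags=extratags, description=grid.crs_label)
    except OSError as exc:
        raise RasterIOError(f"cannot write {path}: {exc}") from exc


def write_categorical(grid: CategoricalGrid, path: str | Path) -> None:
    """Write a CategoricalGrid as an int32 single-band GeoTIFF."""
    path = Path(path)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, 12, 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, 12, 6,
         (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, 2, None, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.codes.astype(np.int32), extratags=extratags,
                     description=grid.crs_label)


def read_categorical(path: str | Path, legend: Mapping[int, str] | None = None) -> CategoricalGrid:
    """Read an integer-coded GeoTIFF; legend defaults to code -> str(code)."""
    g = read_raster(path)
    codes = np.where(np.isnan(g.values), -1, g.values).astype(np.int64)
    if legend is None:
        legend = {int(c): str(int(c)) for c in np.unique(codes[codes != -1])}
    return CategoricalGrid(codes, legend, g.origin_x, g.origin_y,
                           g.cell_size, g.crs_label, nodata=-1)


# ---------------------------------------------------------------------------
# Resampling and compositing
# ---------------------------------------------------------------------------

def align_to(grid: Grid, template: Grid, method: str = "nearest") -> Grid:
    """Resample ``grid`` onto ``template``'s geometry.

    ``nearest`` takes the source cell containing each target cell centre;
    ``mean-aggregate`` averages all source cells whose centres fall inside
    each target cell, ignoring nodata.  Both grids must share a CRS;
    reprojection is out of scope.
    """
    if grid.crs_label != template.crs_label:
        raise ValueError(
            f"CRS mismatch: {grid.crs_label!r} vs {template.crs_label!r}"
        )
    if grid.co_registered(template):
        return template.with_values(grid.values.copy())

    nr, nc = template.shape
    if method == "nearest":
        tx, ty = template.cell_centers()
        col = np.floor((tx - grid.origin_x) / grid.cell_size).astype(np.int64)
        row = np.floor((grid.origin_y - ty) / grid.cell_size).astype(np.int64)
        inside = (row >= 0) & (row < grid.shape[0]) & (col >= 0) & (col < grid.shape[1])
        if not inside.any():
            raise ValueError("empty overlap between grid and template")
        out = np.full((nr, nc), np.nan)
        out[inside] = grid.values[row[inside], col[inside]]
        return template.with_values(out)
    if method == "mean-aggregate":
        sx, sy = grid.cell_centers()
        tcol = np.floor((sx - template.origin_x) / template.cell_size).astype(np.int64)
        trow = np.floor((template.origin_y - sy) / template.cell_size).astype(np.int64)
        inside = (trow >= 0) & (trow < nr) & (tcol >= 0) & (tcol < nc)
        valid = inside & grid.valid_mask
        if not inside.any():
            raise ValueError("empty overlap between grid and template")
        flat = trow[valid] * nc + tcol[valid]
        sums = np.bincount(flat, weights=grid.values[valid], minlength=nr * nc)
        counts = np.bincount(flat, minlength=nr * nc)
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return template.with_values(out.reshape(nr, nc))
    raise ValueError(f"unknown resampling method: {method!r}")


def temporal_median_composite(stack: RasterStack,
                              qa_masks: RasterStack | None = None) -> Grid:
    """Per-pixel median across dates, after QA rejection.

    ``qa_masks`` (nonzero = reject) mirrors the quality-control band used to
    drop cloud/cloud-shadow observations before compositing.  Pixels with no
    surviving observation become nodata.  An even number of survivors yields
    the midpoint of the two central values.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    cube = stack.as_array().copy()
    if qa_masks is not None:
        if len(qa_masks) != len(stack):
            raise ValueError("qa_masks must have one mask per layer")
        for i, (layer, mask) in enumerate(zip(stack, qa_masks)):
            if not layer.co_registered(mask):
                raise ValueError(f"qa mask {i} not co-registered with its layer")
        reject = qa_masks.as_array()
        cube[np.nan_to_num(reject, nan=1.0) != 0] = np.nan
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(cube, axis=0)
    return stack.layers[0].with_values(med)
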