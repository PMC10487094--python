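"""Raster data model, text-grid I/O, resampling, areas, and map algebra.

Every spatial layer in the pipeline -- suitability surfaces, binary habitat
maps, categorical land-cover maps, continuous driver layers -- is carried by
:class:`Raster`, a plain numpy array plus a :class:`GridSpec` and a nodata
mask.  Two coordinate modes are supported:

``equal-area-synthetic``
    A flat grid whose map units are metres.  Cell areas are exact
    (``cell_size**2``), which makes synthetic-data tests deterministic.
``lonlat``
    Geographic coordinates in decimal degrees.  Cell areas use the standard
    cosine-of-latitude approximation on a spherical Earth.

Grid convention: row 0 is the northernmost row; cell ``(i, j)`` covers the
half-open box ``[x0 + j*s, x0 + (j+1)*s) x (y0 - (i+1)*s, y0 - i*s]`` where
``s`` is the cell size and ``(x0, y0)`` the top-left corner, i.e. a cell owns
its top and left edges.  Two rasters are alignable iff their GridSpecs are
equal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0088

VALID_KINDS = ("continuous", "binary", "categorical")
VALID_CRS = ("equal-area-synthetic", "lonlat")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    ``x_origin``/``y_origin`` locate the *top-left corner* of cell (0, 0);
    units are metres for ``equal-area-synthetic`` grids and decimal degrees
    for ``lonlat`` grids.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_tag: str = "equal-area-synthetic"

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.crs_tag not in VALID_CRS:
            raise ValueError(f"unknown crs_tag {self.crs_tag!r}")

    # -- coordinate helpers -------------------------------------------------
    def cell_center(self, row: int | np.ndarray, col: int | np.ndarray):
        """Map coordinates (x, y) of the center of cell (row, col)."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def cell_index(self, x, y):
        """(row, col) of the cell containing point (x, y).

        The half-open convention means a point exactly on a cell's top or
        left edge belongs to that cell.
        """
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_center_latitudes(self) -> np.ndarray:
        """Latitude (y coordinate) of each row's cell centers, north to south."""
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_area_km2(self) -> np.ndarray:
        """Per-row cell area in km2, shape (n_rows,)."""
        if self.crs_tag == "equal-area-synthetic":
            a = (self.cell_size / 1000.0) ** 2
            return np.full(self.n_rows, a)
        # lonlat: spherical cos(lat) weighting at cell-center latitude
        lat = np.deg2rad(self.row_center_latitudes())
        deg_km = np.deg2rad(1.0) * EARTH_RADIUS_KM
        return (self.cell_size * deg_km) ** 2 * np.cos(lat)


@dataclass
class Raster:
    """A single-band raster: values + nodata mask + grid geometry."""

    grid: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata_mask shape mismatch")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind in ("binary", "categorical"):
            self.values = self.values.astype(np.int64)
        else:
            self.values = self.values.astype(np.float64)
        self._validate_values()

    def _validate_values(self) -> None:
        ok = ~self.nodata_mask
        if self.kind == "binary":
            v = self.values[ok]
            if v.size and not np.isin(v, (0, 1)).all():
                raise ValueError("binary raster contains values outside {0, 1}")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.nodata_mask.copy(), self.kind)

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Raster":
        return Raster(self.grid, values, self.nodata_mask.copy(), kind or self.kind)


@dataclass(frozen=True)
class LatBandProfile:
    """Suitable area per half-open latitude band [b, b + bandwidth)."""

    band_lower_edges: np.ndarray
    band_area: np.ndarray
    bandwidth: float

    @property
    def peak_band(self) -> float:
        """Lower edge of the band with maximum area; ties -> southernmost."""
        return float(self.band_lower_edges[int(np.argmax(self.band_area))])

    @property
    def total_area(self) -> float:
        return float(self.band_area.sum())


# ---------------------------------------------------------------------------
# I/O: plain-text grid format (JSON header line + whitespace-separated rows)
# ---------------------------------------------------------------------------

_MAGIC = "#hiersdm-grid"
_NODATA_TOKEN = "NA"


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as a text grid: one JSON header line, then the rows.

    Float values are written with 17 significant digits so that the
    write/read round trip is bit-exact; integer kinds are written as
    integers.  Nodata cells are written as ``NA``.
    """
    path = Path(path)
    g = raster.grid
    header = {
        "n_rows": g.n_rows,
        "n_cols": g.n_cols,
        "x_origin": g.x_origin,
        "y_origin": g.y_origin,
        "cell_size": g.cell_size,
        "crs_tag": g.crs_tag,
        "kind": raster.kind,
        "n_bands": 1,
    }
    fmt = "%d" if raster.kind in ("binary", "categorical") else "%.17g"
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC} {json.dumps(header)}\n")
        for i in range(g.n_rows):
            toks = [
                _NODATA_TOKEN if raster.nodata_mask[i, j] else fmt % raster.values[i, j]
                for j in range(g.n_cols)
            ]
            fh.write(" ".join(toks) + "\n")
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a text-grid raster written by :func:`write_raster`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_MAGIC):
            raise ValueError(f"{path}: not a hiersdm text grid (bad magic)")
        header = json.loads(first[len(_MAGIC):])
        if header.get("n_bands", 1) != 1:
            raise ValueError(
                f"{path}: expected single-band raster, got {header['n_bands']} bands"
            )
        grid = GridSpec(
            n_rows=header["n_rows"],
            n_cols=header["n_cols"],
            x_origin=header["x_origin"],
            y_origin=header["y_origin"],
            cell_size=header["cell_size"],
            crs_tag=header["crs_tag"],
        )
        kind = header["kind"]
        dtype = np.int64 if kind in ("binary", "categorical") else np.float64
        values = np.zeros(grid.shape, dtype=dtype)
        mask = np.zeros(grid.shape, dtype=bool)
        for i in range(grid.n_rows):
            toks = fh.readline().split()
            if len(toks) != grid.n_cols:
                raise ValueError(f"{path}: row {i} has {len(toks)} values, "
                                 f"expected {grid.n_cols}")
            for j, tok in enumerate(toks):
                if tok == _NODATA_TOKEN:
                    mask[i, j] = True
                else:
                    values[i, j] = dtype(float(tok) if dtype is np.float64 else int(tok))
    return Raster(grid, values, mask, kind)


# ---------------------------------------------------------------------------
# Resampling and map algebra
# ---------------------------------------------------------------------------

def resample_nearest(raster: Raster, target: GridSpec) -> Raster:
    """Nearest-neighbour resampling: each target cell takes the value of the
    source cell containing the target cell's center.

    Raises if the extents are disjoint (no target center falls inside the
    source grid).  Target cells whose centers fall outside the source extent
    become nodata.
    """
    if target == raster.grid:
        return raster.copy()
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    cx, cy = np.meshgrid(
        target.x_origin + (cols + 0.5) * target.cell_size,
        target.y_origin - (rows + 0.5) * target.cell_size,
    )
    src_row, src_col = raster.grid.cell_index(cx, cy)
    inside = (
        (src_row >= 0)
        & (src_row < raster.grid.n_rows)
        & (src_col >= 0)
        & (src_col < raster.grid.n_cols)
    )
    if not inside.any():
        raise ValueError("source and target extents are disjoint")
    values = np.zeros(target.shape, dtype=raster.values.dtype)
    mask = np.ones(target.shape, dtype=bool)
    sr = src_row[inside]
    sc = src_col[inside]
    values[inside] = raster.values[sr, sc]
    mask[inside] = raster.nodata_mask[sr, sc]
    return Raster(target, values, mask, raster.kind)


def _require_binary(raster: Raster, op: str) -> None:
    if raster.kind != "binary":
        raise ValueError(f"{op} requires a binary raster, got kind={raster.kind!r}")


def area_km2(binary: Raster) -> float:
    """Total area of 1-cells in km2.

    Equal-area grids count cells times the exact cell area; lonlat grids
    weight each cell by cos(latitude of its row center).
    """
    _require_binary(binary, "area_km2")
    row_area = binary.grid.cell_area_km2()
    ones = (binary.values == 1) & binary.valid
    return float((ones.sum(axis=1) * row_area).sum())


def overlay_and(a: Raster, b: Raster) -> Raster:
    """Cellwise logical AND of two binary rasters on the same grid."""
    _require_binary(a, "overlay_and")
    _require_binary(b, "overlay_and")
    if a.grid != b.grid:
        raise ValueError("overlay_and requires identical GridSpecs")
    mask = a.nodata_mask | b.nodata_mask
    values = ((a.values == 1) & (b.values == 1)).astype(np.int64)
    values[mask] = 0
    return Raster(a.grid, values, mask, "binary")


def latitudinal_profile(binary: Raster, bandwidth: float) -> LatBandProfile:
    """Suitable area per half-open latitude band of the given width.

    Band edges are aligned to integer multiples of ``bandwidth`` so that
    profiles from different maps share a common banding.
    """
    _require_binary(binary, "latitudinal_profile")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if binary.grid.crs_tag != "lonlat":
        raise ValueError(
            "latitudinal_profile requires a lonlat grid (latitude metadata)"
        )
    lat = binary.grid.row_center_latitudes()
    row_area = binary.grid.cell_area_km2()
    ones_per_row = ((binary.values == 1) & binary.valid).sum(axis=1)
    row_band = np.floor(lat / bandwidth).astype(int)
    lo, hi = row_band.min(), row_band.max()
    edges = np.arange(lo, hi + 1) * bandwidth
    areas = np.zeros(edges.size)
    np.add.at(areas, row_band - lo, ones_per_row * row_area)
    return LatBandProfile(band_lower_edges=edges, band_area=areas, bandwidth=bandwidth)
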