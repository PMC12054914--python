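"""Shared raster geometry and text-raster I/O.

All layers in a run live on a single :class:`GridSpec` — a north-up,
axis-aligned grid in projected meters.  Rasters are plain 2-D float or int
``numpy`` arrays indexed ``[row, col]`` with row 0 at the northern edge;
missing cells carry the grid's nodata sentinel (NaN is accepted on input and
normalised to the sentinel on write).

On disk a raster is an ESRI ASCII grid (``.asc``): a six-line header
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value``) followed by one
whitespace-separated row of values per grid row, north first.  Values are
written with ``%.17g`` so a write→read round trip is bit-identical for
float64.  The CRS identifier and a units tag travel in a ``.meta.json``
sidecar next to the ``.asc`` file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "GridAlignmentError",
    "read_raster",
    "write_raster",
    "align_resample",
]

DEFAULT_NODATA = -9999.0


class GridAlignmentError(ValueError):
    """Two layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry contract every raster layer in a run must share.

    Parameters
    ----------
    nrows, ncols
        Grid shape; row 0 is the northern edge.
    cellsize
        Square cell edge length in projected meters.
    origin_x, origin_y
        Projected coordinates of the lower-left corner of the grid
        (the ``xllcorner``/``yllcorner`` convention).
    crs
        Free-text identifier of the projected CRS (e.g. ``"EPSG:32649"``).
    nodata
        Sentinel value marking missing cells.
    """

    nrows: int
    ncols: int
    cellsize: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs: str = "local-meters"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid shape must be >= 1x1, got {self.nrows}x{self.ncols}")
        if not self.cellsize > 0:
            raise ValueError(f"cellsize must be positive, got {self.cellsize}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_m2(self) -> float:
        return self.cellsize * self.cellsize

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of every cell center, each (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.origin_x + (cols + 0.5) * self.cellsize
        # row 0 is the northern (top) row
        y = self.origin_y + (self.nrows - rows - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def same_geometry(self, other: "GridSpec") -> bool:
        """Geometric equality, ignoring the CRS label and nodata sentinel."""
        return (
            self.nrows == other.nrows
            and self.ncols == other.ncols
            and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12)
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-6)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-6)
        )

    def require_same(self, other: "GridSpec", context: str = "layers") -> None:
        if not self.same_geometry(other):
            raise GridAlignmentError(f"{context}: grid mismatch between {self} and {other}")


def mask_nodata(values: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Boolean mask of missing cells (nodata sentinel or NaN)."""
    arr = np.asarray(values, dtype=float)
    return np.isnan(arr) | (arr == grid.nodata)


def write_raster(values: np.ndarray, grid: GridSpec, path: str | Path, units: str = "") -> Path:
    """Write one raster layer as an ESRI ASCII grid with a JSON metadata sidecar."""
    path = Path(path)
    arr = np.asarray(values, dtype=float)
    if arr.shape != grid.shape:
        raise GridAlignmentError(f"array shape {arr.shape} does not match grid {grid.shape}")
    out = arr.copy()
    out[np.isnan(out)] = grid.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.17g}\n")
        fh.write(f"yllcorner {grid.origin_y:.17g}\n")
        fh.write(f"cellsize {grid.cellsize:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps({"crs": grid.crs, "units": units}) + "\n")
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns ``(values, GridSpec)``.

    Nodata cells are returned carrying the sentinel value (not NaN) so that a
    write→read round trip is exact.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    crs, units = "local-meters", ""
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        crs = meta.get("crs", crs)
        units = meta.get("units", units)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        cellsize=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        crs=crs,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
    if values.shape != grid.shape:
        raise GridAlignmentError(f"{path}: data shape {values.shape} != header {grid.shape}")
    return values, grid


def read_aligned(paths: list[str | Path]) -> tuple[list[np.ndarray], GridSpec]:
    """Read several layers that must share one grid; raises on any mismatch."""
    if not paths:
        raise ValueError("no raster paths given")
    layers = []
    first: GridSpec | None = None
    for p in paths:
        arr, g = read_raster(p)
        if first is None:
            first = g
        else:
            first.require_same(g, context=str(p))
        layers.append(arr)
    assert first is not None
    return layers, first


def align_resample(
    values: np.ndarray,
    src: GridSpec,
    dst: GridSpec,
    method: str = "nearest",
    categorical: bool = False,
) -> np.ndarray:
    """Resample a layer from ``src`` geometry onto ``dst`` geometry.

    ``method`` is ``"nearest"`` or ``"bilinear"``; categorical layers must use
    nearest so no class codes are invented.  Cells of ``dst`` falling outside
    the ``src`` extent, and cells interpolating from nodata, come back as
    ``dst.nodata``.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if categorical and method != "nearest":
        raise ValueError("categorical layers must be resampled with method='nearest'")
    arr = np.asarray(values, dtype=float)
    if arr.shape != src.shape:
        raise GridAlignmentError(f"array shape {arr.shape} does not match src grid {src.shape}")

    xs, ys = dst.cell_centers()
    # fractional (row, col) indices into the source grid
    fcol = (xs - src.origin_x) / src.cellsize - 0.5
    frow = (src.origin_y + src.nrows * src.cellsize - ys) / src.cellsize - 0.5
    inside = (
        (fcol >= -0.5) & (fcol <= src.ncols - 0.5) & (frow >= -0.5) & (frow <= src.nrows - 0.5)
    )

    bad = mask_nodata(arr, src)
    if method == "nearest":
        r = np.clip(np.rint(frow).astype(int), 0, src.nrows - 1)
        c = np.clip(np.rint(fcol).astype(int), 0, src.ncols - 1)
        out = arr[r, c]
        missing = bad[r, c] | ~inside
    else:
        work = arr.copy()
        work[bad] = np.nan
        out = ndimage.map_coordinates(
            work, [frow, fcol], order=1, mode="nearest", cval=np.nan
        )
        missing = np.isnan(out) | ~inside
    out = out.astype(float)
    out[missing] = dst.nodata
    return out


def with_nodata(grid: GridSpec, nodata: float) -> GridSpec:
    return replace(grid, nodata=nodata)
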