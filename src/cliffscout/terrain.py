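"""Raster terrain model: ESRI ASCII Grid I/O, cell geometry, and slope.

Grid convention is GIS-like: row 0 is the northernmost row and column 0 the
westernmost; ``origin_x``/``origin_y`` give the outer corner of the
*lower-left* cell, matching the ``xllcorner``/``yllcorner`` keys of the ESRI
ASCII format.  All coordinates are planar metres in a projected, UTM-like
system — no geodesy is attempted, which is adequate at the 10x10-km survey
square scale this package targets.

Slope is expressed throughout as a dimensionless gradient (rise/run), the
unit in which occupied-cliff slope thresholds in the 0.3-0.7 range are
meaningful; it is computed with Horn's 3x3 weighted finite differences, the
de facto GIS default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ExtentError, GridFormatError, InvalidInputError

__all__ = [
    "GridPoint",
    "RasterGrid",
    "ElevationGrid",
    "SlopeGrid",
    "read_esri_ascii",
    "write_esri_ascii",
    "slope",
]


@dataclass(frozen=True)
class GridPoint:
    """A location in projected planar coordinates (metres)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise InvalidInputError(f"non-finite coordinates ({self.x}, {self.y})")


@dataclass
class RasterGrid:
    """A regular raster with square cells and a lower-left origin.

    ``values`` is a 2-D array indexed ``[row, col]`` with row 0 north.
    Cells equal to ``nodata`` (when not None) are treated as missing.
    """

    values: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float | None = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise InvalidInputError("grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise InvalidInputError(f"cell_size must be > 0, got {self.cell_size}")
        if np.issubdtype(self.values.dtype, np.floating):
            bad = ~np.isfinite(self.values)
            if self.nodata is not None:
                bad &= self.values != self.nodata
            if bad.any():
                raise InvalidInputError(
                    "grid contains non-finite values that are not the nodata sentinel"
                )

    # -- geometry -----------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def y_top(self) -> float:
        return self.origin_y + self.n_rows * self.cell_size

    @property
    def x_right(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) cells."""
        if self.nodata is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.values != self.nodata

    def cell_center(self, row: int, col: int) -> GridPoint:
        """Centre coordinates of cell ``(row, col)``."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ExtentError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.y_top - (row + 0.5) * self.cell_size
        return GridPoint(x, y)

    def point_to_cell(self, p: GridPoint) -> tuple[int, int]:
        """Containing cell of ``p``; half-open ownership.

        A point on an interior shared edge belongs to the cell with the
        larger row/col index, so every point maps to exactly one cell.
        """
        col = int(np.floor((p.x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.y_top - p.y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ExtentError(f"point ({p.x}, {p.y}) outside grid extent")
        return row, col

    def contains(self, p: GridPoint) -> bool:
        try:
            self.point_to_cell(p)
        except ExtentError:
            return False
        return True

    def value_at(self, p: GridPoint) -> float:
        r, c = self.point_to_cell(p)
        return self.values[r, c]

    def like(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """A new grid sharing this grid's geometry."""
        return RasterGrid(
            values=values,
            cell_size=self.cell_size,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            nodata=nodata,
        )


#: Raster of ground elevations (m).
ElevationGrid = RasterGrid
#: Raster of dimensionless gradients (rise/run), >= 0 where valid.
SlopeGrid = RasterGrid


# -- ESRI ASCII Grid I/O ----------------------------------------------------

_REQUIRED_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_esri_ascii(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII Grid file.

    Accepts the standard header (``ncols nrows xllcorner yllcorner cellsize
    [NODATA_value]``); ``xllcenter``/``yllcenter`` variants are converted to
    corner registration.  Raises :class:`GridFormatError` naming the
    offending header key or data row on malformed input.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and not _is_number(parts[0]):
            key = parts[0].lower()
            if key not in (*_REQUIRED_KEYS, "xllcenter", "yllcenter", "nodata_value"):
                raise GridFormatError(f"unknown header key {parts[0]!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"non-numeric value for header key {parts[0]!r}") from exc
        else:
            break
    cellsize = header.get("cellsize")
    if "xllcenter" in header and cellsize is not None:
        header["xllcorner"] = header.pop("xllcenter") - cellsize / 2
    if "yllcenter" in header and cellsize is not None:
        header["yllcorner"] = header.pop("yllcenter") - cellsize / 2
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise GridFormatError(f"missing header key {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    if ncols < 1 or nrows < 1:
        raise GridFormatError("ncols and nrows must be >= 1")
    nodata = header.get("nodata_value")

    data_lines = [ln for ln in lines[i:] if ln.strip()]
    if len(data_lines) != nrows:
        raise GridFormatError(f"expected {nrows} data rows, found {len(data_lines)}")
    rows = []
    for r, ln in enumerate(data_lines):
        vals = ln.split()
        if len(vals) != ncols:
            raise GridFormatError(f"row {r}: expected {ncols} values, found {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise GridFormatError(f"row {r}: non-numeric value") from exc
    return RasterGrid(
        values=np.array(rows, dtype=float),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=nodata,
    )


def write_esri_ascii(grid: RasterGrid, path: str | Path) -> None:
    """Write ``grid`` as an ESRI ASCII Grid; round-trips with the reader.

    Values are formatted with ``repr`` so floats (including the nodata
    sentinel) survive the round trip bit-faithfully.
    """
    values = grid.values
    if values.dtype == bool:
        values = values.astype(int)
    out = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {grid.origin_x!r}",
        f"yllcorner {grid.origin_y!r}",
        f"cellsize {grid.cell_size!r}",
    ]
    if grid.nodata is not None:
        out.append(f"NODATA_value {grid.nodata!r}")
    for row in values:
        out.append(" ".join(repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v)) for v in row))
    Path(path).write_text("\n".join(out) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


# -- slope ------------------------------------------------------------------

def slope(dem: ElevationGrid) -> SlopeGrid:
    """Horn 3x3 slope of a DEM, as dimensionless gradient (rise/run).

    Interior cells get the weighted finite-difference gradient magnitude

        dz/dx = ((c + 2f + i) - (a + 2d + g)) / (8 * cell_size)
        dz/dy = ((g + 2h + i) - (a + 2b + c)) / (8 * cell_size)

    over the 3x3 window ``[[a b c], [d e f], [g h i]]``.  Edge cells, and
    cells whose window touches nodata, are nodata: no values are invented at
    boundaries.  Exact for affine planes: slope(a*x + b*y + c) = hypot(a, b).
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise InvalidInputError("slope requires a grid of at least 3x3 cells")
    z = dem.values.astype(float)
    valid = dem.mask
    cs = dem.cell_size

    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; f = z[1:-1, 2:]
    g = z[2:, :-2]; h = z[2:, 1:-1]; i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    grad = np.hypot(dzdx, dzdy)

    win_valid = np.ones(grad.shape, dtype=bool)
    for dr in (0, 1, 2):
        for dc in (0, 1, 2):
            win_valid &= valid[dr:dr + grad.shape[0], dc:dc + grad.shape[1]]

    out_nodata = dem.nodata if dem.nodata is not None else -9999.0
    out = np.full(z.shape, out_nodata, dtype=float)
    interior = out[1:-1, 1:-1]
    interior[win_valid] = grad[win_valid]
    out[1:-1, 1:-1] = interior
    return dem.like(out, nodata=out_nodata)
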