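"""Gridded raster data model, ESRI ASCII I/O, alignment, and terrain derivatives.

The grid convention used throughout the package: square cells, 0-based
(row, col) indexing with row 0 at the north (top) edge, coordinates anchored
at the lower-left corner.  A single sentinel value per layer marks nodata
cells; nodata is excluded from every aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import DomainError, RasterFormatError

__all__ = [
    "GridSpec",
    "RasterLayer",
    "read_ascii_grid",
    "write_ascii_grid",
    "align",
    "slope_percent",
]

#: offsets of the 8 neighbours, clockwise from East; row axis points south.
NEIGHBOR_OFFSETS = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: size, cell edge length, lower-left anchor, nodata sentinel."""

    n_rows: int
    n_cols: int
    cell_size: float
    x_ll: float = 0.0
    y_ll: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise DomainError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise DomainError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of cell (row, col); row 0 is north."""
        x = self.x_ll + (col + 0.5) * self.cell_size
        y = self.y_ll + (self.n_rows - row - 0.5) * self.cell_size
        return (x, y)

    def bounds(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) of the grid footprint."""
        return (
            self.x_ll,
            self.y_ll,
            self.x_ll + self.n_cols * self.cell_size,
            self.y_ll + self.n_rows * self.cell_size,
        )


@dataclass
class RasterLayer:
    """A georeferenced 2-D grid of one variable.

    ``values`` is an ``(n_rows, n_cols)`` float array; cells equal to
    ``spec.nodata`` are treated as missing by every aggregate.
    """

    spec: GridSpec
    values: np.ndarray
    semantics: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise DomainError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.spec.shape}"
            )

    # -- nodata handling -------------------------------------------------
    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where the cell is nodata."""
        return self.values == self.spec.nodata

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata replaced by ``fill``."""
        return np.where(self.nodata_mask, fill, self.values)

    # -- aggregates (nodata excluded) ------------------------------------
    def total(self) -> float:
        return float(self.values[self.valid_mask].sum())

    def mean(self) -> float:
        valid = self.values[self.valid_mask]
        return float(valid.mean()) if valid.size else float("nan")

    def with_values(self, values: np.ndarray, semantics: str | None = None,
                    units: str | None = None) -> "RasterLayer":
        return RasterLayer(
            self.spec,
            np.asarray(values, dtype=float),
            self.semantics if semantics is None else semantics,
            self.units if units is None else units,
        )

    def copy(self) -> "RasterLayer":
        return self.with_values(self.values.copy())


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path, semantics: str = "", units: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid (.asc).

    Header keys are case-insensitive; ``nodata_value`` is optional and
    defaults to -9999.  The body is whitespace-separated, row-major, north
    to south.  Anisotropic (dx/dy) grids are rejected: cells are square.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].isalpha() or (
            len(parts) == 2 and parts[0].replace("_", "").isalpha()
        ):
            key = parts[0].lower()
            if key in ("dx", "dy"):
                raise RasterFormatError(
                    "anisotropic cells (dx/dy headers) are not supported; "
                    "cells must be square"
                )
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"header value for {key!r} is not numeric: {parts[1]!r}"
                ) from exc
            body_start = i + 1
        else:
            break
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise RasterFormatError(f"missing required header key {key!r}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        x_ll=header["xllcorner"],
        y_ll=header["yllcorner"],
        nodata=nodata,
    )
    flat = np.array(" ".join(lines[body_start:]).split(), dtype=float)
    if flat.size != n_rows * n_cols:
        raise RasterFormatError(
            f"body has {flat.size} cells, expected {n_rows * n_cols}"
        )
    return RasterLayer(spec, flat.reshape(n_rows, n_cols), semantics, units)


def _fmt(v: float) -> str:
    """Shortest decimal representation that round-trips through float()."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_ascii_grid(layer: RasterLayer, path: str | Path) -> None:
    """Write an ESRI ASCII grid; inverse of :func:`read_ascii_grid`."""
    spec = layer.spec
    lines = [
        f"ncols {spec.n_cols}",
        f"nrows {spec.n_rows}",
        f"xllcorner {_fmt(spec.x_ll)}",
        f"yllcorner {_fmt(spec.y_ll)}",
        f"cellsize {_fmt(spec.cell_size)}",
        f"NODATA_value {_fmt(spec.nodata)}",
    ]
    for row in layer.values:
        lines.append(" ".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _overlaps(a: GridSpec, b: GridSpec) -> bool:
    ax0, ay0, ax1, ay1 = a.bounds()
    bx0, by0, bx1, by1 = b.bounds()
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def align(layers: list[RasterLayer], target: GridSpec,
          method: str = "nearest") -> list[RasterLayer]:
    """Resample layers onto ``target``.

    ``nearest`` assigns the value of the source cell containing each target
    cell center; ``mean-aggregate`` averages the non-nodata source cells
    whose centers fall inside each target cell.  Layers already on the
    target geometry are returned unchanged.
    """
    if method not in ("nearest", "mean-aggregate"):
        raise DomainError(f"unknown alignment method {method!r}")
    out = []
    for layer in layers:
        src = layer.spec
        if (src.n_rows, src.n_cols, src.cell_size, src.x_ll, src.y_ll) == (
            target.n_rows, target.n_cols, target.cell_size, target.x_ll, target.y_ll
        ):
            out.append(layer)
            continue
        if not _overlaps(src, target):
            raise DomainError("layer does not spatially overlap the target grid")
        if method == "nearest":
            out.append(_align_nearest(layer, target))
        else:
            out.append(_align_mean(layer, target))
    return out


def _align_nearest(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    src = layer.spec
    rows = np.arange(target.n_rows)
    cols = np.arange(target.n_cols)
    # target cell centers in map coordinates
    xc = target.x_ll + (cols + 0.5) * target.cell_size
    yc = target.y_ll + (target.n_rows - rows - 0.5) * target.cell_size
    # source indices containing those centers
    sj = np.floor((xc - src.x_ll) / src.cell_size).astype(int)
    si = np.floor((src.y_ll + src.n_rows * src.cell_size - yc) / src.cell_size).astype(int)
    vals = np.full(target.shape, target.nodata, dtype=float)
    jj, ii = np.meshgrid(sj, si)
    inside = (ii >= 0) & (ii < src.n_rows) & (jj >= 0) & (jj < src.n_cols)
    src_vals = layer.values
    picked = np.where(inside, src_vals[np.clip(ii, 0, src.n_rows - 1),
                                       np.clip(jj, 0, src.n_cols - 1)], target.nodata)
    picked = np.where(inside & (picked == src.nodata), target.nodata, picked)
    vals[:, :] = picked
    return RasterLayer(target, vals, layer.semantics, layer.units)


def _align_mean(layer: RasterLayer, target: GridSpec) -> RasterLayer:
    src = layer.spec
    si = np.arange(src.n_rows)
    sj = np.arange(src.n_cols)
    xc = src.x_ll + (sj + 0.5) * src.cell_size
    yc = src.y_ll + (src.n_rows - si - 0.5) * src.cell_size
    tj = np.floor((xc - target.x_ll) / target.cell_size).astype(int)
    ti = np.floor((target.y_ll + target.n_rows * target.cell_size - yc)
                  / target.cell_size).astype(int)
    sums = np.zeros(target.shape)
    counts = np.zeros(target.shape)
    jj, ii = np.meshgrid(tj, ti)
    ok = ((ii >= 0) & (ii < target.n_rows) & (jj >= 0) & (jj < target.n_cols)
          & layer.valid_mask)
    np.add.at(sums, (ii[ok], jj[ok]), layer.values[ok])
    np.add.at(counts, (ii[ok], jj[ok]), 1.0)
    vals = np.full(target.shape, target.nodata, dtype=float)
    covered = counts > 0
    vals[covered] = sums[covered] / counts[covered]
    return RasterLayer(target, vals, layer.semantics, layer.units)


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------

def slope_percent(dem: RasterLayer) -> RasterLayer:
    """Per-cell slope as 100 x rise/run of the steepest 8-neighbour descent.

    Pits and flats (no lower neighbour) get slope 0.  Diagonal neighbour
    distance is cell_size * sqrt(2).  Invariant under adding a constant to
    the DEM.
    """
    z = dem.values
    spec = dem.spec
    nod = dem.nodata_mask
    best = np.zeros(spec.shape)
    for (di, dj) in NEIGHBOR_OFFSETS:
        dist = spec.cell_size * (np.sqrt(2.0) if di != 0 and dj != 0 else 1.0)
        zn = np.full(spec.shape, np.nan)
        i0, i1 = max(di, 0), spec.n_rows + min(di, 0)
        j0, j1 = max(dj, 0), spec.n_cols + min(dj, 0)
        zn[i0 - di:i1 - di, j0 - dj:j1 - dj] = z[i0:i1, j0:j1]
        zn[i0 - di:i1 - di, j0 - dj:j1 - dj][nod[i0:i1, j0:j1]] = np.nan
        with np.errstate(invalid="ignore"):
            drop = (z - zn) / dist
        best = np.fmax(best, np.where(np.isnan(drop), 0.0, drop))
    out = 100.0 * best
    out[nod] = spec.nodata
    return RasterLayer(spec, out, semantics="slope", units="%")
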