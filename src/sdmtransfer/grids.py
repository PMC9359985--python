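"""Raster data model, I/O and covariate-engineering operators.

Grids live on a projected plane measured in km. Internally row 0 is the
*southernmost* row (y grows with the row index); ESRI ASCII and GeoTIFF
files use the conventional north-up row order and are flipped on I/O.
Point-to-cell assignment is half-open: a point at ``x`` falls in column
``floor((x - x0) / cell_size)``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage


class GridAlignmentError(ValueError):
    """Raised when an operation receives grids on different geometries."""


@dataclass
class Grid:
    """A rectangular raster of real values with a validity mask.

    Parameters
    ----------
    values
        ``(nrows, ncols)`` float array. Entries under an invalid mask cell
        are ignored (and stored as NaN).
    valid_mask
        Boolean array of the same shape; ``False`` marks nodata.
    cell_size
        Side of a square cell, km.
    origin
        ``(x0, y0)`` coordinates of the lower-left corner of the grid, km.
    """

    values: np.ndarray
    valid_mask: np.ndarray | None = None
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape must match values")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid")
        self.values = np.where(self.valid_mask, self.values, np.nan)

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def geometry(self) -> tuple[int, int, float, tuple[float, float]]:
        return (self.nrows, self.ncols, self.cell_size, self.origin)

    def same_geometry(self, other: "Grid | CategoricalGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices; out-of-grid -> -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        bad = (row < 0) | (row >= self.nrows) | (col < 0) | (col >= self.ncols)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def cell_centers(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(cols) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(rows) + 0.5) * self.cell_size
        return x, y

    def extract(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Values at point locations; NaN outside the grid or on nodata."""
        row, col = self.cell_of(x, y)
        out = np.full(row.shape, np.nan)
        inside = row >= 0
        r, c = row[inside], col[inside]
        vals = self.values[r, c]
        vals = np.where(self.valid_mask[r, c], vals, np.nan)
        out[inside] = vals
        return out

    def copy_with(self, values: np.ndarray, valid_mask: np.ndarray | None = None) -> "Grid":
        return Grid(values, valid_mask, self.cell_size, self.origin)


@dataclass
class CategoricalGrid:
    """Integer class-coded raster sharing Grid georeferencing."""

    values: np.ndarray
    valid_mask: np.ndarray | None = None
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    code_table: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("CategoricalGrid values must be integers")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape must match values")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.code_table is not None:
            codes = np.unique(self.values[self.valid_mask])
            unknown = set(codes.tolist()) - set(self.code_table)
            if unknown:
                raise ValueError(f"class codes {sorted(unknown)} not in code table")

    nrows = Grid.nrows
    ncols = Grid.ncols
    shape = Grid.shape
    geometry = Grid.geometry
    same_geometry = Grid.same_geometry
    cell_of = Grid.cell_of
    cell_centers = Grid.cell_centers

    def as_grid(self) -> Grid:
        return Grid(self.values.astype(float), self.valid_mask,
                    self.cell_size, self.origin)


class CovariateStack:
    """Ordered mapping of variable name -> Grid, all mutually aligned."""

    def __init__(self, grids: Mapping[str, Grid]):
        grids = dict(grids)
        if not grids:
            raise ValueError("empty stack")
        first = next(iter(grids.values()))
        for name, g in grids.items():
            if not first.same_geometry(g):
                raise GridAlignmentError(f"grid {name!r} not aligned with stack")
        self._grids = grids

    @property
    def names(self) -> list[str]:
        return list(self._grids)

    def __getitem__(self, name: str) -> Grid:
        return self._grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self._grids

    def __iter__(self) -> Iterator[str]:
        return iter(self._grids)

    def __len__(self) -> int:
        return len(self._grids)

    @property
    def template(self) -> Grid:
        return next(iter(self._grids.values()))

    def joint_valid_mask(self) -> np.ndarray:
        mask = np.ones(self.template.shape, dtype=bool)
        for g in self._grids.values():
            mask &= g.valid_mask
        return mask

    def subset(self, names: Sequence[str]) -> "CovariateStack":
        return CovariateStack({n: self._grids[n] for n in names})

    def extract(self, x: np.ndarray, y: np.ndarray,
                variables: Sequence[str] | None = None) -> np.ndarray:
        """(n_points, n_vars) matrix of covariate values at points."""
        names = list(variables) if variables is not None else self.names
        return np.column_stack([self._grids[n].extract(x, y) for n in names])

    def to_matrix(self, variables: Sequence[str] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (n_joint_valid_cells, n_vars) plus the flat cell index."""
        names = list(variables) if variables is not None else self.names
        mask = self.joint_valid_mask()
        idx = np.flatnonzero(mask.ravel())
        X = np.column_stack([self._grids[n].values.ravel()[idx] for n in names])
        return X, idx


@dataclass
class RegionPartition:
    """Integer region labels over the study domain (e.g. three states)."""

    labels: CategoricalGrid

    def __post_init__(self) -> None:
        if not isinstance(self.labels, CategoricalGrid):
            raise TypeError("RegionPartition wraps a CategoricalGrid")

    @property
    def region_ids(self) -> list[int]:
        vals = self.labels.values[self.labels.valid_mask]
        return sorted(np.unique(vals).tolist())

    def mask_of(self, region: int) -> np.ndarray:
        return self.labels.valid_mask & (self.labels.values == region)

    def label_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region label per point; -1 outside the grid or on nodata."""
        row, col = self.labels.cell_of(np.asarray(x), np.asarray(y))
        out = np.full(row.shape, -1, dtype=int)
        inside = row >= 0
        r, c = row[inside], col[inside]
        lab = np.where(self.labels.valid_mask[r, c], self.labels.values[r, c], -1)
        out[inside] = lab
        return out


# ---------------------------------------------------------------------------
# Covariate-engineering operators
# ---------------------------------------------------------------------------

def aggregate_proportion(fine: CategoricalGrid, target_classes: Iterable[int],
                         factor: int) -> Grid:
    """Proportion of fine cells in each factor x factor block belonging to
    ``target_classes``. Trailing partial blocks are dropped; blocks with no
    valid fine cell become nodata."""
    target_classes = set(target_classes)
    if not target_classes:
        raise ValueError("target_classes must be non-empty")
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = fine.shape
    if nr < factor or nc < factor:
        raise ValueError("fine grid smaller than aggregation factor")
    nrb, ncb = nr // factor, nc // factor
    vals = fine.values[: nrb * factor, : ncb * factor]
    mask = fine.valid_mask[: nrb * factor, : ncb * factor]
    is_target = np.isin(vals, sorted(target_classes)) & mask
    blk = lambda a: a.reshape(nrb, factor, ncb, factor).sum(axis=(1, 3))
    n_valid = blk(mask.astype(np.int64))
    n_target = blk(is_target.astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = n_target / n_valid
    return Grid(np.where(n_valid > 0, prop, np.nan), n_valid > 0,
                fine.cell_size * factor, fine.origin)


def distance_to_class(target_mask: Grid) -> Grid:
    """Euclidean distance (km, between cell centers) to the nearest target
    cell of a 0/1 mask grid. Target cells get 0; nodata propagates."""
    tgt = (target_mask.values == 1) & target_mask.valid_mask
    if not tgt.any():
        raise ValueError("no target cells: distance undefined")
    dist = ndimage.distance_transform_edt(~tgt, sampling=target_mask.cell_size)
    return Grid(dist, target_mask.valid_mask.copy(),
                target_mask.cell_size, target_mask.origin)


def correlation_matrix(stack: CovariateStack,
                       cells: np.ndarray | None = None) -> "pd.DataFrame":
    """Pearson correlation between stack variables over jointly valid cells.

    ``cells`` optionally restricts to a boolean cell mask. Zero-variance
    variables get NaN off-diagonal entries (undefined, not silently zero).
    """
    import pandas as pd

    names = stack.names
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    mask = stack.joint_valid_mask()
    if cells is not None:
        mask = mask & np.asarray(cells, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 jointly valid cells")
    X = np.column_stack([stack[n].values[mask] for n in names])
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[np.ix_(sd == 0, sd > 0)] = np.nan
    corr[np.ix_(sd > 0, sd == 0)] = np.nan
    corr[np.ix_(sd == 0, sd == 0)] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def admissible_variable_sets(variables: Sequence[str], corr,
                             r_threshold: float = 0.7) -> list[tuple[str, ...]]:
    """All non-empty subsets of ``variables`` containing no pair with
    ``|r| >= r_threshold``, in lexicographic (by input order, then size)
    enumeration order."""
    if not 0 < r_threshold <= 1:
        raise ValueError("r_threshold must be in (0, 1]")
    corr_arr = np.asarray(corr)
    idx = {v: i for i, v in enumerate(variables)}
    forbidden = {
        (a, b)
        for a, b in itertools.combinations(variables, 2)
        if abs(corr_arr[idx[a], idx[b]]) >= r_threshold
    }
    out: list[tuple[str, ...]] = []
    for r in range(1, len(variables) + 1):
        for combo in itertools.combinations(variables, r):
            if not any(pair in forbidden
                       for pair in itertools.combinations(combo, 2)):
                out.append(combo)
    return out


def map_correlation(a: Grid, b: Grid) -> float:
    """Pearson correlation of two aligned maps over jointly valid cells.

    Returns NaN (with a warning) if either map has zero variance.
    """
    if not a.same_geometry(b):
        raise GridAlignmentError("maps not aligned")
    mask = a.valid_mask & b.valid_mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 jointly valid cells")
    va, vb = a.values[mask], b.values[mask]
    if va.std() == 0 or vb.std() == 0:
        warnings.warn("map correlation undefined: zero variance", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])


# ---------------------------------------------------------------------------
# File I/O: ESRI ASCII grid and GeoTIFF
# ---------------------------------------------------------------------------

_ASCII_NODATA = -9999.0


def write_ascii_grid(grid: Grid | CategoricalGrid, path: str | Path,
                     nodata: float = _ASCII_NODATA) -> None:
    """Write an ESRI ASCII grid (north-up row order, full precision)."""
    path = Path(path)
    categorical = isinstance(grid, CategoricalGrid)
    vals = np.where(grid.valid_mask, grid.values, nodata)
    vals = np.flipud(vals)  # internal south-up -> file north-up
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {int(nodata) if categorical else nodata!r}\n"
    )
    fmt = (lambda v: "%d" % v) if categorical else (lambda v: repr(float(v)))
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(fmt(v) for v in row) + "\n")


def read_ascii_grid(path: str | Path, categorical: bool = False,
                    code_table: Mapping[int, str] | None = None
                    ) -> Grid | CategoricalGrid:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in {"ncols", "nrows", "xllcorner",
                                           "yllcorner", "cellsize",
                                           "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    vals = np.flipud(np.asarray(rows))
    nodata = header.get("nodata_value", _ASCII_NODATA)
    mask = vals != nodata
    if int(header["nrows"]) != vals.shape[0] or int(header["ncols"]) != vals.shape[1]:
        raise ValueError("ASCII grid dimensions disagree with header")
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    cell = header.get("cellsize", 1.0)
    if categorical:
        return CategoricalGrid(np.where(mask, vals, 0).astype(int), mask,
                               cell, origin, code_table)
    return Grid(np.where(mask, vals, np.nan), mask, cell, origin)


# GeoTIFF tags: ModelPixelScale (33550), ModelTiepoint (33922), GDAL nodata (42113)
_TIFF_NODATA = -9999.0


def write_geotiff(grid: Grid, path: str | Path) -> None:
    """Write a single-band float32 GeoTIFF with pixel-scale/tiepoint tags."""
    import tifffile

    vals = np.where(grid.valid_mask, grid.values, _TIFF_NODATA)
    vals = np.flipud(vals).astype(np.float32)
    x0, y0 = grid.origin
    y_top = y0 + grid.nrows * grid.cell_size
    scale = (float(grid.cell_size), float(grid.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(x0), float(y_top), 0.0)
    extratags = [
        (33550, "d", 3, scale, True),
        (33922, "d", 6, tiepoint, True),
        (42113, "s", 0, str(_TIFF_NODATA), True),
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


def read_geotiff(path: str | Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        vals = page.asarray().astype(float)
        tags = page.tags
        scale = tags[33550].value if 33550 in tags else (1.0, 1.0, 0.0)
        tiepoint = tags[33922].value if 33922 in tags else (0, 0, 0, 0.0, 0.0, 0)
        nodata = float(tags[42113].value) if 42113 in tags else _TIFF_NODATA
    cell = float(scale[0])
    x0 = float(tiepoint[3])
    y_top = float(tiepoint[4])
    nrows = vals.shape[0]
    origin = (x0, y_top - nrows * cell)
    mask = vals != nodata
    return Grid(np.flipud(np.where(mask, vals, np.nan)), np.flipud(mask),
                cell, origin)
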