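"""Occurrence handling: ingestion, spatial thinning, background sampling
and design-matrix construction with class balancing.

Presence records carry projected km coordinates and an optional integer
region label. Thinning mirrors the standard survey-data filters: at most
one (randomly retained) point per raster cell, and a greedy minimum
inter-point distance filter. Background ("pseudo-absence") points are
drawn uniformly over the valid study domain; during design construction
background rows are down-weighted so that the two classes carry equal
total weight (prevalence 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import CovariateStack, Grid, RegionPartition


@dataclass
class OccurrenceSet:
    """Point records (x, y in km) with optional region labels (-1 = none)."""

    x: np.ndarray
    y: np.ndarray
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.region is None:
            self.region = np.full(self.x.shape, -1, dtype=int)
        self.region = np.atleast_1d(np.asarray(self.region, dtype=int))
        if self.region.shape != self.x.shape:
            raise ValueError("region labels must match point count")

    def __len__(self) -> int:
        return self.x.size

    def take(self, idx: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.x[idx], self.y[idx], self.region[idx])

    def with_regions(self, partition: RegionPartition) -> "OccurrenceSet":
        return OccurrenceSet(self.x, self.y,
                             partition.label_points(self.x, self.y))

    def restrict_region(self, region: int) -> "OccurrenceSet":
        return self.take(np.flatnonzero(self.region == region))

    def to_frame(self, role: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"x": self.x, "y": self.y, "region": self.region})
        if role is not None:
            df["role"] = role
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        region = df["region"].to_numpy(int) if "region" in df else None
        return cls(df["x"].to_numpy(float), df["y"].to_numpy(float), region)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read an occurrence CSV with columns x,y[,region]."""
    return OccurrenceSet.from_frame(pd.read_csv(path))


def write_occurrences(occ: OccurrenceSet, path: str | Path,
                      role: str | None = None) -> None:
    occ.to_frame(role).to_csv(path, index=False)


@dataclass
class SampleDesign:
    """Presence/background design matrix with balancing weights.

    ``y`` is 1 for presences, 0 for background. Background weights are
    scaled so both classes carry the same total weight.
    """

    X: np.ndarray
    y: np.ndarray
    weights: np.ndarray
    variables: list[str]
    coords: np.ndarray          # (n, 2) x/y of the retained rows
    region: np.ndarray
    n_dropped: int = 0          # rows removed for missing covariates

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (self.y.size == n == self.weights.size):
            raise ValueError("inconsistent design dimensions")
        if self.X.shape[1] != len(self.variables):
            raise ValueError("variable list does not match X columns")

    @property
    def n_presence(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_background(self) -> int:
        return int((self.y == 0).sum())

    def subset_rows(self, idx: np.ndarray) -> "SampleDesign":
        return SampleDesign(self.X[idx], self.y[idx], self.weights[idx],
                            list(self.variables), self.coords[idx],
                            self.region[idx], self.n_dropped)

    def subset_variables(self, variables: Sequence[str]) -> "SampleDesign":
        cols = [self.variables.index(v) for v in variables]
        return SampleDesign(self.X[:, cols], self.y, self.weights,
                            list(variables), self.coords, self.region,
                            self.n_dropped)


# ---------------------------------------------------------------------------
# Thinning
# ---------------------------------------------------------------------------

def thin_one_per_cell(occ: OccurrenceSet, grid: Grid, seed: int
                      ) -> tuple[OccurrenceSet, int]:
    """Retain at most one (uniformly random) point per grid cell.

    Returns the thinned set and the count of points falling outside the
    grid (these are excluded).
    """
    rng = np.random.default_rng(seed)
    row, col = grid.cell_of(occ.x, occ.y)
    inside = row >= 0
    n_outside = int((~inside).sum())
    idx_inside = np.flatnonzero(inside)
    cell_id = row[idx_inside] * grid.ncols + col[idx_inside]
    # random priority per point, keep the max-priority point of each cell
    priority = rng.random(idx_inside.size)
    order = np.lexsort((priority, cell_id))
    cid_sorted = cell_id[order]
    is_last = np.r_[cid_sorted[1:] != cid_sorted[:-1], True] if order.size else \
        np.zeros(0, dtype=bool)
    keep = np.sort(idx_inside[order[is_last]])
    return occ.take(keep), n_outside


def thin_min_distance(occ: OccurrenceSet, d_min: float, seed: int
                      ) -> OccurrenceSet:
    """Greedy seeded-random-order thinning to a minimum inter-point distance.

    Points are visited in a seeded random order; a point is kept iff it is
    at least ``d_min`` from every already-kept point. The result is an
    approximate maximum independent set of the proximity graph.
    """
    if not d_min > 0:
        raise ValueError("d_min must be positive")
    n = len(occ)
    if n == 0:
        return occ
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # coarse cell index at d_min resolution limits candidate comparisons
    cx = np.floor(occ.x / d_min).astype(np.int64)
    cy = np.floor(occ.y / d_min).astype(np.int64)
    kept: list[int] = []
    buckets: dict[tuple[int, int], list[int]] = {}
    d2 = d_min * d_min
    for i in order:
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in buckets.get((cx[i] + dx, cy[i] + dy), ()):
                    if (occ.x[i] - occ.x[j]) ** 2 + (occ.y[i] - occ.y[j]) ** 2 < d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            kept.append(i)
            buckets.setdefault((cx[i], cy[i]), []).append(i)
    return occ.take(np.sort(np.asarray(kept, dtype=int)))


# ---------------------------------------------------------------------------
# Background sampling and design construction
# ---------------------------------------------------------------------------

def sample_background(domain: Grid, n: int, seed: int,
                      restrict: int | None = None,
                      regions: RegionPartition | None = None,
                      replace_cells: bool = True,
                      jitter: bool = True) -> OccurrenceSet:
    """Sample ``n`` background points uniformly over valid domain cells.

    ``restrict`` limits sampling to one region of ``regions``. By default
    cells may repeat (with-replacement semantics of "n random points");
    ``replace_cells=False`` enforces distinct cells. Each drawn cell
    yields one point at its center plus uniform sub-cell jitter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mask = domain.valid_mask.copy()
    if restrict is not None:
        if regions is None:
            raise ValueError("restrict requires a RegionPartition")
        mask &= regions.mask_of(restrict)
    cells = np.flatnonzero(mask.ravel())
    if cells.size == 0:
        raise ValueError("no valid cells to sample from")
    if not replace_cells and n > cells.size:
        raise ValueError(
            f"requested {n} distinct cells but only {cells.size} available")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(cells, size=n, replace=replace_cells)
    rows, cols = np.unravel_index(drawn, domain.shape)
    x, y = domain.cell_centers(rows, cols)
    if jitter:
        x = x + (rng.random(n) - 0.5) * domain.cell_size
        y = y + (rng.random(n) - 0.5) * domain.cell_size
    region = None
    if regions is not None:
        region = regions.label_points(x, y)
    return OccurrenceSet(x, y, region)


def build_design(presences: OccurrenceSet, background: OccurrenceSet,
                 stack: CovariateStack,
                 variables: Sequence[str] | None = None) -> SampleDesign:
    """Extract covariates and assemble a weighted presence/background design.

    Presence rows get weight 1; background rows get weight
    ``n_presence / n_background`` so class weight totals are equal. Rows
    with any missing covariate are dropped and counted.
    """
    names = list(variables) if variables is not None else stack.names
    unknown = set(names) - set(stack.names)
    if unknown:
        raise ValueError(f"variables not in stack: {sorted(unknown)}")
    Xp = stack.extract(presences.x, presences.y, names)
    Xb = stack.extract(background.x, background.y, names)
    ok_p = np.all(np.isfinite(Xp), axis=1)
    ok_b = np.all(np.isfinite(Xb), axis=1)
    n_dropped = int((~ok_p).sum() + (~ok_b).sum())
    n_p, n_b = int(ok_p.sum()), int(ok_b.sum())
    if n_p == 0 or n_b == 0:
        raise ValueError("empty class after dropping missing-covariate rows")
    X = np.vstack([Xp[ok_p], Xb[ok_b]])
    y = np.r_[np.ones(n_p), np.zeros(n_b)]
    w = np.r_[np.ones(n_p), np.full(n_b, n_p / n_b)]
    coords = np.vstack([
        np.column_stack([presences.x[ok_p], presences.y[ok_p]]),
        np.column_stack([background.x[ok_b], background.y[ok_b]]),
    ])
    region = np.r_[presences.region[ok_p], background.region[ok_b]]
    return SampleDesign(X, y, w, names, coords, region, n_dropped)


def subsample_balanced(occ_by_region: Mapping[int, OccurrenceSet],
                       seed: int) -> dict[int, OccurrenceSet]:
    """Downsample every region's occurrences (uniformly, seeded) to the
    smallest region count; the smallest region is returned unchanged."""
    if len(occ_by_region) < 2:
        raise ValueError("need at least 2 regions")
    counts = {r: len(o) for r, o in occ_by_region.items()}
    if min(counts.values()) == 0:
        raise ValueError("empty region occurrence set")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    out: dict[int, OccurrenceSet] = {}
    for r in sorted(occ_by_region):
        occ = occ_by_region[r]
        if len(occ) == n_min:
            out[r] = occ
        else:
            keep = np.sort(rng.choice(len(occ), size=n_min, replace=False))
            out[r] = occ.take(keep)
    return out
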