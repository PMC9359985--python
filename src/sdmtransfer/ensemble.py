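"""Ensemble combination of base models: performance-weighted averaging,
committee (vote) averaging, binarization and area accounting.

Weights are proportional to each member's evaluation score above a
no-skill baseline (0.5 for ROC, 0 for TSS), so near-random members get
near-zero weight. The ensemble threshold is re-optimized on the
ensemble's own calibration scores, not averaged from member thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import Grid, GridAlignmentError, RegionPartition
from .models import FittedModel


@dataclass
class EnsembleModel:
    """Weighted set of fitted members with an ensemble threshold."""

    members: list[FittedModel]
    weights: np.ndarray
    weighting_metric: str = "auc"
    threshold: float | None = None
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("one weight per member required")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if (self.weights < 0).any():
            raise ValueError("weights must be nonnegative")

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.column_stack([m.predict(X) for m in self.members])
        return preds @ self.weights


def ensemble_weights(member_scores: Sequence[float], baseline: float = 0.5
                     ) -> np.ndarray:
    """Weights proportional to max(score - baseline, 0), normalized."""
    s = np.asarray(member_scores, dtype=float)
    excess = np.clip(s - baseline, 0.0, None)
    total = excess.sum()
    if total <= 0:
        raise ValueError("no member scores above the no-skill baseline")
    return excess / total


def weighted_average_map(maps: Sequence[Grid], weights) -> Grid:
    """Cellwise weighted average of aligned suitability maps. A cell is
    nodata iff nodata in any member."""
    weights = np.asarray(weights, dtype=float)
    if len(maps) != weights.size:
        raise ValueError("one weight per map required")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    first = maps[0]
    mask = first.valid_mask.copy()
    acc = np.zeros(first.shape)
    for g, w in zip(maps, weights):
        if not first.same_geometry(g):
            raise GridAlignmentError("ensemble member maps not aligned")
        mask &= g.valid_mask
        acc += w * np.where(g.valid_mask, g.values, 0.0)
    return Grid(np.where(mask, acc, np.nan), mask, first.cell_size,
                first.origin)


def committee_map(members: Sequence[tuple[Grid, float]]) -> Grid:
    """Fraction of members voting presence, each binarized at its own
    threshold: cell value = (1/m) sum 1(map_i >= tau_i)."""
    if not members:
        raise ValueError("no members")
    first = members[0][0]
    mask = first.valid_mask.copy()
    votes = np.zeros(first.shape)
    for g, tau in members:
        if not first.same_geometry(g):
            raise GridAlignmentError("committee member maps not aligned")
        mask &= g.valid_mask
        votes += np.where(g.valid_mask, g.values >= tau, 0.0)
    return Grid(np.where(mask, votes / len(members), np.nan), mask,
                first.cell_size, first.origin)


def binarize_and_area(suitability: Grid, tau: float,
                      regions: RegionPartition | None = None
                      ) -> tuple[Grid, pd.DataFrame]:
    """Binary suitable/unsuitable map at threshold ``tau`` plus per-region
    suitable area in km^2 (cell count x cell_size^2)."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0, 1]")
    suitable = suitability.valid_mask & (suitability.values >= tau)
    binary = Grid(np.where(suitability.valid_mask, suitable.astype(float),
                           np.nan),
                  suitability.valid_mask.copy(), suitability.cell_size,
                  suitability.origin)
    cell_area = suitability.cell_size ** 2
    rows = []
    if regions is not None:
        for r in regions.region_ids:
            rows.append({"region": r,
                         "area_km2": float(suitable[regions.mask_of(r)].sum()
                                           * cell_area)})
    rows.append({"region": "total",
                 "area_km2": float(suitable.sum() * cell_area)})
    return binary, pd.DataFrame(rows)
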