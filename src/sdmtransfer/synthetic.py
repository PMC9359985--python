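"""Virtual-species landscape generator.

Builds every input the modeling pipeline needs — spatially
autocorrelated covariate grids, a region partition, and presence points
— from a known ground-truth suitability surface, so that recovery can be
checked exactly.

The simulated landscape mimics a northern-forest working landscape: a
``natural_prop`` cover fraction, crops and developed-land masks from
which distance layers are derived, a road-density surface and a snowfall
gradient. True suitability is logistic in the covariates, dominated by
natural cover and (log1p-transformed, hence saturating) distance to
crops, with a mild road penalty and an optional quadratic snowfall term.
Covariate fields are smoothed uniform noise (moving-average kernel) plus
deterministic gradients: autocorrelated without heavyweight
geostatistics.

The ``range_truncated`` preset stamps crop cells on a regular lattice
throughout one region, so that region never exhibits large distances to
crops: its covariate range is truncated relative to the rest of the
domain, the situation that makes extrapolation from that region
hazardous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit

from .grids import (CategoricalGrid, CovariateStack, Grid, RegionPartition,
                    distance_to_class, write_ascii_grid)
from .occurrences import OccurrenceSet, write_occurrences

COVARIATES = ("natural_prop", "dist_crops", "dist_developed",
              "road_density", "snowfall")


@dataclass
class ScenarioConfig:
    """Configuration of one virtual-species scenario.

    ``beta`` holds the true coefficients of the logistic suitability:
    intercept, ``natural_prop`` (per unit cover fraction),
    ``log1p_dist_crops`` (per unit of log1p km), ``road_density``
    (per km/km^2, <= 0) and ``snow_quad`` (per squared metre of
    departure from ``snow_opt``).
    """

    nrows: int = 240
    ncols: int = 360
    cell_size: float = 1.0
    region_fractions: tuple[float, ...] = (1 / 3, 2 / 3)  # vertical bands
    smooth: int = 9                   # moving-average kernel size, cells
    crops_threshold: float = 0.62     # noise-field quantile cut for crops
    developed_threshold: float = 0.92
    beta: dict = field(default_factory=lambda: {
        "intercept": -8.0,
        "natural_prop": 7.0,
        "log1p_dist_crops": 2.5,
        "road_density": -1.0,
        "snow_quad": -0.2,
    })
    snow_opt: float = 2.5             # metres; suitability peaks here
    truncated_region: int | None = None  # region with crops everywhere
    truncation_lattice: int = 8       # crop-stamp spacing in that region
    n_presences: int = 500
    seed_landscape: int = 11
    seed_sampling: int = 12

    def __post_init__(self) -> None:
        fr = self.region_fractions
        if not all(0 < a < 1 for a in fr) or list(fr) != sorted(set(fr)):
            raise ValueError("degenerate region bands")


@dataclass
class TruthBundle:
    """Ground truth of a generated scenario."""

    psi: Grid                          # true suitability, inverse-logit exact
    beta: dict
    regions: RegionPartition
    covariate_ranges: pd.DataFrame     # per (region, variable) min/max


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  size: int) -> np.ndarray:
    """Moving-average-smoothed uniform noise, rescaled to [0, 1]."""
    f = uniform_filter(rng.random(shape), size=size, mode="reflect")
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo)


def _region_partition(config: ScenarioConfig) -> RegionPartition:
    bounds = [int(round(f * config.ncols)) for f in config.region_fractions]
    if len(set(bounds)) != len(bounds) or any(
            b <= 0 or b >= config.ncols for b in bounds):
        raise ValueError("degenerate region bands")
    labels = np.ones((config.nrows, config.ncols), dtype=int)
    for i, b in enumerate(bounds):
        labels[:, b:] = i + 2
    return RegionPartition(CategoricalGrid(
        labels, None, config.cell_size, (0.0, 0.0),
        {i + 1: f"region_{i + 1}" for i in range(len(bounds) + 1)}))


def true_linear_predictor(beta: Mapping[str, float], natural: np.ndarray,
                          dist_crops: np.ndarray, road: np.ndarray,
                          snow: np.ndarray, snow_opt: float) -> np.ndarray:
    """The declared linear predictor of the virtual species."""
    return (beta["intercept"]
            + beta["natural_prop"] * natural
            + beta["log1p_dist_crops"] * np.log1p(dist_crops)
            + beta["road_density"] * road
            + beta["snow_quad"] * (snow - snow_opt) ** 2)


def generate_landscape(config: ScenarioConfig
                       ) -> tuple[CovariateStack, RegionPartition, TruthBundle]:
    """Deterministically generate covariates, regions and ground truth."""
    rng = np.random.default_rng(config.seed_landscape)
    shape = (config.nrows, config.ncols)
    cell, origin = config.cell_size, (0.0, 0.0)
    regions = _region_partition(config)

    # contrast-stretch the cover field: real cover-proportion maps are
    # bimodal (saturated forest blocks vs open farmland)
    natural = np.clip((_smooth_field(rng, shape, config.smooth) - 0.35) / 0.3,
                      0.0, 1.0)
    crops_field = _smooth_field(rng, shape, config.smooth)
    developed_field = _smooth_field(rng, shape, config.smooth)
    road_field = _smooth_field(rng, shape, max(3, config.smooth // 2))
    snow_noise = _smooth_field(rng, shape, config.smooth)

    crops_mask = crops_field > config.crops_threshold
    if config.truncated_region is not None:
        # stamp crops on a regular lattice so no cell in that region is far
        # from crops: truncates the dist_crops range there by construction
        rmask = regions.mask_of(config.truncated_region)
        lattice = np.zeros(shape, dtype=bool)
        step = config.truncation_lattice
        lattice[step // 2::step, step // 2::step] = True
        crops_mask |= rmask & lattice
    if not crops_mask.any():
        raise ValueError("crops threshold leaves no crop cells")
    developed_mask = developed_field > config.developed_threshold
    if not developed_mask.any():
        raise ValueError("developed threshold leaves no developed cells")

    # crops exclude natural cover where they occur
    natural = np.where(crops_mask | developed_mask, natural * 0.2, natural)

    as_grid = lambda a: Grid(a.astype(float), None, cell, origin)
    dist_crops = distance_to_class(as_grid(crops_mask.astype(float)))
    dist_developed = distance_to_class(as_grid(developed_mask.astype(float)))
    road = 3.0 * road_field                       # km of road per km^2
    # north-south gradient (row 0 = south) plus noise, metres of snow
    lat = np.linspace(0.0, 1.0, config.nrows)[:, None]
    snow = 3.0 * (0.7 * lat + 0.3 * snow_noise)

    stack = CovariateStack({
        "natural_prop": as_grid(natural),
        "dist_crops": dist_crops,
        "dist_developed": dist_developed,
        "road_density": as_grid(road),
        "snowfall": as_grid(snow),
    })

    eta = true_linear_predictor(config.beta, natural, dist_crops.values,
                                road, snow, config.snow_opt)
    psi = Grid(expit(eta), None, cell, origin)
    ranges = covariate_ranges(stack, regions)
    return stack, regions, TruthBundle(psi, dict(config.beta), regions, ranges)


def covariate_ranges(stack: CovariateStack, regions: RegionPartition
                     ) -> pd.DataFrame:
    """Per-(region, variable) observed min/max — the violin-plot concept
    of comparing available environmental gradients across regions."""
    rows = []
    for r in regions.region_ids:
        rmask = regions.mask_of(r)
        for name in stack.names:
            g = stack[name]
            vals = g.values[rmask & g.valid_mask]
            rows.append({"region": r, "variable": name,
                         "min": float(vals.min()), "max": float(vals.max())})
    return pd.DataFrame(rows)


def sample_presences(truth: TruthBundle, n: int, seed: int,
                     bias_mask: Grid | None = None,
                     replace_cells: bool = False) -> OccurrenceSet:
    """Draw ``n`` presence cells with probability proportional to the true
    suitability (times an optional bias mask); one jittered point per
    drawn cell, region labels attached.

    Cells are drawn without replacement by default (one point per cell,
    matching a 1-km-thinned survey); ``replace_cells=True`` allows
    repeats for sampling-distribution checks.
    """
    psi = truth.psi
    p = np.where(psi.valid_mask, psi.values, 0.0).ravel()
    if bias_mask is not None:
        if not psi.same_geometry(bias_mask):
            raise ValueError("bias mask not aligned with truth")
        p = p * np.where(bias_mask.valid_mask, bias_mask.values, 0.0).ravel()
    if p.sum() <= 0:
        raise ValueError("no cells with positive sampling probability")
    support = int((p > 0).sum())
    if not replace_cells and n > support:
        raise ValueError(f"requested {n} cells but only {support} have "
                         "positive suitability")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(p.size, size=n, replace=replace_cells, p=p / p.sum())
    rows, cols = np.unravel_index(drawn, psi.shape)
    x, y = psi.cell_centers(rows, cols)
    x = x + (rng.random(n) - 0.5) * psi.cell_size
    y = y + (rng.random(n) - 0.5) * psi.cell_size
    return OccurrenceSet(x, y, truth.regions.label_points(x, y))


def scenario_presets() -> dict[str, ScenarioConfig]:
    """Named study conditions.

    * ``homogeneous`` — one generating process everywhere, overlapping
      covariate ranges across regions.
    * ``range_truncated`` — region 3 has crops everywhere, so its
      distance-to-crops range is truncated relative to the domain.
    * ``null`` — all slope coefficients zero: no environmental signal.
    """
    base = ScenarioConfig()
    null_beta = {k: (v if k == "intercept" else 0.0)
                 for k, v in base.beta.items()}
    return {
        "homogeneous": ScenarioConfig(),
        "range_truncated": ScenarioConfig(truncated_region=3),
        "null": ScenarioConfig(beta=null_beta),
    }


def write_scenario(path: str | Path, stack: CovariateStack,
                   regions: RegionPartition, truth: TruthBundle,
                   presences: OccurrenceSet, config: ScenarioConfig) -> None:
    """Write the full input bundle (ASCII grids, CSV, scenario.json)."""
    import dataclasses
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in stack.names:
        write_ascii_grid(stack[name], path / f"{name}.asc")
    write_ascii_grid(regions.labels, path / "regions.asc")
    write_ascii_grid(truth.psi, path / "true_suitability.asc")
    write_occurrences(presences, path / "presences.csv", role="presence")
    truth.covariate_ranges.to_csv(path / "covariate_ranges.csv", index=False)
    cfg = dataclasses.asdict(config)
    (path / "scenario.json").write_text(json.dumps(cfg, indent=1))
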