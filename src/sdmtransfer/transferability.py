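"""Spatial-transferability assessment: single-region model schemes and
map/niche comparison metrics.

Two schemes probe how a model calibrated on one region transfers to the
rest of the domain:

* ``regional`` background ("state cross-validation") — presences come
  from the focal region but background spans the whole study area;
* ``focal-only`` background ("extrapolation") — background is restricted
  to the focal region, so the model never sees conditions outside it.

Either way the fitted ensemble predicts over the *entire* domain and is
validated on the presences of the non-focal regions. Map similarity to
the all-region model is measured by Spearman rank correlation and the
niche-overlap statistics Schoener's D and Hellinger-based I, both on
cell-normalized suitability surfaces and ranging 0 (no overlap) to 1
(complete overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .evaluation import auc as auc_metric
from .fitting import EnsembleFit, FitConfig, fit_ensemble
from .grids import CovariateStack, Grid, GridAlignmentError, RegionPartition
from .occurrences import OccurrenceSet, sample_background

CROSS_VALIDATION = "regional"
EXTRAPOLATION = "focal-only"
SCHEMES = (CROSS_VALIDATION, EXTRAPOLATION)


@dataclass
class SchemeSpec:
    """One single-region transfer run: which region calibrates the model
    and where its background points may fall."""

    focal_region: int
    background_scope: str           # "regional" | "focal-only"
    n_background: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_scope not in SCHEMES:
            raise ValueError(
                f"background_scope must be one of {SCHEMES}")


@dataclass
class SchemeResult:
    spec: SchemeSpec
    fit: EnsembleFit
    suitability: Grid


def run_scheme(occ_by_region: Mapping[int, OccurrenceSet],
               stack: CovariateStack, regions: RegionPartition,
               scheme: SchemeSpec, config: FitConfig) -> SchemeResult:
    """Fit the full ensemble pipeline on one region's presences and
    predict suitability over the whole domain.

    ``occ_by_region`` should already be balanced (equal counts per
    region) when comparisons across regions are intended.
    """
    if scheme.focal_region not in occ_by_region:
        raise ValueError(f"no occurrences for region {scheme.focal_region}")
    presences = occ_by_region[scheme.focal_region]
    if len(presences) == 0:
        raise ValueError("empty focal region")
    domain = stack.template
    restrict = (scheme.focal_region
                if scheme.background_scope == EXTRAPOLATION else None)
    background = sample_background(domain, scheme.n_background,
                                   seed=scheme.seed, restrict=restrict,
                                   regions=regions)
    fit = fit_ensemble(presences, background, stack, config,
                       seed=scheme.seed)
    suitability, _, _ = fit.predict_maps(stack)
    return SchemeResult(scheme, fit, suitability)


def validate(suitability: Grid, validation_presences: OccurrenceSet,
             validation_background: OccurrenceSet, tau: float
             ) -> tuple[float, float, int]:
    """Validation ROC and sensitivity of a map on held-out points.

    Scores are extracted from the map at the point coordinates; points on
    nodata cells are dropped and counted. Sensitivity uses the model's
    own calibration threshold ``tau``. Returns (roc, sensitivity,
    n_dropped).
    """
    sp = suitability.extract(validation_presences.x, validation_presences.y)
    sb = suitability.extract(validation_background.x,
                             validation_background.y)
    n_dropped = int(np.isnan(sp).sum() + np.isnan(sb).sum())
    sp, sb = sp[~np.isnan(sp)], sb[~np.isnan(sb)]
    if sp.size == 0 or sb.size == 0:
        raise ValueError("validation sets empty after nodata drops")
    roc = auc_metric(sp, sb)
    sensitivity = float((sp >= tau).mean())
    return roc, sensitivity, n_dropped


def _normalized_pair(map1: Grid, map2: Grid) -> tuple[np.ndarray, np.ndarray]:
    if not map1.same_geometry(map2):
        raise GridAlignmentError("maps not aligned")
    mask = map1.valid_mask & map2.valid_mask
    v1, v2 = map1.values[mask], map2.values[mask]
    t1, t2 = v1.sum(), v2.sum()
    if not (t1 > 0 and t2 > 0):
        raise ValueError("niche overlap undefined for an all-zero map")
    return v1 / t1, v2 / t2


def schoener_d(map1: Grid, map2: Grid) -> float:
    """Schoener's D: 1 - 0.5 sum |p1 - p2| over cell-normalized maps."""
    p1, p2 = _normalized_pair(map1, map2)
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def hellinger_i(map1: Grid, map2: Grid) -> float:
    """Hellinger-based I: 1 - 0.5 sum (sqrt(p1) - sqrt(p2))^2."""
    p1, p2 = _normalized_pair(map1, map2)
    return float(1.0 - 0.5 * ((np.sqrt(p1) - np.sqrt(p2)) ** 2).sum())


def spearman_maps(map1: Grid, map2: Grid) -> float:
    """Spearman rank correlation over jointly valid cells (midranks)."""
    if not map1.same_geometry(map2):
        raise GridAlignmentError("maps not aligned")
    mask = map1.valid_mask & map2.valid_mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 jointly valid cells")
    v1, v2 = map1.values[mask], map2.values[mask]
    r1 = rankdata(v1, method="average")
    r2 = rankdata(v2, method="average")
    if r1.std() == 0 or r2.std() == 0:
        warnings.warn("spearman undefined: constant map", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(r1, r2)[0, 1])


def transfer_report(regional: tuple[EnsembleFit, Grid],
                    scheme_results: list[SchemeResult],
                    occ_by_region: Mapping[int, OccurrenceSet],
                    validation_background: OccurrenceSet
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(scheme, region) metric table plus a per-scheme summary.

    Each row carries: mean internal ROC (CV), validation ROC and
    sensitivity on non-focal presences against the shared validation
    background, Spearman r, Schoener's D and Hellinger's I against the
    all-region map.
    """
    regional_fit, regional_map = regional
    rows = []
    for res in scheme_results:
        focal = res.spec.focal_region
        others = [r for r in sorted(occ_by_region) if r != focal]
        vp = np.concatenate([occ_by_region[r].x for r in others]), \
            np.concatenate([occ_by_region[r].y for r in others])
        val_pres = OccurrenceSet(vp[0], vp[1])
        roc_val, sens_val, _ = validate(res.suitability, val_pres,
                                        validation_background,
                                        res.fit.threshold)
        rows.append({
            "scheme": res.spec.background_scope,
            "region": focal,
            "roc_internal": res.fit.mean_internal_auc(),
            "roc_validation": roc_val,
            "sensitivity_validation": sens_val,
            "spearman_vs_regional": spearman_maps(res.suitability,
                                                  regional_map),
            "schoener_d": schoener_d(res.suitability, regional_map),
            "hellinger_i": hellinger_i(res.suitability, regional_map),
        })
    report = pd.DataFrame(rows)
    summary = (report
               .drop(columns="region")
               .groupby("scheme", as_index=False)
               .mean(numeric_only=True))
    return report, summary
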