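"""Model evaluation: CV splitting, discrimination metrics, threshold
optimization, permutation importance and response curves.

Conventions: a presence is classified as predicted-present at score
``s >= tau`` (inclusive). AUC follows the pairwise probability
definition, ties counted 1/2. TSS = sensitivity + specificity - 1 holds
as an exact identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .models import FittedModel
from .occurrences import SampleDesign


@dataclass
class EvaluationScores:
    auc: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float

    def as_dict(self) -> dict:
        return {"auc": self.auc, "tss": self.tss,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "threshold": self.threshold}


@dataclass
class CVSplit:
    run: int
    train_idx: np.ndarray
    test_idx: np.ndarray


def split_cv(design: SampleDesign, runs: int = 3, train_fraction: float = 0.8,
             seed: int = 0) -> list[CVSplit]:
    """Repeated seeded stratified random splits (not a partition).

    Each run draws ``train_fraction`` of every class (rounded) for
    training; the rest tests. Requires >= 5 rows per class.
    """
    y = design.y
    idx_p = np.flatnonzero(y == 1)
    idx_b = np.flatnonzero(y == 0)
    if idx_p.size < 5 or idx_b.size < 5:
        raise ValueError("each class needs at least 5 rows for CV")
    rng = np.random.default_rng(seed)
    splits = []
    for r in range(runs):
        train_parts, test_parts = [], []
        for cls_idx in (idx_p, idx_b):
            perm = rng.permutation(cls_idx)
            n_train = int(round(train_fraction * cls_idx.size))
            n_train = min(max(n_train, 1), cls_idx.size - 1)
            train_parts.append(perm[:n_train])
            test_parts.append(perm[n_train:])
        splits.append(CVSplit(r, np.sort(np.concatenate(train_parts)),
                              np.sort(np.concatenate(test_parts))))
    return splits


def auc(presence_scores, background_scores) -> float:
    """P(random presence outscores random background), ties as 1/2.

    Computed from midranks; exactly equal to the brute-force pairwise
    count [#(s_p > s_b) + 0.5 #(s_p = s_b)] / (n_p n_b).
    """
    sp = np.asarray(presence_scores, dtype=float)
    sb = np.asarray(background_scores, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]), method="average")
    rank_sum_p = ranks[: sp.size].sum()
    return float((rank_sum_p - sp.size * (sp.size + 1) / 2) / (sp.size * sb.size))


def confusion_metrics(presence_scores, background_scores, tau: float
                      ) -> tuple[float, float, float]:
    """(sensitivity, specificity, tss) at threshold ``tau``; presence
    classified at score >= tau."""
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0, 1]")
    sp = np.asarray(presence_scores, dtype=float)
    sb = np.asarray(background_scores, dtype=float)
    sens = float((sp >= tau).mean())
    spec = float((sb < tau).mean())
    return sens, spec, sens + spec - 1.0


def optimize_threshold(presence_scores, background_scores
                       ) -> tuple[float, EvaluationScores]:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique pooled scores; ties broken by the smallest
    threshold. Equivalent to an exhaustive scan.
    """
    sp = np.asarray(presence_scores, dtype=float)
    sb = np.asarray(background_scores, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([sp, sb]))
    # vectorized counts: at candidate t, sens = #(sp >= t)/n_p, spec = #(sb < t)/n_b
    sp_sorted = np.sort(sp)
    sb_sorted = np.sort(sb)
    sens = 1.0 - np.searchsorted(sp_sorted, candidates, side="left") / sp.size
    spec = np.searchsorted(sb_sorted, candidates, side="left") / sb.size
    total = sens + spec
    k = int(np.argmax(total))  # first max -> smallest candidate threshold
    tau = float(candidates[k])
    scores = EvaluationScores(auc=auc(sp, sb), tss=float(total[k] - 1.0),
                              sensitivity=float(sens[k]),
                              specificity=float(spec[k]), threshold=tau)
    return tau, scores


def evaluate_scores(presence_scores, background_scores) -> EvaluationScores:
    """Full evaluation at the max-sens/spec threshold."""
    _, scores = optimize_threshold(presence_scores, background_scores)
    return scores


def permutation_importance(model: FittedModel, design: SampleDesign,
                           variable: str, reps: int = 5, seed: int = 0
                           ) -> float:
    """Mean over reps of 1 - cor(original predictions, predictions with the
    variable's column permuted), clamped at 0. Constant original
    predictions give 0 by definition."""
    if variable not in design.variables:
        raise ValueError(f"variable {variable!r} not in design")
    X = design.X[:, [design.variables.index(v) for v in model.variables]]
    base = model.predict(X)
    if np.std(base) == 0:
        return 0.0
    if variable not in model.variables:
        return 0.0
    col = model.variables.index(variable)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(reps):
        Xp = X.copy()
        Xp[:, col] = rng.permutation(Xp[:, col])
        pred = model.predict(Xp)
        r = 0.0 if np.std(pred) == 0 else float(np.corrcoef(base, pred)[0, 1])
        vals.append(max(0.0, 1.0 - r))
    return float(np.mean(vals))


def response_curve(model: FittedModel, design: SampleDesign, variable: str,
                   n_steps: int = 50) -> np.ndarray:
    """Evaluation-strip response curve: the focal variable sweeps its
    observed calibration range in ``n_steps`` equal steps while all other
    variables sit at their calibration median. Returns an (n_steps, 2)
    array of (value, prediction)."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    cols = [design.variables.index(v) for v in model.variables]
    X = design.X[:, cols]
    if variable not in model.variables:
        raise ValueError(f"variable {variable!r} not used by the model")
    j = model.variables.index(variable)
    grid_vals = np.linspace(X[:, j].min(), X[:, j].max(), n_steps)
    Xq = np.tile(np.median(X, axis=0), (n_steps, 1))
    Xq[:, j] = grid_vals
    return np.column_stack([grid_vals, model.predict(Xq)])
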