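"""Base distribution-model algorithms with a uniform fit/predict contract.

Four algorithms are implemented natively:

* **GLM** — weighted-likelihood logistic regression (IRLS), linear or
  linear+quadratic terms per covariate.
* **SRE** (surface range envelope / BIOCLIM) — per-variable central
  quantile envelope of the presence values; a site is suitable iff every
  covariate lies inside its envelope.
* **CTA** — binary recursive partitioning minimizing weighted Gini
  impurity; leaves predict the weighted presence fraction.
* **GBM** — stagewise gradient boosting of small regression trees on the
  logistic deviance gradient.

All models map covariate matrices to scores in [0, 1]. Further members of
an ensemble (random forest, GAM, MaxEnt, FDA, ...) plug in through
:class:`ModelAdapter` without their internals living here.

For CTA and GBM the split search scans, per node and variable, midpoints
between consecutive distinct sorted values using cumulative sums, which
is exact (equivalent to exhaustive enumeration). Ties in split quality
are broken by lowest variable index, then lowest split value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit

from .occurrences import SampleDesign


class FittedModel:
    """Common surface for calibrated base models.

    Attributes
    ----------
    algorithm : str
        Algorithm identifier (``glm``, ``sre``, ``cta``, ``gbm`` or an
        adapter name).
    variables : list[str]
        Covariate names the model consumes, in column order.
    threshold : float or None
        Calibration threshold (max sensitivity+specificity), attached by
        the evaluation stage; in [0, 1].
    scores : dict
        Evaluation scores (per CV run and mean), attached by the pipeline.
    """

    algorithm: str = "base"

    def __init__(self, variables: Sequence[str]):
        self.variables = list(variables)
        self.threshold: float | None = None
        self.scores: dict = {}

    def predict(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    # -- JSON serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {"algorithm": self.algorithm, "variables": self.variables,
             "threshold": self.threshold, "scores": self.scores}
        d.update(self._params_dict())
        return d

    def _params_dict(self) -> dict:  # pragma: no cover
        return {}

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _check_X(X: np.ndarray, n_vars: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != n_vars:
        raise ValueError(f"expected {n_vars} covariate columns, got {X.shape[1]}")
    return X


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

class GLMModel(FittedModel):
    algorithm = "glm"

    def __init__(self, variables: Sequence[str], terms: str,
                 coef: np.ndarray, kept_columns: np.ndarray,
                 separation: bool = False):
        super().__init__(variables)
        self.terms = terms
        self.coef = np.asarray(coef, dtype=float)
        self.kept_columns = np.asarray(kept_columns, dtype=int)
        self.separation = separation

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        X = _check_X(X, len(self.variables))
        cols = [X] if self.terms == "linear" else [X, X ** 2]
        full = np.column_stack([np.ones(X.shape[0])] + cols)
        return full[:, np.r_[0, self.kept_columns + 1]]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.design_matrix(X) @ self.coef)

    def _params_dict(self) -> dict:
        return {"terms": self.terms, "coef": self.coef.tolist(),
                "kept_columns": self.kept_columns.tolist(),
                "separation": self.separation}


def fit_glm(design: SampleDesign, terms: str = "quadratic",
            max_iter: int = 100, tol: float = 1e-10) -> GLMModel:
    """Weighted logistic regression via iteratively reweighted least squares.

    ``terms`` is ``"linear"`` (one slope per covariate) or ``"quadratic"``
    (adds a squared term per covariate). Zero-variance expanded columns
    are excluded. Perfect separation is detected from diverging
    coefficients and flagged on the returned model.
    """
    if terms not in ("linear", "quadratic"):
        raise ValueError("terms must be 'linear' or 'quadratic'")
    X = design.X
    cols = [X] if terms == "linear" else [X, X ** 2]
    F = np.column_stack(cols)
    sd = F.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    # standardize for numerical stability; back-transform at the end
    mu, sig = F[:, kept].mean(axis=0), F[:, kept].std(axis=0)
    Z = np.column_stack([np.ones(X.shape[0]), (F[:, kept] - mu) / sig])
    y, w = design.y, design.weights

    beta = np.zeros(Z.shape[1])
    dev_old = np.inf
    separation = False
    for _ in range(max_iter):
        eta = Z @ beta
        p = expit(eta)
        s = w * np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / np.clip(p * (1 - p), 1e-10, None)
        WZ = Z * s[:, None]
        beta_new, *_ = np.linalg.lstsq(Z.T @ WZ, Z.T @ (s * z), rcond=None)
        eta_new = Z @ beta_new
        p_new = np.clip(expit(eta_new), 1e-12, 1 - 1e-12)
        dev = -2 * np.sum(w * (y * np.log(p_new) + (1 - y) * np.log(1 - p_new)))
        beta = beta_new
        # standardized slopes beyond ~30 mean saturated probabilities:
        # the MLE is diverging (quasi-complete separation)
        if np.max(np.abs(beta)) > 30:
            separation = True
            break
        if np.isfinite(dev_old) and \
                abs(dev_old - dev) <= tol * (abs(dev_old) + 1e-12):
            dev_old = dev
            break
        dev_old = dev
    # a converged fit with extreme standardized slopes is still separation:
    # odds ratios beyond e^15 per SD have no finite-MLE interpretation
    if not separation and beta.size > 1 and np.max(np.abs(beta[1:])) > 15:
        separation = True
    if separation:
        warnings.warn("possible perfect separation: coefficients diverging",
                      stacklevel=2)
    # back-transform to the original covariate scale
    coef = np.zeros(1 + kept.size)
    coef[1:] = beta[1:] / sig
    coef[0] = beta[0] - np.sum(beta[1:] * mu / sig)
    return GLMModel(design.variables, terms, coef, kept, separation)


# ---------------------------------------------------------------------------
# SRE / BIOCLIM
# ---------------------------------------------------------------------------

class SREModel(FittedModel):
    algorithm = "sre"

    def __init__(self, variables: Sequence[str], lower: np.ndarray,
                 upper: np.ndarray, alpha: float):
        super().__init__(variables)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.alpha = float(alpha)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = _check_X(X, len(self.variables))
        inside = (X >= self.lower) & (X <= self.upper)
        return inside.all(axis=1).astype(float)

    def _params_dict(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist(),
                "alpha": self.alpha}


def fit_sre(design: SampleDesign, alpha: float = 0.025) -> SREModel:
    """Surface range envelope: per-variable [alpha, 1-alpha] empirical
    quantile interval of the *presence* values (linear-interpolation
    quantiles). Prediction is 1 iff every variable falls inside."""
    if not 0 <= alpha < 0.5:
        raise ValueError("alpha must be in [0, 0.5)")
    P = design.X[design.y == 1]
    if P.shape[0] == 0:
        raise ValueError("no presence rows")
    lower = np.quantile(P, alpha, axis=0, method="linear")
    upper = np.quantile(P, 1 - alpha, axis=0, method="linear")
    return SREModel(design.variables, lower, upper, alpha)


# ---------------------------------------------------------------------------
# Shared exact split search (CTA + GBM trees)
# ---------------------------------------------------------------------------

def _best_split(X: np.ndarray, t: np.ndarray, w: np.ndarray
                ) -> tuple[int, float, float] | None:
    """Best (variable, threshold) by weighted-SSE reduction of target ``t``.

    Minimizing weighted child SSE of a binary 0/1 target is equivalent to
    minimizing weighted Gini impurity, so this one scan serves both the
    classification tree and the boosted regression trees. Candidates are
    midpoints between consecutive distinct sorted values; rows with
    ``x <= threshold`` go left. Returns (var, threshold, gain) with gain
    strictly positive, or None if no admissible split exists. Ties:
    lowest variable index, then lowest threshold.
    """
    W = w.sum()
    Swt = (w * t).sum()
    base = Swt ** 2 / W
    best: tuple[int, float, float] | None = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        cw = np.cumsum(w[order])
        cwt = np.cumsum((w * t)[order])
        # split after position i (0-based) iff xs[i] < xs[i+1]
        boundary = np.flatnonzero(xs[:-1] < xs[1:])
        if boundary.size == 0:
            continue
        wl, wr = cw[boundary], W - cw[boundary]
        sl, sr = cwt[boundary], Swt - cwt[boundary]
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = sl ** 2 / wl + sr ** 2 / wr - base
        ok = (wl > 0) & (wr > 0)
        gain = np.where(ok, gain, -np.inf)
        k = int(np.argmax(gain))  # argmax returns first max -> lowest threshold
        g = float(gain[k])
        if g <= 1e-12:
            continue
        thr = 0.5 * (xs[boundary[k]] + xs[boundary[k] + 1])
        if best is None or g > best[2] + 1e-12:
            best = (j, float(thr), g)
    return best


@dataclass
class _TreeNode:
    feature: int = -1            # -1 marks a leaf
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    value: float = 0.0

    def to_dict(self) -> dict:
        if self.feature < 0:
            return {"value": self.value}
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}


def _grow_tree(X: np.ndarray, t: np.ndarray, w: np.ndarray, depth: int,
               max_depth: int, min_node_weight: float,
               leaf_value: Callable[[np.ndarray], float]) -> _TreeNode:
    """Recursive partitioning; ``t`` is the split target, ``leaf_value``
    maps a row-index subset to the leaf prediction."""
    idx_all = np.arange(X.shape[0])
    node = _TreeNode(value=leaf_value(idx_all))
    if depth >= max_depth or w.sum() <= min_node_weight or np.ptp(t) == 0:
        return node
    split = _best_split(X, t, w)
    if split is None:
        return node
    j, thr, _ = split
    left = X[:, j] <= thr
    node.feature, node.threshold = j, thr
    node.left = _grow_tree(X[left], t[left], w[left], depth + 1, max_depth,
                           min_node_weight, lambda s, m=left: leaf_value(idx_all[m][s]))
    node.right = _grow_tree(X[~left], t[~left], w[~left], depth + 1, max_depth,
                            min_node_weight, lambda s, m=~left: leaf_value(idx_all[m][s]))
    return node


def _predict_tree(node: _TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if nd.feature < 0:
            out[idx] = nd.value
            continue
        go_left = X[idx, nd.feature] <= nd.threshold
        stack.append((nd.left, idx[go_left]))
        stack.append((nd.right, idx[~go_left]))
    return out


# ---------------------------------------------------------------------------
# CTA
# ---------------------------------------------------------------------------

class CTAModel(FittedModel):
    algorithm = "cta"

    def __init__(self, variables: Sequence[str], root: _TreeNode,
                 max_depth: int, min_node_weight: float):
        super().__init__(variables)
        self.root = root
        self.max_depth = max_depth
        self.min_node_weight = min_node_weight

    def predict(self, X: np.ndarray) -> np.ndarray:
        return _predict_tree(self.root, _check_X(X, len(self.variables)))

    def _params_dict(self) -> dict:
        return {"tree": self.root.to_dict(), "max_depth": self.max_depth,
                "min_node_weight": self.min_node_weight}


def fit_cta(design: SampleDesign, max_depth: int = 8,
            min_node_weight: float = 1.0) -> CTAModel:
    """Classification tree: recursive weighted-Gini partitioning.

    Leaves predict the weighted presence fraction. Growth stops at
    ``max_depth``, when node weight drops to ``min_node_weight``, or when
    the node is pure.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    X, y, w = design.X, design.y, design.weights

    def leaf_value(idx: np.ndarray) -> float:
        ww = w[idx]
        return float((ww * y[idx]).sum() / ww.sum())

    root = _grow_tree(X, y.astype(float), w, 0, max_depth, min_node_weight,
                      leaf_value)
    return CTAModel(design.variables, root, max_depth, min_node_weight)


def cta_root_split(design: SampleDesign) -> tuple[int, float] | None:
    """Expose the root (variable, threshold) chosen by the Gini scan."""
    split = _best_split(design.X, design.y.astype(float), design.weights)
    return None if split is None else (split[0], split[1])


# ---------------------------------------------------------------------------
# GBM
# ---------------------------------------------------------------------------

class GBMModel(FittedModel):
    algorithm = "gbm"

    def __init__(self, variables: Sequence[str], f0: float,
                 trees: list[_TreeNode], learning_rate: float,
                 train_deviance: list[float]):
        super().__init__(variables)
        self.f0 = float(f0)
        self.trees = trees
        self.learning_rate = float(learning_rate)
        self.train_deviance = list(train_deviance)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = _check_X(X, len(self.variables))
        F = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            F += self.learning_rate * _predict_tree(tree, X)
        return F

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision_function(X))

    def _params_dict(self) -> dict:
        return {"f0": self.f0, "learning_rate": self.learning_rate,
                "n_trees": len(self.trees),
                "trees": [t.to_dict() for t in self.trees]}


def fit_gbm(design: SampleDesign, n_trees: int = 250,
            learning_rate: float = 0.1, tree_depth: int = 2,
            min_node_weight: float = 1e-9) -> GBMModel:
    """Stagewise gradient boosting on the weighted logistic deviance.

    Each stage fits a depth-``tree_depth`` regression tree to the
    gradient residuals ``y - p`` (weighted least squares) and sets leaf
    values by a single Newton step. The initial score is the logit of the
    weighted prevalence. Per-stage training deviance is recorded and is
    non-increasing.
    """
    if n_trees < 0:
        raise ValueError("n_trees must be >= 0")
    if not 0 < learning_rate <= 1:
        raise ValueError("learning_rate must be in (0, 1]")
    X, y, w = design.X, design.y, design.weights
    prev = float((w * y).sum() / w.sum())
    prev = min(max(prev, 1e-12), 1 - 1e-12)
    f0 = float(logit(prev))
    F = np.full(X.shape[0], f0)

    def deviance(F: np.ndarray) -> float:
        p = np.clip(expit(F), 1e-12, 1 - 1e-12)
        return float(-2 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))

    trees: list[_TreeNode] = []
    dev_path = [deviance(F)]
    for _ in range(n_trees):
        p = expit(F)
        resid = y - p
        hess = np.clip(p * (1 - p), 1e-10, None)

        def leaf_value(idx: np.ndarray) -> float:
            # Newton step for the logistic loss within the leaf
            num = (w[idx] * resid[idx]).sum()
            den = (w[idx] * hess[idx]).sum()
            return float(num / den) if den > 0 else 0.0

        tree = _grow_tree(X, resid, w, 0, tree_depth, min_node_weight,
                          leaf_value)
        F = F + learning_rate * _predict_tree(tree, X)
        trees.append(tree)
        dev_path.append(deviance(F))
    return GBMModel(design.variables, f0, trees, learning_rate, dev_path)


# ---------------------------------------------------------------------------
# Adapters and map prediction
# ---------------------------------------------------------------------------

@dataclass
class ModelAdapter:
    """Pluggable contract for external algorithms (RF, GAM, MaxEnt, FDA...).

    ``fit`` maps a SampleDesign to an opaque fitted object; ``predict``
    maps (object, X) to scores that must lie in [0, 1].
    """

    name: str
    fit: Callable[[SampleDesign], object]
    predict: Callable[[object, np.ndarray], np.ndarray]

    def __call__(self, design: SampleDesign) -> "AdapterModel":
        fitted = self.fit(design)
        return AdapterModel(self.name, design.variables, fitted, self.predict)


class AdapterModel(FittedModel):
    def __init__(self, name: str, variables: Sequence[str], fitted: object,
                 predict_fn: Callable[[object, np.ndarray], np.ndarray]):
        super().__init__(variables)
        self.algorithm = name
        self._fitted = fitted
        self._predict_fn = predict_fn

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.asarray(self._predict_fn(self._fitted,
                                          _check_X(X, len(self.variables))),
                         dtype=float)
        if out.min() < -1e-9 or out.max() > 1 + 1e-9:
            raise ValueError(f"adapter {self.algorithm!r} broke the [0,1] "
                             "score contract")
        return np.clip(out, 0.0, 1.0)


def predict_map(model: FittedModel, stack):
    """Cellwise model prediction over a covariate stack -> suitability Grid.

    Nodata in any used covariate propagates to the output.
    """
    from .grids import Grid

    missing = set(model.variables) - set(stack.names)
    if missing:
        raise ValueError(f"stack lacks variables: {sorted(missing)}")
    sub = stack.subset(model.variables)
    X, idx = sub.to_matrix()
    template = stack.template
    flat = np.full(template.nrows * template.ncols, np.nan)
    flat[idx] = model.predict(X)
    mask = sub.joint_valid_mask()
    return Grid(flat.reshape(template.shape), mask,
                template.cell_size, template.origin)
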