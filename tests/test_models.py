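"""Base SDM algorithms: GLM, SRE, CTA, GBM, adapters, map prediction."""

import numpy as np
import pytest

import sdmtransfer as st
from sdmtransfer.grids import CovariateStack, Grid
from sdmtransfer.models import (ModelAdapter, cta_root_split, fit_cta,
                                fit_gbm, fit_glm, fit_sre, predict_map)
from sdmtransfer.occurrences import SampleDesign


def design_from(X, y, w=None, names=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if w is None else np.asarray(w, dtype=float)
    names = names or [f"v{i}" for i in range(X.shape[1])]
    coords = np.zeros((len(y), 2))
    return SampleDesign(X, y, w, names, coords, np.full(len(y), -1))


class TestGLM:
    def test_two_cell_closed_form(self):
        # 2/10 presences at x=0, 8/10 at x=1 -> saturated logistic MLE
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.ones(2), np.zeros(8), np.ones(8), np.zeros(2)]
        m = fit_glm(design_from(x, y), terms="linear")
        assert np.isclose(m.coef[0], np.log(2 / 8), atol=1e-6)
        assert np.isclose(m.coef[1], np.log(16), atol=1e-6)

    def test_intercept_only_balanced_predicts_half(self):
        rng = np.random.default_rng(0)
        X = np.ones(40)  # constant covariate -> excluded -> intercept only
        y = np.r_[np.ones(20), np.zeros(20)]
        m = fit_glm(design_from(X, y), terms="linear")
        assert m.kept_columns.size == 0
        assert np.allclose(m.predict(np.ones((5, 1))), 0.5)

    def test_weighted_fit_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        eta = -0.5 + 1.2 * X[:, 0] - 0.8 * X[:, 1]
        y = (rng.random(300) < 1 / (1 + np.exp(-eta))).astype(float)
        w = np.where(y == 1, 1.0, 0.37)
        m = fit_glm(design_from(X, y, w), terms="linear")
        sm_fit = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial(),
                        freq_weights=w).fit()
        assert np.allclose(m.coef, sm_fit.params, atol=1e-5)

    def test_coefficient_recovery_within_3se(self):
        rng = np.random.default_rng(2)
        n = 2000
        X = rng.normal(size=(n, 2))
        beta = np.array([0.3, 1.0, -0.7])
        eta = beta[0] + X @ beta[1:]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_glm(design_from(X, y), terms="linear")
        # asymptotic SEs from the inverse Fisher information
        p = m.predict(X)
        Z = np.column_stack([np.ones(n), X])
        info = Z.T @ (Z * (p * (1 - p))[:, None])
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        assert np.all(np.abs(m.coef - beta) < 3 * se)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(UserWarning):
            m = fit_glm(design_from(x, y), terms="linear")
        assert m.separation

    def test_quadratic_terms_fit_curvature(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-2, 2, 800)
        eta = 1.0 - 2.0 * x ** 2
        y = (rng.random(800) < 1 / (1 + np.exp(-eta))).astype(float)
        m = fit_glm(design_from(x, y), terms="quadratic")
        pred = m.predict(np.array([[-2.0], [0.0], [2.0]]))
        assert pred[1] > pred[0] and pred[1] > pred[2]


class TestSRE:
    def test_envelope_membership(self):
        rng = np.random.default_rng(0)
        X = np.r_[rng.uniform(1, 100, 50), rng.uniform(0, 1, 50)]
        X[:2] = [1.0, 100.0]
        y = np.r_[np.ones(50), np.zeros(50)]
        m = fit_sre(design_from(X, y), alpha=0.0)
        assert m.predict(np.array([[50.0]]))[0] == 1.0
        assert m.predict(np.array([[101.0]]))[0] == 0.0

    def test_quantile_bounds_match_order_statistic_oracle(self):
        rng = np.random.default_rng(1)
        vals = np.sort(rng.normal(size=200))
        y = np.r_[np.ones(200), np.zeros(10)]
        X = np.r_[vals, rng.normal(size=10)]
        m = fit_sre(design_from(X, y), alpha=0.025)
        # linear-interpolation order statistic: q = v[k] + frac*(v[k+1]-v[k])
        def q(p):
            h = p * (len(vals) - 1)
            k = int(np.floor(h))
            return vals[k] + (h - k) * (vals[min(k + 1, len(vals) - 1)] - vals[k])
        assert np.isclose(m.lower[0], q(0.025))
        assert np.isclose(m.upper[0], q(0.975))

    def test_presence_coverage_union_bound(self, small_design):
        alpha = 0.025
        m = fit_sre(small_design, alpha=alpha)
        P = small_design.X[small_design.y == 1]
        frac_in = m.predict(P).mean()
        assert frac_in >= 1 - 2 * alpha * P.shape[1]

    def test_binary_predictions_only(self, small_design):
        m = fit_sre(small_design)
        out = m.predict(small_design.X)
        assert set(np.unique(out)) <= {0.0, 1.0}


class TestCTA:
    def test_perfect_separation_depth_one(self):
        x = np.r_[np.zeros(6), np.ones(6)]
        y = np.r_[np.zeros(6), np.ones(6)]
        m = fit_cta(design_from(x, y), max_depth=3)
        preds = m.predict(np.array([[0.0], [1.0]]))
        assert preds.tolist() == [0.0, 1.0]
        assert m.root.left.feature == -1 and m.root.right.feature == -1

    def test_depth_zero_predicts_prevalence(self):
        x = np.arange(10, dtype=float)
        y = np.r_[np.ones(5), np.zeros(5)]
        m = fit_cta(design_from(x, y), max_depth=0)
        assert np.allclose(m.predict(x[:, None]), 0.5)

    @staticmethod
    def exhaustive_root_split(d):
        """Enumerate every (variable, midpoint) split, minimize weighted
        Gini; ties -> lowest variable then lowest split value."""
        best = None
        W = d.weights.sum()
        for j in range(d.X.shape[1]):
            vals = np.unique(d.X[:, j])
            for lo, hi in zip(vals[:-1], vals[1:]):
                thr = (lo + hi) / 2
                left = d.X[:, j] <= thr
                gini = 0.0
                for m_ in (left, ~left):
                    wm = d.weights[m_].sum()
                    if wm == 0:
                        continue
                    p = (d.weights[m_] * d.y[m_]).sum() / wm
                    gini += wm / W * 2 * p * (1 - p)
                if best is None or gini < best[0] - 1e-12:
                    best = (gini, j, thr)
        return best

    def test_root_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(100):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(1, 4))
            X = rng.integers(0, 4, size=(n, k)).astype(float)
            y = rng.integers(0, 2, size=n).astype(float)
            w = rng.uniform(0.5, 2.0, size=n)
            if np.ptp(y) == 0:
                y[0] = 1 - y[0]
            d = design_from(X, y, w)
            got = cta_root_split(d)
            oracle = self.exhaustive_root_split(d)
            if got is None:
                assert oracle is None or oracle[0] >= self._root_gini(d) - 1e-12
                continue
            jg, tg = got
            go, jo, to = oracle
            # achieved impurity must equal the exhaustive minimum
            assert np.isclose(self._split_gini(d, jg, tg), go, atol=1e-10)

    @staticmethod
    def _split_gini(d, j, thr):
        W = d.weights.sum()
        left = d.X[:, j] <= thr
        gini = 0.0
        for m_ in (left, ~left):
            wm = d.weights[m_].sum()
            if wm == 0:
                continue
            p = (d.weights[m_] * d.y[m_]).sum() / wm
            gini += wm / W * 2 * p * (1 - p)
        return gini

    @staticmethod
    def _root_gini(d):
        p = (d.weights * d.y).sum() / d.weights.sum()
        return 2 * p * (1 - p)

    def test_training_auc_at_least_chance(self, small_design):
        m = fit_cta(small_design)
        pred = m.predict(small_design.X)
        assert st.auc(pred[small_design.y == 1],
                      pred[small_design.y == 0]) >= 0.5


class TestGBM:
    def test_zero_trees_constant_prevalence(self):
        x = np.arange(20, dtype=float)
        y = np.r_[np.ones(5), np.zeros(15)]
        m = fit_gbm(design_from(x, y), n_trees=0)
        assert np.allclose(m.predict(x[:, None]), 0.25)

    def test_separable_training_auc_one(self):
        x = np.arange(40, dtype=float)
        y = (x >= 20).astype(float)
        m = fit_gbm(design_from(x, y), n_trees=100)
        pred = m.predict(x[:, None])
        assert st.auc(pred[y == 1], pred[y == 0]) == 1.0

    def test_training_deviance_nonincreasing(self, small_design):
        m = fit_gbm(small_design, n_trees=40)
        dev = np.asarray(m.train_deviance)
        assert np.all(np.diff(dev) <= 1e-9)

    def test_deterministic(self, small_design):
        a = fit_gbm(small_design, n_trees=20)
        b = fit_gbm(small_design, n_trees=20)
        assert np.array_equal(a.predict(small_design.X),
                              b.predict(small_design.X))


class TestContracts:
    @pytest.mark.parametrize("fitter", [
        lambda d: fit_glm(d),
        lambda d: fit_sre(d),
        lambda d: fit_cta(d),
        lambda d: fit_gbm(d, n_trees=30),
    ])
    def test_predictions_within_unit_interval(self, small_design, fitter):
        m = fitter(small_design)
        out = m.predict(small_design.X)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_adapter_contract_enforced(self, small_design):
        bad = ModelAdapter("bad", fit=lambda d: None,
                           predict=lambda f, X: np.full(X.shape[0], 2.0))
        model = bad(small_design)
        with pytest.raises(ValueError):
            model.predict(small_design.X)

    def test_adapter_random_forest_plugs_in(self, small_design):
        from sklearn.ensemble import RandomForestClassifier

        rf = ModelAdapter(
            "rf",
            fit=lambda d: RandomForestClassifier(
                n_estimators=20, random_state=0).fit(
                    d.X, d.y, sample_weight=d.weights),
            predict=lambda f, X: f.predict_proba(X)[:, 1])
        model = rf(small_design)
        out = model.predict(small_design.X)
        assert out.shape == (len(small_design.y),)
        assert out.min() >= 0 and out.max() <= 1

    def test_serialization_roundtrip(self, small_design, tmp_path):
        import json

        m = fit_glm(small_design)
        p = tmp_path / "glm.json"
        m.save_json(p)
        d = json.loads(p.read_text())
        assert d["algorithm"] == "glm"
        assert np.allclose(d["coef"], m.coef)


class TestPredictMap:
    def test_constant_glm_constant_map(self, small_landscape, small_design):
        _, stack, _, _ = small_landscape
        x = np.ones(40)
        y = np.r_[np.ones(20), np.zeros(20)]
        m = fit_glm(design_from(x, y, names=["natural_prop"]),
                    terms="linear")
        g = predict_map(m, stack)
        assert np.allclose(g.values[g.valid_mask], 0.5)

    def test_sre_map_binary(self, small_landscape, small_design):
        _, stack, _, _ = small_landscape
        m = fit_sre(small_design)
        g = predict_map(m, stack)
        assert set(np.unique(g.values[g.valid_mask])) <= {0.0, 1.0}

    def test_pointwise_vs_map_consistency(self, small_landscape):
        cfg, stack, regions, truth = small_landscape
        occ = st.sample_presences(truth, 100, 5)
        bg = st.sample_background(stack.template, 200, 6, regions=regions)
        d = st.build_design(occ, bg, stack)
        m = fit_glm(d)
        g = predict_map(m, stack)
        # at cell centers the map value equals a direct pointwise predict
        row, col = g.cell_of(occ.x, occ.y)
        cx, cy = g.cell_centers(row, col)
        X = stack.extract(cx, cy, m.variables)
        assert np.allclose(g.extract(cx, cy), m.predict(X))

    def test_missing_variable_error(self, small_landscape):
        _, stack, _, _ = small_landscape
        x = np.arange(10, dtype=float)
        y = np.r_[np.ones(5), np.zeros(5)]
        m = fit_glm(design_from(x, y, names=["not_in_stack"]))
        with pytest.raises(ValueError):
            predict_map(m, stack)
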