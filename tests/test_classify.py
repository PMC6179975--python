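"""Multinomial logit, AIC selection, LR tests, pseudo-R2, forest importance."""

import numpy as np
import pandas as pd
import pytest

import ricotype as rt
from ricotype.classify import SeparationWarning, softmax_probabilities


def simulate_mlr(beta, n, seed):
    """Draw (panel, labels) from a multinomial logit with known beta."""
    rng = np.random.default_rng(seed)
    p = beta.shape[0] - 1
    x = rng.normal(0, 1, (n, p))
    xmat = np.column_stack([np.ones(n), x])
    probs = softmax_probabilities(xmat @ beta)
    u = rng.random(n)
    y = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1) + 1
    panel = pd.DataFrame(x, columns=[f"v{j}" for j in range(p)])
    return panel, pd.Series(y, index=panel.index)


class TestScore:
    def test_inner_product(self):
        assert rt.mlr_score(np.array([1.0, 0.5]), np.array([1.0, 2.0])) == 2.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rt.mlr_score(np.ones(3), np.ones(2))

    def test_softmax_normalisation(self):
        rng = np.random.default_rng(0)
        probs = softmax_probabilities(rng.normal(size=(20, 2)))
        assert probs.sum(axis=1) == pytest.approx(np.ones(20))
        assert (probs > 0).all()

    def test_zero_scores_uniform(self):
        probs = softmax_probabilities(np.zeros((1, 2)))
        assert probs[0] == pytest.approx([1 / 3] * 3)


class TestFit:
    def test_intercept_only_deviance_closed_form(self):
        """-2 log L of the intercept-only model with class sizes 114/70/27
        equals the multinomial closed form, 405.87."""
        labels = pd.Series([1] * 114 + [2] * 70 + [3] * 27)
        m = rt.fit_mlr(pd.DataFrame(index=labels.index), labels)
        assert m.deviance == pytest.approx(405.87, abs=0.005)
        assert m.deviance == pytest.approx(m.null_deviance, abs=1e-6)

    def test_aic_identity_vs_direct_loglikelihood(self):
        """AIC = deviance + 2 x free parameters, with the deviance verified
        by direct per-sample log-likelihood summation from the fitted
        coefficients."""
        beta = np.array([[0.2, -0.3], [0.9, 0.1], [-0.5, 0.8], [0.0, -0.6]])
        panel, y = simulate_mlr(beta, 400, seed=11)
        m = rt.fit_mlr(panel, y)
        xmat = np.column_stack([np.ones(len(panel)), panel.to_numpy()])
        probs = softmax_probabilities(xmat @ m.params.to_numpy())
        order = [m.reference] + [c for c in m.classes if c != m.reference]
        col = {c: i for i, c in enumerate(order)}
        ll = float(np.log(probs[np.arange(len(y)), [col[c] for c in y]]).sum())
        assert m.deviance == pytest.approx(-2 * ll, rel=1e-8)
        assert m.aic == pytest.approx(-2 * ll + 2 * m.n_free_params, rel=1e-8)

    def test_parameter_recovery_single_seed(self):
        beta = np.array([[0.3, -0.2], [1.0, 0.5], [-0.8, 0.7]])
        panel, y = simulate_mlr(beta, 4000, seed=2)
        m = rt.fit_mlr(panel, y)
        assert np.abs(m.params.to_numpy() - beta).max() < 0.25

    def test_probabilities_sum_to_one(self, selected_model):
        proba = selected_model.predict_proba()
        assert proba.sum(axis=1).to_numpy() == pytest.approx(np.ones(len(proba)))

    def test_separation_warning(self):
        """A binary predictor that perfectly splits two classes drives the
        coefficients toward infinity and must be flagged."""
        x = pd.DataFrame({"b": [0.0] * 20 + [1.0] * 20})
        y = pd.Series([1] * 20 + [2] * 20)
        with pytest.warns(SeparationWarning):
            rt.fit_mlr(x, y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"a": rng.normal(size=60)})
        x["b"] = 2 * x["a"]
        y = pd.Series(rng.integers(1, 3, 60), index=x.index)
        with pytest.raises(ValueError, match="collinear"):
            rt.fit_mlr(x, y)


class TestSelection:
    def test_strong_predictor_always_enters(self):
        """A standardized effect of 2 among pure-noise predictors is found."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 500
            y = pd.Series(rng.integers(1, 4, n))
            x = pd.DataFrame(rng.normal(size=(n, 10)),
                             columns=[f"v{j}" for j in range(10)])
            x["v0"] += 2.0 * (y == 2)
            m = rt.forward_aic_select(x, y)
            hits += int("v0" in m.variables)
        assert hits == 5

    def test_never_worse_than_intercept_only(self, default_panel):
        panel, truth = default_panel
        m = rt.forward_aic_select(panel[["PT", "HRD", "SPR"]], truth)
        null = rt.fit_mlr(panel[[]], truth)
        assert m.aic <= null.deviance + 2 * null.n_free_params + 1e-9


class TestLRAndFit:
    def test_lr_equals_explicit_nested_deviance_difference(self):
        beta = np.array([[0.1, -0.2], [0.7, 0.4], [-0.6, 0.5]])
        panel, y = simulate_mlr(beta, 300, seed=4)
        full = rt.fit_mlr(panel, y)
        reduced = rt.fit_mlr(panel[["v0"]], y)
        chi2, df, p = rt.lr_test(full, "v1")
        assert chi2 == pytest.approx(reduced.deviance - full.deviance, abs=1e-6)
        assert df == 2
        assert 0 <= p <= 1

    def test_pseudo_r2_worked_example(self):
        """The study deviances 405.87 -> 66.20 over n = 211 give McFadden
        0.84, Cox & Snell 0.80, Cragg & Uhler 0.94."""
        r2 = rt.pseudo_r2(405.87, 66.20, 211)
        assert round(r2["mcfadden"], 2) == 0.84
        assert round(r2["cox_snell"], 2) == 0.80
        assert round(r2["cragg_uhler"], 2) == 0.94

    def test_null_model_pseudo_r2_zero(self):
        r2 = rt.pseudo_r2(400.0, 400.0, 200)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in r2.values())

    def test_accuracy_counting(self):
        labels = pd.Series([1] * 25 + [2] * 25)
        x = pd.DataFrame({"s": (labels == 2).astype(float) * 4 - 2})
        x.iloc[:3, 0] = 2.0  # three class-1 samples look like class 2
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            m = rt.fit_mlr(x, labels)
        assert m.accuracy() == pytest.approx(94.0)

    def test_model_chi2_identity(self, selected_model):
        fit = rt.goodness_of_fit(selected_model)
        assert fit.model_chi2 == pytest.approx(
            fit.null_deviance - fit.deviance, abs=1e-9)
        assert 0 <= fit.pseudo_r2["mcfadden"] <= 1


class TestForest:
    def test_pure_noise_importance_near_zero(self):
        rng = np.random.default_rng(0)
        n = 200
        y = pd.Series(rng.integers(1, 4, n))
        x = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        imp = rt.rf_importance(x, y, n_trees=150, seed=0)
        assert np.abs(imp.raw.to_numpy()).max() < 0.05

    def test_bitwise_reproducibility(self):
        rng = np.random.default_rng(1)
        n = 150
        y = pd.Series(rng.integers(1, 3, n))
        x = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        x["a"] += 1.5 * (y == 2)
        a = rt.rf_importance(x, y, n_trees=100, seed=42)
        b = rt.rf_importance(x, y, n_trees=100, seed=42)
        assert a.raw.equals(b.raw)
        assert a.standardized.equals(b.standardized)
        assert a.oob_error == b.oob_error

    def test_single_class_rejected(self):
        x = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError):
            rt.rf_importance(x, pd.Series([1] * 10), n_trees=10)
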