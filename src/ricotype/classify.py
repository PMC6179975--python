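"""Cluster classification: multinomial logit, forward-AIC selection, forests.

The classification model is a multinomial logistic regression: each sample i
gets a linear score f(X_i, k) = beta_k . X_i per cluster k, with the
reference cluster's score fixed at 0 and class probabilities given by the
softmax over scores.  Variables enter by forward stepwise selection under
AIC; retained variables are tested by likelihood-ratio tests, the fit is
summarised by deviance-based pseudo-R-squared statistics and resubstitution
accuracy, and variable importance per cluster comes from out-of-bag
permutation importance of a 500-tree random forest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MLRModel",
    "FitReport",
    "ImportanceResult",
    "SeparationWarning",
    "mlr_score",
    "softmax_probabilities",
    "fit_mlr",
    "forward_aic_select",
    "lr_test",
    "pseudo_r2",
    "goodness_of_fit",
    "rf_importance",
]


class SeparationWarning(UserWarning):
    """The likelihood is maximised at (near-)infinite coefficients."""


def mlr_score(beta: np.ndarray, x: np.ndarray) -> float:
    """Linear score beta . x for one cluster (intercept prepended in beta)."""
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    if beta.shape != x.shape:
        raise ValueError(f"dimension mismatch: beta {beta.shape} vs x {x.shape}")
    return float(beta @ x)


def softmax_probabilities(scores: np.ndarray) -> np.ndarray:
    """Class probabilities from per-cluster scores (reference score = 0).

    ``scores`` has one column per non-reference cluster; a zero column for
    the reference is prepended before the softmax.
    """
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    full = np.hstack([np.zeros((s.shape[0], 1)), s])
    full = full - full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class MLRModel:
    """A fitted multinomial logit with per-cluster coefficient vectors.

    ``params``/``bse`` are (intercept + predictors) x (non-reference
    clusters).  ``deviance`` is -2 log L of the fit, ``null_deviance`` that
    of the intercept-only model on the same samples.  The design is kept so
    likelihood-ratio refits can reuse it.
    """

    reference: int
    classes: list[int]
    variables: list[str]
    params: pd.DataFrame
    bse: pd.DataFrame
    deviance: float
    null_deviance: float
    converged: bool
    n_obs: int
    design: pd.DataFrame = field(repr=False)
    labels: pd.Series = field(repr=False)

    @property
    def n_free_params(self) -> int:
        return (len(self.classes) - 1) * (len(self.variables) + 1)

    @property
    def aic(self) -> float:
        return self.deviance + 2 * self.n_free_params

    @property
    def llf(self) -> float:
        return -self.deviance / 2

    def predict_proba(self, panel: pd.DataFrame | None = None) -> pd.DataFrame:
        """Softmax class probabilities; columns ordered reference first."""
        x = self.design if panel is None else panel[self.variables]
        xmat = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
        scores = xmat @ self.params.to_numpy()
        proba = softmax_probabilities(scores)
        order = [self.reference] + [c for c in self.classes if c != self.reference]
        return pd.DataFrame(proba, index=x.index, columns=order)

    def predict(self, panel: pd.DataFrame | None = None) -> pd.Series:
        proba = self.predict_proba(panel)
        return proba.idxmax(axis=1).rename("cluster")

    def accuracy(self, panel: pd.DataFrame | None = None,
                 labels: pd.Series | None = None) -> float:
        """Resubstitution classification accuracy in percent."""
        y = self.labels if labels is None else labels
        pred = self.predict(panel)
        return float((pred.to_numpy() == y.to_numpy()).mean() * 100)


def _check_design(x: pd.DataFrame) -> None:
    xmat = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(xmat)
    if rank < xmat.shape[1]:
        # identify offending columns by dropping one at a time
        bad = []
        for j, col in enumerate(x.columns):
            reduced = np.delete(xmat, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def fit_mlr(
    panel: pd.DataFrame,
    labels: pd.Series,
    reference: int = 1,
    tol: float = 1e-8,
    max_iter: int = 500,
    start_params: np.ndarray | None = None,
) -> MLRModel:
    """Maximum-likelihood multinomial logit fit (Newton iterations).

    ``panel`` holds the predictors (may have zero columns for an
    intercept-only model); ``labels`` the 1-based cluster memberships.
    Standard errors come from the observed information matrix.  Emits a
    :class:`SeparationWarning` when coefficients diverge (quasi-separated
    data); the capped-iteration fit is still returned.  ``start_params``
    ((intercept + predictors) x non-reference clusters) warm-starts the
    optimiser — useful for nested refits on near-separated data.
    """
    labels = labels.reindex(panel.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all panel samples")
    classes = sorted(labels.unique().tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 clusters")
    if reference not in classes:
        raise ValueError(f"reference cluster {reference} not among {classes}")
    n, p = len(labels), len(panel.columns)
    if n <= (len(classes) - 1) * (p + 1):
        raise ValueError("more free parameters than observations")
    _check_design(panel)

    # encode so the reference cluster is category 0
    order = [reference] + [c for c in classes if c != reference]
    codes = labels.map({c: i for i, c in enumerate(order)}).to_numpy()
    xmat = np.column_stack([np.ones(n), panel.to_numpy(dtype=float)])

    attempts = [
        dict(method="newton", maxiter=max_iter, tol=tol),
        dict(method="bfgs", maxiter=max_iter, gtol=tol),
        dict(method="lbfgs", maxiter=max_iter, pgtol=tol),
        dict(method="nm", maxiter=4 * max_iter, xatol=1e-6, fatol=1e-6),
    ]
    if start_params is not None:
        start = np.asarray(start_params, dtype=float)
        if start.shape != (p + 1, len(classes) - 1):
            raise ValueError("start_params shape must be (p + 1, n_classes - 1)")
        for kwargs in attempts:
            kwargs["start_params"] = start.ravel(order="F")
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels convergence chatter
        model = sm.MNLogit(codes, xmat)
        for kwargs in attempts:
            try:
                cand = model.fit(disp=0, **kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.all(np.isfinite(cand.params)) and np.isfinite(cand.llf):
                res = cand
                break
    if res is None:
        raise ValueError("multinomial logit fit diverged to non-finite estimates")
    converged = bool(res.mle_retvals.get("converged", True))

    rows = ["intercept"] + list(panel.columns)
    cols = order[1:]
    params = pd.DataFrame(np.asarray(res.params), index=rows, columns=cols)
    with np.errstate(invalid="ignore"):
        bse = pd.DataFrame(np.asarray(res.bse), index=rows, columns=cols)

    if not converged or np.max(np.abs(params.to_numpy())) > 25:
        warnings.warn(
            "possible (quasi-)separation: coefficients diverged or fit did not converge",
            SeparationWarning, stacklevel=2)

    # intercept-only -2LL in closed form: class proportions
    counts = np.bincount(codes)[: len(classes)]
    null_dev = -2 * float(np.sum(counts * np.log(counts / n)))

    return MLRModel(
        reference=reference, classes=classes, variables=list(panel.columns),
        params=params, bse=bse, deviance=float(-2 * res.llf),
        null_deviance=null_dev, converged=converged, n_obs=n,
        design=panel.copy(), labels=labels.copy(),
    )


def forward_aic_select(
    panel: pd.DataFrame,
    labels: pd.Series,
    reference: int = 1,
    tol: float = 1e-8,
    max_iter: int = 500,
    verbose: bool = False,
) -> MLRModel:
    """Forward stepwise selection minimising AIC, from the intercept-only model.

    At each step the candidate whose addition gives the lowest AIC enters
    (ties break toward the earlier column); selection stops when no addition
    lowers the AIC.  Returns the final refit with the selected variables in
    entry order.
    """
    selected: list[str] = []
    current = fit_mlr(panel[selected], labels, reference, tol, max_iter)
    best_aic = current.aic
    remaining = list(panel.columns)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        while remaining:
            trials = []
            for var in remaining:
                try:
                    m = fit_mlr(panel[selected + [var]], labels, reference, tol, max_iter)
                except (ValueError, np.linalg.LinAlgError):
                    continue
                if np.isfinite(m.aic):
                    trials.append((m.aic, var, m))
            if not trials:
                break
            aic_new, var_new, model_new = min(trials, key=lambda t: t[0])
            if aic_new >= best_aic:
                break
            selected.append(var_new)
            remaining.remove(var_new)
            best_aic, current = aic_new, model_new
            if verbose:
                print(f"  + {var_new:<14s} AIC = {aic_new:.2f}")
    return current


def lr_test(model: MLRModel, variable: str) -> tuple[float, int, float]:
    """Likelihood-ratio test for one variable in a fitted model.

    Refits without the variable; chi2 is the deviance difference, df the
    number of non-reference clusters, p the chi2 upper tail.
    """
    if variable not in model.variables:
        raise ValueError(f"{variable!r} not in model")
    rest = [v for v in model.variables if v != variable]
    df = len(model.classes) - 1
    start = model.params.loc[["intercept"] + rest].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        try:
            reduced = fit_mlr(model.design[rest], model.labels, model.reference,
                              start_params=start)
        except ValueError:
            warnings.warn(f"LR refit without {variable!r} did not converge",
                          UserWarning, stacklevel=2)
            return float("nan"), df, float("nan")
    chi2 = max(reduced.deviance - model.deviance, 0.0)
    p = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, p


def lr_test_table(model: MLRModel) -> pd.DataFrame:
    """LR chi2/df/p for every variable in the model, in entry order."""
    rows = []
    for v in model.variables:
        chi2, df, p = lr_test(model, v)
        rows.append({"variable": v, "lr_chisq": chi2, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("variable")


def pseudo_r2(null_deviance: float, deviance: float, n: int) -> dict[str, float]:
    """McFadden, Cox & Snell, and Cragg & Uhler (Nagelkerke) pseudo-R2.

    McFadden = 1 - D_f/D_0; Cox & Snell = 1 - exp(-chi2/n) with
    chi2 = D_0 - D_f; Cragg & Uhler rescales Cox & Snell by its maximum
    1 - exp(-D_0/n).
    """
    if null_deviance <= 0:
        raise ValueError("null deviance must be positive")
    chi2 = null_deviance - deviance
    cox_snell = 1 - np.exp(-chi2 / n)
    max_cs = 1 - np.exp(-null_deviance / n)
    return {
        "mcfadden": 1 - deviance / null_deviance,
        "cox_snell": float(cox_snell),
        "cragg_uhler": float(cox_snell / max_cs),
    }


@dataclass
class FitReport:
    """Goodness-of-fit summary of a multinomial logit."""

    null_deviance: float
    deviance: float
    model_chi2: float
    df: int
    p: float
    pseudo_r2: dict[str, float]
    accuracy_pct: float
    aic: float
    n_obs: int


def goodness_of_fit(model: MLRModel) -> FitReport:
    """Model chi2, pseudo-R2 statistics and resubstitution accuracy."""
    chi2 = model.null_deviance - model.deviance
    df = (len(model.classes) - 1) * len(model.variables)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    return FitReport(
        null_deviance=model.null_deviance,
        deviance=model.deviance,
        model_chi2=float(chi2),
        df=df,
        p=p,
        pseudo_r2=pseudo_r2(model.null_deviance, model.deviance, model.n_obs),
        accuracy_pct=model.accuracy(),
        aic=model.aic,
        n_obs=model.n_obs,
    )


@dataclass
class ImportanceResult:
    """Per-cluster OOB permutation importance of a random forest.

    ``raw`` holds the mean over trees of the OOB class-wise accuracy
    decrease after permuting each variable; ``standardized`` divides each
    mean by its standard error over trees (the convention of standard
    forest importance output).  Columns: one per cluster plus ``overall``.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame
    oob_error: float
    n_trees: int
    vars_per_split: int
    seed: int

    def ranking(self, cluster) -> list[str]:
        """Variables by decreasing standardized importance for a cluster."""
        return list(self.standardized[cluster].sort_values(ascending=False).index)


def rf_importance(
    panel: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    vars_per_split: int = 3,
    seed: int = 20180245,
) -> ImportanceResult:
    """Per-cluster permutation importance from a bootstrap forest.

    Fits ``n_trees`` CART trees on bootstrap resamples with
    ``vars_per_split`` variables considered at each split.  For each tree
    and variable, the variable's values are permuted among that tree's
    out-of-bag samples and the per-class and overall accuracy decreases are
    recorded; importances are tree-averaged and standardized by their
    standard error.  Reproducible bit-for-bit under a fixed seed.
    """
    x = panel.to_numpy(dtype=float)
    y = labels.reindex(panel.index).to_numpy()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes for a forest")
    n, p = x.shape
    vars_per_split = min(vars_per_split, p)

    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features=vars_per_split),
        n_estimators=n_trees, bootstrap=True, random_state=seed, n_jobs=1)
    forest.fit(x, y)
    # base trees are fit on 0..K-1 encoded labels; work in that space
    y_enc = np.searchsorted(forest.classes_, y)

    rng = np.random.default_rng(seed)
    cols = list(forest.classes_) + ["overall"]
    drops = np.full((n_trees, p, len(cols)), np.nan)
    votes = np.zeros((n, classes.size))
    vote_counts = np.zeros(n)

    for t_idx, (tree, inbag) in enumerate(zip(forest.estimators_, forest.estimators_samples_)):
        oob = np.setdiff1d(np.arange(n), inbag)
        if oob.size == 0:
            continue
        x_oob, y_oob = x[oob], y_enc[oob]
        base_pred = tree.predict(x_oob)
        # accumulate OOB votes for the forest-level OOB error
        for ci in range(classes.size):
            votes[oob[base_pred == ci], ci] += 1
        vote_counts[oob] += 1

        class_masks = [(y_oob == ci) for ci in range(classes.size)]
        base_acc = [
            (base_pred[m] == ci).mean() if m.any() else np.nan
            for ci, m in enumerate(class_masks)
        ]
        base_all = (base_pred == y_oob).mean()
        for j in range(p):
            x_perm = x_oob.copy()
            x_perm[:, j] = x_perm[rng.permutation(oob.size), j]
            perm_pred = tree.predict(x_perm)
            for ci, m in enumerate(class_masks):
                if m.any():
                    drops[t_idx, j, ci] = base_acc[ci] - (perm_pred[m] == ci).mean()
            drops[t_idx, j, -1] = base_all - (perm_pred == y_oob).mean()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(drops, axis=0)
        sd = np.nanstd(drops, axis=0, ddof=1)
        used = np.sum(~np.isnan(drops), axis=0)
        se = sd / np.sqrt(np.maximum(used, 1))
        standardized = np.where(se > 0, mean / se, mean)

    raw = pd.DataFrame(mean, index=panel.columns, columns=cols)
    std = pd.DataFrame(standardized, index=panel.columns, columns=cols)

    seen = vote_counts > 0
    oob_pred = np.argmax(votes[seen], axis=1)
    oob_error = float((oob_pred != y_enc[seen]).mean())

    return ImportanceResult(raw=raw, standardized=std, oob_error=oob_error,
                            n_trees=n_trees, vars_per_split=vars_per_split, seed=seed)
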