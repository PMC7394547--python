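"""State discrimination: balanced leave-one-out LDA and the two-predictor GLM.

The LDA protocol subsamples every class to the minority-class count, then
runs leave-one-out cross-validation with a pooled-covariance linear
discriminant; the whole procedure is repeated (default 50 times) with fresh
subsamples and performance reported as percent correct.  Accuracies are
logit-transformed before averaging across channels, following the
convention that proportions should be made unbounded before linear
aggregation.

The general linear model predicts the state from z-scored spectral slope
and slow-oscillation power (<1.25 Hz) plus their interaction, and
attributes unique explained variance to each term via eta squared
(Type II sums of squares by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "ClassifierResult",
    "GLMResult",
    "lda_balanced_cv",
    "logit_transform",
    "inverse_logit",
    "glm_state_model",
]

LOGIT_EPS = 1e-4


@dataclass
class ClassifierResult:
    accuracy: float  # percent correct, mean over repeats
    logit_accuracy: float  # logit of the mean proportion
    per_repeat: np.ndarray  # percent correct per repeat
    n_repeats: int
    chance_level: float  # percent


@dataclass
class GLMResult:
    eta_squared: dict[str, float]
    coefficients: dict[str, float]
    residual_variance: float
    ss_type: int


def lda_balanced_cv(features: np.ndarray, labels: np.ndarray,
                    n_repeats: int = 50, seed: int = 0) -> ClassifierResult:
    """Balanced leave-one-out LDA accuracy (percent correct).

    Each repeat subsamples every class to the minority count and holds each
    remaining trial out once.  A singular pooled covariance is
    ridge-regularized (epsilon recorded on the estimator via shrinkage).
    Works for 1-D features (slope or SO power) and for 2 or 3 classes
    (chance 50% / 33%).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 trials per class")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    per_repeat = np.empty(n_repeats)
    for rep in range(n_repeats):
        idx = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
            for c in classes
        ])
        Xb, yb = X[idx], y[idx]
        assert all(np.sum(yb == c) == n_min for c in classes)
        correct = 0
        for i in range(len(yb)):
            mask = np.ones(len(yb), dtype=bool)
            mask[i] = False
            clf = LinearDiscriminantAnalysis(solver="lsqr")
            try:
                clf.fit(Xb[mask], yb[mask])
            except np.linalg.LinAlgError:
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
                clf.fit(Xb[mask], yb[mask])
            correct += int(clf.predict(Xb[i : i + 1])[0] == yb[i])
        per_repeat[rep] = 100.0 * correct / len(yb)
    acc = float(per_repeat.mean())
    return ClassifierResult(
        accuracy=acc,
        logit_accuracy=logit_transform(acc / 100.0),
        per_repeat=per_repeat,
        n_repeats=n_repeats,
        chance_level=100.0 / classes.size,
    )


def logit_transform(p: float) -> float:
    """ln(p / (1 - p)), with p clipped to [eps, 1 - eps], eps = 1e-4."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    p = min(max(p, LOGIT_EPS), 1.0 - LOGIT_EPS)
    return float(np.log(p / (1.0 - p)))


def inverse_logit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def glm_state_model(state: np.ndarray, slope: np.ndarray, so_power: np.ndarray,
                    include_interaction: bool = True, ss_type: int = 2) -> GLMResult:
    """Linear model state ~ slope + so + slope:so on z-scored predictors.

    ``state`` is a binary (0/1) outcome per trial.  Eta squared per term is
    that term's sum of squares divided by the total sum of squares under the
    requested decomposition (Type II default; 1 and 3 available).
    """
    state = np.asarray(state, dtype=float)
    slope = np.asarray(slope, dtype=float)
    so_power = np.asarray(so_power, dtype=float)
    if state.size < 10:
        raise ValueError("need at least 10 trials")
    if slope.std() == 0 or so_power.std() == 0:
        raise ValueError("constant predictor")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    df = pd.DataFrame({"state": state, "slope": z(slope), "so": z(so_power)})
    formula = "state ~ slope + so"
    if include_interaction:
        formula += " + slope:so"
    fit = smf.ols(formula, data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    anova = sm.stats.anova_lm(fit, typ=ss_type)
    ss_total = float(np.sum((state - state.mean()) ** 2))
    eta = {}
    for term in anova.index:
        if term in ("Residual", "Intercept"):
            continue
        eta[term.replace(":", "_x_")] = float(anova.loc[term, "sum_sq"] / ss_total)
    return GLMResult(
        eta_squared=eta,
        coefficients={k: float(v) for k, v in fit.params.items()},
        residual_variance=float(fit.mse_resid),
        ss_type=ss_type,
    )
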