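"""Logistic regression of disease status on functional PC scores.

The functional generalized linear model with logit link,

    ln(pi_i / (1 - pi_i)) = beta_0 + sum_j gamma_ij beta_1j
                                   + sum_l tau_il beta_2l,

regresses case/control status on the FPC scores of the thermogram curves
(gamma) and optionally of their first-derivative "velocity" curves (tau).
Inference is Wald-based: standard errors from the observed information,
odds ratios exp(beta) with 95% CI exp(beta ± 1.96 se), matching the usual
GLM summary layout.  Subjects are classified as cases when the predicted
probability strictly exceeds the cutoff (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import ParameterError, ValidationError
from .fpca import FPCAResult


@dataclass
class FGLMFit:
    """Fitted score-logistic model with Wald inference."""

    intercept: float
    coefs: np.ndarray
    std_errors: np.ndarray        # incl. intercept at position 0
    p_values: np.ndarray          # incl. intercept at position 0
    odds_ratios: np.ndarray       # per score column
    or_ci: np.ndarray             # (J, 2) 95% CI bounds
    score_columns: list[str]
    separation: bool = False
    _params: np.ndarray = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        """Full parameter vector (intercept first)."""
        return self._params

    def coef_table(self) -> pd.DataFrame:
        """Summary table: Estimate, Std. Error, OR (95% CI), p-value."""
        rows = ["Intercept"] + list(self.score_columns)
        est = np.r_[self.intercept, self.coefs]
        ors = np.r_[np.exp(self.intercept), self.odds_ratios]
        lo = np.r_[np.exp(self.intercept - 1.96 * self.std_errors[0]),
                   self.or_ci[:, 0]]
        hi = np.r_[np.exp(self.intercept + 1.96 * self.std_errors[0]),
                   self.or_ci[:, 1]]
        return pd.DataFrame({
            "Coefficient": rows,
            "Estimate": est,
            "Std. Error": self.std_errors,
            "OR (95% CI)": [f"{o:.2f} ({l:.2f}, {h:.2f})"
                            for o, l, h in zip(ors, lo, hi)],
            "p-value": self.p_values,
        })


@dataclass
class CompositeCurveResult:
    """Representative case/control curves from the significant harmonics."""

    plus_curve: np.ndarray
    minus_curve: np.ndarray
    predicted_prob_plus: float
    predicted_prob_minus: float
    significant: list[int]        # 1-based PC indices
    signs: np.ndarray             # sign(beta_j) on the significant PCs


def fit_fglm(scores: np.ndarray, status, columns=None) -> FGLMFit:
    """Maximum-likelihood logistic fit of status on score columns.

    Perfect separation is flagged in ``separation`` (coefficients are still
    reported, with a warning) rather than raising.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    status = np.asarray(status, dtype=float)
    n, J = scores.shape
    if len(status) != n:
        raise ValidationError("status length must match score rows")
    if n <= J + 1:
        raise ValidationError(
            f"need n > number of predictors + 1 (n={n}, predictors={J})")
    if np.any(scores.std(axis=0) == 0):
        raise ValidationError("constant score column in design")
    if columns is None:
        columns = [f"PC {j + 1}" for j in range(J)]

    X = sm.add_constant(scores, has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(status, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        for wmsg in caught:
            if "separat" in str(wmsg.message).lower():
                separation = True
    probs = res.predict(X)
    eps = 1e-10
    if not separation:
        # flat likelihood beyond machine range: fitted probs are all 0/1
        hard = (probs < eps) | (probs > 1 - eps)
        if hard.all() or np.any(np.abs(res.params) > 1e3):
            separation = True
    if separation:
        warnings.warn("perfect separation detected; coefficients are "
                      "unstable", stacklevel=2)

    params = np.asarray(res.params)
    se = np.asarray(res.bse)
    p = np.asarray(res.pvalues)
    coefs = params[1:]
    with np.errstate(over="ignore"):  # inf CI bounds under separation are fine
        return FGLMFit(
            intercept=float(params[0]),
            coefs=coefs,
            std_errors=se,
            p_values=p,
            odds_ratios=np.exp(coefs),
            or_ci=np.column_stack([np.exp(coefs - 1.96 * se[1:]),
                                   np.exp(coefs + 1.96 * se[1:])]),
            score_columns=list(columns),
            separation=separation,
            _params=params,
        )


def predict_status(fit: FGLMFit, scores_new: np.ndarray, cutoff: float = 0.5):
    """Predicted probabilities and hard labels (case iff prob > cutoff)."""
    scores_new = np.atleast_2d(np.asarray(scores_new, dtype=float))
    if scores_new.shape[1] != len(fit.coefs):
        raise ValidationError(
            f"expected {len(fit.coefs)} score columns, got {scores_new.shape[1]}")
    eta = fit.intercept + scores_new @ fit.coefs
    probs = expit(eta)
    labels = (probs > cutoff).astype(int)
    return probs, labels


def composite_curves(fpca: FPCAResult, fit: FGLMFit,
                     alpha: float = 0.05) -> CompositeCurveResult:
    """Representative curves from the statistically significant harmonics.

    The "plus" curve adds sign(beta_j) * sqrt(mu_j) * xi_j(t) to the mean for
    every PC with Wald p < alpha (pushing each significant score one SD in
    the case direction); the "minus" curve uses the opposite signs.  The
    returned probabilities run those two synthetic score vectors through the
    fitted model.
    """
    J = len(fit.coefs)
    if J > fpca.J:
        raise ParameterError("fit has more score columns than FPCA harmonics")
    pvals = fit.p_values[1:J + 1]
    sig = np.flatnonzero(pvals < alpha)
    if sig.size == 0:
        raise ValidationError(
            f"no principal component is significant at alpha={alpha}")
    signs = np.sign(fit.coefs[sig])
    signs[signs == 0] = 1.0

    sd = np.sqrt(fpca.eigenvalues[:J])
    score_plus = np.zeros(J)
    score_plus[sig] = signs * sd[sig]
    score_minus = -score_plus

    plus = fpca.mean_fn.copy()
    minus = fpca.mean_fn.copy()
    for idx, s in zip(sig, signs):
        dev = s * sd[idx] * fpca.harmonics[idx]
        plus += dev
        minus -= dev

    p_plus, _ = predict_status(fit, score_plus[None, :])
    p_minus, _ = predict_status(fit, score_minus[None, :])
    return CompositeCurveResult(
        plus_curve=plus, minus_curve=minus,
        predicted_prob_plus=float(p_plus[0]),
        predicted_prob_minus=float(p_minus[0]),
        significant=[int(j) + 1 for j in sig],
        signs=signs,
    )
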