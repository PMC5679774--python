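"""Functional-response linear regression with categorical predictors.

Model: y_i(t) = beta_0(t) + sum_j x_ij beta_j(t) + eps_i(t), with each
coefficient function expanded in a common B-spline basis.  Two design
parameterizations are supported:

``reduced``
    The redundant two-group coding [1 | case(+1)/control(-1) |
    control(+1)/case(-1)] with a sum-to-zero identifiability constraint on
    the two group-effect functions, so beta_0 is the grand-mean curve and
    the case and control perturbations are mirror images.

``full``
    Baseline-contrast (treatment) coding for disease status plus the
    categorical covariates sex (M baseline), race (Black baseline) and
    year-of-birth category (1924-1944 baseline), giving an intercept plus
    seven predictor coefficient functions.

Estimation is pointwise constrained least squares on the working grid
followed by projection of each coefficient function onto the basis — for a
common basis this is equivalent to solving for the b_{j,k} directly and is
straightforward to check against group-mean oracles.  The response curves
are first smoothed onto the same basis, so fitted-plus-residual reproduces
the smoothed curves exactly and residual functions are orthogonal to the
design span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisSystem, FunctionalData, eval_fd, smooth_curves
from .errors import ValidationError
from .io import ThermogramSet

YOB_LEVELS = ("1924-1944", "1945-1955", "1956-1971", "1972-1993")
SEX_LEVELS = ("M", "F")
RACE_LEVELS = ("Black", "White")


@dataclass
class DesignMatrix:
    """Covariate design for the functional-response model.

    ``constraint`` holds optional rows C with C @ beta(t) = 0 enforced at
    every temperature (used to identify the redundant group coding).
    """

    matrix: np.ndarray
    labels: list[str]
    scheme: str
    constraint: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FunctionalRegressionFit:
    """Estimated coefficient functions, fitted curves and residuals."""

    beta_fns: FunctionalData          # one row per design column
    fitted: FunctionalData            # one row per subject
    residuals: np.ndarray             # n x T, on the working grid
    design: DesignMatrix
    grid: np.ndarray
    response: np.ndarray              # smoothed response curves on the grid


def build_design(status, covariates: pd.DataFrame | None = None,
                 scheme: str = "reduced") -> DesignMatrix:
    """Build the design matrix for the functional-response model.

    ``reduced``: intercept plus redundant ±1 case/control columns with a
    sum-to-zero constraint.  ``full``: treatment-coded status, sex, race and
    year-of-birth (7 predictors + intercept); requires a covariate table.
    """
    status = np.asarray(status, dtype=int)
    if not np.all(np.isin(status, [0, 1])):
        raise ValidationError("status labels must be binary 0/1")
    n = len(status)
    if scheme == "reduced":
        case = np.where(status == 1, 1.0, -1.0)
        X = np.column_stack([np.ones(n), case, -case])
        C = np.array([[0.0, 1.0, 1.0]])
        return DesignMatrix(X, ["intercept", "case", "control"], scheme, C)
    if scheme != "full":
        raise ValidationError(f"unknown design scheme {scheme!r}")
    if covariates is None:
        raise ValidationError("full scheme requires a covariate table")
    cols = [np.ones(n), status.astype(float)]
    labels = ["intercept", "case"]
    spec = [("sex", SEX_LEVELS), ("race", RACE_LEVELS), ("yob_cat", YOB_LEVELS)]
    cov = covariates.reset_index(drop=True)
    for name, levels in spec:
        vals = cov[name].astype(str).to_numpy()
        unknown = sorted(set(vals) - set(levels))
        if unknown:
            raise ValidationError(f"unknown {name} level(s): {unknown}")
        for lev in levels[1:]:  # first level is baseline
            cols.append((vals == lev).astype(float))
            labels.append(f"{name}:{lev}")
    X = np.column_stack(cols)
    return DesignMatrix(X, labels, scheme)


def _solve_constrained(X, C, Y):
    """Pointwise least squares min ||Y - X B|| subject to C B = 0.

    Solves the KKT system; Y is n x T, returns B of shape p x T.
    """
    n, p = X.shape
    XtX = X.T @ X
    XtY = X.T @ Y
    if C is None:
        aug = XtX
        rhs = XtY
    else:
        q = C.shape[0]
        aug = np.block([[XtX, C.T], [C, np.zeros((q, q))]])
        rhs = np.vstack([XtY, np.zeros((q, Y.shape[1]))])
    cond = np.linalg.cond(aug)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"singular constrained normal equations (condition number {cond:.3g}); "
            "check for degenerate designs (e.g. a single group under the "
            "redundant coding)")
    sol = np.linalg.solve(aug, rhs)
    return sol[:p]


def fit_freg(ts: ThermogramSet, design: DesignMatrix,
             coef_basis: BasisSystem) -> FunctionalRegressionFit:
    """Fit the functional-response linear model.

    The response curves are smoothed onto ``coef_basis``, coefficient
    functions are estimated by pointwise constrained least squares on the
    grid, and each beta_j(t) is expanded in the same basis.  Under the
    reduced (sum-to-zero) coding beta_0 is the grand-mean curve.
    """
    if design.n != ts.n_subjects:
        raise ValidationError(
            f"design has {design.n} rows but cohort has {ts.n_subjects} curves")
    grid = ts.grid
    fd_y = smooth_curves(ts, coef_basis)
    Y = eval_fd(fd_y, grid)                       # n x T smoothed responses
    B = _solve_constrained(design.matrix, design.constraint, Y)  # p x T
    # project coefficient functions onto the basis (exact: Y lies in span)
    Phi = coef_basis.evaluate(grid)
    bcoefs, *_ = np.linalg.lstsq(Phi, B.T, rcond=None)
    beta_fns = FunctionalData(coef_basis, bcoefs.T, grid=grid)
    fitted_grid = design.matrix @ B
    fit_coefs = design.matrix @ bcoefs.T
    fitted = FunctionalData(coef_basis, fit_coefs, grid=grid)
    residuals = Y - fitted_grid
    return FunctionalRegressionFit(beta_fns=beta_fns, fitted=fitted,
                                   residuals=residuals, design=design,
                                   grid=grid, response=Y)


def _profile_row(fit: FunctionalRegressionFit, profile: dict) -> np.ndarray:
    design = fit.design
    x = np.zeros(len(design.labels))
    x[design.labels.index("intercept")] = 1.0
    if design.scheme == "reduced":
        status = str(profile.get("status", "")).lower()
        if status not in {"case", "control"}:
            raise ValidationError(
                f"reduced scheme needs status 'case' or 'control' "
                f"(got {profile.get('status')!r})")
        sgn = 1.0 if status == "case" else -1.0
        x[design.labels.index("case")] = sgn
        x[design.labels.index("control")] = -sgn
        return x
    status = str(profile.get("status", "control")).lower()
    if status not in {"case", "control"}:
        raise ValidationError(f"unknown status level {profile.get('status')!r}")
    x[design.labels.index("case")] = 1.0 if status == "case" else 0.0
    for name, levels in (("sex", SEX_LEVELS), ("race", RACE_LEVELS),
                         ("yob_cat", YOB_LEVELS)):
        if name in profile:
            lev = str(profile[name])
            if lev not in levels:
                raise ValidationError(f"unknown {name} level {lev!r}")
            if lev != levels[0]:
                x[design.labels.index(f"{name}:{lev}")] = 1.0
    return x


def predict_group_curves(fit: FunctionalRegressionFit, profile: dict) -> np.ndarray:
    """Predicted mean curve beta_0(t) + sum_j x_j beta_j(t) for a profile.

    ``profile`` maps covariate names to levels, e.g. ``{"status": "case"}``;
    omitted full-scheme covariates sit at their baseline level.
    """
    x = _profile_row(fit, profile)
    B = eval_fd(fit.beta_fns, fit.grid)
    return x @ B
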