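"""Pointwise and maxwise permutation t- and F-tests for functional data.

Statistic conventions follow the standard functional-data-analysis ones
(the ``tperm.fd`` / ``Fperm.fd`` conventions):

t-test
    T(t) = |xbar_case(t) - xbar_control(t)| /
           sqrt(s2_case(t)/n_case + s2_control(t)/n_control)
    (Welch-style, unpooled variances), computed on the smoothed curves
    evaluated on the working grid.

F-test
    F(t) = Var_i(yhat_i(t)) / mean_i[(y_i(t) - yhat_i(t))^2],
    the variance-explained ratio.  Note this is *not* the mean-square ratio
    of classical ANOVA; values well below 1 are routine (an observed max
    around 0.35 against a permutation critical value near 0.06 indicates a
    strong relationship).

Both tests calibrate critical values by permuting curve labels (t-test) or
rows of the response against the fixed design (F-test): the pointwise
critical value is the per-temperature (1 - alpha) quantile of the permuted
statistics and the maxwise critical value is the (1 - alpha) quantile of
the permutation maxima.  The overall null is rejected iff the observed
maximum exceeds the maxwise critical value.  Ties in the location of the
maximum break toward the lowest temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import FunctionalData, eval_fd, make_bspline_basis, smooth_curves
from .errors import ParameterError, ValidationError
from .freg import DesignMatrix, _solve_constrained
from .io import ThermogramSet


@dataclass
class PermTestResult:
    """Observed statistic curve plus permutation critical values."""

    stat_fn: np.ndarray        # statistic at each grid temperature
    grid: np.ndarray
    max_stat: float
    argmax_t: float
    pointwise_crit: np.ndarray
    maxwise_crit: float
    n_perm: int
    alpha: float
    seed: int

    @property
    def reject(self) -> bool:
        """Overall decision: observed max beyond the maxwise critical value."""
        return bool(self.max_stat > self.maxwise_crit)


def _welch_t(values, case_mask):
    """|Welch t| at every grid column for a two-group split."""
    a = values[case_mask]
    b = values[~case_mask]
    va = a.var(axis=0, ddof=1) / a.shape[0]
    vb = b.var(axis=0, ddof=1) / b.shape[0]
    denom = np.sqrt(va + vb)
    # float-roundoff variances of numerically identical groups count as zero
    floor = 1e-12 * np.sqrt(np.mean(values * values) + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom > floor, t, 0.0)


def _result(grid, stat, perm_stats, n_perm, alpha, seed):
    imax = int(np.argmax(stat))  # argmax ties -> lowest temperature
    pointwise = np.quantile(perm_stats, 1 - alpha, axis=0)
    maxwise = float(np.quantile(perm_stats.max(axis=1), 1 - alpha))
    return PermTestResult(stat_fn=stat, grid=grid, max_stat=float(stat[imax]),
                          argmax_t=float(grid[imax]), pointwise_crit=pointwise,
                          maxwise_crit=maxwise, n_perm=n_perm, alpha=alpha,
                          seed=seed)


def functional_t_test(ts: ThermogramSet, fd: FunctionalData | None = None,
                      n_perm: int = 200, alpha: float = 0.05,
                      seed: int = 0) -> PermTestResult:
    """Maxwise permutation t-test for a case/control difference in curves.

    ``fd`` supplies the smoothed representation of the cohort's curves; when
    omitted, a saturated B-spline expansion of the cohort is used.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    case = ts.case_mask
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 < 2 or n0 < 2:
        raise ValidationError(
            f"both groups need n >= 2 (got {n1} cases, {n0} controls)")
    if fd is None:
        fd = smooth_curves(ts, make_bspline_basis((ts.grid[0], ts.grid[-1]),
                                                  ts.n_temps))
    values = eval_fd(fd, ts.grid)
    stat = _welch_t(values, case)

    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, len(ts.grid)))
    for b in range(n_perm):
        perm = rng.permutation(ts.n_subjects)
        perm_stats[b] = _welch_t(values, case[perm])
    return _result(ts.grid, stat, perm_stats, n_perm, alpha, seed)


def _f_stat(Y, X, C):
    """Variance-explained F(t) for response matrix Y (n x T)."""
    B = _solve_constrained(X, C, Y)
    yhat = X @ B
    num = yhat.var(axis=0, ddof=1)
    den = np.mean((Y - yhat) ** 2, axis=0)
    # residuals at solver-roundoff level mean a perfect fit, not an infinite F
    floor = 1e-20 * (np.mean(Y * Y) + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    return np.where(den > floor, f, 0.0)


def functional_F_test(ts: ThermogramSet, design: DesignMatrix,
                      n_perm: int = 200, alpha: float = 0.05, seed: int = 0,
                      fd: FunctionalData | None = None) -> PermTestResult:
    """Maxwise permutation F-test for a design/curve-structure relationship.

    The null distribution relabels response curves against the fixed design.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if design.n != ts.n_subjects:
        raise ValidationError("design rows must match the number of curves")
    if fd is None:
        fd = smooth_curves(ts, make_bspline_basis((ts.grid[0], ts.grid[-1]),
                                                  ts.n_temps))
    Y = eval_fd(fd, ts.grid)
    X, C = design.matrix, design.constraint
    stat = _f_stat(Y, X, C)

    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, len(ts.grid)))
    for b in range(n_perm):
        perm = rng.permutation(ts.n_subjects)
        perm_stats[b] = _f_stat(Y[perm], X, C)
    return _result(ts.grid, stat, perm_stats, n_perm, alpha, seed)
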