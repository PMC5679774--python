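"""B-spline basis systems and basis expansion of thermogram curves.

Curves are represented as x_i(t) = sum_k c_{i,k} phi_k(t) for a common
B-spline basis {phi_k}.  Coefficients are obtained by ordinary least squares
against the observed grid values; with a *saturated* basis (as many basis
functions as grid points) the expansion interpolates the data exactly, which
is the representation used upstream of FPCA.  The basis dimension K can be
chosen by generalized cross-validation (GCV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .errors import ParameterError, RangeError


@dataclass(frozen=True)
class BasisSystem:
    """An order-`order` B-spline basis of dimension `n_basis` on [lo, hi].

    Interior knots are equally spaced; the full knot vector repeats each
    endpoint `order` times, so ``n_basis = len(interior_knots) + order``.
    """

    order: int
    n_basis: int
    lo: float
    hi: float
    interior_knots: np.ndarray

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector."""
        return np.concatenate([
            np.full(self.order, self.lo),
            self.interior_knots,
            np.full(self.order, self.hi),
        ])

    def evaluate(self, t, deriv: int = 0) -> np.ndarray:
        """Basis (or derivative) matrix, shape (len(t), n_basis)."""
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < self.lo - 1e-9 or t.max() > self.hi + 1e-9):
            raise RangeError(
                f"evaluation points outside basis range [{self.lo}, {self.hi}]")
        t = np.clip(t, self.lo, self.hi)
        spl = BSpline(self.knots, np.eye(self.n_basis), self.degree,
                      extrapolate=False)
        if deriv:
            spl = spl.derivative(deriv)
        out = spl(t)
        # clamped evaluation at the right endpoint returns NaN columns
        return np.nan_to_num(out, nan=0.0)


@dataclass
class FunctionalData:
    """A set of curves expanded in a common basis: coefs[i, k] = c_{i,k}."""

    basis: BasisSystem
    coefs: np.ndarray
    #: default evaluation grid (the grid the curves were smoothed on), if any
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        if not np.all(np.isfinite(self.coefs)):
            raise ParameterError("coefficient matrix contains non-finite values")
        if self.coefs.shape[1] != self.basis.n_basis:
            raise ParameterError(
                f"coefficient matrix has {self.coefs.shape[1]} columns, "
                f"basis has {self.basis.n_basis} functions")

    @property
    def n_curves(self) -> int:
        return self.coefs.shape[0]


def make_bspline_basis(rng: tuple[float, float], n_basis: int,
                       order: int = 4) -> BasisSystem:
    """Build a B-spline basis with equally spaced interior knots.

    Parameters
    ----------
    rng : (lo, hi)
        Domain in °C.
    n_basis : int
        Number of basis functions K; must satisfy ``K >= order``.
    order : int
        Spline order (degree + 1); 4 gives cubic splines.
    """
    lo, hi = float(rng[0]), float(rng[1])
    if not np.isfinite([lo, hi]).all() or lo >= hi:
        raise ParameterError(f"invalid basis range ({lo}, {hi})")
    if order < 1:
        raise ParameterError(f"order must be >= 1 (got {order})")
    if n_basis < order:
        raise ParameterError(
            f"n_basis must be >= order (got n_basis={n_basis}, order={order})")
    n_int = n_basis - order
    interior = lo + (hi - lo) * np.arange(1, n_int + 1) / (n_int + 1)
    return BasisSystem(order=order, n_basis=n_basis, lo=lo, hi=hi,
                       interior_knots=interior)


def smooth_curves(ts, basis: BasisSystem) -> FunctionalData:
    """Least-squares expansion of each curve of a cohort onto `basis`.

    For a saturated basis (K equal to the number of grid points) the fit
    interpolates the observed values.  Raises if K exceeds the number of
    grid points (rank-deficient design).
    """
    grid = np.asarray(ts.grid, dtype=float)
    if basis.lo > grid[0] + 1e-9 or basis.hi < grid[-1] - 1e-9:
        raise RangeError("basis range does not cover the data grid")
    T = len(grid)
    if basis.n_basis > T:
        raise ParameterError(
            f"n_basis={basis.n_basis} exceeds the {T} grid points "
            "(rank-deficient least-squares design)")
    Phi = basis.evaluate(grid)
    coefs, *_ = np.linalg.lstsq(Phi, np.asarray(ts.values, dtype=float).T,
                                rcond=None)
    return FunctionalData(basis=basis, coefs=coefs.T, grid=grid)


def eval_fd(fd: FunctionalData, t, deriv: int = 0) -> np.ndarray:
    """Evaluate curves (deriv=0) or their analytic derivatives on points `t`.

    Returns an (n_curves, len(t)) matrix.
    """
    if deriv not in (0, 1, 2):
        raise ParameterError(f"deriv must be 0, 1 or 2 (got {deriv})")
    Phi = fd.basis.evaluate(t, deriv=deriv)
    return fd.coefs @ Phi.T


def derivative_fd(fd: FunctionalData, grid=None) -> FunctionalData:
    """First-derivative ("velocity") curves re-expanded in the same basis.

    The analytic derivative is evaluated on the grid and projected back onto
    the basis by least squares, yielding the d_{i,k} coefficient matrix that
    plays the role of c_{i,k} for velocity-curve analyses.
    """
    grid = fd.grid if grid is None else np.asarray(grid, dtype=float)
    if grid is None:
        raise ParameterError("derivative_fd needs a grid (fd.grid is unset)")
    vel = eval_fd(fd, grid, deriv=1)
    Phi = fd.basis.evaluate(grid)
    coefs, *_ = np.linalg.lstsq(Phi, vel.T, rcond=None)
    return FunctionalData(basis=fd.basis, coefs=coefs.T, grid=grid)


def select_nbasis_gcv(ts, candidates, order: int = 4):
    """Select the B-spline basis dimension by generalized cross-validation.

    For each candidate K the cohort GCV score is::

        GCV(K) = sum_i  T * SSE_i / (T - df)**2

    with ``df = K`` (trace of the unpenalized least-squares hat matrix) and
    SSE_i the residual sum of squares of curve i on the grid.  Returns the
    minimizing K and a table ``[(K, gcv), ...]`` over all candidates.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("empty candidate list")
    grid = np.asarray(ts.grid, dtype=float)
    T = len(grid)
    Y = np.asarray(ts.values, dtype=float).T  # T x n
    table = []
    for K in candidates:
        if K > T:
            raise ParameterError(f"candidate K={K} exceeds the {T} grid points")
        if K < order:
            raise ParameterError(f"candidate K={K} below spline order {order}")
        if K == T:
            # saturated: interpolating fit, df = T, GCV undefined (0/0);
            # treated as +inf so GCV never selects the saturated basis
            table.append((K, np.inf))
            continue
        basis = make_bspline_basis((grid[0], grid[-1]), K, order)
        Phi = basis.evaluate(grid)
        coefs, *_ = np.linalg.lstsq(Phi, Y, rcond=None)
        sse = np.sum((Y - Phi @ coefs) ** 2, axis=0)
        table.append((K, float(np.sum(T * sse / (T - K) ** 2))))
    k_opt = min(table, key=lambda kv: kv[1])[0]
    return k_opt, table
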