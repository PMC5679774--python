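"""Functional principal component analysis of thermogram curves.

The eigenproblem of the sample covariance function v(s, t),

    integral v(s, t) xi_j(t) dt = mu_j xi_j(s),

is solved by quadrature-weighted discretization on the working grid: with
trapezoidal weights W the symmetric matrix W^{1/2} C W^{1/2} (C the 1/(n-1)
sample covariance of the curves at the grid points) is eigendecomposed and
eigenvectors are back-transformed by W^{-1/2}, giving eigenfunctions xi_j
with quadrature norm integral xi_j^2 = 1.  Scores are the quadrature inner
products gamma_ij = integral xi_j(t) (x_i(t) - xbar(t)) dt, whose sample
variance equals mu_j, and the eigenvalue total equals the integrated
pointwise variance integral v(t, t) dt.

Signs are fixed deterministically: each eigenfunction is oriented so its
integral is positive, tie-broken by the sign of its value at the lowest
temperature, making results reproducible run to run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .basis import FunctionalData, eval_fd
from .errors import ParameterError, RangeError, ValidationError


@dataclass
class FPCAResult:
    """Mean curve, harmonics, eigenvalues, scores and variance proportions."""

    grid: np.ndarray
    mean_fn: np.ndarray            # xbar(t) on the grid
    harmonics: np.ndarray          # J x T eigenfunctions xi_j(t)
    eigenvalues: np.ndarray        # mu_j, length J (curve-units^2 * degC)
    scores: np.ndarray             # n x J
    varprop: np.ndarray            # mu_j / total variance, length J
    total_variance: float          # sum over *all* eigenvalues
    weights: np.ndarray            # quadrature weights on the grid

    @property
    def J(self) -> int:
        return len(self.eigenvalues)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    d = np.diff(grid)
    w[0] = d[0] / 2
    w[-1] = d[-1] / 2
    w[1:-1] = (d[:-1] + d[1:]) / 2
    return w


def _orient(xi: np.ndarray, w: np.ndarray) -> np.ndarray:
    s = float(np.sum(w * xi))
    if abs(s) < 1e-12:
        s = float(xi[0])
    return -xi if s < 0 else xi


def _curves_and_grid(fd, grid):
    if isinstance(fd, FunctionalData):
        g = fd.grid if grid is None else np.asarray(grid, dtype=float)
        if g is None:
            raise ParameterError("fit_fpca needs a grid (fd.grid is unset)")
        return eval_fd(fd, g), g
    # also accept a raw (curves, grid) pairing via ThermogramSet-likes
    if hasattr(fd, "grid") and hasattr(fd, "values"):
        return np.asarray(fd.values, dtype=float), np.asarray(fd.grid, dtype=float)
    raise ParameterError("fd must be FunctionalData or carry .values/.grid")


def fit_fpca(fd, n_harmonics: int | None = None, grid=None) -> FPCAResult:
    """Functional PCA of a set of curves.

    Parameters
    ----------
    fd : FunctionalData or ThermogramSet
        The curves; evaluated on ``grid`` (default: their own grid).
    n_harmonics : int, optional
        Number of retained components J (default: all with positive
        eigenvalue, capped at n_curves - 1).
    """
    X, g = _curves_and_grid(fd, grid)
    n, T = X.shape
    if n < 2:
        raise ValidationError("FPCA requires at least 2 curves")
    w = _trapezoid_weights(g)
    mean_fn = X.mean(axis=0)
    Xc = X - mean_fn
    C = (Xc.T @ Xc) / (n - 1)
    sw = np.sqrt(w)
    M = (sw[:, None] * C) * sw[None, :]
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = float(np.sum(w * np.diag(C)))

    max_j = min(n - 1, T)
    if n_harmonics is None:
        J = int(np.sum(evals[:max_j] > 1e-12 * max(total, 1.0))) or 1
    else:
        if n_harmonics < 1 or n_harmonics > max_j:
            raise ParameterError(
                f"n_harmonics must be in [1, {max_j}] (got {n_harmonics})")
        J = n_harmonics
    harmonics = np.empty((J, T))
    for j in range(J):
        harmonics[j] = _orient(evecs[:, j] / sw, w)
    scores = (Xc * w) @ harmonics.T
    varprop = evals[:J] / total if total > 0 else np.zeros(J)
    return FPCAResult(grid=g, mean_fn=mean_fn, harmonics=harmonics,
                      eigenvalues=evals[:J], scores=scores, varprop=varprop,
                      total_variance=total, weights=w)


def choose_harmonics(result: FPCAResult, threshold: float = 0.99) -> int:
    """Smallest J whose cumulative variance proportion reaches `threshold`."""
    if not 0 < threshold <= 1:
        raise ParameterError(f"threshold must be in (0, 1] (got {threshold})")
    cum = np.cumsum(result.varprop)
    hit = np.flatnonzero(cum >= threshold - 1e-12)
    if hit.size == 0:
        warnings.warn(
            f"retained components explain only {cum[-1]:.3f} < {threshold}; "
            "returning all of them", stacklevel=2)
        return result.J
    return int(hit[0]) + 1


def harmonic_variation_curves(result: FPCAResult, j: int):
    """Mean curve ± one score standard deviation of harmonic j (1-based)."""
    if not 1 <= j <= result.J:
        raise ParameterError(f"harmonic index {j} out of range [1, {result.J}]")
    dev = np.sqrt(result.eigenvalues[j - 1]) * result.harmonics[j - 1]
    return result.mean_fn + dev, result.mean_fn - dev


def project_scores(result: FPCAResult, fd_new, grid=None) -> np.ndarray:
    """Scores of new curves against the training mean and harmonics."""
    X, g = _curves_and_grid(fd_new, grid if grid is not None else result.grid)
    if X.shape[1] != len(result.grid) or not np.allclose(g, result.grid):
        raise RangeError("new curves must be evaluated on the training grid")
    Xc = X - result.mean_fn
    return (Xc * result.weights) @ result.harmonics.T
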