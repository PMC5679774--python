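"""B-spline basis construction, smoothing, GCV selection and derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermofda import (
    FunctionalData,
    ThermogramSet,
    eval_fd,
    make_bspline_basis,
    select_nbasis_gcv,
    smooth_curves,
)
from thermofda.basis import derivative_fd
from thermofda.errors import ParameterError


def _set(grid, values):
    values = np.atleast_2d(values)
    n = values.shape[0]
    return ThermogramSet(np.asarray(grid, float), values,
                         np.array([f"s{i}" for i in range(n)]),
                         np.zeros(n, dtype=int))


def test_single_span_cubic_is_bernstein_partition_of_unity():
    b = make_bspline_basis((0.0, 1.0), 4, 4)
    assert len(b.interior_knots) == 0
    assert np.isclose(b.evaluate([0.3]).sum(), 1.0, atol=1e-12)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=4, max_value=40),
       st.floats(min_value=45.0, max_value=90.0))
def test_partition_of_unity_everywhere(K, t):
    b = make_bspline_basis((45.0, 90.0), K, 4)
    assert np.isclose(b.evaluate([t]).sum(), 1.0, atol=1e-10)


def test_interior_knot_count_is_K_minus_order():
    b = make_bspline_basis((45.0, 90.0), 35, 4)
    assert len(b.interior_knots) == 31
    assert b.knots.size == 35 + 4  # clamped: K + order knots total


def test_nbasis_below_order_rejected():
    with pytest.raises(ParameterError):
        make_bspline_basis((0.0, 1.0), 3, 4)


def test_projection_recovers_coefficients_exactly():
    basis = make_bspline_basis((0.0, 1.0), 8, 4)
    grid = np.linspace(0, 1, 30)
    rng = np.random.default_rng(0)
    coefs = rng.normal(size=(3, 8))
    fd = FunctionalData(basis, coefs, grid=grid)
    refit = smooth_curves(_set(grid, eval_fd(fd, grid)), basis)
    assert np.allclose(refit.coefs, coefs, atol=1e-9)


def test_saturated_basis_interpolates():
    grid = np.linspace(60, 85, 51)
    rng = np.random.default_rng(1)
    values = rng.normal(size=(4, 51))
    fd = smooth_curves(_set(grid, values), make_bspline_basis((60, 85), 51, 4))
    fitted = eval_fd(fd, grid)
    assert np.max(np.abs(fitted - values)) / np.max(np.abs(values)) < 1e-8


def test_constant_curve_fits_exactly_by_partition_of_unity():
    grid = np.linspace(0, 1, 20)
    fd = smooth_curves(_set(grid, np.full((1, 20), 5.0)),
                       make_bspline_basis((0, 1), 7, 4))
    assert np.allclose(eval_fd(fd, np.linspace(0, 1, 100)), 5.0)


def test_oversaturated_basis_rejected():
    grid = np.linspace(0, 1, 10)
    with pytest.raises(ParameterError):
        smooth_curves(_set(grid, np.zeros((1, 10))),
                      make_bspline_basis((0, 1), 11, 4))


def test_smoothing_is_idempotent():
    grid = np.linspace(45, 90, 60)
    rng = np.random.default_rng(2)
    ts = _set(grid, rng.normal(size=(2, 60)))
    basis = make_bspline_basis((45, 90), 12, 4)
    fd1 = smooth_curves(ts, basis)
    fd2 = smooth_curves(_set(grid, eval_fd(fd1, grid)), basis)
    assert np.allclose(fd1.coefs, fd2.coefs, atol=1e-10)


class TestGCV:
    def _gcv_oracle(self, ts, K, order=4):
        grid = ts.grid
        T = len(grid)
        Phi = make_bspline_basis((grid[0], grid[-1]), K, order).evaluate(grid)
        hat_df = K
        total = 0.0
        for y in ts.values:
            c, *_ = np.linalg.lstsq(Phi, y, rcond=None)
            sse = float(np.sum((y - Phi @ c) ** 2))
            total += T * sse / (T - hat_df) ** 2
        return total

    def test_single_candidate_returned(self):
        grid = np.linspace(0, 1, 20)
        ts = _set(grid, np.zeros((1, 20)))
        K, table = select_nbasis_gcv(ts, [7])
        assert K == 7 and len(table) == 1

    def test_gcv_table_matches_direct_computation(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(45, 90, 80)
        ts = _set(grid, rng.normal(size=(3, 80)))
        _, table = select_nbasis_gcv(ts, [6, 12, 20])
        for K, val in table:
            assert np.isclose(val, self._gcv_oracle(ts, K), rtol=1e-10)

    def test_recovers_generating_dimension(self):
        rng = np.random.default_rng(4)
        grid = np.linspace(45, 90, 251)
        basis10 = make_bspline_basis((45, 90), 10, 4)
        fd = FunctionalData(basis10, rng.normal(size=(5, 10)), grid=grid)
        values = eval_fd(fd, grid) + 0.05 * rng.normal(size=(5, 251))
        K, _ = select_nbasis_gcv(_set(grid, values), [5, 10, 200])
        assert K == 10

    def test_candidate_above_T_rejected(self):
        grid = np.linspace(0, 1, 20)
        with pytest.raises(ParameterError):
            select_nbasis_gcv(_set(grid, np.zeros((1, 20))), [25])

    def test_empty_candidates_rejected(self):
        grid = np.linspace(0, 1, 20)
        with pytest.raises(ParameterError):
            select_nbasis_gcv(_set(grid, np.zeros((1, 20))), [])


class TestDerivatives:
    def test_fitted_line_has_constant_derivative(self):
        grid = np.linspace(0, 1, 25)
        fd = smooth_curves(_set(grid, 2.0 + 3.0 * grid),
                           make_bspline_basis((0, 1), 8, 4))
        d = eval_fd(fd, np.linspace(0.05, 0.95, 40), deriv=1)
        assert np.allclose(d, 3.0, atol=1e-8)

    def test_analytic_derivative_matches_finite_differences(self):
        grid = np.linspace(45, 90, 101)
        values = np.sin(0.3 * grid) + 0.1 * grid
        fd = smooth_curves(_set(grid, values), make_bspline_basis((45, 90), 25, 4))
        t = np.linspace(50, 85, 37)
        h = 1e-4
        fdiff = (eval_fd(fd, t + h) - eval_fd(fd, t - h)) / (2 * h)
        exact = eval_fd(fd, t, deriv=1)
        assert np.max(np.abs(exact - fdiff)) / np.max(np.abs(exact)) < 1e-4

    def test_derivative_operator_is_linear(self):
        basis = make_bspline_basis((0, 1), 9, 4)
        grid = np.linspace(0, 1, 30)
        rng = np.random.default_rng(5)
        f = FunctionalData(basis, rng.normal(size=(1, 9)), grid=grid)
        g = FunctionalData(basis, rng.normal(size=(1, 9)), grid=grid)
        combo = FunctionalData(basis, 2.0 * f.coefs - 0.5 * g.coefs, grid=grid)
        t = np.linspace(0, 1, 17)
        assert np.allclose(eval_fd(combo, t, deriv=1),
                           2.0 * eval_fd(f, t, deriv=1)
                           - 0.5 * eval_fd(g, t, deriv=1), atol=1e-10)

    def test_velocity_reexpansion_agrees_with_analytic_derivative(self):
        grid = np.linspace(60, 85, 251)
        values = np.exp(-0.5 * ((grid - 70) / 3) ** 2)[None, :]
        fd = smooth_curves(_set(grid, values), make_bspline_basis((60, 85), 251, 4))
        vfd = derivative_fd(fd)
        assert np.allclose(eval_fd(vfd, grid), eval_fd(fd, grid, deriv=1),
                           atol=1e-6)
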