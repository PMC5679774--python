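"""Functional-response regression: design coding, fits, oracles."""

import numpy as np
import pandas as pd
import pytest

from thermofda import (
    ThermogramSet,
    ValidationError,
    build_design,
    eval_fd,
    fit_freg,
    make_bspline_basis,
    predict_group_curves,
    smooth_curves,
)

GRID = np.linspace(60.0, 85.0, 51)


def _cohort(n_case=4, n_ctrl=4, noise=0.0, seed=0):
    """Noiseless-by-default cohort whose curves live in a spline span."""
    rng = np.random.default_rng(seed)
    basis = make_bspline_basis((60, 85), 51, 4)
    case_curve = np.exp(-0.5 * ((GRID - 75) / 4) ** 2)
    ctrl_curve = np.exp(-0.5 * ((GRID - 65) / 3) ** 2)
    values = np.vstack([np.tile(case_curve, (n_case, 1)),
                        np.tile(ctrl_curve, (n_ctrl, 1))])
    values = values + noise * rng.normal(size=values.shape)
    status = np.r_[np.ones(n_case, int), np.zeros(n_ctrl, int)]
    ids = np.array([f"s{i}" for i in range(n_case + n_ctrl)])
    return ThermogramSet(GRID, values, ids, status), basis


class TestDesign:
    def test_reduced_coding_rows(self):
        d = build_design([1, 1, 0, 0], scheme="reduced")
        expected = np.array([[1, 1, -1], [1, 1, -1], [1, -1, 1], [1, -1, 1]],
                            dtype=float)
        assert np.array_equal(d.matrix, expected)
        assert np.array_equal(d.constraint, [[0.0, 1.0, 1.0]])

    def test_full_scheme_has_intercept_plus_seven_predictors(self):
        cov = pd.DataFrame({
            "sex": ["F", "M", "F", "F"],
            "race": ["Black", "White", "White", "Black"],
            "yob_cat": ["1924-1944", "1945-1955", "1956-1971", "1972-1993"],
        })
        d = build_design([1, 0, 1, 0], covariates=cov, scheme="full")
        # status + sex + race + three year-of-birth contrasts, plus intercept
        assert d.matrix.shape == (4, 7)
        assert d.labels[0] == "intercept"
        assert np.all(d.matrix[:, 0] == 1)

    def test_unknown_covariate_level_is_listed(self):
        cov = pd.DataFrame({"sex": ["X"], "race": ["Black"],
                            "yob_cat": ["1924-1944"]})
        with pytest.raises(ValidationError, match="X"):
            build_design([1], covariates=cov, scheme="full")

    def test_single_group_reduced_design_is_singular(self):
        ts, basis = _cohort(n_case=4, n_ctrl=4)
        all_case = ThermogramSet(ts.grid, ts.values, ts.subject_ids,
                                 np.ones(8, dtype=int))
        d = build_design(all_case.status, scheme="reduced")
        with pytest.raises(np.linalg.LinAlgError):
            fit_freg(all_case, d, basis)


class TestFit:
    def test_intercept_only_recovers_mean_curve(self):
        ts, basis = _cohort(noise=0.01, seed=1)
        from thermofda.freg import DesignMatrix
        d = DesignMatrix(np.ones((8, 1)), ["intercept"], "reduced", None)
        fit = fit_freg(ts, d, basis)
        mean_smoothed = eval_fd(smooth_curves(ts, basis), ts.grid).mean(axis=0)
        b0 = eval_fd(fit.beta_fns, ts.grid)[0]
        assert np.allclose(b0, mean_smoothed, atol=1e-8)

    def test_noiseless_groups_fitted_curves_equal_group_means(self):
        ts, basis = _cohort()
        d = build_design(ts.status, scheme="reduced")
        fit = fit_freg(ts, d, basis)
        sm = eval_fd(smooth_curves(ts, basis), ts.grid)
        case_mean = sm[ts.status == 1].mean(axis=0)
        ctrl_mean = sm[ts.status == 0].mean(axis=0)
        assert np.allclose(predict_group_curves(fit, {"status": "case"}),
                           case_mean, atol=1e-6)
        assert np.allclose(predict_group_curves(fit, {"status": "control"}),
                           ctrl_mean, atol=1e-6)

    def test_sum_to_zero_constraint_and_coding_algebra(self):
        ts, basis = _cohort(noise=0.05, seed=2)
        fit = fit_freg(ts, build_design(ts.status, scheme="reduced"), basis)
        B = eval_fd(fit.beta_fns, ts.grid)
        assert np.allclose(B[1] + B[2], 0.0, atol=1e-8)
        # case linear predictor is b0 + b_case - b_control, so the group
        # difference is 2*(b_case - b_control) = 4*b_case under sum-to-zero
        diff = (predict_group_curves(fit, {"status": "case"})
                - predict_group_curves(fit, {"status": "control"}))
        assert np.allclose(diff, 2 * (B[1] - B[2]), atol=1e-8)

    def test_residuals_orthogonal_to_design_span(self):
        ts, basis = _cohort(n_case=5, n_ctrl=3, noise=0.05, seed=3)
        d = build_design(ts.status, scheme="reduced")
        fit = fit_freg(ts, d, basis)
        scale = np.abs(fit.response).max()
        cross = d.matrix.T @ fit.residuals
        assert np.abs(cross).max() < 1e-6 * scale * len(ts.status)

    def test_fitted_plus_residuals_reproduce_smoothed_response(self):
        ts, basis = _cohort(noise=0.05, seed=4)
        fit = fit_freg(ts, build_design(ts.status, scheme="reduced"), basis)
        recon = eval_fd(fit.fitted, ts.grid) + fit.residuals
        assert np.allclose(recon, fit.response, atol=1e-8)

    def test_refit_on_fitted_values_is_idempotent(self):
        ts, basis = _cohort(noise=0.05, seed=5)
        d = build_design(ts.status, scheme="reduced")
        fit1 = fit_freg(ts, d, basis)
        fitted_set = ThermogramSet(ts.grid, eval_fd(fit1.fitted, ts.grid),
                                   ts.subject_ids, ts.status)
        fit2 = fit_freg(fitted_set, d, basis)
        assert np.allclose(fit1.beta_fns.coefs, fit2.beta_fns.coefs, atol=1e-7)

    def test_label_swap_negates_group_effect(self):
        ts, basis = _cohort(noise=0.05, seed=6)
        fit1 = fit_freg(ts, build_design(ts.status, scheme="reduced"), basis)
        swapped = ThermogramSet(ts.grid, ts.values, ts.subject_ids,
                                1 - ts.status)
        fit2 = fit_freg(swapped, build_design(swapped.status,
                                              scheme="reduced"), basis)
        B1 = eval_fd(fit1.beta_fns, ts.grid)
        B2 = eval_fd(fit2.beta_fns, ts.grid)
        assert np.allclose(B1[1], -B2[1], atol=1e-8)
        assert np.allclose(B1[0], B2[0], atol=1e-8)

    def test_full_scheme_baseline_profile_is_intercept(self):
        ts, basis = _cohort(noise=0.02, seed=7)
        rng = np.random.default_rng(0)
        cov = pd.DataFrame({
            "sex": rng.permutation(["F", "M"] * 4),
            "race": rng.permutation(["Black", "White"] * 4),
            "yob_cat": rng.permutation(["1924-1944", "1945-1955",
                                        "1956-1971", "1972-1993"] * 2),
        }, index=ts.subject_ids)
        d = build_design(ts.status, covariates=cov.loc[ts.subject_ids],
                         scheme="full")
        fit = fit_freg(ts, d, basis)
        baseline = predict_group_curves(
            fit, {"status": "control", "sex": "M", "race": "Black",
                  "yob_cat": "1924-1944"})
        assert np.allclose(baseline, eval_fd(fit.beta_fns, ts.grid)[0],
                           atol=1e-8)
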