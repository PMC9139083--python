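"""Quadratic and logistic strip-calibration models."""

import numpy as np
import pytest

from chromacal.calibration import (
    CalibrationPoint,
    LogisticCalibration,
    PolynomialCalibration,
    fit_logistic,
    fit_polynomial,
    invert_polynomial,
    peroxide_response,
    predict_logistic,
    replicate_summary,
)
from chromacal.exceptions import (
    AmbiguousCalibrationError,
    CalibrationRangeError,
    SingularFitError,
)


def quad_points(coef=(0.0, 0.035, -5e-4), levels=None):
    if levels is None:
        levels = np.linspace(0, 25, 12)
    c = np.asarray(coef)
    return [
        CalibrationPoint(lv, float(np.polynomial.polynomial.polyval(lv, c)))
        for lv in levels
    ]


def logistic_points(A=0.31, B=0.46, C=8.8, D=10.0, levels=range(5, 14)):
    return [
        CalibrationPoint(lv, A + (B - A) / (1 + (lv / C) ** D)) for lv in levels
    ]


class TestPeroxideResponse:
    @pytest.mark.parametrize(
        "R,R0,expected", [(250, 250, 0.0), (0, 250, 1.0), (200, 250, 0.2)]
    )
    def test_normalized_response(self, R, R0, expected):
        assert peroxide_response(R, R0) == pytest.approx(expected)

    def test_nonpositive_blank_rejected(self):
        with pytest.raises(ValueError):
            peroxide_response(100, 0)


class TestPolynomialCalibration:
    def test_exact_quadratic_recovered(self):
        cal = fit_polynomial(quad_points())
        np.testing.assert_allclose(cal.coef_, [0.0, 0.035, -5e-4], atol=1e-9)
        assert cal.range_ == (0.0, 25.0)

    def test_constant_response_gives_zero_slope_terms(self):
        pts = [CalibrationPoint(lv, 0.4) for lv in (0, 5, 10, 15, 20)]
        cal = fit_polynomial(pts)
        assert abs(cal.coef_[1]) < 1e-9 and abs(cal.coef_[2]) < 1e-9

    def test_duplicate_levels_rank_error(self):
        pts = [CalibrationPoint(5.0, 0.1 * i) for i in range(4)]
        with pytest.raises(SingularFitError):
            fit_polynomial(pts)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least"):
            fit_polynomial(quad_points(levels=[0, 5, 10]))

    def test_inversion_round_trip_at_calibration_points(self):
        cal = fit_polynomial(quad_points())
        for lv in np.linspace(0, 25, 12):
            assert invert_polynomial(cal, float(cal.predict(lv))) == pytest.approx(
                lv, abs=1e-6
            )

    def test_blank_response_maps_to_level_zero(self):
        cal = fit_polynomial(quad_points())
        assert invert_polynomial(cal, float(cal.coef_[0])) == pytest.approx(0.0, abs=1e-9)

    def test_response_above_curve_maximum_is_out_of_range(self):
        cal = fit_polynomial(quad_points())
        top = float(cal.predict(25.0))
        with pytest.raises(CalibrationRangeError):
            invert_polynomial(cal, top + 0.2)

    def test_two_in_range_roots_is_ambiguous(self):
        # non-monotone over the fitted range: vertex at level 10
        pts = quad_points(coef=(0.0, 0.2, -0.01), levels=np.linspace(0, 20, 9))
        cal = fit_polynomial(pts)
        with pytest.raises(AmbiguousCalibrationError):
            invert_polynomial(cal, float(cal.predict(5.0)))


class TestLogisticCalibration:
    def test_exact_recovery_from_generated_responses(self):
        cal = fit_logistic(logistic_points())
        assert cal.C_ == pytest.approx(8.8, rel=1e-6)
        assert cal.D_ == pytest.approx(10.0, rel=1e-6)

    def test_linearized_and_refined_agree_on_clean_data(self):
        # with the asymptotes pinned exactly, the linearized stage is
        # unbiased and refinement cannot move the estimates
        pts = logistic_points()
        lin = LogisticCalibration(refine=False).fit(pts, plateaus=(0.31, 0.46))
        ref = LogisticCalibration(refine=True).fit(pts, plateaus=(0.31, 0.46))
        assert ref.C_ == pytest.approx(lin.C_, rel=1e-3)
        assert ref.D_ == pytest.approx(lin.D_, rel=1e-3)

    def test_plateau_heuristic_bias_is_removed_by_refinement(self):
        # a steep mid-range series never quite reaches its asymptotes, so the
        # extreme-response plateau estimate skews the linearized stage; the
        # nonlinear refinement recovers the generating parameters
        pts = logistic_points(levels=range(2, 15))
        lin = LogisticCalibration(refine=False).fit(pts)
        ref = LogisticCalibration(refine=True).fit(pts)
        assert abs(lin.C_ - 8.8) / 8.8 < 0.05  # close but biased
        assert ref.C_ == pytest.approx(8.8, rel=1e-6)
        assert ref.D_ == pytest.approx(10.0, rel=1e-6)

    def test_refinement_never_increases_sse(self):
        rng = np.random.default_rng(0)
        pts = [
            CalibrationPoint(p.level, p.response + rng.normal(0, 0.004))
            for p in logistic_points()
        ]
        levels = np.array([p.level for p in pts])
        resp = np.array([p.response for p in pts])

        def sse(cal):
            return float(np.sum((cal.predict(levels) - resp) ** 2))

        assert sse(LogisticCalibration(refine=True).fit(pts)) <= sse(
            LogisticCalibration(refine=False).fit(pts)
        ) + 1e-12

    def test_midpoint_identity(self):
        cal = fit_logistic(logistic_points())
        assert float(cal.predict(cal.C_)) == pytest.approx(
            (cal.A_ + cal.B_) / 2, abs=1e-9
        )

    def test_plateau_point_rejected_with_warning(self):
        pts = logistic_points(levels=range(5, 13))
        pts.append(CalibrationPoint(14.0, 0.31))  # exactly at the A plateau
        with pytest.warns(UserWarning, match="plateau"):
            cal = LogisticCalibration(refine=False).fit(pts)
        assert (14.0, 0.31) in cal.rejected_

    def test_exclusions_are_caller_specified(self):
        pts = logistic_points(levels=range(3, 15))
        cal = fit_logistic(pts, exclude=(3.0, 14.0))
        assert cal.excluded_ == [3.0, 14.0]
        assert 3.0 not in cal.fit_levels_ and 14.0 not in cal.fit_levels_

    def test_too_few_usable_points(self):
        with pytest.raises(ValueError):
            fit_logistic(logistic_points(levels=[6, 8, 10]))

    def test_inverse_round_trip(self):
        cal = fit_logistic(logistic_points())
        for ph in (5.5, 7.0, 8.74, 11.0):
            assert predict_logistic(cal, float(cal.predict(ph))) == pytest.approx(
                ph, abs=1e-9
            )

    def test_midpoint_response_inverts_to_C(self):
        cal = fit_logistic(logistic_points())
        assert predict_logistic(cal, (cal.A_ + cal.B_) / 2) == pytest.approx(cal.C_)

    def test_plateau_response_is_out_of_range(self):
        cal = fit_logistic(logistic_points())
        for bad in (cal.A_, cal.B_, cal.A_ - 0.05, cal.B_ + 0.05):
            with pytest.raises(CalibrationRangeError):
                predict_logistic(cal, bad)

    def test_inverse_strictly_monotone_in_response(self):
        cal = fit_logistic(logistic_points())
        lo, hi = sorted((cal.A_, cal.B_))
        responses = np.linspace(lo + 1e-4, hi - 1e-4, 50)
        levels = [predict_logistic(cal, r) for r in responses]
        diffs = np.diff(levels)
        assert np.all(diffs < 0) or np.all(diffs > 0)

    def test_noisy_recovery_of_midpoint_and_slope(self):
        # sigma 0.002 on the CIE x response, 9 points, 100 simulations
        true_C, true_D = 8.8, 10.0
        c_err, d_rel = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = [
                CalibrationPoint(p.level, p.response + rng.normal(0, 0.002))
                for p in logistic_points(C=true_C, D=true_D)
            ]
            try:
                cal = fit_logistic(pts)
            except ValueError:
                continue
            c_err.append(abs(cal.C_ - true_C))
            d_rel.append(abs(cal.D_ - true_D) / true_D)
        assert len(c_err) >= 95
        assert np.median(c_err) < 0.1
        assert np.median(d_rel) < 0.10


class TestReplicateSummary:
    def test_identical_triplicates_have_zero_ci(self):
        s = replicate_summary([5.0, 5.0, 5.0])
        assert s.ci95_halfwidth == 0.0 and s.estimate == 5.0

    def test_truth_equal_to_mean_gives_zero_error(self):
        s = replicate_summary([4.0, 6.0], truth=5.0)
        assert s.relative_error == 0.0

    def test_table_style_triplicate_arithmetic(self):
        s = replicate_summary([7.28, 7.30, 7.26], truth=7.35)
        assert s.estimate == pytest.approx(7.28)
        assert s.relative_error == pytest.approx(100 * 0.07 / 7.35, abs=1e-6)
        assert s.n_replicates == 3

    def test_single_estimate_has_nan_ci(self):
        s = replicate_summary([3.3])
        assert np.isnan(s.ci95_halfwidth) and s.n_replicates == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_summary([])
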