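"""Analyte calibration models for colorimetric test strips.

Two calibration shapes cover the common strip chemistries:

* **Quadratic (peroxide-type).**  A single dye darkens with analyte
  concentration; the normalized red-channel response ``(R0 - R) / R0``
  (``R0`` = blank strip) follows a second-degree polynomial of the
  concentration over the strip's working range (0-25 mg/L for the H2O2
  strips this models).

* **Four-parameter logistic (pH-type).**  Indicator strips sweep through a
  color gamut; the CIE ``x`` chromaticity coordinate responds as

      y = A + (B - A) / (1 + (pH / C)^D)

  with plateaus ``A`` (high-pH) and ``B`` (low-pH), midpoint ``C`` and
  slope exponent ``D``.  The fit linearizes

      log((B - A)/(y - A) - 1) = D log(pH) - D log(C)

  and solves it by ordinary least squares, followed (by default) by a
  nonlinear refinement of all four parameters that is kept only when it
  does not increase the sum of squared errors.

Both models invert responses back to analyte levels; unknowns are read in
replicate and summarized with Student-t 95% confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import AmbiguousCalibrationError, CalibrationRangeError, SingularFitError

__all__ = [
    "CalibrationPoint",
    "PolynomialCalibration",
    "LogisticCalibration",
    "PredictionResult",
    "peroxide_response",
    "fit_polynomial",
    "invert_polynomial",
    "fit_logistic",
    "predict_logistic",
    "replicate_summary",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: analyte level and scalar response.

    ``rgb`` optionally carries the replicate color the response derives
    from ((R0-R)/R0 for peroxide, CIE x for pH).
    """

    level: float
    response: float
    rgb: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.level) and np.isfinite(self.response)):
            raise ValueError("level and response must be finite")


def peroxide_response(R: float, R0: float) -> float:
    """Normalized red-channel response (R0 - R) / R0 of a peroxide strip."""
    if R0 <= 0:
        raise ValueError(f"blank red level R0 must be > 0, got {R0}")
    R = np.asarray(R, dtype=float)
    out = (R0 - R) / R0
    return float(out) if out.ndim == 0 else out


def _levels_responses(points) -> tuple[np.ndarray, np.ndarray]:
    pts = list(points)
    levels = np.array([p.level for p in pts], dtype=float)
    responses = np.array([p.response for p in pts], dtype=float)
    return levels, responses


class PolynomialCalibration(RegressorMixin, BaseEstimator):
    """Least-squares polynomial calibration (default degree 2).

    ``fit(levels, responses)`` stores ascending coefficients ``coef_``
    (c0, c1, c2, ...) of response = c0 + c1*level + c2*level^2 and the
    calibrated level range ``range_``.  ``inverse`` solves the polynomial
    for the level, accepting only roots inside the calibrated range.
    """

    def __init__(self, degree: int = 2):
        self.degree = degree

    def fit(self, levels, responses=None):
        if responses is None:
            levels, responses = _levels_responses(levels)
        levels = np.asarray(levels, dtype=float).ravel()
        responses = np.asarray(responses, dtype=float).ravel()
        if levels.shape != responses.shape:
            raise ValueError("levels and responses must have the same length")
        n = len(levels)
        if n < self.degree + 2:
            raise ValueError(
                f"need at least degree+2 = {self.degree + 2} points, got {n}"
            )
        design = np.vander(levels, self.degree + 1, increasing=True)
        if np.linalg.matrix_rank(design) < self.degree + 1:
            raise SingularFitError(
                f"degenerate design: need {self.degree + 1} distinct levels "
                f"to fit a degree-{self.degree} polynomial"
            )
        coef, _, _, _ = np.linalg.lstsq(design, responses, rcond=None)
        self.coef_ = coef
        self.range_ = (float(levels.min()), float(levels.max()))
        self.n_points_ = n
        return self

    def predict(self, levels) -> np.ndarray:
        self._check_fitted()
        levels = np.asarray(levels, dtype=float)
        return np.polynomial.polynomial.polyval(levels, self.coef_)

    def inverse(self, response: float) -> float:
        """Level whose fitted response equals ``response``.

        Raises :class:`CalibrationRangeError` when no real root falls in the
        calibrated range (reported downstream as "N/A"), and
        :class:`AmbiguousCalibrationError` when two distinct in-range roots
        exist (a non-monotone calibration cannot be inverted safely).
        """
        self._check_fitted()
        coeffs = self.coef_.copy()
        coeffs[0] -= float(response)
        roots = np.polynomial.polynomial.polyroots(coeffs)
        lo, hi = self.range_
        tol = 1e-9 * max(1.0, hi - lo)
        real = roots[np.abs(roots.imag) < 1e-9].real
        in_range = np.unique(real[(real >= lo - tol) & (real <= hi + tol)])
        # collapse numerically coincident roots (repeated root at the vertex)
        if len(in_range) > 1 and np.ptp(in_range) < 1e-6 * max(1.0, hi - lo):
            in_range = in_range[:1]
        if len(in_range) == 0:
            raise CalibrationRangeError(
                f"response {response:g} has no solution inside the calibrated "
                f"range [{lo:g}, {hi:g}]"
            )
        if len(in_range) > 1:
            raise AmbiguousCalibrationError(
                f"response {response:g} matches {len(in_range)} levels "
                f"({in_range}) inside the calibrated range; the calibration "
                "is not monotone over its range"
            )
        return float(np.clip(in_range[0], lo, hi))

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise AttributeError("calibration is not fitted yet; call fit()")


def _logistic(level, A, B, C, D):
    return A + (B - A) / (1.0 + (np.asarray(level, dtype=float) / C) ** D)


class LogisticCalibration(BaseEstimator):
    """Four-parameter logistic calibration on a scalar color response.

    Fitted attributes are the plateaus ``A_`` (high-level) and ``B_``
    (low-level), midpoint ``C_`` and slope exponent ``D_``, plus
    ``excluded_`` (caller-excluded levels) and ``rejected_`` (points whose
    response fell outside the open plateau interval and could not enter the
    linearized fit).

    Parameters
    ----------
    refine : bool
        Run a nonlinear least-squares refinement of (A, B, C, D) seeded by
        the linearized estimates; kept only if it does not increase the SSE.
    """

    def __init__(self, refine: bool = True):
        self.refine = refine

    def fit(self, levels, responses=None, exclude=(), plateaus=None):
        """Fit the four parameters.

        ``plateaus=(A, B)`` fixes the asymptotes instead of estimating them
        from the two most extreme-level responses; with exact plateaus the
        linearized stage is unbiased and refinement becomes a no-op on
        clean data.
        """
        if responses is None:
            levels, responses = _levels_responses(levels)
        levels = np.asarray(levels, dtype=float).ravel()
        responses = np.asarray(responses, dtype=float).ravel()
        if levels.shape != responses.shape:
            raise ValueError("levels and responses must have the same length")
        if np.any(levels <= 0):
            raise ValueError("levels must be > 0 for the logistic model")
        order = np.argsort(levels)
        levels, responses = levels[order], responses[order]

        # Plateau estimates from the two most extreme-level responses each:
        # B is the low-level plateau of the model, A the high-level one.
        if len(levels) < 4:
            raise ValueError("need at least 4 points to estimate a logistic fit")
        if plateaus is not None:
            A0, B0 = (float(v) for v in plateaus)
        else:
            B0 = float(responses[:2].mean())
            A0 = float(responses[-2:].mean())
        if A0 == B0:
            raise ValueError("flat response: plateau estimates coincide")

        self.excluded_ = sorted(float(e) for e in exclude)
        excl = np.isin(levels, np.asarray(self.excluded_, dtype=float))
        lv, rs = levels[~excl], responses[~excl]

        # Linearized OLS: log((B-y)/(y-A)) = D log(level) - D log(C).
        arg = (B0 - rs) / (rs - A0)
        valid = np.isfinite(arg) & (arg > 0)
        rejected = [(float(l), float(r)) for l, r in zip(lv[~valid], rs[~valid])]
        if rejected:
            warnings.warn(
                f"{len(rejected)} point(s) outside the open plateau interval "
                f"were dropped from the linearized fit: "
                f"levels {[l for l, _ in rejected]}",
                stacklevel=2,
            )
        self.rejected_ = rejected
        lv_ok, arg_ok = lv[valid], arg[valid]
        if len(lv_ok) < 4:
            raise ValueError(
                f"only {len(lv_ok)} usable points after exclusions and plateau "
                "screening; need >= 4"
            )
        slope, intercept = np.polyfit(np.log(lv_ok), np.log(arg_ok), 1)
        D0 = float(slope)
        if D0 == 0:
            raise ValueError("linearized fit produced zero slope (D = 0)")
        C0 = float(np.exp(-intercept / D0))

        A, B, C, D = A0, B0, C0, D0
        if self.refine:
            sse_lin = float(np.sum((_logistic(lv, A0, B0, C0, D0) - rs) ** 2))
            try:
                popt, _ = optimize.curve_fit(
                    _logistic, lv, rs, p0=[A0, B0, C0, D0], maxfev=20000
                )
                sse_ref = float(np.sum((_logistic(lv, *popt) - rs) ** 2))
                if np.isfinite(sse_ref) and sse_ref <= sse_lin and popt[2] > 0:
                    A, B, C, D = (float(v) for v in popt)
            except (RuntimeError, ValueError):
                pass  # keep the linearized estimates

        self.A_, self.B_, self.C_, self.D_ = A, B, C, D
        self.fit_levels_ = lv
        return self

    def predict(self, levels) -> np.ndarray:
        self._check_fitted()
        return _logistic(levels, self.A_, self.B_, self.C_, self.D_)

    def inverse(self, response: float) -> float:
        """Analyte level for a response strictly between the plateaus.

        pH = C * ((B - A)/(response - A) - 1)^(1/D); responses at or beyond
        a plateau raise :class:`CalibrationRangeError` (the "N/A" case).
        """
        self._check_fitted()
        lo, hi = sorted((self.A_, self.B_))
        if not lo < response < hi:
            raise CalibrationRangeError(
                f"response {response:g} is outside the open plateau interval "
                f"({lo:g}, {hi:g}); no level can be interpolated"
            )
        arg = (self.B_ - self.A_) / (response - self.A_) - 1.0
        return float(self.C_ * arg ** (1.0 / self.D_))

    def _check_fitted(self) -> None:
        if not hasattr(self, "C_"):
            raise AttributeError("calibration is not fitted yet; call fit()")


@dataclass(frozen=True)
class PredictionResult:
    """Replicate summary of an unknown: mean level, CI, relative error."""

    estimate: float
    ci95_halfwidth: float
    n_replicates: int
    relative_error: float | None = None


def replicate_summary(estimates, truth: float | None = None) -> PredictionResult:
    """Mean and Student-t 95% CI of replicate level estimates.

    With ``truth`` supplied, also the relative error 100*|mean - truth|/truth
    in percent.  A single replicate yields a NaN CI half-width.
    """
    est = np.asarray(list(estimates), dtype=float)
    if est.size < 1:
        raise ValueError("need at least one estimate")
    mean = float(est.mean())
    if est.size >= 2:
        hw = float(
            stats.t.ppf(0.975, est.size - 1) * est.std(ddof=1) / np.sqrt(est.size)
        )
    else:
        hw = float("nan")
    rel = None if truth is None else float(100.0 * abs(mean - truth) / truth)
    return PredictionResult(
        estimate=mean, ci95_halfwidth=hw, n_replicates=int(est.size), relative_error=rel
    )


# -- thin functional wrappers ------------------------------------------------

def fit_polynomial(points, degree: int = 2) -> PolynomialCalibration:
    return PolynomialCalibration(degree=degree).fit(points)


def invert_polynomial(cal: PolynomialCalibration, response: float) -> float:
    return cal.inverse(response)


def fit_logistic(points, exclude=()) -> LogisticCalibration:
    return LogisticCalibration().fit(points, exclude=exclude)


def predict_logistic(cal: LogisticCalibration, response: float) -> float:
    return cal.inverse(response)
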