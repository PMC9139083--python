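"""Affine device-color correction against a reference chart.

A camera's filter and sensor impose a device-specific mapping on the RGB
values it records.  Over a chart of known reference colors that mapping is
well approximated by an affine transform, and its inverse is estimated by
ordinary least squares:

    [RGB]_c = M1 . [RGB]_0 + M2

where ``[RGB]_0`` is the device-measured triple, ``M1`` is a 3x3 matrix
absorbing chromatic cross-talk and ``M2`` a length-3 offset absorbing
intensity differences.  The fit is performed directly in the 8-bit encoded
sRGB space the measurements live in (a flag switches to linear-light
fitting for experimentation).

Correction quality is judged in CIELAB with CIEDE2000 (2:1:1) against the
just-noticeable-difference criterion: a device passes when the mean color
difference over the chart falls below 2.3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from . import colorspace as cs
from .colorspace import DeltaEParams
from .exceptions import SingularFitError

__all__ = [
    "ColorPairSet",
    "AffineColorCorrection",
    "EvaluationReport",
    "fit_correction",
    "apply_correction",
    "evaluate_pairs",
    "JND_DELTA_E",
]

#: Just-noticeable-difference threshold on CIEDE2000.
JND_DELTA_E = 2.3


@dataclass
class ColorPairSet:
    """Paired device-measured and reference colors, keyed by sample id."""

    ids: list[str]
    measured: np.ndarray  # (n, 3) real-valued RGB, 0..255 scale
    reference: np.ndarray  # (n, 3)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.measured = np.atleast_2d(np.asarray(self.measured, dtype=float))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        n = len(self.ids)
        if self.measured.shape != (n, 3) or self.reference.shape != (n, 3):
            raise ValueError("measured and reference must both be (n, 3) with n ids")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids) -> "ColorPairSet":
        keep = set(keep_ids)
        idx = [i for i, s in enumerate(self.ids) if s in keep]
        return ColorPairSet(
            [self.ids[i] for i in idx],
            self.measured[idx],
            self.reference[idx],
            self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "R_measured": self.measured[:, 0],
                "G_measured": self.measured[:, 1],
                "B_measured": self.measured[:, 2],
                "R_reference": self.reference[:, 0],
                "G_reference": self.reference[:, 1],
                "B_reference": self.reference[:, 2],
            }
        )


class AffineColorCorrection(TransformerMixin, BaseEstimator):
    """Least-squares affine RGB correction (3x3 matrix + offset).

    Parameters
    ----------
    fit_space : {"encoded", "linear"}
        Space in which the affine model is fitted and applied.  The default
        "encoded" fits the 8-bit gamma-encoded values directly, which is the
        space chart CSVs live in; "linear" first decodes to linear light.

    Attributes
    ----------
    M1_ : ndarray of shape (3, 3)
        Chromatic mixing matrix.
    M2_ : ndarray of shape (3,)
        Intensity offset, in counts.
    n_fit_ : int
        Number of color pairs used in the fit.
    residual_rms_ : float
        Root-mean-square training residual over all channels, in counts.

    The estimator follows scikit-learn conventions: ``fit(X, y)`` with
    measured colors as ``X`` and reference colors as ``y``, and
    ``transform(X)`` applying the fitted correction.
    """

    def __init__(self, fit_space: str = "encoded"):
        self.fit_space = fit_space

    # -- helpers -------------------------------------------------------
    def _to_space(self, rgb: np.ndarray) -> np.ndarray:
        if self.fit_space == "encoded":
            return rgb
        if self.fit_space == "linear":
            return cs.decode_srgb(rgb) * 255.0
        raise ValueError(f"fit_space must be 'encoded' or 'linear', got {self.fit_space!r}")

    def _from_space(self, rgb: np.ndarray, clip: bool, quantize: bool) -> np.ndarray:
        if self.fit_space == "linear":
            rgb = cs.encode_srgb(rgb / 255.0, clip=True, quantize=False)
        if clip:
            rgb = np.clip(rgb, 0.0, 255.0)
        if quantize:
            rgb = cs.round_half_away(np.clip(rgb, 0.0, 255.0)).astype(np.int64)
        return rgb

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        """Fit M1, M2 by OLS from measured colors ``X`` to references ``y``.

        Solved as three independent per-channel regressions on the
        augmented regressor (R0, G0, B0, 1); needs >= 4 pairs and a
        full-rank design.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if X.shape != y.shape or X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X and y must both have shape (n, 3)")
        n = X.shape[0]
        if n < 4:
            raise ValueError(
                f"need at least 4 color pairs to determine the 12 affine "
                f"parameters, got {n}"
            )
        Xs = self._to_space(X)
        ys = self._to_space(y)
        design = np.column_stack([Xs, np.ones(n)])
        rank = np.linalg.matrix_rank(design)
        if rank < 4:
            raise SingularFitError(
                f"design matrix has rank {rank} < 4: measured colors are "
                "affinely dependent (e.g. collinear in RGB space)"
            )
        coef, _, _, _ = np.linalg.lstsq(design, ys, rcond=None)
        self.M1_ = coef[:3].T.copy()
        self.M2_ = coef[3].copy()
        self.n_fit_ = n
        resid = design @ coef - ys
        self.residual_rms_ = float(np.sqrt(np.mean(resid ** 2)))
        return self

    def transform(self, X, clip: bool = True, quantize: bool = True):
        """Apply ``M1 . rgb + M2``; clip to [0, 255] and round by default.

        ``quantize=False`` (with ``clip`` optionally False) exposes the
        unclipped real-valued triple for diagnostics.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        Xs = self._to_space(np.atleast_2d(X))
        out = Xs @ self.M1_.T + self.M2_
        out = self._from_space(out, clip=clip, quantize=quantize)
        return out[0] if single else out

    def _check_fitted(self) -> None:
        if not hasattr(self, "M1_"):
            raise AttributeError("correction model is not fitted yet; call fit()")

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        self._check_fitted()
        return json.dumps(
            {
                "M1": self.M1_.tolist(),
                "M2": self.M2_.tolist(),
                "n_fit": self.n_fit_,
                "residual_rms": self.residual_rms_,
                "fit_space": self.fit_space,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AffineColorCorrection":
        d = json.loads(text)
        model = cls(fit_space=d.get("fit_space", "encoded"))
        model.M1_ = np.asarray(d["M1"], dtype=float)
        model.M2_ = np.asarray(d["M2"], dtype=float)
        if model.M1_.shape != (3, 3) or model.M2_.shape != (3,):
            raise ValueError("model JSON must contain a 3x3 M1 and length-3 M2")
        model.n_fit_ = int(d.get("n_fit", 0))
        model.residual_rms_ = float(d.get("residual_rms", float("nan")))
        return model


@dataclass
class EvaluationReport:
    """Per-sample and mean Lab differences of a chart evaluation.

    ``per_sample`` has columns id, dL, da, db, dE2000; the means carry
    two-sided 95% Student-t confidence half-widths (NaN when n < 2).
    ``passed`` is the JND acceptance gate: mean dE2000 < threshold.
    """

    per_sample: pd.DataFrame
    mean_dL: float
    mean_da: float
    mean_db: float
    mean_dE: float
    ci_dL: float
    ci_da: float
    ci_db: float
    ci_dE: float
    params: DeltaEParams
    n: int
    threshold: float = JND_DELTA_E
    corrected: bool = False
    signed: bool = False

    @property
    def passed(self) -> bool:
        return self.mean_dE < self.threshold

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "statistic": ["dL", "da", "db", "dE2000"],
                "mean": [self.mean_dL, self.mean_da, self.mean_db, self.mean_dE],
                "ci95_halfwidth": [self.ci_dL, self.ci_da, self.ci_db, self.ci_dE],
            }
        )


def _t_halfwidth(values: np.ndarray) -> float:
    n = len(values)
    if n < 2:
        return float("nan")
    sd = float(np.std(values, ddof=1))
    return float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))


def evaluate_pairs(
    data: ColorPairSet,
    model: AffineColorCorrection | None = None,
    params: DeltaEParams = DeltaEParams(),
    threshold: float = JND_DELTA_E,
    quantize: bool = True,
    signed: bool = False,
) -> EvaluationReport:
    """Evaluate (optionally corrected) measurements against references in Lab.

    Measured colors are corrected with ``model`` when given (clipped and
    rounded, mirroring 8-bit storage; ``quantize=False`` keeps the real-
    valued diagnostic path), both sides are converted to Lab, and the
    report collects per-sample |dL|, |da|, |db| (signed when ``signed``)
    and CIEDE2000 under ``params``, with Student-t 95% CIs on the means.
    """
    if len(data) == 0:
        raise ValueError("cannot evaluate an empty pair set")
    measured = data.measured
    if model is not None:
        measured = model.transform(measured, clip=quantize, quantize=quantize)
    lab_m = cs.srgb_to_lab(measured)
    lab_r = cs.srgb_to_lab(data.reference)
    diff = lab_m - lab_r
    if not signed:
        diff = np.abs(diff)
    de = np.atleast_1d(cs.delta_e_2000(lab_m, lab_r, params))
    per_sample = pd.DataFrame(
        {
            "id": data.ids,
            "dL": diff[:, 0],
            "da": diff[:, 1],
            "db": diff[:, 2],
            "dE2000": de,
        }
    )
    return EvaluationReport(
        per_sample=per_sample,
        mean_dL=float(diff[:, 0].mean()),
        mean_da=float(diff[:, 1].mean()),
        mean_db=float(diff[:, 2].mean()),
        mean_dE=float(de.mean()),
        ci_dL=_t_halfwidth(diff[:, 0]),
        ci_da=_t_halfwidth(diff[:, 1]),
        ci_db=_t_halfwidth(diff[:, 2]),
        ci_dE=_t_halfwidth(de),
        params=params,
        n=len(data),
        threshold=threshold,
        corrected=model is not None,
        signed=signed,
    )


def fit_correction(data: ColorPairSet, fit_space: str = "encoded") -> AffineColorCorrection:
    """Fit the affine correction on a pair set (wrapper over the estimator)."""
    return AffineColorCorrection(fit_space=fit_space).fit(data.measured, data.reference)


def apply_correction(model: AffineColorCorrection, rgb, clip: bool = True, quantize: bool = True):
    """Apply a fitted correction to one or many RGB triples."""
    return model.transform(rgb, clip=clip, quantize=quantize)
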