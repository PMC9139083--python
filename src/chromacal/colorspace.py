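"""Color-space transforms and the CIEDE2000 color difference.

The device side of digital image colorimetry lives in 8-bit gamma-encoded
sRGB (the JPEG default, referenced to the D65 illuminant).  Perceptual
evaluation happens in CIELAB, and the pH calibration regressor is the CIE
1931 ``x`` chromaticity coordinate.  This module provides the exact,
invertible chain

    sRGB (8-bit) <-> linear RGB <-> XYZ <-> CIELAB,   XYZ -> (x, y)

plus the full CIEDE2000 formula with configurable parametric factors
``kL:kC:kH`` (default 2:1:1, the weighting appropriate for controlled-
lighting comparisons).

All functions are vectorized over a trailing axis of length 3: inputs may
be single triples or arrays of shape ``(..., 3)``.  Internal math is double
precision; quantization to 8-bit happens only in :func:`encode_srgb`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DeltaEParams",
    "D65_WHITE_XYZ",
    "D65_WHITE_xy",
    "RGB_TO_XYZ_MATRIX",
    "XYZ_TO_RGB_MATRIX",
    "decode_srgb",
    "encode_srgb",
    "linear_to_xyz",
    "xyz_to_linear",
    "xyz_to_lab",
    "lab_to_xyz",
    "xyz_to_xy",
    "srgb_to_lab",
    "lab_to_srgb",
    "srgb_to_xy",
    "delta_e_2000",
    "round_half_away",
]


class GamutError(ValueError):
    """Raised when an encode would leave the 8-bit sRGB cube and clipping is off."""


@dataclass(frozen=True)
class DeltaEParams:
    """Parametric weighting factors kL:kC:kH of CIEDE2000.

    The default 2:1:1 halves the weight of the lightness term relative to
    the standard 1:1:1 form.
    """

    kL: float = 2.0
    kC: float = 1.0
    kH: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kL > 0 and self.kC > 0 and self.kH > 0):
            raise ValueError("kL, kC, kH must all be > 0")


#: D65 reference white, Y = 100 scale.
D65_WHITE_XYZ = np.array([95.047, 100.0, 108.883])

#: Chromaticity of the D65 white above.
D65_WHITE_xy = tuple(D65_WHITE_XYZ[:2] / D65_WHITE_XYZ.sum())

# sRGB primaries (CIE 1931 chromaticities) per IEC 61966-2-1.
_PRIMARIES_xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])


def _derive_rgb_to_xyz() -> np.ndarray:
    # Columns are primary XYZ directions scaled so that (1,1,1) maps to the
    # D65 white (Y=1 scale here); this ties the matrix to the exact white
    # point used for Lab, making the gray axis exactly neutral.
    x, y = _PRIMARIES_xy[:, 0], _PRIMARIES_xy[:, 1]
    cols = np.stack([x / y, np.ones(3), (1.0 - x - y) / y])
    scale = np.linalg.solve(cols, D65_WHITE_XYZ / 100.0)
    return cols * scale


#: Linear-RGB -> XYZ (Y in [0,1]) matrix derived from the sRGB primaries
#: and the D65 white above.  Rounded to 6 digits this is the familiar
#: [[0.412456, 0.357576, 0.180437], [0.212673, 0.715152, 0.072175],
#:  [0.019334, 0.119192, 0.950304]].
RGB_TO_XYZ_MATRIX = _derive_rgb_to_xyz()
XYZ_TO_RGB_MATRIX = np.linalg.inv(RGB_TO_XYZ_MATRIX)

# CIE 1976 Lab constants (exact rational forms).
_LAB_EPS = 216.0 / 24389.0  # (6/29)^3
_LAB_KAPPA = 24389.0 / 27.0


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def _as_triples(c, name: str) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if arr.shape[-1:] != (3,):
        raise ValueError(f"{name} must have trailing dimension 3, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def decode_srgb(c) -> np.ndarray:
    """Gamma-encoded 8-bit sRGB -> linear RGB in [0, 1].

    Standard IEC 61966-2-1 inverse companding: channels are normalized by
    255, values at or below 0.04045 use the linear segment (/12.92), the
    rest the 2.4-power branch.  Accepts real-valued channels (for the
    unquantized diagnostic path) but requires them inside [0, 255].
    """
    arr = _as_triples(c, "RGB")
    if np.any(arr < 0) or np.any(arr > 255):
        bad = arr[(arr < 0) | (arr > 255)]
        raise ValueError(f"RGB channels must lie in [0, 255]; got {bad[:4]}")
    v = arr / 255.0
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def encode_srgb(c, clip: bool = True, quantize: bool = True) -> np.ndarray:
    """Linear RGB -> gamma-encoded sRGB on the 0..255 scale.

    With ``clip=False`` an out-of-gamut result raises :class:`GamutError`
    instead of being silently clipped.  ``quantize=False`` returns the
    real-valued encoding (for diagnostics and round-trip analysis).
    """
    lin = _as_triples(c, "linear RGB")
    out_of_gamut = (lin < 0) | (lin > 1)
    if np.any(out_of_gamut):
        if not clip:
            raise GamutError(
                f"{int(out_of_gamut.any(axis=-1).sum())} color(s) fall outside "
                "the sRGB gamut; pass clip=True to clip"
            )
        lin = np.clip(lin, 0.0, 1.0)
    v = np.where(lin <= 0.04045 / 12.92, lin * 12.92, 1.055 * lin ** (1 / 2.4) - 0.055)
    v = v * 255.0
    if quantize:
        v = round_half_away(np.clip(v, 0.0, 255.0)).astype(np.int64)
    return v


def linear_to_xyz(c) -> np.ndarray:
    """Linear RGB -> CIE XYZ scaled so the reference white has Y = 100."""
    lin = _as_triples(c, "linear RGB")
    return lin @ (RGB_TO_XYZ_MATRIX.T * 100.0)


def xyz_to_linear(c) -> np.ndarray:
    xyz = _as_triples(c, "XYZ")
    return (xyz / 100.0) @ XYZ_TO_RGB_MATRIX.T


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _LAB_EPS, np.cbrt(t), (_LAB_KAPPA * t + 16.0) / 116.0)


def _lab_f_inv(f: np.ndarray) -> np.ndarray:
    f3 = f ** 3
    return np.where(f3 > _LAB_EPS, f3, (116.0 * f - 16.0) / _LAB_KAPPA)


def xyz_to_lab(c, white=D65_WHITE_XYZ) -> np.ndarray:
    """XYZ -> CIE 1976 L*a*b* relative to ``white`` (default D65, Y=100)."""
    xyz = _as_triples(c, "XYZ")
    white = _as_triples(white, "white")
    if np.any(white <= 0):
        raise ValueError("reference white must have strictly positive components")
    f = _lab_f(xyz / white)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(c, white=D65_WHITE_XYZ) -> np.ndarray:
    lab = _as_triples(c, "Lab")
    white = _as_triples(white, "white")
    if np.any(white <= 0):
        raise ValueError("reference white must have strictly positive components")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _lab_f_inv(f) * white


def xyz_to_xy(c) -> np.ndarray:
    """XYZ -> CIE 1931 (x, y) chromaticity.  Black (X+Y+Z = 0) is undefined."""
    xyz = _as_triples(c, "XYZ")
    s = xyz.sum(axis=-1)
    if np.any(s <= 0):
        raise ValueError("chromaticity is undefined for X+Y+Z <= 0")
    return xyz[..., :2] / s[..., None]


def srgb_to_lab(c) -> np.ndarray:
    """8-bit sRGB -> Lab (D65), the evaluation space of the methodology."""
    return xyz_to_lab(linear_to_xyz(decode_srgb(c)))


def lab_to_srgb(c, clip: bool = True, quantize: bool = True) -> np.ndarray:
    return encode_srgb(xyz_to_linear(lab_to_xyz(c)), clip=clip, quantize=quantize)


def srgb_to_xy(c) -> np.ndarray:
    """8-bit sRGB -> CIE (x, y); the x coordinate is the pH regressor."""
    return xyz_to_xy(linear_to_xyz(decode_srgb(c)))


def delta_e_2000(lab1, lab2, params: DeltaEParams = DeltaEParams()) -> np.ndarray:
    """CIEDE2000 color difference between Lab pairs.

    Full formula: G-factor a' rescaling, C'/h' means with hue-angle
    wraparound, the T term, the rotation term RT, and SL/SC/SH weights
    divided by the parametric factors.  Hue angles for neutral colors
    (C' = 0) are taken as 0 and excluded from the hue-difference terms,
    following the standard implementation notes.

    Returns a scalar for a single pair, an array for batched input.
    """
    lab1 = _as_triples(lab1, "lab1")
    lab2 = _as_triples(lab2, "lab2")
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    c7 = Cbar ** 7
    G = 0.5 * (1.0 - np.sqrt(c7 / (c7 + 25.0 ** 7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    def hue(ap, b):
        h = np.degrees(np.arctan2(b, ap))
        h = np.where(h < 0, h + 360.0, h)
        return np.where((ap == 0) & (b == 0), 0.0, h)

    h1p = hue(a1p, b1)
    h2p = hue(a2p, b2)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        habs <= 180.0,
        0.5 * hsum,
        np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
    )
    hbp = np.where(C1p * C2p == 0, hsum, hbp)

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    cb7 = Cbp ** 7
    RC = 2.0 * np.sqrt(cb7 / (cb7 + 25.0 ** 7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    tL = dLp / (params.kL * SL)
    tC = dCp / (params.kC * SC)
    tH = dHp / (params.kH * SH)
    de = np.sqrt(tL ** 2 + tC ** 2 + tH ** 2 + RT * tC * tH)
    return de if de.shape else float(de)
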