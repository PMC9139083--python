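"""Synthetic data generators: charts, device distortion, illuminants, strips.

Every pipeline stage is testable without hardware through these
generators:

* :func:`synth_chart` builds a RAL-like reference chart of in-gamut,
  hue-stratified colors (the shipped stand-in for the licensed commercial
  chart).
* :func:`simulate_measurement` applies a device model — affine chromatic/
  intensity distortion plus Gaussian sensor noise, optional channel
  clipping and 8-bit quantization — in encoded RGB space, the space the
  affine correction fits.  A ``linear`` space flag applies the distortion
  in linear light instead, stress-testing the affine model.
* :func:`render_rgb` is a simplified spectral camera: per-channel inner
  products of illuminant power x surface reflectance x sensor sensitivity
  over 380-780 nm.
* :func:`synth_strip_series` emits calibration series following the
  quadratic (peroxide) and four-parameter logistic (pH) response models.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import colorsys

import numpy as np

from . import colorspace as cs
from .calibration import CalibrationPoint, _logistic
from .chart import ChartEntry, ReferenceChart
from .correction import ColorPairSet

__all__ = [
    "DeviceModel",
    "IlluminantSPD",
    "synth_chart",
    "simulate_measurement",
    "measure_chart",
    "render_rgb",
    "synth_strip_series",
    "gaussian_sensitivities",
    "flat_spd",
    "DEFAULT_NOISE_SD",
]

#: Default sensor noise (counts); the magnitude observed for smartphone
#: patch SDs under controlled light-box illumination (~1.1-1.3 counts).
DEFAULT_NOISE_SD = 1.2


@dataclass
class DeviceModel:
    """Affine device distortion: measured = mix . true + offset + noise."""

    mix: np.ndarray
    offset: np.ndarray
    noise_sd: float = DEFAULT_NOISE_SD
    clip: bool = True
    quantize: bool = True
    space: str = "encoded"  # "encoded" (default) or "linear" hard mode
    seed: int = 0

    def __post_init__(self) -> None:
        self.mix = np.asarray(self.mix, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float).ravel()
        if self.mix.shape != (3, 3) or self.offset.shape != (3,):
            raise ValueError("mix must be 3x3 and offset length 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.space not in ("encoded", "linear"):
            raise ValueError("space must be 'encoded' or 'linear'")

    @classmethod
    def identity(cls, **kwargs) -> "DeviceModel":
        return cls(mix=np.eye(3), offset=np.zeros(3), **kwargs)

    @classmethod
    def realistic(cls, seed: int = 0, strength: float = 25.0, **kwargs) -> "DeviceModel":
        """A smartphone-like affine distortion of controlled magnitude.

        A random chromatic/intensity deviation (cross-talk + offsets) is
        drawn and rescaled so the mean RGB displacement it causes over the
        8-bit cube equals ``strength`` counts.  The default 25 counts
        reproduces the mismatch scale of uncorrected consumer cameras,
        whose mean chart error sits far above the just-noticeable
        difference before correction.
        """
        rng = np.random.default_rng(seed)
        dev_mix = rng.uniform(-0.1, 0.1, (3, 3))
        dev_off = rng.uniform(-10.0, 10.0, 3)
        # mean displacement over a fixed probe grid spanning the cube
        probe = np.array(
            [[r, g, b] for r in (16, 128, 240) for g in (16, 128, 240) for b in (16, 128, 240)],
            dtype=float,
        )
        disp = probe @ dev_mix.T + dev_off
        scale = strength / float(np.mean(np.linalg.norm(disp, axis=1)))
        return cls(
            mix=np.eye(3) + scale * dev_mix,
            offset=scale * dev_off,
            seed=seed,
            **kwargs,
        )


def synth_chart(n: int, seed: int = 0, name: str = "synthetic-chart") -> ReferenceChart:
    """Generate ``n`` distinct, never-saturated, hue-stratified colors.

    Channels stay within [8, 247] so no sample trips the 0/255 screening
    rule; hues are stratified over the circle to emulate a homogeneous
    distribution of color families.  Ids follow a RAL-like "SYN hnnn"
    pattern.  Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    hues = (np.arange(n) + rng.uniform(0.1, 0.9, n)) / n
    sat = rng.uniform(0.25, 0.95, n)
    val = rng.uniform(0.30, 0.95, n)
    rgb = np.array([colorsys.hsv_to_rgb(h, s, v) for h, s, v in zip(hues, sat, val)])
    rgb8 = np.clip(np.round(8.0 + rgb * (247.0 - 8.0)), 8, 247).astype(int)
    # nudge duplicates apart deterministically (rare for moderate n)
    seen: set[tuple[int, int, int]] = set()
    entries: list[ChartEntry] = []
    for i, triple in enumerate(rgb8):
        t = tuple(int(v) for v in triple)
        step = 0
        while t in seen:
            step += 1
            t = tuple(int(np.clip(v + step, 8, 247)) for v in triple)
        seen.add(t)
        sector = int(hues[i] * 8) + 1
        entries.append(ChartEntry(f"SYN {sector}{i:03d}", t))
    return ReferenceChart(entries, name=name)


def simulate_measurement(
    dev: DeviceModel, reference, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Measure reference color(s) through a device model.

    mix . ref + offset + N(0, noise_sd) per channel, in encoded RGB space
    (or linear when the device's ``space`` is "linear"), then optional
    clipping to [0, 255] and 8-bit quantization.
    """
    if rng is None:
        rng = np.random.default_rng(dev.seed)
    ref = np.asarray(reference, dtype=float)
    single = ref.ndim == 1
    ref2 = np.atleast_2d(ref)
    if dev.space == "linear":
        work = cs.decode_srgb(ref2) * 255.0
    else:
        work = ref2
    out = work @ dev.mix.T + dev.offset
    if dev.noise_sd > 0:
        out = out + rng.normal(0.0, dev.noise_sd, out.shape)
    if dev.space == "linear":
        out = cs.encode_srgb(np.clip(out, 0.0, None) / 255.0, clip=True, quantize=False)
    if dev.clip:
        out = np.clip(out, 0.0, 255.0)
    if dev.quantize:
        out = cs.round_half_away(np.clip(out, 0.0, 255.0)).astype(np.int64)
    return out[0] if single else out


def measure_chart(
    dev: DeviceModel, chart: ReferenceChart, rng: np.random.Generator | None = None
) -> ColorPairSet:
    """Measure a whole chart, returning measured/reference pairs."""
    measured = simulate_measurement(dev, chart.rgb_array, rng=rng)
    return ColorPairSet(
        ids=chart.ids,
        measured=measured,
        reference=chart.rgb_array,
        provenance=f"simulated device seed={dev.seed} noise_sd={dev.noise_sd}",
    )


@dataclass
class IlluminantSPD:
    """Relative spectral power distribution over 380-780 nm."""

    wavelengths: np.ndarray
    power: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.wavelengths.shape != self.power.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and power must be equal-length 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def flat_spd(step: float = 5.0) -> IlluminantSPD:
    wl = np.arange(380.0, 780.0 + step / 2, step)
    return IlluminantSPD(wl, np.ones_like(wl), name="equal-energy")


def gaussian_sensitivities(step: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Smooth synthetic camera sensitivities: Gaussian bands centered at
    600 (R), 540 (G) and 450 nm (B).  Purely synthetic stand-ins, not a
    measured camera."""
    wl = np.arange(380.0, 780.0 + step / 2, step)
    centers, widths = (600.0, 540.0, 450.0), (45.0, 45.0, 40.0)
    sens = np.stack([np.exp(-0.5 * ((wl - c) / w) ** 2) for c, w in zip(centers, widths)])
    return wl, sens


def render_rgb(
    spd: IlluminantSPD,
    reflectance: tuple[np.ndarray, np.ndarray],
    sensitivities: tuple[np.ndarray, np.ndarray] | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Render a reflective sample to RGB under an illuminant.

    ``reflectance`` is (wavelengths, values in [0, 1]); ``sensitivities``
    is (wavelengths, (3, n) array), defaulting to the synthetic Gaussian
    bands.  Per channel:  integral(spd x reflectance x sensitivity),
    normalized so a perfect reflector under the same illuminant maps to
    (255, 255, 255), then quantized.
    """
    if sensitivities is None:
        sensitivities = gaussian_sensitivities()
    if np.all(spd.power == 0):
        raise ValueError("all-zero illuminant power")
    wl = spd.wavelengths
    refl = np.interp(wl, reflectance[0], reflectance[1])
    sens = np.stack([np.interp(wl, sensitivities[0], s) for s in sensitivities[1]])
    signal = np.trapezoid(spd.power * refl * sens, wl, axis=1)
    white = np.trapezoid(spd.power * sens, wl, axis=1)
    if np.any(white == 0):
        raise ValueError("a channel gathers no light under this illuminant")
    out = 255.0 * signal / white
    if quantize:
        out = cs.round_half_away(np.clip(out, 0.0, 255.0)).astype(np.int64)
    return out


# -- strip-response series ---------------------------------------------------

#: Default quadratic response coefficients for the peroxide series
#: (response = c1*conc + c2*conc^2, zero blank response), chosen to span
#: roughly half the normalized range over the 0-25 mg/L working window.
H2O2_DEFAULT_COEF = (0.0, 0.035, -5.0e-4)
H2O2_DEFAULT_RANGE = (0.0, 25.0)
H2O2_DEFAULT_BLANK_R0 = 250.0

#: Default logistic parameters for the pH series (CIE x response):
#: orange plateau ~0.46 at low pH, blue-gray ~0.31 at high pH, transition
#: near pH 8.8.
PH_DEFAULT_PARAMS = {"A": 0.31, "B": 0.46, "C": 8.8, "D": 10.0}
PH_DEFAULT_LEVELS = tuple(float(v) for v in range(2, 15))


def _rgb_for_x(x: float, Y: float = 40.0) -> np.ndarray:
    """Construct an RGB whose chromaticity x matches ``x``.

    y tracks x along a line through realistic strip colors; this is a
    synthetic embedding, only the x coordinate is meaningful.
    """
    y = 0.33 + 0.55 * (x - 0.33)
    S = Y / y
    xyz = np.array([x * S, Y, (1.0 - x - y) * S])
    return cs.encode_srgb(np.clip(cs.xyz_to_linear(xyz), 0.0, 1.0), quantize=False)


def synth_strip_series(
    mode: str,
    params: dict | None = None,
    seed: int = 0,
    levels=None,
    replicates: int = 1,
    noise_sd: float = 0.0,
    quantize: bool = False,
) -> list[CalibrationPoint]:
    """Generate a strip-response calibration series.

    mode "h2o2": red-channel series following a quadratic response over
    0-25 mg/L; ``noise_sd`` is in counts on R.  mode "ph": RGB series whose
    CIE x follows the four-parameter logistic over pH 2-14; ``noise_sd`` is
    in CIE x units.  ``quantize=True`` rounds the replicate RGB to 8 bits
    (and recomputes the response from the rounded color) for realism;
    the default keeps continuous responses for exact round trips.
    """
    rng = np.random.default_rng(seed)
    points: list[CalibrationPoint] = []
    if mode == "h2o2":
        p = {"coef": H2O2_DEFAULT_COEF, "R0": H2O2_DEFAULT_BLANK_R0}
        if params:
            p.update(params)
        if levels is None:
            levels = np.linspace(*H2O2_DEFAULT_RANGE, 12)
        c = np.asarray(p["coef"], dtype=float)
        R0 = float(p["R0"])
        for lv in np.asarray(levels, dtype=float):
            resp_true = float(np.polynomial.polynomial.polyval(lv, c))
            for _ in range(replicates):
                R = R0 * (1.0 - resp_true) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                if quantize:
                    R = float(cs.round_half_away(np.clip(R, 0, 255)))
                rgb = (float(R), 190.0, 205.0)  # cyan-ish carrier; only R is used
                points.append(CalibrationPoint(lv, (R0 - R) / R0, rgb))
    elif mode == "ph":
        p = dict(PH_DEFAULT_PARAMS)
        if params:
            p.update(params)
        if levels is None:
            levels = PH_DEFAULT_LEVELS
        for lv in np.asarray(levels, dtype=float):
            x_true = float(_logistic(lv, p["A"], p["B"], p["C"], p["D"]))
            for _ in range(replicates):
                x = x_true + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                rgb = _rgb_for_x(x)
                if quantize:
                    rgb = cs.round_half_away(rgb)
                    x = float(cs.srgb_to_xy(rgb)[0])
                points.append(CalibrationPoint(lv, x, tuple(float(v) for v in rgb)))
    else:
        raise ValueError(f"mode must be 'h2o2' or 'ph', got {mode!r}")
    return points
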