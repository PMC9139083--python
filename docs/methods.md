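# Methods

## Color model

All device colors are 8-bit gamma-encoded sRGB (the JPEG default).  The
transform chain to the evaluation space is the standard one:

1. **Decoding** — channels normalized by 255; inverse companding with the
   linear segment below 0.04045 (÷12.92) and the 2.4-power branch above.
2. **RGB → XYZ** — a 3×3 matrix derived at double precision from the sRGB
   primaries (R 0.64/0.33, G 0.30/0.60, B 0.15/0.06) and the D65 reference
   white fixed at **XYZ = (95.047, 100, 108.883)**.  Deriving the matrix
   from this exact white (rather than from the rounded chromaticity
   (0.3127, 0.3290), which yields Z = 108.906) makes white RGB map to
   exactly that XYZ, so the gray axis is exactly neutral in Lab
   (a = b = 0) and all 16.7M sRGB colors round-trip with zero channel
   error after quantization.  No chromatic adaptation transform is applied.
3. **XYZ → CIELAB** — CIE 1976 with the cube-root/linear split at
   (6/29)³; **XYZ → (x, y)** by projective normalization.

Quantization back to 8 bits happens only at explicit encode boundaries and
rounds halves away from zero.  Out-of-gamut encodes either clip (default)
or raise, caller's choice — never silently both.

**CIEDE2000** is implemented in full (G-factor a′ rescaling, hue means
with wraparound, T and RT terms, SL/SC/SH weights over kL/kC/kH).  Neutral
colors (C′ = 0) take hue 0 and drop out of the hue-difference terms,
following the standard implementation notes.  The package default is
**kL:kC:kH = 2:1:1**, the weighting suited to controlled-lighting
comparisons; the published 34-pair verification dataset (shipped under
`chromacal/data/`) is reproduced to < 1e-4 in the 1:1:1 form.

## Affine correction

The correction `[RGB]_c = M1·[RGB]_0 + M2` is fitted by OLS as three
independent per-channel regressions on the augmented regressor
(R₀, G₀, B₀, 1) — 12 parameters, requiring ≥ 4 pairs and a full-rank
design (collinear measured colors raise a singular-fit error).  Fitting
happens **in encoded 8-bit space**, the space chart CSVs live in; a
`fit_space="linear"` switch exists for experimentation.  Corrected values
are clipped to [0, 255] and rounded before any Lab conversion, mirroring
8-bit storage; an unclipped real-valued path serves diagnostics.

Evaluation converts both sides to Lab and reports per-sample |ΔL|, |Δa|,
|Δb| (a flag emits signed means instead) and ΔE₀₀, with two-sided 95%
Student-t confidence half-widths on the means (undefined at n = 1, reported
as NaN).  The acceptance gate is mean ΔE₀₀ < 2.3, the just-noticeable
difference.

## Screening and matching

Two screening rules, exposed independently and applied
discard-then-evaluate:

* **saturation** — any channel exactly 0 or 255 (information irrecoverably
  clipped); applied to the device side of a pair set;
* **accuracy** — ΔE₀₀ ≥ threshold (default 2.3; the boundary is an
  inclusive reject).

Nearest-chart matching minimizes ΔE₀₀(2:1:1) in Lab between the query and
each entry; Euclidean RGB is available as an alternative metric.  Ties
break by chart order (first entry wins).

## Strip calibrations

**Quadratic (peroxide-type).**  Response `(R₀ − R)/R₀` on the red channel
(the dye absorbs around 650 nm), OLS polynomial of degree 2, working range
0–25 mg/L.  Inversion solves the quadratic and accepts the unique root
inside the calibrated range; no in-range root is an out-of-range error
(reported "N/A" downstream) and two in-range roots is an ambiguity error —
never a silent branch choice.

**Four-parameter logistic (pH-type).**  Response is the CIE `x`
chromaticity; `x = A + (B − A)/(1 + (pH/C)^D)` with B the low-pH plateau,
A the high-pH plateau, C the midpoint and D the slope exponent.  Fit is
two-stage: plateaus estimated as the mean of the two most extreme-level
responses each (or pinned exactly via `plateaus=(A, B)`), then OLS on
`log((B−x)/(x−A)) = D·log pH − D·log C`, then nonlinear refinement of all
four parameters seeded by the linear estimates (default on; kept only when
it does not increase the SSE).  Points whose response falls outside the
open plateau interval cannot enter the linearized fit and are dropped with
a warning; excluded levels are always caller-specified, never automatic.
One subtlety: on a steep series that never quite reaches its asymptotes
the extreme-response plateau heuristic is biased (≈2% in C for the default
synthetic pH series), which the refinement stage removes; with exact
plateaus the linearized stage alone is already unbiased.

Unknowns are measured in replicate; summaries report the mean, Student-t
95% CI half-width, and `100·|mean − truth|/truth` when a truth is given.

## Image statistics

ROIs are 0-based, row-major, half-open.  Per-channel mean and
**population** SD (flag for sample SD); exact 256-bin histograms; block-
averaged intensity surfaces (ragged edges included) whose per-channel
max − min block mean quantifies light gradients.  A 500 kpixel minimum-ROI
guidance is a warning (applied by the CLI `stats` command), not an error.
JPEG/PNG input through Pillow; EXIF orientation honored, alpha dropped,
CMYK and >8-bit depths rejected with named errors.

## Synthetic data

The simulator stands in for cameras, charts, illuminants, and strips:

* **Charts** — n distinct colors, hue-stratified over 8 sectors, channels
  confined to [8, 247] so no synthetic sample trips the saturation rule.
* **Devices** — `measured = mix·reference + offset + N(0, noise_sd)`,
  applied in encoded RGB space so the affine correction is exactly
  recoverable (a deliberate idealization; a `space="linear"` hard mode
  applies the distortion in linear light, where the encoded-space affine
  model can only reduce, not eliminate, the error).  Defaults:
  `noise_sd = 1.2` counts, the patch-SD magnitude of a smartphone under
  controlled light-box illumination; `DeviceModel.realistic()` draws a
  random chromatic/intensity deviation rescaled so its mean RGB
  displacement over the cube is 25 counts, the mismatch scale of
  uncorrected consumer cameras (chart means of several ΔE₀₀ before
  correction).  Clipping and 8-bit quantization are on by default;
  recovery-style studies switch them off explicitly.
* **Spectral rendering** — per-channel inner products of illuminant power
  × reflectance × sensitivity over 380–780 nm (linear interpolation onto
  the illuminant grid), normalized so a perfect reflector maps to
  (255, 255, 255).  The Gaussian sensor bands (600/540/450 nm) are purely
  synthetic stand-ins.
* **Strip series** — quadratic response with coefficients
  (0, 0.035, −5·10⁻⁴) over 0–25 mg/L and blank R₀ = 250 (spanning roughly
  half the normalized range, monotone over the window); logistic CIE-x
  response with (A, B, C, D) = (0.31, 0.46, 8.8, 10) over the integer pH
  levels 2–14 — plateaus and midpoint chosen to mimic a universal-indicator
  strip sweeping orange → blue-gray.  Replicate RGB carry the responses
  (an embedding in which only `x` is meaningful for the pH mode);
  `quantize=True` rounds them to 8 bits for realism, while the default
  continuous series supports exact round-trip tests.

All generators are deterministic under a fixed seed.

**What the synthetic studies do not show.**  The device model is affine in
encoded space by construction, so correction quality on it bounds nothing
about real cameras, whose tone curves, demosaicing and JPEG compression
are not affine; the spectral model ignores observer metamerism and uses
invented sensitivities; strip series have Gaussian, time-independent
noise, whereas real strip colors drift with development time.  Passing
tests demonstrate the correctness of the estimators and the internal
consistency of the pipeline, not field accuracy of any device.

## Problem sizes and numerical choices

Study sizes follow the workflow the package models: 55-color charts for
correction studies, 10 held-out colors for matching, triplicate unknowns,
100-simulation noise studies for calibration recovery (σ_x = 0.002, 9
points).  Tolerances in tests: exact color math to 1e-9/1e-10 against
independent oracles (an exact rational-arithmetic derivation of the
transform chain; scikit-image's CIEDE2000), published ΔE pairs to 1e-4
(their printed precision), noise-free model recovery to 1e-6, quantized
recovery to the 0.5-count rounding floor.  `lstsq`/`polyfit` handle all
linear algebra; `scipy.optimize.curve_fit` performs the logistic
refinement with the linearized seed, which keeps it inside the correct
basin on every tested configuration.
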