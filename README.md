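# chromacal

Color management for smartphone **digital image colorimetry** (DIC):
quantifying analytes — peroxide, pH, anything that changes the color of a
test strip — from the RGB channels of ordinary JPEG photographs.

The obstacle to DIC is that every camera sees color differently: filter and
sensor vary between devices, so the same strip photographed with two phones
yields different RGB triples. `chromacal` standardizes measurements to a
common reference by fitting an affine correction against a chart of known
colors, judged in a perceptual color space:

```
[RGB]_c = M1 · [RGB]_0 + M2
```

where `[RGB]_0` is the device-measured color, the 3×3 matrix `M1` absorbs
chromatic cross-talk, and the offset `M2` absorbs intensity differences.
`M1`, `M2` are estimated by ordinary least squares over the chart.
Correction quality is evaluated with the CIEDE2000 color difference
(parametric factors `kL:kC:kH = 2:1:1`) in CIELAB under the D65 white: the
device passes when the mean ΔE₀₀ over the chart drops below the
just-noticeable difference, **ΔE = 2.3**.

Corrected colors feed two strip-calibration models:

* **quadratic** — the normalized red-channel response `(R₀ − R)/R₀` of a
  single darkening dye vs. concentration (H₂O₂-type strips, 0–25 mg/L);
* **four-parameter logistic** — the CIE `x` chromaticity of an indicator
  strip vs. pH: `x = A + (B − A)/(1 + (pH/C)^D)`, fitted through its
  linearization `log((B−A)/(x−A) − 1) = D·log pH − D·log C` with an
  optional nonlinear refinement, then inverted for unknowns.

The package includes exact sRGB ↔ linear RGB ↔ XYZ ↔ CIELAB transforms (and
XYZ → CIE xy), the full CIEDE2000 formula, chart screening rules (channels
railed at 0/255; pairs beyond the JND), nearest-chart-entry matching, ROI
image statistics, and a seeded synthetic-data module (charts, affine device
distortion with sensor noise, simplified spectral rendering, strip series)
so the whole pipeline is testable without hardware.

## Worked example

Simulate a 55-color chart measured by a smartphone-like device (affine
distortion, 1.2 counts of sensor noise), then fit and evaluate the
correction:

```sh
chromacal simulate pairs --n 55 --seed 11 \
    --measured-out measured.csv --reference-out reference.csv
chromacal fit measured.csv reference.csv --model-out model.json
```

```json
{
  "config": {"delta_e_params": [2.0, 1.0, 1.0], "jnd_threshold": 2.3},
  "n_fit": 54,
  "residual_rms": 1.1735480817383304,
  "mean_dE_before": 3.2952899870671932,
  "mean_dE_after": 0.5949705132801805,
  "ci95_dE_after": 0.12310752250807483,
  "pass": true
}
```

Reading the output: one of the 55 samples saturated a channel in the
simulated exposure and was screened out (`n_fit: 54`).  Before correction
the device's mean color error (3.30 ΔE₀₀) is well above the 2.3 JND — its
colors are visibly wrong.  After applying the fitted `M1`/`M2` the mean
error falls to 0.59 ± 0.12 (95% CI), below the JND: the corrected
measurements are perceptually faithful to the reference chart, and the
residual RMS of 1.17 counts is at the level of the sensor noise.  The model
in `model.json` can now correct real sample photographs
(`chromacal apply`), match colors to a chart (`chromacal match`), or feed
strip quantitation (`chromacal quantify --mode h2o2|ph`).

The same workflow is available as a library:

```python
from chromacal import fit_correction, evaluate_pairs
from chromacal.simulate import DeviceModel, measure_chart, synth_chart

pairs = measure_chart(DeviceModel.realistic(seed=11), synth_chart(55, seed=11))
model = fit_correction(pairs)
print(evaluate_pairs(pairs, model).mean_dE)   # 0.59...
```

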