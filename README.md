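# oecfkit

Radiometric characterisation and linearisation of consumer-camera
responses for quantitative (visible and UV) photography.

Consumer cameras apply a nonlinear gain — the opto-electronic conversion
function (OECF) — between scene irradiance and pixel values. `oecfkit`
fits two models to measured OECF curves and inverts them so pixel values
become proportional to scene irradiance:

- **Biexponential gain** `f(E) = a − b·e^(−cE) − d·e^(−gE)` with the
  constraint `a = b + d` (so `f(0) = 0`), fitted by bounded trust-region
  least squares and inverted by bracketed root-finding.
- **Cubic Bézier curve** on normalised axes, with the outer control
  points pinned to the extreme data points, the inner two solved by
  linear least squares with a Gauss–Newton parameter-correction pass,
  and inversion through an axis-swapped 256-entry look-up table.

Supporting machinery: spectral radiometry (photon-flux conversion,
binning, ND filters, the camera exposure equation), dataset
normalisation anchors (`g_max`, `p_min`, `E_max`), Monte-Carlo
propagation of fit-coefficient uncertainty to recovered exposures,
bootstrap confidence intervals for Bézier control points, a whole-image
linearisation pipeline (dark-frame subtraction, ROI sampling,
per-level inversion tables, saturation/below-range masks), SSE +
Wilcoxon signed-rank method comparison, and a synthetic-data module so
every stage is testable offline. Published per-channel calibrations for
two camera models ship as packaged fixtures.

## Library quick start

```python
import numpy as np
from oecfkit import (
    SyntheticTruth, fixtures, simulate_oecf, fit_biexp, invert_biexp,
    normalise_dataset, filter_p_min, fit_bezier, build_lut, lut_lookup,
)

truth = SyntheticTruth(fixtures.fixture_biexp("canon40d_red"), noise_sd=1.0, seed=1)
ds = simulate_oecf(truth)                      # 96-point synthetic OECF
params = fit_biexp(ds)                         # constrained biexponential fit
E = invert_biexp(params, 128.0)                # exposure for pixel level 128

ds.e_max = params.e_max
norm = filter_p_min(normalise_dataset(ds), 31 / 255)
lut = build_lut(fit_bezier(norm))              # 256-entry inversion table
E_norm = lut_lookup(lut, 0.5)                  # normalised exposure at p = 0.5
```

## Command line

The `oecf` entry point bundles the full pipeline (exit codes: 0 ok,
2 usage, 3 data, 4 convergence):

```sh
oecf simulate oecf --channel canon40d_red --noise 1.0 --seed 1 -o oecf.csv
oecf fit-biexp oecf.csv -o params.json
oecf invert-biexp params.json --response 128
oecf fit-bezier oecf.csv --pmin 31 -o curve.json
oecf lut curve.json -n 256 -o lut.csv
oecf mc-bounds params.json --draws 1000 --levels 256 --seed 1 -o bounds.csv
oecf bootstrap oecf.csv --boot 1000 --subset 32 --seed 1 -o curve_ci.json
oecf simulate image --seed 1 -o img.tif
oecf linearize img.tif --dark img.dark.tif --method biexp --calib params.json -o linear.tif
oecf compare --measured m.csv --biexp a.csv --bezier b.csv -o report.json
oecf radiometry exposure --radiance rad.csv --sens sens.csv --trans trans.csv \
    --fnumber 8 --tint 0.017
```

A YAML config file (`oecf --config run.yaml <subcommand> ...`) can
pre-set options; explicit flags win. Stochastic subcommands take an
explicit `--seed` and can write a JSON run log (`--log`).

## Known data caveats

The packaged per-channel calibration fixtures store the published values
verbatim, including two internal inconsistencies in the source tables:
the rate coefficients (`c`, `g`) are not unit-consistent with the printed
anchor exposure `E_max` (the library therefore re-derives `E_max` from
the coefficients via `f(E_max) = g_max` where one is needed), and two
channels' printed control-point x-coordinates are non-monotone in `t`
(such curves are flagged and refuse LUT construction rather than being
silently repaired).
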