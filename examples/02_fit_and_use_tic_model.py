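"""Calibrate the TIC-prediction model and use it to gate windows.

The MS2 total ion current an instrument collects over an m/z-RT window is
linearly related to the integrated MS1 intensity in that window. Here we
simulate calibration pairs from a DDA run of a hypothetical platform
(true relation TIC = 2.2 * integral + 500 with measurement noise), fit the
model by ordinary least squares, and show how the fitted model converts a
window integral into a predicted TIC that is compared against the quality
threshold.
"""

import numpy as np

from ms2path import fit_tic_model, predict_tic

rng = np.random.default_rng(0)
integrals = rng.uniform(100.0, 5000.0, size=120)
observed_tic = 2.2 * integrals + 500.0 + rng.normal(0.0, 150.0, size=120)

model = fit_tic_model(list(zip(integrals, observed_tic)), delta=0.2)
print(f"fitted: slope={model.slope:.3f}  intercept={model.intercept:.1f}  "
      f"R^2={model.r_squared:.4f}")
print(f"true:   slope=2.200  intercept=500.0")

threshold = 1e3
for integral in (100.0, 250.0, 1000.0):
    tic = predict_tic(model, integral)
    verdict = "acquire" if tic >= threshold else "skip (below threshold)"
    print(f"integral {integral:7.1f} intensity*s -> predicted TIC {tic:7.1f} -> {verdict}")
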