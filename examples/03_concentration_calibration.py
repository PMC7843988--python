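"""Concentration calibration and minimum detectable concentration.

Runs the full synthetic experiment for NaCl and glucose: 11 concentrations
(0-100 mg/ml), 5 replicates, 3000 averaged frames per image at 12 GHz.
Fits I(c) = B + A exp(-c/c0) to the ROI intensities and evaluates
Cmin(c) = dEmax * c0/A * exp(c/c0).
"""

import numpy as np

from teoim import NoiseConfig, SceneConfig, default_spec
from teoim.config import default_roi
from teoim.pipeline import calibrate_series, demo_grid, run_concentration_experiment

grid = demo_grid(128)
scene = SceneConfig()
roi = default_roi(grid)

for solute, seed in (("nacl", 11), ("glucose", 12)):
    series = run_concentration_experiment(
        default_spec(solute), grid=grid, scene=scene, noise=NoiseConfig(seed=seed), roi=roi
    )
    fit, de, curve = calibrate_series(series)
    means = series.intensities.mean(axis=0)
    print(f"\n{solute}:")
    print(f"  ROI means 0..100 mg/ml: {np.array2string(means, precision=4)}")
    print(f"  fit: A={fit.amplitude:.4g}  c0={fit.decay_scale:.4g} mg/ml  B={fit.offset:.4g}")
    print(f"  dEmax ({curve.rule}) = {de:.3g}")
    print(f"  Cmin(0) = {curve.cmin[0]:.3g} mg/ml,  Cmin(100) = {curve.cmin[-1]:.3g} mg/ml")

print(
    "\nIntensity falls monotonically with concentration and saturates; the"
    "\nconducting NaCl responds much more strongly than glucose, so its"
    "\nminimum detectable concentration (~1 mg/ml at low c) is several times"
    "\nsmaller. Cmin grows with c: the sensor is most sensitive in dilute"
    "\nsolutions."
)
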