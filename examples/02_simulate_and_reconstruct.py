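"""Forward simulation and heat-source reconstruction round trip.

Simulates the analyzer frames for a water-filled tube (noise-free), extracts
the two linear-birefringence images, applies the second-derivative inverse
operator, and compares the reconstructed heat source with the true one.
"""

import numpy as np

from teoim import (
    GridSpec,
    ReconstructionConfig,
    SceneConfig,
    WATER,
    extract_lb,
    reconstruct_heat_source,
    simulate_measurement,
)

grid = GridSpec(128, 128, 0.1)
pc = 2e-4  # photoelastic coefficient: keeps retardance deep in the linear regime

frames = simulate_measurement(
    SceneConfig(), WATER, 0.0, None, grid, photoelastic_coefficient=pc
)
q_true = frames.meta["true_heat_source"].values
print(f"max retardance: {frames.meta['delta_max_rad']:.2e} rad")

lb = extract_lb(frames)
for stencil in ("spectral", "central"):
    cfg = ReconstructionConfig(scale_c=1.0 / pc, stencil=stencil, crop_margin_px=2)
    qhat = reconstruct_heat_source(lb, cfg)
    m = cfg.crop_margin_px
    ref = (q_true - q_true.mean())[m:-m, m:-m]
    err = np.linalg.norm(qhat.values - ref) / np.linalg.norm(ref)
    print(f"{stencil:>8} stencil: interior relative L2 error = {err:.2e}")

print(
    "\nThe spectral stencil inverts the periodic forward model essentially"
    "\nexactly; central differences add only discretization error (<1%)."
    "\nThe reconstruction is defined up to the calibration scale C and the"
    "\nsubtracted mean of the source."
)
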