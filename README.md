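# teoim

Analysis pipeline for **thermo-elastic optical indicator microscopy (TEOIM)**
— a scan-free way of visualizing microwave magnetic near fields and, through
them, measuring solute concentrations of aqueous solutions.

A conductive film (ITO on glass) absorbs the magnetic near field of a
microwave-irradiated sample, heats up, and stresses the glass; circularly
polarized probe light picks up a photoelastic retardance that a CCD camera
records through an analyzer at 0° and 45°. The two analyzer images β₁, β₂
encode the normal-stress-difference and shear-stress distributions, and the
heat-source density that produced them is recovered by the second-derivative
operator

    q(x, y) = C ( ∂²β₁/∂x² − ∂²β₁/∂y² + 2 ∂²β₂/∂x∂y ).

When the sample is a thin tube of NaCl or glucose solution, the visualized
intensity tracks the microwave absorption of the liquid: the power surviving
a path *l* through the solution is P(l) = P₀ e^(−2l/Dp) with penetration
depth

    Dp = c / ( ω √(2ε′) √( √(1 + (ε″/ε′)²) − 1 ) ),

where (ε′, ε″) come from a single-Debye-plus-conductivity model of the
solution. ROI intensity versus concentration is fitted with
I(c) = B + A e^(−c/c₀), and the minimum detectable concentration follows
from the fitted curve as Cmin(c) = |ΔEmax (dI/dc)⁻¹| = ΔEmax·c₀/A·e^(c/c₀),
with ΔEmax the largest replicate fluctuation.

The package is aimed at people building or modeling near-field microwave
sensors for biofluids: it provides a physics-based synthetic generator of
analyzer frames (heat source → plane-stress thermoelastic solve → Mueller
polarimetric render → CCD noise and frame averaging), the inverse
reconstruction, the dielectric absorption model, and the calibration /
sensitivity analysis, each usable separately.

## Worked example

Run the synthetic concentration experiment (11 concentrations 0–100 mg/ml,
5 replicates, 3000 averaged frames per image, 12 GHz):

```
python examples/03_concentration_calibration.py
```

prints (abridged):

```
nacl:
  fit: A=0.01383  c0=69.3 mg/ml  B=0.006954
  dEmax (max_sd) = 0.000209
  Cmin(0) = 1.04 mg/ml,  Cmin(100) = 4.42 mg/ml

glucose:
  fit: A=0.005618  c0=100.5 mg/ml  B=0.01533
  Cmin(0) = 4.13 mg/ml,  Cmin(100) = 11.2 mg/ml
```

Reading: the ROI intensity of the reconstructed heat map decays
exponentially with concentration and saturates. The ionic NaCl solution
absorbs much more strongly than glucose (its conductivity adds loss ∝ c),
so its calibration curve is steeper (smaller c₀, larger amplitude) and its
minimum detectable concentration — about 1 mg/ml in dilute solution — is
several times smaller than glucose's. Cmin grows as e^(c/c₀): the sensor is
most sensitive where the solution is dilute.

The other examples show the dielectric model (`01`), the forward/inverse
round trip (`02`, interior relative L2 error ~10⁻⁸ with the spectral
stencil), and the 7–15 GHz frequency sweep whose water-minus-background
contrast peaks at the 12 GHz operating frequency (`04`).

A thin CLI wraps the same pipeline: `teoim simulate`, `teoim reconstruct`,
`teoim calibrate`, `teoim sweep`, and `teoim demo --seed 7` for the full
experiment (outputs CSV/JSON into a directory).

## Layout

- `src/teoim/dielectric.py` — Debye permittivity, penetration depth, attenuation
- `src/teoim/forward_sim.py` — synthetic analyzer-frame generator
- `src/teoim/reconstruct.py` — birefringence extraction and the inverse operator
- `src/teoim/calibrate.py` — replicate statistics, exponential fit, Cmin, sweep curve
- `src/teoim/config.py`, `imgio.py`, `cli.py` — YAML config, TIFF/PNG I/O, CLI
- `src/teoim/pipeline.py` — experiment runners used by examples, CLI and scripts
- `docs/methods.md` — model assumptions, parameter choices, limitations
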