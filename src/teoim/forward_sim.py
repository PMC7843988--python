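"""Synthetic measurement generator.

Produces analyzer-frame images with the physical and statistical structure the
downstream analysis assumes, through a self-consistent chain:

1. a parametric microwave magnetic near-field intensity |H|^2: an isotropic
   Gaussian background (the waveguide aperture mode) plus, for a filled tube,
   a pattern elongated along the tube axis whose amplitude carries the
   dielectric physics — a Lorentzian coupling resonance in frequency times the
   power attenuation ``exp(-2 * effective_path / Dp)`` through the liquid;
2. ohmic heating of the conductive indicator film, ``q = k * |H|^2``;
3. a plane-stress thermoelastic solve for the stresses the heating induces in
   the indicator glass (spectral biharmonic inverse on a periodic domain);
4. a circular-input Mueller polarimetric render of the two analyzer frames
   (0 and 45 degrees) plus unstressed baselines, with per-frame CCD read noise
   averaged over ``n_frames`` and a per-replicate multiplicative drift.

The stress solve uses the thermoelastic potential ``phi`` with
``lap^2 phi = coupling * q`` (periodic, zero-mean right-hand side) and

    sigma_xx = -s d2phi/dy2,  sigma_yy = -s d2phi/dx2,  sigma_xy = s d2phi/dxdy,

up to one shared scale ``s``. This makes the second-derivative heat-source
reconstruction in :mod:`teoim.reconstruct` an exact discrete inverse of the
forward model, which is what the round-trip tests pin down.

Every stochastic operation is a pure function of its inputs and a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dielectric
from .dielectric import PermittivitySpec, complex_permittivity, penetration_depth
from .errors import ParameterError
from .grid import GridSpec, ScalarFieldMap

#: Frequency band (GHz) the parametric near-field model is declared valid in.
SUPPORTED_BAND_GHZ = (1.0, 40.0)

#: Retardance (rad) above which the linearized analysis degrades; the renderer
#: warns when exceeded.
RETARDANCE_GUARD_RAD = 0.3

_MIN_SIM_GRID = 16


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and coupling parameters of one measurement scene.

    The tube lies along x through the grid center. ``effective_path_mm``
    defaults to the tube inner diameter (the microwave path through liquid).
    """

    frequency_GHz: float = 12.0
    polarization: str = "parallel"  # E-field parallel or perpendicular to tube
    tube_inner_diameter_mm: float = 1.0
    tube_outer_diameter_mm: float = 1.5
    tube_filled: bool = True
    background_amplitude: float = 0.3
    background_width_mm: float = 3.0
    tube_coupling_amplitude: float = 5.0
    tube_length_scale_mm: float = 5.0
    resonance_center_GHz: float = 12.0
    resonance_width_GHz: float = 1.5
    effective_path_mm: float | None = None
    perpendicular_suppression: float = 0.02

    def __post_init__(self) -> None:
        if self.polarization not in ("parallel", "perpendicular"):
            raise ParameterError(
                f"polarization must be 'parallel' or 'perpendicular', got "
                f"{self.polarization!r}"
            )
        if not (0 < self.tube_inner_diameter_mm < self.tube_outer_diameter_mm):
            raise ParameterError("need 0 < inner diameter < outer diameter")
        if not self.resonance_width_GHz > 0:
            raise ParameterError("resonance width must be positive")
        if self.background_amplitude < 0 or self.tube_coupling_amplitude < 0:
            raise ParameterError("field amplitudes must be non-negative")
        if not self.background_width_mm > 0 or not self.tube_length_scale_mm > 0:
            raise ParameterError("field length scales must be positive")
        if self.effective_path_mm is not None and self.effective_path_mm < 0:
            raise ParameterError("effective path must be non-negative")
        if not 0 <= self.perpendicular_suppression <= 1:
            raise ParameterError("perpendicular_suppression must be in [0, 1]")

    @property
    def effective_path(self) -> float:
        """Microwave path length through the liquid, mm."""
        if self.effective_path_mm is None:
            return self.tube_inner_diameter_mm
        return self.effective_path_mm


@dataclass(frozen=True)
class NoiseConfig:
    """CCD noise model: per-frame additive Gaussian read noise (i.i.d. pixels),
    frame averaging, and one multiplicative drift factor per replicate."""

    read_noise_sigma: float = 0.01  # fraction of full scale, per frame
    n_frames: int = 3000
    replicate_drift_sigma: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sigma < 0 or self.replicate_drift_sigma < 0:
            raise ParameterError("noise sigmas must be non-negative")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be at least 1")


@dataclass
class StressField:
    """Plane-stress components and the thermoelastic potential they derive from."""

    grid: GridSpec
    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    sigma_xy: np.ndarray
    phi: np.ndarray
    mean_subtracted: float = 0.0  # constant removed from q before the solve

    def __post_init__(self) -> None:
        for name in ("sigma_xx", "sigma_yy", "sigma_xy", "phi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ParameterError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)


@dataclass
class AnalyzerFrameSet:
    """The two analyzer intensity images plus unstressed baselines.

    Intensities are in full-scale [0, 1] units; ``i_full`` is the full-scale
    intensity the Mueller chain was rendered with.
    """

    grid: GridSpec
    i0: np.ndarray
    i45: np.ndarray
    baseline0: np.ndarray
    baseline45: np.ndarray
    i_full: float
    scene: SceneConfig | None = None
    noise: NoiseConfig | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("i0", "i45", "baseline0", "baseline45"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ParameterError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            setattr(self, name, arr)


def _require_sim_grid(grid: GridSpec) -> None:
    if grid.nx < _MIN_SIM_GRID or grid.ny < _MIN_SIM_GRID:
        raise ParameterError(
            f"simulation grids must be at least {_MIN_SIM_GRID} pixels per side"
        )


def background_field(grid: GridSpec, scene: SceneConfig) -> ScalarFieldMap:
    """Circularly symmetric aperture |H|^2 pattern (isotropic Gaussian).

    Peak value equals ``scene.background_amplitude`` at the grid center.
    """
    _require_sim_grid(grid)
    x, y = grid.meshgrid_centered()
    w = scene.background_width_mm
    values = scene.background_amplitude * np.exp(-(x**2 + y**2) / (2.0 * w * w))
    return ScalarFieldMap(grid, values, "field_intensity")


def resonance_gain(scene: SceneConfig, frequency_GHz: float) -> float:
    """Lorentzian coupling resonance, unity at ``resonance_center_GHz``."""
    df = (frequency_GHz - scene.resonance_center_GHz) / scene.resonance_width_GHz
    return 1.0 / (1.0 + df * df)


def tube_field(
    grid: GridSpec, scene: SceneConfig, eps: tuple[float, float]
) -> ScalarFieldMap:
    """|H|^2 pattern localized around the liquid-filled tube.

    An anisotropic Gaussian elongated along the tube axis (x), with peak
    amplitude ``tube_coupling_amplitude * g(f) * exp(-2 * path / Dp)`` where
    ``g`` is the Lorentzian resonance and ``Dp`` the penetration depth of the
    liquid. Perpendicular E-field polarization multiplies the amplitude by
    ``perpendicular_suppression`` (the liquid then barely perturbs the field).
    An empty tube contributes nothing.
    """
    _require_sim_grid(grid)
    if not scene.tube_filled:
        return ScalarFieldMap(grid, np.zeros(grid.shape), "field_intensity")
    lo, hi = SUPPORTED_BAND_GHZ
    if not lo <= scene.frequency_GHz <= hi:
        raise ParameterError(
            f"frequency {scene.frequency_GHz} GHz outside supported band {SUPPORTED_BAND_GHZ}"
        )
    er, ei = eps
    dp = penetration_depth(er, ei, scene.frequency_GHz * 1e9)
    path_m = scene.effective_path * 1e-3
    atten = 1.0 if math.isinf(dp) else math.exp(-2.0 * path_m / dp)
    amp = scene.tube_coupling_amplitude * resonance_gain(scene, scene.frequency_GHz) * atten
    if scene.polarization == "perpendicular":
        amp *= scene.perpendicular_suppression
    x, y = grid.meshgrid_centered()
    lx = scene.tube_length_scale_mm
    ly = scene.tube_outer_diameter_mm / 2.0
    values = amp * np.exp(-(x**2) / (2.0 * lx * lx) - (y**2) / (2.0 * ly * ly))
    return ScalarFieldMap(grid, values, "field_intensity")


def heat_source_from_field(
    h2: ScalarFieldMap, sheet_coefficient: float = 1.0
) -> ScalarFieldMap:
    """Ohmic heating of the indicator film: ``q = sheet_coefficient * |H|^2``."""
    if sheet_coefficient < 0:
        raise ParameterError("sheet_coefficient must be non-negative")
    if h2.role != "field_intensity":
        raise ParameterError(f"expected a field_intensity map, got role {h2.role!r}")
    return ScalarFieldMap(h2.grid, sheet_coefficient * h2.values, "heat_source")


def _wavenumbers(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Angular wavenumbers (1/mm) of the periodic spectral basis, broadcastable."""
    kx = 2.0 * np.pi * np.fft.fftfreq(grid.nx, d=grid.pitch_mm)
    ky = 2.0 * np.pi * np.fft.fftfreq(grid.ny, d=grid.pitch_mm)
    return kx[np.newaxis, :], ky[:, np.newaxis]


def solve_thermoelastic(
    q: ScalarFieldMap, coupling: float = 1.0, stress_scale: float = 1.0
) -> StressField:
    """Plane-stress thermoelastic solve on a periodic domain.

    Solves ``lap^2 phi = coupling * q`` spectrally after subtracting the mean
    of ``q`` (the periodic problem requires a zero-mean source; the removed
    constant is reported on the result), then forms the stresses from second
    derivatives of ``phi`` as described in the module docstring.
    """
    if q.role != "heat_source":
        raise ParameterError(f"expected a heat_source map, got role {q.role!r}")
    values = q.values
    if not np.all(np.isfinite(values)):
        raise ParameterError("heat source must be finite")
    mean = float(values.mean())
    qz = values - mean
    kx, ky = _wavenumbers(q.grid)
    k2 = kx**2 + ky**2
    k4 = k2**2
    qhat = np.fft.fft2(qz)
    with np.errstate(divide="ignore", invalid="ignore"):
        phihat = np.where(k4 > 0, coupling * qhat / np.where(k4 > 0, k4, 1.0), 0.0)
    phi = np.real(np.fft.ifft2(phihat))
    s = stress_scale
    sigma_xx = s * np.real(np.fft.ifft2(ky**2 * phihat))
    sigma_yy = s * np.real(np.fft.ifft2(kx**2 * phihat))
    sigma_xy = -s * np.real(np.fft.ifft2(kx * ky * phihat))
    return StressField(q.grid, sigma_xx, sigma_yy, sigma_xy, phi, mean_subtracted=mean)


def _averaged_noise(
    rng: np.random.Generator, shape: tuple[int, int], noise: NoiseConfig
) -> np.ndarray:
    """Noise of the n_frames-averaged image.

    The average of ``n`` i.i.d. Gaussian read-noise frames is itself Gaussian
    with standard deviation ``sigma / sqrt(n)``; it is sampled directly. The
    unit draw is independent of ``n_frames``, so the same seed at different
    frame counts yields the same noise pattern at different amplitudes.
    """
    unit = rng.standard_normal(shape)
    return unit * (noise.read_noise_sigma / math.sqrt(noise.n_frames))


def render_analyzer_frames(
    stress: StressField,
    photoelastic_coefficient: float,
    i_full: float = 1.0,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AnalyzerFrameSet:
    """Render the two analyzer frames and baselines from a stress field.

    Circularly polarized probe light picks up a retardance
    ``delta = pc * sqrt((sxx - syy)^2 + (2 sxy)^2)`` with fast-axis angle
    ``theta`` given by ``tan 2theta = 2 sxy / (sxx - syy)``; the analyzer at
    angle A then sees ``I(A) = i_full/2 * (1 + sin(delta) sin(2(A - theta)))``.
    The 45-degree frame carries the normal-stress-difference channel and the
    0-degree frame the (negated) shear channel. Baselines are rendered with
    zero stress using the same noise stream discipline.

    Warns if the maximum retardance exceeds the linearization guard (0.3 rad).
    """
    if not i_full > 0:
        raise ParameterError(f"i_full must be positive, got {i_full}")
    if photoelastic_coefficient < 0:
        raise ParameterError("photoelastic_coefficient must be non-negative")
    n = stress.sigma_xx - stress.sigma_yy
    shear = 2.0 * stress.sigma_xy
    r = np.hypot(n, shear)
    delta_max = photoelastic_coefficient * float(r.max(initial=0.0))
    if delta_max > RETARDANCE_GUARD_RAD:
        warnings.warn(
            f"maximum retardance {delta_max:.3f} rad exceeds the linearization "
            f"guard {RETARDANCE_GUARD_RAD} rad; extracted channels will be biased",
            stacklevel=2,
        )
    # sin(pc*r)/r with the r -> 0 limit pc, via the normalized sinc.
    sinc_term = photoelastic_coefficient * np.sinc(photoelastic_coefficient * r / np.pi)
    half = i_full / 2.0
    i45 = half * (1.0 + sinc_term * n)
    i0 = half * (1.0 - sinc_term * shear)
    b45 = np.full(stress.grid.shape, half)
    b0 = np.full(stress.grid.shape, half)
    if noise is not None and noise.read_noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        # Fixed draw order: i0, i45, baseline0, baseline45.
        i0 = i0 + _averaged_noise(rng, stress.grid.shape, noise)
        i45 = i45 + _averaged_noise(rng, stress.grid.shape, noise)
        b0 = b0 + _averaged_noise(rng, stress.grid.shape, noise)
        b45 = b45 + _averaged_noise(rng, stress.grid.shape, noise)
    i0, i45, b0, b45 = (np.clip(a, 0.0, 1.0) for a in (i0, i45, b0, b45))
    return AnalyzerFrameSet(
        stress.grid, i0, i45, b0, b45, i_full, noise=noise,
        meta={"delta_max_rad": delta_max},
    )


def simulate_measurement(
    scene: SceneConfig,
    spec: PermittivitySpec,
    concentration: float,
    noise: NoiseConfig | None,
    grid: GridSpec,
    *,
    sheet_coefficient: float = 1.0,
    coupling: float = 1.0,
    stress_scale: float = 1.0,
    photoelastic_coefficient: float = 0.05,
    i_full: float = 1.0,
    rng: np.random.Generator | None = None,
) -> AnalyzerFrameSet:
    """End-to-end synthetic measurement for one scene and concentration.

    Composes background + tube field -> film heating -> thermoelastic solve ->
    polarimetric render. Deterministic given (configs, seed). A multiplicative
    per-replicate drift (one scalar per call, drawn before the image noise)
    scales the whole field amplitude when a noise config is supplied.
    """
    eps = complex_permittivity(spec, concentration, scene.frequency_GHz * 1e9)
    h2 = background_field(grid, scene)
    tube = tube_field(grid, scene, eps)
    values = h2.values + tube.values
    if noise is not None:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        if noise.replicate_drift_sigma > 0:
            values = values * (1.0 + noise.replicate_drift_sigma * rng.standard_normal())
    field_map = ScalarFieldMap(grid, values, "field_intensity")
    q = heat_source_from_field(field_map, sheet_coefficient)
    stress = solve_thermoelastic(q, coupling=coupling, stress_scale=stress_scale)
    frames = render_analyzer_frames(
        stress, photoelastic_coefficient, i_full=i_full, noise=noise, rng=rng
    )
    frames.scene = scene
    frames.meta.update(
        solute=spec.solute,
        concentration_mg_ml=float(concentration),
        frequency_GHz=scene.frequency_GHz,
        eps_real=eps[0],
        eps_imag=eps[1],
        true_heat_source=q,
    )
    return frames


DEFAULT_CONCENTRATIONS = tuple(float(c) for c in range(0, 101, 10))
DEFAULT_FREQUENCIES_GHZ = tuple(float(f) for f in range(7, 16))


def _cell_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (below 2^31) derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def generate_concentration_dataset(
    spec: PermittivitySpec,
    scene: SceneConfig,
    noise: NoiseConfig,
    grid: GridSpec,
    concentrations=DEFAULT_CONCENTRATIONS,
    replicates: int = 5,
    out_dir=None,
    **chain_kwargs,
) -> tuple[list[AnalyzerFrameSet], pd.DataFrame]:
    """One frame set per (concentration, replicate), plus a manifest table.

    Concentrations must be non-negative and sorted ascending. Each cell gets
    its own child seed derived from ``noise.seed`` (recorded in the manifest),
    which drives both the replicate drift and the read noise. If ``out_dir``
    is given the four frames of every cell are written as 16-bit TIFFs and the
    manifest as ``manifest.csv`` there.
    """
    conc = [float(c) for c in concentrations]
    if not conc:
        raise ParameterError("concentration list must not be empty")
    if any(c < 0 for c in conc):
        raise ParameterError("concentrations must be non-negative")
    if conc != sorted(conc):
        raise ParameterError("concentrations must be sorted ascending")
    if replicates < 1:
        raise ParameterError("need at least one replicate")
    seeds = _cell_seeds(noise.seed, len(conc) * replicates)
    frame_sets: list[AnalyzerFrameSet] = []
    rows = []
    k = 0
    for c in conc:
        for rep in range(replicates):
            cell_noise = replace(noise, seed=seeds[k])
            frames = simulate_measurement(
                scene, spec, c, cell_noise, grid, **chain_kwargs
            )
            frames.meta["replicate"] = rep
            frame_sets.append(frames)
            rows.append(
                {
                    "solute": spec.solute,
                    "concentration_mg_ml": c,
                    "replicate": rep,
                    "frequency_GHz": scene.frequency_GHz,
                    "seed": seeds[k],
                }
            )
            k += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        from . import imgio  # deferred: keeps the simulator import-light

        manifest = imgio.write_frame_sets(out_dir, frame_sets, manifest)
    return frame_sets, manifest


def generate_frequency_sweep(
    scene: SceneConfig,
    grid: GridSpec,
    noise: NoiseConfig,
    frequencies=DEFAULT_FREQUENCIES_GHZ,
    water_spec: PermittivitySpec | None = None,
    **chain_kwargs,
) -> list[dict]:
    """Paired empty-tube / DI-water frame sets across a frequency sweep.

    The background (empty tube) and water scenes at each frequency share the
    same child seed, so the pair is directly comparable. Returns one record
    ``{"frequency_GHz", "seed", "background", "water"}`` per frequency.
    """
    freqs = [float(f) for f in frequencies]
    if not freqs:
        raise ParameterError("frequency list must not be empty")
    lo, hi = SUPPORTED_BAND_GHZ
    if any(not lo <= f <= hi for f in freqs):
        raise ParameterError(f"frequencies must lie within {SUPPORTED_BAND_GHZ} GHz")
    if water_spec is None:
        water_spec = dielectric.WATER
    seeds = _cell_seeds(noise.seed, len(freqs))
    records = []
    for f, seed in zip(freqs, seeds):
        cell_noise = replace(noise, seed=seed)
        bg_scene = replace(scene, frequency_GHz=f, tube_filled=False)
        water_scene = replace(scene, frequency_GHz=f, tube_filled=True)
        bg = simulate_measurement(bg_scene, water_spec, 0.0, cell_noise, grid, **chain_kwargs)
        water = simulate_measurement(
            water_scene, water_spec, 0.0, cell_noise, grid, **chain_kwargs
        )
        records.append(
            {"frequency_GHz": f, "seed": seed, "background": bg, "water": water}
        )
    return records
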