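"""Synthetic generator: near-field patterns, thermoelastic solve, polarimetric render."""

import math

import numpy as np
import pytest
from dataclasses import replace

from teoim import (
    GLUCOSE,
    NACL,
    WATER,
    GridSpec,
    NoiseConfig,
    ParameterError,
    SceneConfig,
    ScalarFieldMap,
    StressField,
    attenuation_factor,
    background_field,
    complex_permittivity,
    generate_concentration_dataset,
    generate_frequency_sweep,
    heat_source_from_field,
    render_analyzer_frames,
    simulate_measurement,
    solve_thermoelastic,
    tube_field,
)
from teoim.forward_sim import resonance_gain
from teoim.pipeline import measure_roi
from teoim.config import default_roi


class TestBackgroundField:
    def test_zero_amplitude_gives_zero_map(self, square_grid):
        f = background_field(square_grid, SceneConfig(background_amplitude=0.0))
        assert np.all(f.values == 0)

    def test_rotational_symmetry_on_square_grid(self, square_grid):
        f = background_field(square_grid, SceneConfig())
        assert np.allclose(f.values, np.rot90(f.values), atol=1e-12)

    def test_peak_at_center_pixel_with_configured_amplitude(self, square_grid):
        f = background_field(square_grid, SceneConfig(background_amplitude=0.7))
        iy, ix = np.unravel_index(np.argmax(f.values), f.values.shape)
        assert (iy, ix) == (16, 16)
        assert f.values[iy, ix] == pytest.approx(0.7, rel=1e-14)

    def test_rejects_tiny_grids(self):
        with pytest.raises(ParameterError):
            background_field(GridSpec(8, 8, 0.5), SceneConfig())


class TestTubeField:
    def test_empty_tube_contributes_nothing(self, square_grid):
        f = tube_field(square_grid, SceneConfig(tube_filled=False), (60.0, 30.0))
        assert np.all(f.values == 0)

    def test_perpendicular_polarization_suppressed(self, square_grid):
        eps = complex_permittivity(WATER, 0.0, 12e9)
        par = tube_field(square_grid, SceneConfig(polarization="parallel"), eps)
        perp = tube_field(square_grid, SceneConfig(polarization="perpendicular"), eps)
        assert perp.values.max() <= 0.05 * par.values.max()

    def test_peak_amplitude_closed_form_at_resonance(self, square_grid):
        """At the resonance center the Lorentzian gain is 1, so the peak equals
        coupling amplitude times the dielectric attenuation factor."""
        scene = SceneConfig(frequency_GHz=12.0, resonance_center_GHz=12.0)
        eps = complex_permittivity(WATER, 0.0, 12e9)
        f = tube_field(square_grid, scene, eps)
        expected = scene.tube_coupling_amplitude * attenuation_factor(
            WATER, 0.0, 12e9, scene.effective_path * 1e-3
        )
        assert f.values.max() == pytest.approx(expected, rel=1e-12)

    def test_elongated_along_tube_axis(self, square_grid):
        eps = complex_permittivity(WATER, 0.0, 12e9)
        f = tube_field(square_grid, SceneConfig(), eps)
        cy, cx = 16, 16
        off = 6
        assert f.values[cy, cx + off] > f.values[cy + off, cx]


class TestHeatSource:
    def test_quadratic_law_in_field_amplitude(self, square_grid, rng):
        h = rng.uniform(0, 1, square_grid.shape)
        q1 = heat_source_from_field(ScalarFieldMap(square_grid, h), 2.0)
        q2 = heat_source_from_field(ScalarFieldMap(square_grid, 4 * h), 2.0)
        assert np.allclose(q2.values, 4 * q1.values)

    def test_uniform_field_uniform_source(self, square_grid):
        q = heat_source_from_field(ScalarFieldMap(square_grid, np.ones(square_grid.shape)), 3.0)
        assert np.all(q.values == 3.0)

    def test_rejects_negative_coefficient(self, square_grid):
        with pytest.raises(ParameterError):
            heat_source_from_field(ScalarFieldMap(square_grid, np.ones(square_grid.shape)), -1.0)


class TestThermoelasticSolve:
    def test_zero_source_zero_stress(self, sim_grid):
        q = ScalarFieldMap(sim_grid, np.zeros(sim_grid.shape), "heat_source")
        s = solve_thermoelastic(q)
        for arr in (s.sigma_xx, s.sigma_yy, s.sigma_xy, s.phi):
            assert np.allclose(arr, 0.0)

    @pytest.mark.parametrize("m,n", [(1, 1), (2, 3)])
    def test_single_fourier_mode_closed_form(self, m, n):
        """phi = coupling * q / |k|^4 for a pure product-of-sines source."""
        grid = GridSpec(32, 24, 0.5)
        lx, ly = grid.nx * grid.pitch_mm, grid.ny * grid.pitch_mm
        x, y = np.meshgrid(grid.pitch_mm * np.arange(grid.nx), grid.pitch_mm * np.arange(grid.ny))
        q = np.sin(2 * np.pi * m * x / lx) * np.sin(2 * np.pi * n * y / ly)
        k2 = (2 * np.pi * m / lx) ** 2 + (2 * np.pi * n / ly) ** 2
        coupling = 2.5
        sol = solve_thermoelastic(ScalarFieldMap(grid, q, "heat_source"), coupling=coupling)
        assert np.allclose(sol.phi, coupling * q / k2**2, atol=1e-12 * coupling / k2**2)

    def test_mean_subtraction_reported(self, sim_grid):
        q = ScalarFieldMap(sim_grid, np.full(sim_grid.shape, 1.5), "heat_source")
        s = solve_thermoelastic(q)
        assert s.mean_subtracted == pytest.approx(1.5)
        assert np.allclose(s.phi, 0.0)


class TestRenderAnalyzerFrames:
    def _uniform_stress(self, grid, normal=0.0, shear=0.0):
        z = np.zeros(grid.shape)
        return StressField(grid, z + normal, z, z + shear / 2.0, z)

    def test_zero_stress_gives_half_intensity(self, square_grid):
        frames = render_analyzer_frames(self._uniform_stress(square_grid), 0.05)
        assert np.allclose(frames.i0, 0.5)
        assert np.allclose(frames.i45, 0.5)

    def test_uniform_normal_stress_matches_mueller_oracle(self, square_grid):
        """delta=0.1 along theta=0: i0 stays at half scale, i45 = (1+sin 0.1)/2."""
        frames = render_analyzer_frames(self._uniform_stress(square_grid, normal=2.0), 0.05)
        assert np.allclose(frames.i0, 0.5, atol=1e-14)
        assert np.allclose(frames.i45, 0.5 * (1 + math.sin(0.1)), atol=1e-14)

    def test_frame_averaging_scales_noise_as_inverse_sqrt_n(self, square_grid):
        noise = NoiseConfig(read_noise_sigma=0.01, n_frames=10_000, replicate_drift_sigma=0.0, seed=3)
        frames = render_analyzer_frames(self._uniform_stress(square_grid), 0.05, noise=noise)
        measured = frames.i0.std()
        assert measured == pytest.approx(0.01 / math.sqrt(10_000), rel=0.1)

    def test_warns_beyond_linearization_guard(self, square_grid):
        with pytest.warns(UserWarning, match="retardance"):
            render_analyzer_frames(self._uniform_stress(square_grid, normal=20.0), 0.05)

    def test_rejects_nonpositive_full_scale(self, square_grid):
        with pytest.raises(ParameterError):
            render_analyzer_frames(self._uniform_stress(square_grid), 0.05, i_full=0.0)


class TestSimulateMeasurement:
    def test_same_seed_bit_identical(self, sim_grid, scene):
        noise = NoiseConfig(seed=11)
        a = simulate_measurement(scene, NACL, 30.0, noise, sim_grid)
        b = simulate_measurement(scene, NACL, 30.0, noise, sim_grid)
        for key in ("i0", "i45", "baseline0", "baseline45"):
            assert np.array_equal(getattr(a, key), getattr(b, key))

    def test_empty_tube_equals_background_only(self, sim_grid):
        scene = SceneConfig(tube_filled=False)
        frames = simulate_measurement(scene, WATER, 0.0, None, sim_grid)
        bg = background_field(sim_grid, scene)
        q = heat_source_from_field(bg)
        stress = solve_thermoelastic(q)
        ref = render_analyzer_frames(stress, 0.05)
        assert np.allclose(frames.i45, ref.i45)
        assert np.allclose(frames.i0, ref.i0)

    def test_concentrated_solution_attenuates_roi_signal(self, sim_grid, scene):
        """Noise-free: the reconstructed ROI mean is strictly larger for pure
        water than for 100 mg/ml NaCl (monotone attenuation through Dp)."""
        roi = default_roi(sim_grid)
        lo = simulate_measurement(scene, NACL, 0.0, None, sim_grid)
        hi = simulate_measurement(scene, NACL, 100.0, None, sim_grid)
        assert measure_roi(lo, roi) > measure_roi(hi, roi)


class TestConcentrationDataset:
    def test_single_cell_dataset(self, sim_grid, scene, quiet_noise):
        sets, manifest = generate_concentration_dataset(
            NACL, scene, quiet_noise, sim_grid, [25.0], replicates=1
        )
        assert len(sets) == 1
        assert list(manifest["concentration_mg_ml"]) == [25.0]
        assert set(manifest.columns) >= {
            "solute", "concentration_mg_ml", "replicate", "frequency_GHz", "seed"
        }

    def test_noise_free_roi_means_strictly_decreasing(self, sim_grid, scene):
        noise = NoiseConfig(read_noise_sigma=0.0, replicate_drift_sigma=0.0, seed=0)
        roi = default_roi(sim_grid)
        sets, _ = generate_concentration_dataset(
            NACL, scene, noise, sim_grid, list(range(0, 101, 20)), replicates=1
        )
        means = [measure_roi(f, roi) for f in sets]
        assert np.all(np.diff(means) < 0)

    def test_nacl_attenuates_more_than_glucose(self, sim_grid, scene):
        noise = NoiseConfig(read_noise_sigma=0.0, replicate_drift_sigma=0.0, seed=0)
        roi = default_roi(sim_grid)
        nacl, _ = generate_concentration_dataset(NACL, scene, noise, sim_grid, [50.0], replicates=1)
        glu, _ = generate_concentration_dataset(GLUCOSE, scene, noise, sim_grid, [50.0], replicates=1)
        assert measure_roi(nacl[0], roi) < measure_roi(glu[0], roi)

    @pytest.mark.parametrize("conc", [[], [-5.0], [30.0, 10.0]])
    def test_rejects_bad_concentration_lists(self, sim_grid, scene, quiet_noise, conc):
        with pytest.raises(ParameterError):
            generate_concentration_dataset(NACL, scene, quiet_noise, sim_grid, conc)


class TestFrequencySweep:
    def test_single_frequency_yields_one_pair(self, sim_grid, scene, quiet_noise):
        recs = generate_frequency_sweep(scene, sim_grid, quiet_noise, [12.0])
        assert len(recs) == 1
        assert recs[0]["background"].scene.tube_filled is False
        assert recs[0]["water"].scene.tube_filled is True

    def test_narrower_resonance_sharper_contrast(self, scene):
        """Halving the resonance width drops the off-peak Lorentzian gain."""
        narrow = replace(scene, resonance_width_GHz=scene.resonance_width_GHz / 2)
        assert resonance_gain(narrow, 13.0) < resonance_gain(scene, 13.0)
        assert resonance_gain(narrow, 12.0) == resonance_gain(scene, 12.0) == 1.0

    def test_rejects_out_of_band_frequency(self, sim_grid, scene, quiet_noise):
        with pytest.raises(ParameterError):
            generate_frequency_sweep(scene, sim_grid, quiet_noise, [0.1])
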