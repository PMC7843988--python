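"""Birefringence extraction, the second-derivative inverse, and ROI statistics."""

import numpy as np
import pytest

from teoim import (
    GridSpec,
    LBImagePair,
    NoiseConfig,
    ParameterError,
    ReconstructionConfig,
    ScalarFieldMap,
    SceneConfig,
    WATER,
    extract_lb,
    reconstruct_heat_source,
    render_analyzer_frames,
    roi_mean,
    simulate_measurement,
)
from teoim.errors import GridMismatchError
from teoim.forward_sim import StressField


def _lb_from_arrays(grid, b1, b2):
    return LBImagePair(
        ScalarFieldMap(grid, b1, "beta"), ScalarFieldMap(grid, b2, "beta")
    )


def _coord_arrays(grid):
    x, y = np.meshgrid(grid.x_mm(), grid.y_mm())
    return x, y


class TestExtractLB:
    def test_frames_equal_baselines_give_zero(self, square_grid):
        z = np.zeros(square_grid.shape)
        stress = StressField(square_grid, z, z, z, z)
        frames = render_analyzer_frames(stress, 0.05)
        lb = extract_lb(frames)
        assert np.allclose(lb.beta1.values, 0.0)
        assert np.allclose(lb.beta2.values, 0.0)

    def test_uniform_retardance_recovered_within_half_percent(self, square_grid):
        """Render at delta=0.02 along theta=0; the normal channel reads back
        0.02 (gain-scaled) within 0.5% and the shear channel stays at zero."""
        z = np.zeros(square_grid.shape)
        stress = StressField(square_grid, z + 1.0, z, z, z)  # N=1, S=0
        frames = render_analyzer_frames(stress, photoelastic_coefficient=0.02)
        lb = extract_lb(frames, gain=1.0)
        assert np.allclose(lb.beta1.values, 0.02, rtol=5e-3)
        assert np.allclose(lb.beta2.values, 0.0, atol=1e-14)

    def test_common_offset_cancels(self, square_grid):
        z = np.zeros(square_grid.shape)
        stress = StressField(square_grid, z + 0.5, z, z + 0.2, z)
        frames = render_analyzer_frames(stress, 0.05)
        lb = extract_lb(frames)
        shifted = render_analyzer_frames(stress, 0.05)
        for key in ("i0", "i45", "baseline0", "baseline45"):
            setattr(shifted, key, getattr(shifted, key) + 0.07)
        lb2 = extract_lb(shifted)
        assert np.allclose(lb.beta1.values, lb2.beta1.values)
        assert np.allclose(lb.beta2.values, lb2.beta2.values)

    def test_mismatched_grids_rejected(self, square_grid):
        z = np.zeros(square_grid.shape)
        stress = StressField(square_grid, z, z, z, z)
        frames = render_analyzer_frames(stress, 0.05)
        frames.i45 = frames.i45[:-1, :]
        with pytest.raises(GridMismatchError):
            extract_lb(frames)


class TestReconstructOperator:
    def test_symmetric_quadratic_annihilated(self, square_grid):
        """beta1 = x^2 + y^2 with beta2 = 0 lies in the operator's null space."""
        x, y = _coord_arrays(square_grid)
        lb = _lb_from_arrays(square_grid, x**2 + y**2, np.zeros_like(x))
        q = reconstruct_heat_source(lb, ReconstructionConfig(stencil="central"))
        assert np.allclose(q.values, 0.0, atol=1e-9)

    def test_quadratic_plus_bilinear_gives_constant(self, square_grid):
        """beta1 = x^2, beta2 = x*y: central differences are exact on quadratics,
        so q = C * (2 - 0 + 2*1) = 4C uniformly."""
        x, y = _coord_arrays(square_grid)
        c_scale = 1.7
        lb = _lb_from_arrays(square_grid, x**2, x * y)
        q = reconstruct_heat_source(
            lb, ReconstructionConfig(scale_c=c_scale, stencil="central")
        )
        assert np.allclose(q.values, 4.0 * c_scale, rtol=1e-10)

    def test_operator_linearity(self, square_grid, rng):
        cfg = ReconstructionConfig(stencil="central")
        b = [rng.standard_normal(square_grid.shape) for _ in range(4)]
        lb1 = _lb_from_arrays(square_grid, b[0], b[1])
        lb2 = _lb_from_arrays(square_grid, b[2], b[3])
        combo = _lb_from_arrays(square_grid, 2.0 * b[0] - 3.0 * b[2], 2.0 * b[1] - 3.0 * b[3])
        q1 = reconstruct_heat_source(lb1, cfg).values
        q2 = reconstruct_heat_source(lb2, cfg).values
        qc = reconstruct_heat_source(combo, cfg).values
        assert np.allclose(qc, 2.0 * q1 - 3.0 * q2, atol=1e-9)

    def test_crop_larger_than_image_rejected(self, square_grid):
        lb = _lb_from_arrays(square_grid, np.zeros(square_grid.shape), np.zeros(square_grid.shape))
        with pytest.raises(ParameterError):
            reconstruct_heat_source(lb, ReconstructionConfig(crop_margin_px=20))

    def test_cropped_grid_keeps_physical_coordinates(self, square_grid):
        lb = _lb_from_arrays(square_grid, np.zeros(square_grid.shape), np.zeros(square_grid.shape))
        q = reconstruct_heat_source(lb, ReconstructionConfig(crop_margin_px=3))
        assert q.grid.nx == square_grid.nx - 6
        assert q.grid.x0_mm == pytest.approx(3 * square_grid.pitch_mm)


class TestRoundTrip:
    def _roundtrip_error(self, grid, stencil, pc=2e-4, noise=None, presmooth=0.0):
        scene = SceneConfig()
        frames = simulate_measurement(
            scene, WATER, 0.0, noise, grid, photoelastic_coefficient=pc
        )
        q_true = frames.meta["true_heat_source"].values
        cfg = ReconstructionConfig(
            scale_c=1.0 / pc, stencil=stencil, crop_margin_px=2, presmooth_sigma_px=presmooth
        )
        qhat = reconstruct_heat_source(extract_lb(frames), cfg)
        m = cfg.crop_margin_px
        ref = (q_true - q_true.mean())[m:-m, m:-m]
        return np.linalg.norm(qhat.values - ref) / np.linalg.norm(ref)

    def test_spectral_roundtrip_recovers_heat_source(self):
        err = self._roundtrip_error(GridSpec(96, 96, 0.15), "spectral")
        assert err < 1e-6

    def test_central_roundtrip_within_two_percent(self):
        err = self._roundtrip_error(GridSpec(96, 96, 0.15), "central")
        assert err < 0.02

    def test_error_decreases_with_frame_count(self):
        """Averaging more CCD frames shrinks the reconstruction error."""
        grid = GridSpec(64, 64, 0.2)
        errs = [
            self._roundtrip_error(
                grid,
                "central",
                pc=0.05,
                noise=NoiseConfig(read_noise_sigma=0.01, n_frames=n,
                                  replicate_drift_sigma=0.0, seed=5),
                presmooth=1.0,
            )
            for n in (30, 300, 3000)
        ]
        assert errs[0] > errs[1] > errs[2]


class TestRoiMean:
    def test_uniform_map(self, square_grid):
        m = ScalarFieldMap(square_grid, np.full(square_grid.shape, 2.5))
        assert roi_mean(m, (1.0, 1.0, 4.0, 4.0)) == pytest.approx(2.5)

    def test_single_pixel_roi(self, square_grid):
        values = np.arange(square_grid.ny * square_grid.nx, dtype=float).reshape(square_grid.shape)
        m = ScalarFieldMap(square_grid, values)
        # pixel (row 4, col 8): center at x=2.0, y=1.0 mm with 0.25 mm pitch
        got = roi_mean(m, (2.0 - 0.1, 1.0 - 0.1, 2.0 + 0.1, 1.0 + 0.1))
        assert got == values[4, 8]

    def test_checkerboard_averages_pairwise(self):
        grid = GridSpec(16, 16, 1.0)
        a, b = 1.0, 5.0
        board = np.fromfunction(lambda i, j: np.where((i + j) % 2 == 0, a, b), grid.shape)
        m = ScalarFieldMap(grid, board)
        assert roi_mean(m, (0.0, 0.0, 8.0, 8.0)) == pytest.approx((a + b) / 2)

    def test_empty_intersection_rejected(self, square_grid):
        m = ScalarFieldMap(square_grid, np.zeros(square_grid.shape))
        with pytest.raises(ParameterError):
            roi_mean(m, (100.0, 100.0, 101.0, 101.0))
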