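"""Heat-source reconstruction from linear-birefringence images.

The two analyzer frames encode the linear birefringence of the indicator
glass: the 45-degree frame carries the normal-stress-difference channel
(beta1) and the 0-degree frame the shear channel (beta2). The heat-source
density that produced the thermoelastic stresses is recovered by the
second-derivative operator

    q(x, y) = C * ( d2(beta1)/dx2 - d2(beta1)/dy2 + 2 * d2(beta2)/dxdy )

with derivatives taken in physical units (per mm^2) and ``C`` a single
calibration scalar related to the probe wavelength and the indicator's
photoelastic constants; absolute heat units are not recoverable without
those, so ``C`` defaults to 1 and results are in arbitrary units.

Two stencils are provided: ``central`` (second-order central differences,
robust for measured images) and ``spectral`` (FFT derivatives, the exact
discrete inverse of the periodic forward model in :mod:`teoim.forward_sim`).
Because the operator amplifies high-frequency noise, optional Gaussian
pre-smoothing is applied identically to both channels before
differentiation, and a crop margin removes boundary pixels from the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GridMismatchError, ParameterError
from .forward_sim import AnalyzerFrameSet, _wavenumbers
from .grid import GridSpec, ScalarFieldMap

STENCILS = ("central", "spectral")


@dataclass
class LBImagePair:
    """The two linear-birefringence images extracted from analyzer frames."""

    beta1: ScalarFieldMap  # normal-stress-difference channel
    beta2: ScalarFieldMap  # shear channel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta1.grid != self.beta2.grid:
            raise GridMismatchError("beta1 and beta2 must share a grid")

    @property
    def grid(self) -> GridSpec:
        return self.beta1.grid


@dataclass(frozen=True)
class ReconstructionConfig:
    """Settings of the second-derivative reconstruction.

    ``scale_c`` is the calibration constant C (arbitrary units, nonzero);
    ``presmooth_sigma_px`` a Gaussian smoothing width in pixels (0 disables);
    ``crop_margin_px`` the boundary margin excluded from the output (must be
    at least the stencil half-width, 1).
    """

    scale_c: float = 1.0
    stencil: str = "central"
    presmooth_sigma_px: float = 0.0
    crop_margin_px: int = 2

    def __post_init__(self) -> None:
        if self.scale_c == 0:
            raise ParameterError("scale_c must be nonzero")
        if self.stencil not in STENCILS:
            raise ParameterError(f"stencil must be one of {STENCILS}")
        if self.presmooth_sigma_px < 0:
            raise ParameterError("presmooth sigma must be non-negative")
        if self.crop_margin_px < 1:
            raise ParameterError("crop margin must be >= 1 (stencil half-width)")


def extract_lb(frames: AnalyzerFrameSet, gain: float = 1.0) -> LBImagePair:
    """Extract the linear-birefringence pair from an analyzer frame set.

    Per the linearized Mueller model, ``beta1 = gain * 2 (i45 - baseline45) /
    i_full`` and ``beta2 = gain * 2 (baseline0 - i0) / i_full`` (the shear
    channel enters the 0-degree frame with a minus sign in this chain, so it
    is negated here; the convention is pinned by the forward/inverse
    round-trip test). A constant offset common to frame and baseline cancels.
    """
    shapes = {frames.i0.shape, frames.i45.shape, frames.baseline0.shape,
              frames.baseline45.shape}
    if len(shapes) != 1 or shapes.pop() != frames.grid.shape:
        raise GridMismatchError("frames and baselines must share the grid")
    scale = 2.0 * gain / frames.i_full
    beta1 = scale * (frames.i45 - frames.baseline45)
    beta2 = scale * (frames.baseline0 - frames.i0)
    meta = {"gain": gain, "i_full": frames.i_full}
    return LBImagePair(
        ScalarFieldMap(frames.grid, beta1, "beta"),
        ScalarFieldMap(frames.grid, beta2, "beta"),
        meta,
    )


def _central_d2x(a: np.ndarray, h: float) -> np.ndarray:
    out = np.zeros_like(a)
    out[:, 1:-1] = (a[:, 2:] - 2.0 * a[:, 1:-1] + a[:, :-2]) / (h * h)
    return out


def _central_d2y(a: np.ndarray, h: float) -> np.ndarray:
    out = np.zeros_like(a)
    out[1:-1, :] = (a[2:, :] - 2.0 * a[1:-1, :] + a[:-2, :]) / (h * h)
    return out


def _central_dxdy(a: np.ndarray, h: float) -> np.ndarray:
    # Composition of central first differences in x and y (cross stencil).
    out = np.zeros_like(a)
    out[1:-1, 1:-1] = (
        a[2:, 2:] - a[2:, :-2] - a[:-2, 2:] + a[:-2, :-2]
    ) / (4.0 * h * h)
    return out


def reconstruct_heat_source(
    lb: LBImagePair, cfg: ReconstructionConfig | None = None
) -> ScalarFieldMap:
    """Apply the second-derivative operator and return the interior heat map.

    The output grid is the input grid cropped by ``crop_margin_px`` on every
    side (its physical origin shifts accordingly, so ROI coordinates remain
    valid). Raises if the crop would consume the whole image.
    """
    if cfg is None:
        cfg = ReconstructionConfig()
    grid = lb.grid
    h = grid.pitch_mm
    b1 = lb.beta1.values
    b2 = lb.beta2.values
    if cfg.presmooth_sigma_px > 0:
        mode = "wrap" if cfg.stencil == "spectral" else "reflect"
        b1 = gaussian_filter(b1, cfg.presmooth_sigma_px, mode=mode)
        b2 = gaussian_filter(b2, cfg.presmooth_sigma_px, mode=mode)
    if cfg.stencil == "spectral":
        kx, ky = _wavenumbers(grid)
        b1hat = np.fft.fft2(b1)
        b2hat = np.fft.fft2(b2)
        # d2/dx2 - d2/dy2 on beta1; 2 d2/dxdy on beta2.
        qhat = (-(kx**2) + ky**2) * b1hat - 2.0 * kx * ky * b2hat
        q = np.real(np.fft.ifft2(qhat))
    else:
        q = (
            _central_d2x(b1, h)
            - _central_d2y(b1, h)
            + 2.0 * _central_dxdy(b2, h)
        )
    q = cfg.scale_c * q
    m = cfg.crop_margin_px
    cropped_grid = grid.crop(m)  # raises if the margin eats the image
    q_int = q[m:-m, m:-m]
    return ScalarFieldMap(
        cropped_grid,
        q_int,
        "heat_source",
        {"config": cfg, "crop_margin_px": m, **lb.meta},
    )


def roi_mean(field_map: ScalarFieldMap, roi: tuple[float, float, float, float]) -> float:
    """Mean over pixels whose centers fall in the half-open rectangle.

    ``roi = (x0, y0, x1, y1)`` in mm, selecting ``x0 <= x < x1`` and
    ``y0 <= y < y1``. Raises if no pixel center falls inside.
    """
    x0, y0, x1, y1 = (float(v) for v in roi)
    if not (x1 > x0 and y1 > y0):
        raise ParameterError(f"degenerate ROI {roi}")
    x = field_map.grid.x_mm()
    y = field_map.grid.y_mm()
    xm = (x >= x0) & (x < x1)
    ym = (y >= y0) & (y < y1)
    if not xm.any() or not ym.any():
        raise ParameterError(
            f"ROI {roi} does not intersect the valid region "
            f"x=[{x[0]:.3g},{x[-1]:.3g}], y=[{y[0]:.3g},{y[-1]:.3g}] mm"
        )
    return float(field_map.values[np.ix_(ym, xm)].mean())
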