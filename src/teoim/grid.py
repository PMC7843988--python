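"""Image grids and scalar field maps.

One coordinate convention is used everywhere in the package:

* ``x`` increases rightward along the tube axis, ``y`` increases downward;
* arrays are indexed ``[row, col] == [y, x]`` with 0-based indices;
* pixel *centers* sit at physical coordinates ``x0_mm + i * pitch_mm``
  (so the top-left pixel center of an uncropped grid is at ``(0, 0)`` mm);
* rectangles (ROIs) are half-open, ``[x0, x1) x [y0, y1)`` in mm, and select
  pixels whose centers fall inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Roles a scalar field map may play in the pipeline.
FIELD_ROLES = ("heat_source", "field_intensity", "beta")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a 2-D pixel grid with physical pixel pitch.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x (columns) and y (rows). At least 4 each;
        simulation entry points additionally require at least 16.
    pitch_mm : float
        Physical size of one pixel, mm.
    x0_mm, y0_mm : float
        Physical coordinate of the top-left pixel center. Nonzero after
        cropping, so ROI coordinates stay valid across crops.
    """

    nx: int
    ny: int
    pitch_mm: float
    x0_mm: float = 0.0
    y0_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ParameterError(
                f"grid must be at least 4x4 pixels, got {self.nx}x{self.ny}"
            )
        if not self.pitch_mm > 0:
            raise ParameterError(f"pitch_mm must be positive, got {self.pitch_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``."""
        return (self.ny, self.nx)

    def x_mm(self) -> np.ndarray:
        """Physical x coordinates of pixel centers, shape ``(nx,)``."""
        return self.x0_mm + self.pitch_mm * np.arange(self.nx)

    def y_mm(self) -> np.ndarray:
        """Physical y coordinates of pixel centers, shape ``(ny,)``."""
        return self.y0_mm + self.pitch_mm * np.arange(self.ny)

    def center_mm(self) -> tuple[float, float]:
        """Physical coordinate of the grid center (may fall between pixels)."""
        return (
            self.x0_mm + self.pitch_mm * (self.nx - 1) / 2.0,
            self.y0_mm + self.pitch_mm * (self.ny - 1) / 2.0,
        )

    def meshgrid_centered(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinate arrays relative to the grid center.

        Returns ``(X, Y)`` each of shape ``(ny, nx)``, in mm.
        """
        cx, cy = self.center_mm()
        return np.meshgrid(self.x_mm() - cx, self.y_mm() - cy)

    def crop(self, margin_px: int) -> "GridSpec":
        """Grid describing the interior after removing ``margin_px`` on all sides."""
        if margin_px < 0:
            raise ParameterError("crop margin must be non-negative")
        nx = self.nx - 2 * margin_px
        ny = self.ny - 2 * margin_px
        if nx < 4 or ny < 4:
            raise ParameterError(
                f"crop margin {margin_px} leaves fewer than 4 pixels per side"
            )
        return GridSpec(
            nx,
            ny,
            self.pitch_mm,
            self.x0_mm + margin_px * self.pitch_mm,
            self.y0_mm + margin_px * self.pitch_mm,
        )


@dataclass
class ScalarFieldMap:
    """A 2-D gridded real field (heat source, |H|^2, or a birefringence image).

    ``values`` has shape ``grid.shape`` and must be finite everywhere.
    """

    grid: GridSpec
    values: np.ndarray
    role: str = "field_intensity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ParameterError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("field values must be finite")
        if self.role not in FIELD_ROLES:
            raise ParameterError(f"unknown field role {self.role!r}; one of {FIELD_ROLES}")

    def with_values(self, values: np.ndarray, role: str | None = None) -> "ScalarFieldMap":
        return ScalarFieldMap(self.grid, values, role or self.role, dict(self.meta))
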