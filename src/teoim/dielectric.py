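"""Microwave dielectric model of NaCl and glucose aqueous solutions.

The complex relative permittivity of the solution is a single-Debye
relaxation plus an ionic-conductivity loss term::

    eps'(c, w)  = eps_inf + (eps_s(c) - eps_inf) / (1 + (w tau(c))^2)
    eps''(c, w) = (eps_s(c) - eps_inf) * w tau(c) / (1 + (w tau(c))^2)
                  + sigma(c) / (w eps0)

with a linear-in-concentration parametrization of the solute effect::

    eps_s(c) = eps_static - static_decrement * c
    tau(c)   = tau_s * (1 + tau_slope * c)
    sigma(c) = conductivity_slope * c          [S/m], c in mg/ml

Absorption of a plane wave entering the lossy liquid follows the
volume-power-density attenuation law ``P(l) = P0 * exp(-2 l / Dp)`` with the
penetration depth

    Dp = c / ( w sqrt(2 eps') sqrt( sqrt(1 + (eps''/eps')^2) - 1 ) ),

``w = 2*pi*f`` the angular frequency and ``c`` the speed of light. A lossless
medium (``eps'' = 0``) yields an infinite penetration depth, returned as the
``math.inf`` sentinel so lossless sanity cases compose with downstream code.

Default solute parametrizations (25 degC water: eps_s = 78.4, eps_inf = 5.2,
tau = 8.27 ps) are phenomenological, chosen so that loss rises with
concentration for both solutes and much faster for NaCl (whose dissolved ions
conduct) than for glucose (a non-electrolyte that mainly slows the water
relaxation). See ``docs/methods.md`` for the rationale and caveats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constants import SPEED_OF_LIGHT, VACUUM_PERMITTIVITY
from .errors import ParameterError

SOLUTES = ("water", "nacl", "glucose")


@dataclass(frozen=True)
class PermittivitySpec:
    """Debye-plus-conductivity parametrization for one solute.

    Parameters
    ----------
    solute : str
        One of ``"water"``, ``"nacl"``, ``"glucose"``.
    eps_static : float
        Static (zero-frequency) relative permittivity of the pure solvent.
    eps_inf : float
        High-frequency relative permittivity.
    tau_s : float
        Debye relaxation time at zero concentration, seconds.
    static_decrement : float
        Decrease of the static permittivity per mg/ml of solute.
    conductivity_slope : float
        Ionic conductivity per mg/ml of solute, S/m per (mg/ml).
    tau_slope : float
        Fractional change of the relaxation time per mg/ml.
    """

    solute: str
    eps_static: float = 78.4
    eps_inf: float = 5.2
    tau_s: float = 8.27e-12
    static_decrement: float = 0.0
    conductivity_slope: float = 0.0
    tau_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.solute not in SOLUTES:
            raise ParameterError(f"unknown solute {self.solute!r}; one of {SOLUTES}")
        if not self.eps_inf >= 1.0:
            raise ParameterError("eps_inf must be >= 1")
        if not self.eps_static > self.eps_inf:
            raise ParameterError("eps_static must exceed eps_inf")
        if not self.tau_s > 0:
            raise ParameterError("tau_s must be positive")
        if self.conductivity_slope < 0:
            raise ParameterError("conductivity_slope must be non-negative")
        if self.static_decrement < 0:
            raise ParameterError("static_decrement must be non-negative")


#: Pure water at 25 degC.
WATER = PermittivitySpec("water")

#: Saline: ions conduct (dominant loss channel) and depress the static permittivity.
NACL = PermittivitySpec(
    "nacl", static_decrement=0.2, conductivity_slope=0.2, tau_slope=0.0
)

#: Glucose: non-electrolyte; slows the water relaxation and mildly depresses eps_s.
GLUCOSE = PermittivitySpec(
    "glucose", static_decrement=0.02, conductivity_slope=0.0, tau_slope=0.003
)

_DEFAULTS = {"water": WATER, "nacl": NACL, "glucose": GLUCOSE}


def default_spec(solute: str, **overrides) -> PermittivitySpec:
    """Default :class:`PermittivitySpec` for a solute, with optional overrides."""
    if solute not in _DEFAULTS:
        raise ParameterError(f"unknown solute {solute!r}; one of {SOLUTES}")
    spec = _DEFAULTS[solute]
    return replace(spec, **overrides) if overrides else spec


def complex_permittivity(
    spec: PermittivitySpec, concentration: float, frequency: float
) -> tuple[float, float]:
    """Real and imaginary permittivity at a concentration and frequency.

    Parameters
    ----------
    spec : PermittivitySpec
    concentration : float
        Solute concentration, mg/ml; must be non-negative.
    frequency : float
        Frequency in Hz (not angular); must be positive.

    Returns
    -------
    (eps_real, eps_imag) : tuple of float
        Dimensionless; ``eps_real > 0`` and ``eps_imag >= 0``.
    """
    c = float(concentration)
    f = float(frequency)
    if c < 0:
        raise ParameterError(f"concentration must be non-negative, got {c}")
    if not f > 0:
        raise ParameterError(f"frequency must be positive, got {f}")
    eps_s = spec.eps_static - spec.static_decrement * c
    if not eps_s > spec.eps_inf:
        raise ParameterError(
            f"concentration {c} mg/ml outside supported range: "
            f"eps_s(c)={eps_s:.3g} does not exceed eps_inf={spec.eps_inf}"
        )
    tau = spec.tau_s * (1.0 + spec.tau_slope * c)
    if not tau > 0:
        raise ParameterError(f"relaxation time non-positive at c={c} mg/ml")
    omega = 2.0 * math.pi * f
    wt = omega * tau
    delta = eps_s - spec.eps_inf
    denom = 1.0 + wt * wt
    eps_real = spec.eps_inf + delta / denom
    eps_imag = delta * wt / denom + spec.conductivity_slope * c / (
        omega * VACUUM_PERMITTIVITY
    )
    return eps_real, eps_imag


def penetration_depth(eps_real: float, eps_imag: float, frequency: float) -> float:
    """Power penetration depth of a plane wave in a lossy dielectric, meters.

    Implements the attenuation-depth expression exactly as given in the module
    docstring, with ``w = 2*pi*frequency``. A lossless medium (``eps_imag == 0``)
    returns ``math.inf``.
    """
    er = float(eps_real)
    ei = float(eps_imag)
    f = float(frequency)
    if not er > 0:
        raise ParameterError(f"eps_real must be positive, got {er}")
    if ei < 0:
        raise ParameterError(f"eps_imag must be non-negative, got {ei}")
    if not f > 0:
        raise ParameterError(f"frequency must be positive, got {f}")
    if ei == 0.0:
        return math.inf
    omega = 2.0 * math.pi * f
    root = math.sqrt(math.sqrt(1.0 + (ei / er) ** 2) - 1.0)
    return SPEED_OF_LIGHT / (omega * math.sqrt(2.0 * er) * root)


@dataclass(frozen=True)
class PropagationResult:
    """Attenuation of volume power density with depth into the liquid.

    Attributes
    ----------
    penetration_depth_m : float
        ``Dp``; may be ``inf`` for a lossless medium.
    surface_power_density : float
        ``P0``, W/m^3 at the surface.
    depths_m : ndarray
        Depths ``l`` at which the profile was evaluated, meters.
    power_density : ndarray
        ``P(l) = P0 * exp(-2 l / Dp)``, W/m^3.
    """

    penetration_depth_m: float
    surface_power_density: float
    depths_m: np.ndarray
    power_density: np.ndarray

    @property
    def profile(self) -> list[tuple[float, float]]:
        """The profile as ``[(l, P(l)), ...]`` pairs."""
        return list(zip(self.depths_m.tolist(), self.power_density.tolist()))


def power_density_profile(p0: float, dp: float, depths) -> PropagationResult:
    """Evaluate the power-density attenuation law at the given depths.

    Parameters
    ----------
    p0 : float
        Surface volume power density, W/m^3; non-negative.
    dp : float
        Penetration depth, meters; positive (``inf`` allowed).
    depths : array-like
        Depths from the surface, meters; all non-negative.
    """
    if p0 < 0:
        raise ParameterError(f"surface power density must be non-negative, got {p0}")
    if not dp > 0:
        raise ParameterError(f"penetration depth must be positive, got {dp}")
    l = np.atleast_1d(np.asarray(depths, dtype=float))
    if np.any(l < 0):
        raise ParameterError("depths must be non-negative")
    if math.isinf(dp):
        power = np.full_like(l, p0)
    else:
        power = p0 * np.exp(-2.0 * l / dp)
    return PropagationResult(dp, p0, l, power)


def attenuation_factor(
    spec: PermittivitySpec, concentration: float, frequency: float, path_m: float
) -> float:
    """Power attenuation ``exp(-2 * path / Dp)`` through ``path_m`` of solution."""
    if path_m < 0:
        raise ParameterError("path length must be non-negative")
    er, ei = complex_permittivity(spec, concentration, frequency)
    dp = penetration_depth(er, ei, frequency)
    if math.isinf(dp):
        return 1.0
    return math.exp(-2.0 * path_m / dp)
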