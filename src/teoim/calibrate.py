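"""Concentration-response analysis.

Takes replicate ROI intensities per concentration, fits the saturating
exponential calibration model

    I(c) = B + A * exp(-c / c0)

to the per-concentration means, and derives the minimum detectable
concentration from the fitted curve,

    Cmin(c) = | dEmax * (dI/dc)^-1 | = dEmax * c0 / A * exp(c / c0),

where ``dEmax`` is the maximum replicate fluctuation over all measured
concentrations (the margin of error of the measurement). For a decreasing
saturating fit (A > 0) the sensitivity degrades with concentration: Cmin is
strictly increasing in c.

Also provides the background-vs-sample frequency-difference curve used to
pick the operating frequency (the difference peaks at the coupling
resonance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitError, ParameterError

DELTA_E_RULES = ("max_sd", "max_half_range")


@dataclass
class ConcentrationSeries:
    """Replicate x concentration table of ROI intensities for one solute.

    ``intensities`` has shape ``(n_replicates, n_concentrations)``; cell
    metadata (seeds, frequency) may ride along in ``meta``.
    """

    solute: str
    concentrations: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.concentrations.ndim != 1:
            raise ParameterError("concentrations must be 1-D")
        if self.intensities.shape[1] != self.concentrations.size:
            raise ParameterError(
                f"intensities shape {self.intensities.shape} does not match "
                f"{self.concentrations.size} concentrations"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ParameterError("intensity table has missing or non-finite cells")
        if np.unique(self.concentrations).size != self.concentrations.size:
            raise ParameterError("concentrations must be distinct")

    @property
    def n_replicates(self) -> int:
        return self.intensities.shape[0]


def replicate_stats(series: ConcentrationSeries) -> pd.DataFrame:
    """Per-concentration mean and sample standard deviation (n-1 denominator).

    A single-replicate series reports sd 0 with a warning.
    """
    if series.n_replicates < 2:
        warnings.warn(
            "single replicate: standard deviations reported as 0", stacklevel=2
        )
        sd = np.zeros(series.concentrations.size)
    else:
        sd = series.intensities.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "concentration_mg_ml": series.concentrations,
            "mean": series.intensities.mean(axis=0),
            "sd": sd,
            "n": series.n_replicates,
        }
    )


@dataclass
class CalibrationFit:
    """Fitted exponential calibration curve ``I(c) = B + A exp(-c/c0)``."""

    amplitude: float  # A
    decay_scale: float  # c0, mg/ml
    offset: float  # B
    covariance: np.ndarray  # 3x3, parameter order (A, c0, B)
    residual_rms: float
    solute: str = ""
    weighted: bool = False
    pooled: bool = False

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return self.offset + self.amplitude * np.exp(-c / self.decay_scale)

    def derivative(self, c) -> np.ndarray:
        """Analytic dI/dc of the fitted model."""
        c = np.asarray(c, dtype=float)
        return -self.amplitude / self.decay_scale * np.exp(-c / self.decay_scale)


def _model(c, a, c0, b):
    return b + a * np.exp(-c / c0)


def fit_exponential(
    series: ConcentrationSeries, *, pooled: bool = False, weighted: bool = False
) -> CalibrationFit:
    """Least-squares fit of the saturating exponential to the series.

    By default the fit uses the per-concentration means (matching how
    calibration points are plotted); ``pooled=True`` fits all replicate
    points, ``weighted=True`` weights means by the replicate sd.
    Deterministic: the initial guess is ``B0 = min(mean)``, ``A0 = range of
    means``, ``c0_0 = half the concentration span``.
    """
    stats = (
        replicate_stats(series)
        if series.n_replicates > 1
        else pd.DataFrame(
            {
                "concentration_mg_ml": series.concentrations,
                "mean": series.intensities.mean(axis=0),
                "sd": 0.0,
            }
        )
    )
    conc = stats["concentration_mg_ml"].to_numpy()
    means = stats["mean"].to_numpy()
    if conc.size < 3:
        raise ParameterError("need at least 3 distinct concentrations to fit")
    spread = float(means.max() - means.min())
    if spread <= 1e3 * np.finfo(float).eps * max(1.0, abs(means).max()):
        raise DegenerateDataError("intensity variation is at machine-epsilon level")
    if pooled:
        x = np.repeat(series.concentrations[np.newaxis, :], series.n_replicates, 0).ravel()
        y = series.intensities.ravel()
        sigma = None
    else:
        x, y = conc, means
        sigma = None
        if weighted:
            sd = stats["sd"].to_numpy()
            if np.any(sd <= 0):
                raise ParameterError("weighted fit requires positive sd at every point")
            sigma = sd
    p0 = (spread, 0.5 * float(conc.max() - conc.min()), float(means.min()))
    try:
        popt, pcov = curve_fit(
            _model,
            x,
            y,
            p0=p0,
            sigma=sigma,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - hard to trigger deterministically
        raise FitError(f"exponential fit failed to converge: {exc}") from exc
    resid = y - _model(x, *popt)
    return CalibrationFit(
        amplitude=float(popt[0]),
        decay_scale=float(popt[1]),
        offset=float(popt[2]),
        covariance=np.asarray(pcov),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        solute=series.solute,
        weighted=weighted,
        pooled=pooled,
    )


@dataclass
class SensitivityCurve:
    """Minimum detectable concentration along the calibration curve."""

    delta_e_max: float
    concentrations: np.ndarray
    cmin: np.ndarray
    rule: str = ""

    @property
    def cmin_at(self) -> list[tuple[float, float]]:
        return list(zip(self.concentrations.tolist(), self.cmin.tolist()))


def min_detectable_concentration(
    fit: CalibrationFit, delta_e_max: float, at_concentrations
) -> SensitivityCurve:
    """Evaluate ``Cmin(c) = |dEmax / (dI/dc)|`` from the analytic derivative.

    For the exponential model this is ``dEmax * c0 / |A| * exp(c / c0)``.
    """
    if not delta_e_max > 0:
        raise ParameterError(f"delta_e_max must be positive, got {delta_e_max}")
    if fit.amplitude == 0:
        raise ParameterError("fit amplitude is zero: sensitivity undefined")
    c = np.atleast_1d(np.asarray(at_concentrations, dtype=float))
    cmin = delta_e_max * fit.decay_scale / abs(fit.amplitude) * np.exp(c / fit.decay_scale)
    return SensitivityCurve(float(delta_e_max), c, cmin)


def delta_e_max_from_series(series: ConcentrationSeries, rule: str = "max_sd") -> float:
    """Maximum replicate fluctuation over all concentrations.

    ``max_sd`` (default): largest per-concentration sample sd.
    ``max_half_range``: largest per-concentration (max - min) / 2.
    """
    if rule not in DELTA_E_RULES:
        raise ParameterError(f"rule must be one of {DELTA_E_RULES}")
    if series.n_replicates < 2:
        raise ParameterError("fluctuation rules need at least 2 replicates")
    if rule == "max_sd":
        return float(series.intensities.std(axis=0, ddof=1).max())
    half_range = (series.intensities.max(axis=0) - series.intensities.min(axis=0)) / 2.0
    return float(half_range.max())


def sweep_difference_curve(
    frequencies_GHz, background_means, sample_means
) -> tuple[pd.DataFrame, float]:
    """Sample-minus-background curve across a frequency sweep, and its peak.

    The three inputs must be equally long and are sorted by frequency; ties
    in the maximum are broken toward the lowest frequency.
    """
    f = np.asarray(frequencies_GHz, dtype=float)
    bg = np.asarray(background_means, dtype=float)
    sample = np.asarray(sample_means, dtype=float)
    if not (f.shape == bg.shape == sample.shape) or f.ndim != 1:
        raise ParameterError("frequency, background and sample arrays must match")
    order = np.argsort(f, kind="stable")
    f, bg, sample = f[order], bg[order], sample[order]
    diff = sample - bg
    peak = float(f[int(np.argmax(diff))])  # argmax returns the first maximum
    table = pd.DataFrame(
        {
            "frequency_GHz": f,
            "background_mean": bg,
            "sample_mean": sample,
            "difference": diff,
        }
    )
    return table, peak
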