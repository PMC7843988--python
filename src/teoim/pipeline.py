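"""Experiment runners tying simulator, reconstruction and calibration together.

These are the functions the CLI, the examples and the acceptance script call:
each one runs the full synthetic experiment the hardware would perform —
generate analyzer frames, extract the birefringence pair, reconstruct the
heat source, average over the ROI — and hands the resulting tables to the
calibration layer.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, dielectric
from .calibrate import CalibrationFit, ConcentrationSeries, SensitivityCurve
from .config import default_roi
from .forward_sim import (
    DEFAULT_CONCENTRATIONS,
    DEFAULT_FREQUENCIES_GHZ,
    AnalyzerFrameSet,
    NoiseConfig,
    SceneConfig,
    generate_concentration_dataset,
    generate_frequency_sweep,
)
from .grid import GridSpec
from .reconstruct import ReconstructionConfig, extract_lb, reconstruct_heat_source, roi_mean

#: Reconstruction settings used for noisy synthetic frames: light smoothing
#: (the operator amplifies pixel noise) and a 2 px boundary crop.
NOISY_RECON = ReconstructionConfig(presmooth_sigma_px=1.0, crop_margin_px=2)


def demo_grid(n: int = 128, pitch_mm: float = 0.1) -> GridSpec:
    return GridSpec(n, n, pitch_mm)


def measure_roi(
    frames: AnalyzerFrameSet,
    roi: tuple[float, float, float, float],
    recon: ReconstructionConfig = NOISY_RECON,
    gain: float = 1.0,
) -> float:
    """Reconstructed-heat-source ROI mean for one frame set (arbitrary units)."""
    lb = extract_lb(frames, gain=gain)
    q = reconstruct_heat_source(lb, recon)
    return roi_mean(q, roi)


def run_concentration_experiment(
    spec: dielectric.PermittivitySpec,
    *,
    grid: GridSpec,
    scene: SceneConfig,
    noise: NoiseConfig,
    roi=None,
    recon: ReconstructionConfig = NOISY_RECON,
    concentrations=DEFAULT_CONCENTRATIONS,
    replicates: int = 5,
    **chain_kwargs,
) -> ConcentrationSeries:
    """Simulate the replicate concentration series and measure ROI intensities."""
    if roi is None:
        roi = default_roi(grid)
    frame_sets, manifest = generate_concentration_dataset(
        spec, scene, noise, grid, concentrations, replicates, **chain_kwargs
    )
    conc = [float(c) for c in concentrations]
    table = np.empty((replicates, len(conc)))
    for frames, (_, row) in zip(frame_sets, manifest.iterrows()):
        ci = conc.index(float(row["concentration_mg_ml"]))
        table[int(row["replicate"]), ci] = measure_roi(frames, roi, recon)
    return ConcentrationSeries(
        spec.solute,
        np.asarray(conc),
        table,
        meta={"manifest": manifest, "roi": tuple(roi), "frequency_GHz": scene.frequency_GHz},
    )


def run_frequency_sweep_experiment(
    *,
    grid: GridSpec,
    scene: SceneConfig,
    noise: NoiseConfig,
    roi=None,
    recon: ReconstructionConfig = NOISY_RECON,
    frequencies=DEFAULT_FREQUENCIES_GHZ,
    **chain_kwargs,
) -> pd.DataFrame:
    """Background vs DI-water ROI means across the frequency sweep."""
    if roi is None:
        roi = default_roi(grid)
    records = generate_frequency_sweep(
        scene, grid, noise, frequencies, **chain_kwargs
    )
    rows = []
    for rec in records:
        rows.append(
            {
                "frequency_GHz": rec["frequency_GHz"],
                "seed": rec["seed"],
                "background_mean": measure_roi(rec["background"], roi, recon),
                "water_mean": measure_roi(rec["water"], roi, recon),
            }
        )
    return pd.DataFrame(rows)


def calibrate_series(
    series: ConcentrationSeries, rule: str = "max_sd"
) -> tuple[CalibrationFit, float, SensitivityCurve]:
    """Fit the exponential model and evaluate Cmin along the measured range."""
    fit = calibrate.fit_exponential(series)
    de = calibrate.delta_e_max_from_series(series, rule)
    curve = calibrate.min_detectable_concentration(fit, de, series.concentrations)
    curve.rule = rule
    return fit, de, curve


def series_from_table(df: pd.DataFrame, solute: str) -> ConcentrationSeries:
    """Build a series from a long table with columns
    solute, concentration_mg_ml, replicate, roi_mean."""
    sub = df[df["solute"] == solute]
    pivot = sub.pivot(index="replicate", columns="concentration_mg_ml", values="roi_mean")
    pivot = pivot.sort_index(axis=1)
    return ConcentrationSeries(
        solute, pivot.columns.to_numpy(float), pivot.to_numpy(float)
    )


def run_demo(
    seed: int = 0,
    out_dir=None,
    grid_n: int = 128,
    replicates: int = 5,
    concentrations=DEFAULT_CONCENTRATIONS,
    solutes: tuple[str, ...] = ("nacl", "glucose"),
    specs: dict | None = None,
) -> dict:
    """The full synthetic experiment at reduced scale.

    Runs, for each solute, the replicate concentration series at 12 GHz with
    frame-averaged CCD noise, fits the calibration curve, computes the
    minimum detectable concentration, and runs the background/DI-water
    frequency sweep. Returns a JSON-serializable summary; if ``out_dir`` is
    given, writes per-solute series/fit/Cmin tables and the sweep as CSV/JSON.
    """
    grid = demo_grid(grid_n)
    scene = SceneConfig()
    roi = default_roi(grid)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(len(solutes) + 1)]
    summary: dict = {"seed": seed, "grid_n": grid_n, "roi": list(roi), "solutes": {}}
    tables = {}
    if specs is None:
        specs = {s: dielectric.default_spec(s) for s in solutes}
    for solute, cseed in zip(solutes, child_seeds):
        noise = NoiseConfig(seed=cseed)
        series = run_concentration_experiment(
            specs[solute],
            grid=grid,
            scene=scene,
            noise=noise,
            roi=roi,
            concentrations=concentrations,
            replicates=replicates,
        )
        fit, de, curve = calibrate_series(series)
        stats = calibrate.replicate_stats(series)
        summary["solutes"][solute] = {
            "amplitude": fit.amplitude,
            "decay_scale_mg_ml": fit.decay_scale,
            "offset": fit.offset,
            "residual_rms": fit.residual_rms,
            "delta_e_max": de,
            "delta_e_rule": curve.rule,
            "cmin_at_zero_mg_ml": float(curve.cmin[0]),
            "mean_intensity": stats["mean"].tolist(),
            "concentrations_mg_ml": stats["concentration_mg_ml"].tolist(),
        }
        tables[solute] = (series, stats, curve)
    sweep_noise = NoiseConfig(seed=child_seeds[-1])
    sweep = run_frequency_sweep_experiment(
        grid=grid, scene=scene, noise=sweep_noise, roi=roi
    )
    diff_table, peak = calibrate.sweep_difference_curve(
        sweep["frequency_GHz"], sweep["background_mean"], sweep["water_mean"]
    )
    summary["sweep_peak_frequency_GHz"] = peak
    summary["sweep"] = diff_table.to_dict(orient="list")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for solute, (series, stats, curve) in tables.items():
            long = pd.DataFrame(
                {
                    "concentration_mg_ml": np.tile(series.concentrations, series.n_replicates),
                    "replicate": np.repeat(np.arange(series.n_replicates), series.concentrations.size),
                    "roi_mean": series.intensities.ravel(),
                }
            )
            long.insert(0, "solute", solute)
            long.to_csv(out / f"series_{solute}.csv", index=False)
            stats.to_csv(out / f"stats_{solute}.csv", index=False)
            pd.DataFrame(
                {"concentration_mg_ml": curve.concentrations, "cmin_mg_ml": curve.cmin}
            ).to_csv(out / f"cmin_{solute}.csv", index=False)
            (out / f"fit_{solute}.json").write_text(
                json.dumps(summary["solutes"][solute], indent=1)
            )
        diff_table.to_csv(out / "sweep.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
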