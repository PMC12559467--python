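"""Stage orchestration: config handling, file outputs, provenance.

A single YAML/JSON config drives the pipeline commands (simulate, synth,
calibrate, budget). Every output directory gets a ``run_log.json`` with the
seed, the config hash and the package version, so a run is reproducible
from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import mc
from .calibration import (
    DosePoint,
    ExposureRecord,
    fit_power,
    refine_dose_range,
)
from .film import combine_triplicate, measure_pair, read_scan
from .synthetic import SyntheticTruth, default_truth, generate_calibration_dataset
from .uncertainty import DEFAULT_THRESHOLD_PCT, budget_table

__all__ = [
    "load_config",
    "config_hash",
    "cmd_simulate",
    "cmd_synth",
    "cmd_calibrate",
    "cmd_budget",
]

_ALLOWED = {
    "top": {"seed", "output_dir", "simulate", "synth", "calibrate", "budget", "verbosity"},
    "simulate": {
        "film_model",
        "n_histories",
        "air_gap_um",
        "include_water",
        "roi_diameter_mm",
        "pitch_mm",
        "extent_mm",
        "activity_bq",
        "three_line_spectrum",
    },
    "synth": {
        "film_model",
        "medium",
        "triplicates",
        "n_times",
        "noise_sd",
        "pv_bg_level",
        "edge_mm",
    },
    "calibrate": {
        "manifest",
        "film_model",
        "medium",
        "dose_rate_gy_min",
        "sigma_rate_rel",
        "sigma_t_min",
        "refine",
        "threshold_pct",
        "weighted",
        "plots",
    },
    "budget": {"curve_json", "points_csv", "threshold_pct"},
}


class ConfigError(ValueError):
    """Config file contains unknown or invalid keys."""


def _check_keys(section: str, block: dict) -> None:
    unknown = set(block) - _ALLOWED[section]
    if unknown:
        raise ConfigError(f"unknown keys in '{section}' config: {sorted(unknown)}")


def load_config(path) -> dict:
    """Load and validate a YAML/JSON pipeline config."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    _check_keys("top", cfg)
    for section in ("simulate", "synth", "calibrate", "budget"):
        if section in cfg:
            _check_keys(section, cfg[section] or {})
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "alphafilm_out")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_log(out: Path, cfg: dict, seed: int, extra: dict) -> None:
    log = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        **extra,
    }
    with open(out / "run_log.json", "w") as f:
        json.dump(log, f, indent=2)


def cmd_simulate(cfg: dict) -> dict:
    """Run the MC for a film model (and its water variant), write dose
    grids, ROI dose rates and line profiles."""
    block = dict(cfg.get("simulate") or {})
    _check_keys("simulate", block)
    model = block.get("film_model", "EBT3")
    n_hist = int(block.get("n_histories", 2_000_000))
    if n_hist < 1:
        raise ConfigError("n_histories must be >= 1")
    seed = int(cfg.get("seed", 0))
    out = Path(cfg.get("output_dir", "alphafilm_out"))
    out.mkdir(parents=True, exist_ok=True)

    spectrum = mc.AM241_THREE_LINES if block.get("three_line_spectrum") else ((5.46, 1.0),)
    source = mc.SourceSpec(
        activity_bq=float(block.get("activity_bq", 48_000.0)), spectrum=spectrum
    )
    stack = mc.film_stack(model, air_gap_um=float(block.get("air_gap_um", 0.0)))
    roi_d = float(block.get("roi_diameter_mm", 1.0))
    sim_kwargs = dict(
        pitch_mm=float(block.get("pitch_mm", 0.01)),
        extent_mm=float(block.get("extent_mm", 12.0)),
    )

    results = {}
    t0 = time.time()
    stacks = {"film": stack}
    if block.get("include_water", True):
        stacks["water"] = stack.water_variant()
    for medium, stk in stacks.items():
        config = mc.SimulationConfig(source=source, stack=stk, **sim_kwargs)
        grid = mc.run_simulation(config, n_hist, seed if medium == "film" else seed + 1)
        res = mc.roi_mean_dose_rate(grid, roi_d, source.activity_bq)
        grid.to_hdf5(out / f"dose_grid_{model}_{medium}.h5")
        prof = mc.line_profiles(grid, res)
        pd.DataFrame(
            {
                "x_mm": prof["x_mm"],
                "horizontal": prof["horizontal"],
                "horizontal_rel_unc": prof["horizontal_rel_unc"],
                "y_mm": prof["y_mm"],
                "vertical": prof["vertical"],
                "vertical_rel_unc": prof["vertical_rel_unc"],
            }
        ).to_csv(out / f"profiles_{model}_{medium}.csv", index=False)
        results[medium] = {
            "dose_rate_gy_min": res.dose_rate_gy_min,
            "sigma_gy_min": res.sigma_gy_min,
            "sigma_rel_pct": res.sigma_rel_pct,
            "roi_diameter_mm": roi_d,
            "n_histories": n_hist,
        }
    if "water" in results:
        results["percent_difference_vs_water"] = 100.0 * (
            results["water"]["dose_rate_gy_min"] - results["film"]["dose_rate_gy_min"]
        ) / results["water"]["dose_rate_gy_min"]
    with open(out / f"dose_rates_{model}.json", "w") as f:
        json.dump(results, f, indent=2)
    _write_log(out, cfg, seed, {"command": "simulate", "film_model": model, "wall_s": time.time() - t0})
    return results


def cmd_synth(cfg: dict) -> pd.DataFrame:
    """Generate a synthetic calibration dataset (TIFFs + manifest + truth)."""
    block = dict(cfg.get("synth") or {})
    _check_keys("synth", block)
    seed = int(cfg.get("seed", 0))
    out = Path(cfg.get("output_dir", "alphafilm_out")) / "synthetic"
    truth = default_truth(
        film_model=block.get("film_model", "EBT3"),
        medium=block.get("medium", "water"),
        n_times=int(block.get("n_times", 9)),
        seed=seed,
        **{
            k: block[k]
            for k in ("noise_sd", "pv_bg_level", "edge_mm")
            if k in block
        },
    )
    manifest = generate_calibration_dataset(truth, out, int(block.get("triplicates", 3)))
    _write_log(out, cfg, seed, {"command": "synth", "n_scan_pairs": len(manifest)})
    return manifest


def points_from_manifest(
    manifest_path,
    dose_rate_gy_min: float,
    sigma_rate_rel: float = 0.004,
    sigma_t_min: float = 1.0 / 60.0,
) -> list[DosePoint]:
    """Read a scan manifest, measure PVnorm per film (triplicates combined),
    and attach exposure records."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    points = []
    for t, group in manifest.groupby("t_min"):
        reps = []
        for _, row in group.iterrows():
            bg = read_scan(base / row["background_path"], "background")
            irr = read_scan(base / row["irradiated_path"], "irradiated")
            reps.append(measure_pair(bg, irr))
        pv, sigma_pv = combine_triplicate(reps)
        exposure = ExposureRecord(
            t_min=float(t),
            sigma_t_min=sigma_t_min,
            dose_rate_gy_min=dose_rate_gy_min,
            sigma_rate_gy_min=sigma_rate_rel * dose_rate_gy_min,
        )
        points.append(DosePoint(pv_norm=pv, sigma_pv_norm=sigma_pv, exposure=exposure))
    return points


def cmd_calibrate(cfg: dict) -> dict:
    """Full analysis chain: PV extraction -> doses -> power fit -> budget
    (-> refinement). Writes all intermediate tables."""
    block = dict(cfg.get("calibrate") or {})
    _check_keys("calibrate", block)
    seed = int(cfg.get("seed", 0))
    out = Path(cfg.get("output_dir", "alphafilm_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = block["manifest"]
    model = block.get("film_model", "EBT3")
    medium = block.get("medium", "water")
    threshold = float(block.get("threshold_pct", DEFAULT_THRESHOLD_PCT))
    points = points_from_manifest(
        manifest,
        dose_rate_gy_min=float(block["dose_rate_gy_min"]),
        sigma_rate_rel=float(block.get("sigma_rate_rel", 0.004)),
        sigma_t_min=float(block.get("sigma_t_min", 1.0 / 60.0)),
    )
    pd.DataFrame(
        {
            "t_min": [p.exposure.t_min for p in points],
            "D_gy": [p.dose_gy for p in points],
            "PVnorm": [p.pv_norm for p in points],
            "sigma_PVnorm": [p.sigma_pv_norm for p in points],
        }
    ).to_csv(out / "pv_measurements.csv", index=False)
    curve, points = fit_power(points, model, medium, weighted=block.get("weighted", True))
    table = budget_table(points, curve, threshold)
    table.to_csv(out / "budget.csv", index=False)
    with open(out / "curve.json", "w") as f:
        json.dump(curve.to_dict(), f, indent=2)
    result = {"curve": curve.to_dict()}
    if block.get("refine", False):
        ref = refine_dose_range(points, curve, threshold)
        ref_table = budget_table(ref.points, ref.curve, threshold)
        ref_table.to_csv(out / "budget_refined.csv", index=False)
        with open(out / "curve_refined.json", "w") as f:
            json.dump({**ref.curve.to_dict(), "converged": ref.converged}, f, indent=2)
        result["refined"] = {**ref.curve.to_dict(), "converged": ref.converged}
        curve_plot, points_plot = ref.curve, ref.points
    else:
        curve_plot, points_plot = curve, points
    if block.get("plots", True):
        _plot_calibration(out, curve_plot, points_plot)
        _plot_budget(out, budget_table(points_plot, curve_plot, threshold), threshold)
    _write_log(out, cfg, seed, {"command": "calibrate", "film_model": model})
    return result


def cmd_budget(cfg: dict) -> pd.DataFrame:
    """Recompute an uncertainty-budget table from a saved curve and points CSV."""
    from .calibration import CalibrationCurve

    block = dict(cfg.get("budget") or {})
    _check_keys("budget", block)
    out = Path(cfg.get("output_dir", "alphafilm_out"))
    out.mkdir(parents=True, exist_ok=True)
    with open(block["curve_json"]) as f:
        c = json.load(f)
    curve = CalibrationCurve(
        film_model=c["model"],
        medium=c["medium"],
        b=c["b"],
        n=c["n"],
        sigma_b=c["sigma_b"],
        sigma_n=c["sigma_n"],
        chi2_red=c["chi2_red"],
        dose_range=tuple(c["dose_range"]),
    )
    df = pd.read_csv(block["points_csv"])
    points = [
        DosePoint(
            pv_norm=row["PVnorm"],
            sigma_pv_norm=row["sigma_PVnorm"],
            exposure=ExposureRecord(
                t_min=row["t_min"],
                sigma_t_min=row.get("sigma_t_min", 1.0 / 60.0),
                dose_rate_gy_min=row["D_gy"] / row["t_min"],
                sigma_rate_gy_min=row.get("sigma_rate_gy_min", 0.0),
            ),
        )
        for _, row in df.iterrows()
    ]
    table = budget_table(points, curve, float(block.get("threshold_pct", DEFAULT_THRESHOLD_PCT)))
    table.to_csv(out / "budget.csv", index=False)
    _write_log(out, cfg, int(cfg.get("seed", 0)), {"command": "budget"})
    return table


def _plot_calibration(out: Path, curve, points) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .calibration import dose_from_pv

    pv = np.array([p.pv_norm for p in points])
    D = np.array([p.dose_gy for p in points])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(pv, D, xerr=[p.sigma_pv_norm for p in points], fmt="o", ms=4, label="measurements")
    xs = np.linspace(pv.min() * 0.9, pv.max() * 1.05, 200)
    ax.plot(xs, dose_from_pv(curve, xs), "-", label=f"fit: b={curve.b:.1f}, n={curve.n:.3f}")
    ax.set_xlabel("PVnorm")
    ax.set_ylabel("dose (Gy)")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "calibration_curve.png", dpi=150)
    plt.close(fig)


def _plot_budget(out: Path, table: pd.DataFrame, threshold: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for col, label in [
        ("sigma_exp_pct", "Exp"),
        ("sigma_fit_pct", "Fit"),
        ("sigma_tot_pct", "Total"),
        ("delta_error_pct", "Error"),
    ]:
        ax.plot(table["D"], table[col].abs(), "o-", ms=3, label=label)
    ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("relative uncertainty / error (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "uncertainty_budget.png", dpi=150)
    plt.close(fig)
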