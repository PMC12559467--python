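"""Synthetic film-scan generator with known ground truth.

Emulates the irradiation/scan protocol: for each exposure time the film
piece is scanned before irradiation (background) and after (irradiated),
in triplicate, as 16-bit RGB TIFFs at 127 dpi. The irradiated footprint is
a 5 mm circle whose green pixel value is the power-law response inverted:

    PV_irr = PV_bg / (1 + (D / b_true)^(1/n_true)),   D = t * dose_rate,

with independent Gaussian pixel noise added to every pixel and channel.
This reproduces the response variable PVnorm = PV_bg/PV_irr - 1 =
(D/b)^(1/n) exactly at zero noise, so every downstream stage (ROI
extraction, calibration fit, uncertainty budget, refinement) can be tested
against known truth.

What is emulated: pixel noise, triplicate exposures, the footprint
geometry, dose-response inversion, timing/rate uncertainties of the
schedule. What is not: scanner lateral-response nonuniformity, PSF blur,
lamp drift, Newton rings, film curl — recovery results on synthetic scans
bound the statistical, not the systematic, behavior on real film.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erfc

from .calibration import FILM_RESPONSE_PRESETS, DosePoint, ExposureRecord
from .film import DEFAULT_DPI, FilmScan, combine_triplicate, measure_pair, write_scan

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "generate_scan_pair",
    "generate_calibration_dataset",
    "synthesize_points",
    "NOMINAL_DOSE_RATES",
]

#: Nominal MC dose rates (Gy/min, relative stat. uncertainty) per film model
#: and medium, used as the synthetic schedule's time->dose conversion.
NOMINAL_DOSE_RATES: dict[tuple[str, str], tuple[float, float]] = {
    ("EBT3", "film"): (3.77, 0.0020),
    ("EBT3", "water"): (4.40, 0.0040),
    ("EBT-XD", "film"): (4.04, 0.0022),
    ("EBT-XD", "water"): (5.00, 0.0040),
    ("HD-V2", "film"): (4.25, 0.0017),
    ("HD-V2", "water"): (5.00, 0.0044),
}

#: Exposure-time windows (min) spanning each film's usable dose range at the
#: nominal water dose rate.
_SCHEDULE_WINDOWS = {
    "EBT3": (5.1, 42.9),
    "EBT-XD": (3.4, 25.7),
    "HD-V2": (72.8, 364.2),
}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a synthetic calibration dataset."""

    film_model: str = "EBT3"
    medium: str = "water"
    b_true: float = 123.5  # Gy
    n_true: float = 1.20
    pv_bg_level: float = 40_000.0  # counts
    noise_sd: float = 150.0  # counts (~0.4% of background)
    schedule_min: tuple[float, ...] = ()
    dose_rate_gy_min: float = 4.40
    sigma_rate_rel: float = 0.004
    sigma_t_min: float = 1.0 / 60.0  # stopwatch-scale timing uncertainty
    footprint_diameter_mm: float = 5.0
    edge_mm: float = 0.0  # erf-smoothed footprint edge width; 0 = sharp
    image_px: int = 64
    dpi: float = DEFAULT_DPI
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b_true <= 0 or self.n_true <= 0:
            raise ValueError("b_true and n_true must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if any(t <= 0 for t in self.schedule_min):
            raise ValueError("schedule times must be strictly positive")

    @property
    def sigma_rate_gy_min(self) -> float:
        return self.sigma_rate_rel * self.dose_rate_gy_min


def default_truth(
    film_model: str = "EBT3",
    medium: str = "water",
    n_times: int = 9,
    seed: int = 0,
    **overrides,
) -> SyntheticTruth:
    """Truth with the film model's nominal response parameters and a
    geometric exposure schedule spanning its usable dose range."""
    b, n = FILM_RESPONSE_PRESETS[(film_model, medium)]
    rate, sigma_rel = NOMINAL_DOSE_RATES[(film_model, medium)]
    t_lo, t_hi = _SCHEDULE_WINDOWS[film_model]
    schedule = tuple(float(t) for t in np.round(np.geomspace(t_lo, t_hi, n_times), 1))
    params = dict(
        film_model=film_model,
        medium=medium,
        b_true=b,
        n_true=n,
        schedule_min=schedule,
        dose_rate_gy_min=rate,
        sigma_rate_rel=sigma_rel,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


def _footprint_weight(truth: SyntheticTruth) -> np.ndarray:
    """Per-pixel weight in [0,1]: 1 inside the darkened footprint."""
    n = truth.image_px
    pitch = 25.4 / truth.dpi
    coords = (np.arange(n) - n / 2 + 0.5) * pitch
    X, Y = np.meshgrid(coords, coords)
    r = np.sqrt(X * X + Y * Y)
    R = truth.footprint_diameter_mm / 2.0
    if truth.edge_mm > 0:
        return 0.5 * erfc((r - R) / (truth.edge_mm / np.sqrt(2.0)))
    return (r <= R).astype(float)


def _make_image(level_map: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    img = np.repeat(np.asarray(level_map, dtype=float)[:, :, None], 3, axis=2)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def generate_scan_pair(
    truth: SyntheticTruth, t_min: float, rng: np.random.Generator
) -> tuple[FilmScan, FilmScan]:
    """One background/irradiated scan pair for an exposure of ``t_min``
    minutes. Warns if the footprint pixel value underflows toward the noise
    floor (dose beyond the film's dynamic range)."""
    D = t_min * truth.dose_rate_gy_min
    pv_in = truth.pv_bg_level / (1.0 + (D / truth.b_true) ** (1.0 / truth.n_true))
    if pv_in < 3.0 * truth.noise_sd:
        warnings.warn(
            f"footprint PV {pv_in:.0f} at {D:.1f} Gy is at the noise floor "
            "(saturated response)",
            stacklevel=2,
        )
    n = truth.image_px
    flat = np.full((n, n), truth.pv_bg_level)
    w = _footprint_weight(truth)
    dark = truth.pv_bg_level - w * (truth.pv_bg_level - pv_in)
    bg = FilmScan(_make_image(flat, truth.noise_sd, rng), dpi=truth.dpi, provenance="background")
    irr = FilmScan(_make_image(dark, truth.noise_sd, rng), dpi=truth.dpi, provenance="irradiated")
    return bg, irr


def generate_calibration_dataset(
    truth: SyntheticTruth,
    out_dir,
    triplicates: int = 3,
) -> pd.DataFrame:
    """Write TIFF scan pairs for the full schedule (each time in
    ``triplicates``) plus a manifest CSV and the truth as JSON.

    Returns the manifest (one row per replicate scan pair). Deterministic
    for a fixed ``truth.seed``.
    """
    if not truth.schedule_min:
        raise ValueError("truth.schedule_min is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    rows = []
    for t in truth.schedule_min:
        for rep in range(1, triplicates + 1):
            film_id = f"{truth.film_model}_t{t:g}_r{rep}"
            bg, irr = generate_scan_pair(truth, t, rng)
            bg_path = out / f"{film_id}_bg.tiff"
            irr_path = out / f"{film_id}_irr.tiff"
            write_scan(bg_path, bg)
            write_scan(irr_path, irr)
            rows.append(
                {
                    "film_id": film_id,
                    "film_model": truth.film_model,
                    "t_min": t,
                    "replicate": rep,
                    "background_path": bg_path.name,
                    "irradiated_path": irr_path.name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    with open(out / "truth.json", "w") as f:
        json.dump(asdict(truth), f, indent=2)
    return manifest


def synthesize_points(
    truth: SyntheticTruth,
    rng: np.random.Generator,
    triplicates: int = 3,
) -> list[DosePoint]:
    """Run the full in-memory pipeline for one synthetic dataset: generate
    scan pairs, locate the footprint, extract 5x5 ROIs, combine triplicates,
    and attach the exposure records. Returns one DosePoint per schedule time."""
    points = []
    for t in truth.schedule_min:
        reps = []
        for _ in range(triplicates):
            bg, irr = generate_scan_pair(truth, t, rng)
            reps.append(measure_pair(bg, irr))
        pv, sigma_pv = combine_triplicate(reps)
        exposure = ExposureRecord(
            t_min=t,
            sigma_t_min=truth.sigma_t_min,
            dose_rate_gy_min=truth.dose_rate_gy_min,
            sigma_rate_gy_min=truth.sigma_rate_gy_min,
        )
        points.append(DosePoint(pv_norm=pv, sigma_pv_norm=sigma_pv, exposure=exposure))
    return points
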