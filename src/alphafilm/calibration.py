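"""Exposure-time doses, power-law calibration fits, and dose-range refinement.

The film dose for an exposure of ``t`` minutes is ``D = t * dose_rate`` with
the dose rate taken from the Monte Carlo (Gy/min). The calibration curve is
the power law

    D = a * PVnorm + b * PVnorm^n,      a fixed at 0,

fitted to (PVnorm, D) pairs by weighted nonlinear least squares. Weights are
1/sigma_D^2 with sigma_D = sqrt(sigma_MC^2 t^2 + sigma_t^2 rate^2) — the
uncertainty of converting exposure time to dose. The goodness of fit is the
reduced chi-squared with N - 2 degrees of freedom (a is not free).

Dose-range refinement removes extreme-dose points, one at a time, until the
fit uncertainty at every retained point is below a threshold (default 5%),
mirroring the manual pruning dosimetrists apply to film calibration sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from . import uncertainty as unc

__all__ = [
    "ExposureRecord",
    "DosePoint",
    "CalibrationCurve",
    "RefinementResult",
    "exposure_to_dose",
    "fit_power",
    "dose_from_pv",
    "refine_dose_range",
    "FILM_RESPONSE_PRESETS",
]

#: Nominal measured-film power-law parameters (b [Gy], n) per film model and
#: dose medium, used as ground truth by the synthetic-scan generator.
FILM_RESPONSE_PRESETS: dict[tuple[str, str], tuple[float, float]] = {
    ("EBT3", "film"): (105.8, 1.20),
    ("EBT3", "water"): (123.5, 1.20),
    ("EBT-XD", "film"): (401.0, 1.04),
    ("EBT-XD", "water"): (496.5, 1.04),
    ("HD-V2", "film"): (9245.6, 1.20),
    ("HD-V2", "water"): (10877.1, 1.20),
}


class FitError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass(frozen=True)
class ExposureRecord:
    """One irradiation: exposure time and the MC dose rate used to convert it."""

    t_min: float
    sigma_t_min: float
    dose_rate_gy_min: float
    sigma_rate_gy_min: float

    @property
    def dose_gy(self) -> float:
        return exposure_to_dose(self.t_min, self.dose_rate_gy_min)

    @property
    def sigma_dose_gy(self) -> float:
        """sigma of the time->dose conversion (timing and MC-rate parts in
        quadrature)."""
        return float(
            np.hypot(
                self.sigma_rate_gy_min * self.t_min,
                self.sigma_t_min * self.dose_rate_gy_min,
            )
        )


@dataclass
class DosePoint:
    """A calibration point: measured PVnorm against the exposure dose."""

    pv_norm: float
    sigma_pv_norm: float
    exposure: ExposureRecord
    d_fit: float = 0.0  # filled by the fit

    @property
    def dose_gy(self) -> float:
        return self.exposure.dose_gy


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted power-law response D = a PV + b PV^n (a locked to 0)."""

    film_model: str
    medium: str
    b: float
    n: float
    sigma_b: float
    sigma_n: float
    chi2_red: float
    dose_range: tuple[float, float]
    a: float = 0.0
    sigma_a: float = 0.0
    cov_bn: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.n <= 0:
            raise ValueError("fit parameters b and n must be positive")

    def to_dict(self) -> dict:
        return {
            "model": self.film_model,
            "medium": self.medium,
            "a": self.a,
            "b": self.b,
            "n": self.n,
            "sigma_b": self.sigma_b,
            "sigma_n": self.sigma_n,
            "chi2_red": self.chi2_red,
            "dose_range": list(self.dose_range),
        }


@dataclass(frozen=True)
class RefinementResult:
    points: list[DosePoint]
    curve: CalibrationCurve
    dose_range: tuple[float, float]
    converged: bool


def exposure_to_dose(t_min: float, dose_rate_gy_min: float) -> float:
    """Dose in Gy for an exposure of ``t_min`` minutes at the given rate."""
    if t_min < 0:
        raise ValueError("exposure time must be >= 0")
    if dose_rate_gy_min <= 0:
        raise ValueError("dose rate must be > 0")
    return t_min * dose_rate_gy_min


def dose_from_pv(curve: CalibrationCurve, pv_norm: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the calibration curve at PVnorm (>= 0)."""
    pv = np.asarray(pv_norm, dtype=float)
    if np.any(pv < 0):
        raise ValueError("PVnorm must be >= 0")
    out = curve.a * pv + curve.b * np.power(pv, curve.n)
    return float(out) if pv.ndim == 0 else out


def fit_power(
    points: list[DosePoint],
    film_model: str = "",
    medium: str = "film",
    *,
    weighted: bool = True,
) -> tuple[CalibrationCurve, list[DosePoint]]:
    """Weighted least-squares fit of D = b PV^n (a locked at 0).

    Returns the fitted curve and the points with ``d_fit`` filled in.
    Weights are 1/sigma_D^2 from the time->dose conversion uncertainty;
    ``weighted=False`` fits unweighted (unit sigmas).
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    pv = np.array([p.pv_norm for p in points])
    if np.any(pv <= 0):
        raise ValueError("all PVnorm values must be > 0 for the power fit")
    D = np.array([p.dose_gy for p in points])
    sigma_D = np.array([p.exposure.sigma_dose_gy for p in points])
    use_sigma = weighted and np.all(sigma_D > 0)

    def f(x, b, n):
        return b * np.power(x, n)

    b0 = float(np.median(D / pv))
    p0 = (b0, 1.0)
    try:
        # scaled covariance (scipy default): parameter errors reflect the
        # actual residual scatter, so a misfitting point inflates sigma_b and
        # the refinement loop can respond to it
        popt, pcov = curve_fit(
            f,
            pv,
            D,
            p0=p0,
            sigma=sigma_D if use_sigma else None,
            absolute_sigma=False,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"power-law fit did not converge: {exc}") from exc
    b, n = popt
    resid = D - f(pv, b, n)
    dof = len(points) - 2
    if use_sigma:
        chi2 = float(np.sum((resid / sigma_D) ** 2))
    else:
        chi2 = float(np.sum(resid**2))
    chi2_red = chi2 / dof if dof > 0 else 0.0
    curve = CalibrationCurve(
        film_model=film_model,
        medium=medium,
        b=float(b),
        n=float(n),
        sigma_b=float(np.sqrt(pcov[0, 0])),
        sigma_n=float(np.sqrt(pcov[1, 1])),
        cov_bn=float(pcov[0, 1]),
        chi2_red=chi2_red,
        dose_range=(float(D.min()), float(D.max())),
    )
    fitted = [replace_dfit(p, dose_from_pv(curve, p.pv_norm)) for p in points]
    return curve, fitted


def replace_dfit(point: DosePoint, d_fit: float) -> DosePoint:
    return DosePoint(
        pv_norm=point.pv_norm,
        sigma_pv_norm=point.sigma_pv_norm,
        exposure=point.exposure,
        d_fit=float(d_fit),
    )


def refine_dose_range(
    points: list[DosePoint],
    curve: CalibrationCurve,
    threshold_pct: float = 5.0,
    min_points: int = 5,
    *,
    weighted: bool = True,
) -> RefinementResult:
    """Iteratively prune extreme-dose points until the fit uncertainty at
    every retained point is below ``threshold_pct``.

    At each step the candidate removals are the lowest- and highest-dose
    retained points; the one with the larger absolute relative dose error is
    dropped (ties drop the high-dose end) and the curve refitted. Stops when
    the threshold is met or ``min_points`` would be violated; in the latter
    case a warning is issued and ``converged`` is False.
    """
    pts = sorted(points, key=lambda p: p.dose_gy)
    cur_curve, pts = fit_power(pts, curve.film_model, curve.medium, weighted=weighted)
    while True:
        fit_unc = [
            unc.sigma_fit_pct(cur_curve, p.pv_norm, p.d_fit) for p in pts
        ]
        if max(fit_unc) <= threshold_pct:
            return RefinementResult(
                pts, cur_curve, (pts[0].dose_gy, pts[-1].dose_gy), True
            )
        if len(pts) <= min_points:
            warnings.warn(
                f"dose-range refinement stopped at {len(pts)} points with max fit "
                f"uncertainty {max(fit_unc):.2f}% > {threshold_pct}%",
                stacklevel=2,
            )
            return RefinementResult(
                pts, cur_curve, (pts[0].dose_gy, pts[-1].dose_gy), False
            )
        lo, hi = pts[0], pts[-1]
        err_lo = abs(unc.rel_dose_error_pct(lo.d_fit, lo.dose_gy))
        err_hi = abs(unc.rel_dose_error_pct(hi.d_fit, hi.dose_gy))
        pts = pts[1:] if err_lo > err_hi else pts[:-1]
        cur_curve, pts = fit_power(pts, curve.film_model, curve.medium, weighted=weighted)
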