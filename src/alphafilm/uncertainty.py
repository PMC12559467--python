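"""Relative uncertainty budget for film-measured doses.

All components are percentages of the fitted dose D_fit at a calibration
point, combined in quadrature into the total:

* experimental: the measured-PVnorm uncertainty propagated through the
  calibration curve, 100 * |a + n b PV^(n-1)| * sigma_PV / D_fit;
* fit: the fit-parameter uncertainties,
  100 * sqrt(PV^2 sigma_a^2 + PV^(2n) sigma_b^2) / D_fit (the sigma_n term
  and the full b-n covariance are available behind flags; the default keeps
  the Devic-style two-term form);
* MC/time: the exposure-to-dose conversion,
  100 * sqrt(sigma_MC^2 t^2 + sigma_t^2 rate^2) / D_fit.

The relative dose error is the signed discrepancy between the curve and the
delivered dose, 100 * (D_fit - D) / D_fit. Points whose total uncertainty
exceeds a threshold (default 5%) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import CalibrationCurve, DosePoint

__all__ = [
    "UncertaintyBudget",
    "sigma_exp_pct",
    "sigma_fit_pct",
    "sigma_mc_pct",
    "sigma_total_pct",
    "rel_dose_error_pct",
    "budget_point",
    "budget_table",
    "DEFAULT_THRESHOLD_PCT",
]

DEFAULT_THRESHOLD_PCT = 5.0


def _check_dfit(d_fit: float) -> None:
    if d_fit <= 0:
        raise ValueError("D_fit must be > 0")


def sigma_exp_pct(
    curve: "CalibrationCurve", pv_norm: float, sigma_pv_norm: float, d_fit: float
) -> float:
    """Experimental component: sigma_PVnorm propagated through the curve."""
    _check_dfit(d_fit)
    slope = curve.a + curve.n * curve.b * pv_norm ** (curve.n - 1.0)
    return 100.0 * abs(slope) * sigma_pv_norm / d_fit


def sigma_fit_pct(
    curve: "CalibrationCurve",
    pv_norm: float,
    d_fit: float,
    *,
    include_sigma_n: bool = False,
    full_covariance: bool = False,
) -> float:
    """Fit component from the parameter uncertainties.

    Default: sqrt(PV^2 sigma_a^2 + PV^(2n) sigma_b^2)/D_fit * 100.
    ``include_sigma_n`` adds the (b PV^n ln PV sigma_n)^2 term;
    ``full_covariance`` additionally uses the fitted b-n covariance.
    """
    _check_dfit(d_fit)
    var = (pv_norm * curve.sigma_a) ** 2 + pv_norm ** (2.0 * curve.n) * curve.sigma_b**2
    if include_sigma_n or full_covariance:
        dn = curve.b * pv_norm**curve.n * np.log(pv_norm)
        var += (dn * curve.sigma_n) ** 2
        if full_covariance:
            db = pv_norm**curve.n
            var += 2.0 * db * dn * curve.cov_bn
            var = max(var, 0.0)
    return 100.0 * float(np.sqrt(var)) / d_fit


def sigma_mc_pct(
    t_min: float,
    sigma_t_min: float,
    dose_rate_gy_min: float,
    sigma_rate_gy_min: float,
    d_fit: float,
) -> float:
    """MC/time component of the exposure-to-dose conversion."""
    _check_dfit(d_fit)
    num = np.hypot(sigma_rate_gy_min * t_min, sigma_t_min * dose_rate_gy_min)
    return 100.0 * float(num) / d_fit


def sigma_total_pct(exp_pct: float, fit_pct: float, mc_pct: float) -> float:
    """Quadrature sum of the three components."""
    return float(np.sqrt(exp_pct**2 + fit_pct**2 + mc_pct**2))


def rel_dose_error_pct(d_fit: float, d: float) -> float:
    """Signed relative dose error 100 * (D_fit - D) / D_fit."""
    _check_dfit(d_fit)
    return 100.0 * (d_fit - d) / d_fit


@dataclass(frozen=True)
class UncertaintyBudget:
    """The four relative components and the relative dose error at one point."""

    pv_norm: float
    dose_gy: float
    d_fit_gy: float
    sigma_exp_pct: float
    sigma_fit_pct: float
    sigma_mc_pct: float
    sigma_total_pct: float
    rel_dose_error_pct: float
    above_threshold: bool


def budget_point(
    point: "DosePoint",
    curve: "CalibrationCurve",
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    **fit_flags,
) -> UncertaintyBudget:
    """Evaluate the full budget at one calibration point."""
    d_fit = point.d_fit if point.d_fit > 0 else None
    if d_fit is None:
        from .calibration import dose_from_pv

        d_fit = float(dose_from_pv(curve, point.pv_norm))
    e = sigma_exp_pct(curve, point.pv_norm, point.sigma_pv_norm, d_fit)
    f = sigma_fit_pct(curve, point.pv_norm, d_fit, **fit_flags)
    m = sigma_mc_pct(
        point.exposure.t_min,
        point.exposure.sigma_t_min,
        point.exposure.dose_rate_gy_min,
        point.exposure.sigma_rate_gy_min,
        d_fit,
    )
    tot = sigma_total_pct(e, f, m)
    return UncertaintyBudget(
        pv_norm=point.pv_norm,
        dose_gy=point.dose_gy,
        d_fit_gy=d_fit,
        sigma_exp_pct=e,
        sigma_fit_pct=f,
        sigma_mc_pct=m,
        sigma_total_pct=tot,
        rel_dose_error_pct=rel_dose_error_pct(d_fit, point.dose_gy),
        above_threshold=tot > threshold_pct,
    )


def budget_table(
    points: list["DosePoint"],
    curve: "CalibrationCurve",
    threshold_pct: float = DEFAULT_THRESHOLD_PCT,
    **fit_flags,
) -> pd.DataFrame:
    """Budget for every point as a table (one row per calibration point)."""
    rows = [budget_point(p, curve, threshold_pct, **fit_flags) for p in points]
    return pd.DataFrame(
        {
            "PVnorm": [r.pv_norm for r in rows],
            "D": [r.dose_gy for r in rows],
            "D_fit": [r.d_fit_gy for r in rows],
            "sigma_exp_pct": [r.sigma_exp_pct for r in rows],
            "sigma_fit_pct": [r.sigma_fit_pct for r in rows],
            "sigma_mc_pct": [r.sigma_mc_pct for r in rows],
            "sigma_tot_pct": [r.sigma_total_pct for r in rows],
            "delta_error_pct": [r.rel_dose_error_pct for r in rows],
            "above_threshold": [r.above_threshold for r in rows],
        }
    )
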