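"""Uncertainty budget: component formulas, identities, coverage."""

import math

import numpy as np
import pytest

from alphafilm import uncertainty as unc
from alphafilm.calibration import (
    CalibrationCurve,
    DosePoint,
    ExposureRecord,
    dose_from_pv,
    fit_power,
)

CURVE = CalibrationCurve(
    "EBT3",
    "water",
    b=123.5,
    n=1.20,
    sigma_b=1.19,
    sigma_n=0.02,
    chi2_red=1.0,
    dose_range=(20.0, 190.0),
)


class TestExperimentalComponent:
    def test_zero_noise_gives_zero(self):
        d = dose_from_pv(CURVE, 0.5)
        assert unc.sigma_exp_pct(CURVE, 0.5, 0.0, d) == 0.0

    def test_matches_finite_difference_propagation(self):
        """Component equals |dD/dPV| * sigma_PV / D_fit from a central finite
        difference of the calibration curve."""
        for pv in (0.1, 0.5, 1.3):
            d = dose_from_pv(CURVE, pv)
            sigma_pv = 0.01 * pv
            h = 1e-7 * pv
            deriv = (dose_from_pv(CURVE, pv + h) - dose_from_pv(CURVE, pv - h)) / (2 * h)
            expected = 100.0 * abs(deriv) * sigma_pv / d
            ours = unc.sigma_exp_pct(CURVE, pv, sigma_pv, d)
            assert ours == pytest.approx(expected, rel=1e-6)

    def test_simplifies_to_n_relative_pv_noise(self, rng):
        # with a = 0 and D_fit on the curve: 100 n sigma_PV / PV
        for _ in range(20):
            pv = rng.uniform(0.05, 2.0)
            sigma_pv = rng.uniform(0.0, 0.05) * pv
            d = dose_from_pv(CURVE, pv)
            assert unc.sigma_exp_pct(CURVE, pv, sigma_pv, d) == pytest.approx(
                100.0 * CURVE.n * sigma_pv / pv, rel=1e-12
            )

    def test_requires_positive_dfit(self):
        with pytest.raises(ValueError):
            unc.sigma_exp_pct(CURVE, 0.5, 0.01, 0.0)


class TestFitComponent:
    def test_zero_parameter_errors_give_zero(self):
        c = CalibrationCurve("x", "water", b=100.0, n=1.2, sigma_b=0.0, sigma_n=0.0, chi2_red=1.0, dose_range=(0, 1))
        assert unc.sigma_fit_pct(c, 0.7, dose_from_pv(c, 0.7)) == 0.0

    def test_linear_in_sigma_b(self):
        def at(sb):
            c = CalibrationCurve("x", "water", b=100.0, n=1.2, sigma_b=sb, sigma_n=0.0, chi2_red=1.0, dose_range=(0, 1))
            return unc.sigma_fit_pct(c, 0.7, dose_from_pv(c, 0.7))

        assert at(2.0) == pytest.approx(2 * at(1.0), rel=1e-12)

    def test_matches_parametric_bootstrap(self, rng):
        """sigma_fit equals the sd of b' PV^n over draws b' ~ N(b, sigma_b)."""
        pv = 0.8
        d = dose_from_pv(CURVE, pv)
        draws = rng.normal(CURVE.b, CURVE.sigma_b, 100_000)
        boot = 100.0 * np.std(draws * pv**CURVE.n) / d
        assert unc.sigma_fit_pct(CURVE, pv, d) == pytest.approx(boot, rel=0.03)

    def test_sigma_n_term_increases_uncertainty_away_from_pv_one(self):
        base = unc.sigma_fit_pct(CURVE, 0.3, dose_from_pv(CURVE, 0.3))
        with_n = unc.sigma_fit_pct(
            CURVE, 0.3, dose_from_pv(CURVE, 0.3), include_sigma_n=True
        )
        assert with_n > base
        # at PV = 1 the sigma_n sensitivity (b PV^n ln PV) vanishes
        assert unc.sigma_fit_pct(
            CURVE, 1.0, dose_from_pv(CURVE, 1.0), include_sigma_n=True
        ) == pytest.approx(unc.sigma_fit_pct(CURVE, 1.0, dose_from_pv(CURVE, 1.0)))


class TestMcComponent:
    def test_zero_sigmas_give_zero(self):
        assert unc.sigma_mc_pct(10.0, 0.0, 4.40, 0.0, 44.0) == 0.0

    def test_reduces_to_relative_rate_uncertainty(self):
        # sigma_t = 0 and D_fit = t * rate: component is 100 sigma_MC / rate
        assert unc.sigma_mc_pct(10.0, 0.0, 4.40, 0.05, 44.0) == pytest.approx(
            100.0 * 0.05 / 4.40
        )

    def test_water_rate_example(self):
        # 10 min at 4.40 Gy/min with a 0.4% rate uncertainty -> 0.4% of 44 Gy
        assert unc.sigma_mc_pct(10.0, 0.0, 4.40, 0.0176, 44.0) == pytest.approx(0.4)


class TestTotalAndError:
    def test_three_four_five(self):
        assert unc.sigma_total_pct(3.0, 4.0, 0.0) == pytest.approx(5.0)

    def test_single_component_passthrough(self):
        assert unc.sigma_total_pct(0.0, 2.7, 0.0) == pytest.approx(2.7)

    def test_total_dominates_components(self, rng):
        for _ in range(50):
            e, f, m = rng.uniform(0, 10, 3)
            tot = unc.sigma_total_pct(e, f, m)
            assert tot >= max(e, f, m) - 1e-12

    def test_rel_dose_error_values(self):
        assert unc.rel_dose_error_pct(100.0, 100.0) == 0.0
        assert unc.rel_dose_error_pct(100.0, 92.0) == pytest.approx(8.0)

    def test_rel_dose_error_numerator_antisymmetry(self):
        a = unc.rel_dose_error_pct(100.0, 80.0)
        b = 100.0 * (80.0 - 100.0) / 100.0
        assert a == pytest.approx(-b)


class TestBudgetTable:
    def test_quadrature_identity_rowwise(self, rng):
        pts = []
        for t in np.geomspace(5.1, 42.9, 9):
            D = t * 4.40
            pv = (D / CURVE.b) ** (1 / CURVE.n) * (1 + rng.normal(0, 0.01))
            pts.append(
                DosePoint(
                    pv_norm=pv,
                    sigma_pv_norm=0.01 * pv,
                    exposure=ExposureRecord(t, 1 / 60, 4.40, 0.0176),
                )
            )
        curve, pts = fit_power(pts, "EBT3", "water")
        table = unc.budget_table(pts, curve)
        lhs = table["sigma_tot_pct"] ** 2
        rhs = (
            table["sigma_exp_pct"] ** 2
            + table["sigma_fit_pct"] ** 2
            + table["sigma_mc_pct"] ** 2
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)
        assert set(table.columns) >= {
            "PVnorm",
            "D",
            "D_fit",
            "sigma_exp_pct",
            "sigma_fit_pct",
            "sigma_mc_pct",
            "sigma_tot_pct",
            "delta_error_pct",
            "above_threshold",
        }

    def test_threshold_flag(self):
        pt = DosePoint(
            pv_norm=0.5,
            sigma_pv_norm=0.1,  # 20% PV noise -> sigma_exp ~ 24%
            exposure=ExposureRecord(10.0, 0.0, 4.40, 0.0),
        )
        row = unc.budget_point(pt, CURVE)
        assert row.above_threshold
        quiet = DosePoint(
            pv_norm=0.5, sigma_pv_norm=0.0, exposure=ExposureRecord(10.0, 0.0, 4.40, 0.0)
        )
        assert not unc.budget_point(quiet, CURVE).above_threshold

    def test_scale_invariance_of_components(self):
        """Rescaling all doses by k leaves every percentage unchanged."""
        pt = DosePoint(
            pv_norm=0.5, sigma_pv_norm=0.005, exposure=ExposureRecord(10.0, 1 / 60, 4.40, 0.0176)
        )
        k = 5.0
        curve_k = CalibrationCurve(
            "EBT3",
            "water",
            b=CURVE.b * k,
            n=CURVE.n,
            sigma_b=CURVE.sigma_b * k,
            sigma_n=CURVE.sigma_n,
            chi2_red=1.0,
            dose_range=(0, 1000),
        )
        pt_k = DosePoint(
            pv_norm=0.5,
            sigma_pv_norm=0.005,
            exposure=ExposureRecord(10.0, 1 / 60, 4.40 * k, 0.0176 * k),
        )
        a = unc.budget_point(pt, CURVE)
        b = unc.budget_point(pt_k, curve_k)
        assert b.sigma_exp_pct == pytest.approx(a.sigma_exp_pct, rel=1e-12)
        assert b.sigma_fit_pct == pytest.approx(a.sigma_fit_pct, rel=1e-12)
        assert b.sigma_mc_pct == pytest.approx(a.sigma_mc_pct, rel=1e-12)


class TestCoverage:
    def test_nominal_coverage_on_simulated_truth(self):
        """Over ~500 simulated points with correctly specified noise, the
        delivered dose lies within D_fit +- 1.96 sigma_tot in roughly 95% of
        cases (90-99% allowing for the neglected parameter correlations).

        Coverage is evaluated on held-out points: the curve is fitted to one
        realization and the budget checked on fresh exposures, so the fit
        does not follow the noise of the points it is judged on.
        """
        rng = np.random.default_rng(303)
        b, n, rate = 123.5, 1.20, 4.40
        times = np.geomspace(5.1, 42.9, 9)

        def draw_point(t):
            t_actual = t + rng.normal(0.0, 1 / 60)
            rate_actual = rate + rng.normal(0.0, 0.004 * rate)
            D_actual = t_actual * rate_actual
            pv_clean = (D_actual / b) ** (1.0 / n)
            sigma_pv = 0.01 * pv_clean
            pv = pv_clean + rng.normal(0.0, sigma_pv)
            point = DosePoint(
                pv_norm=pv,
                sigma_pv_norm=sigma_pv,
                exposure=ExposureRecord(t, 1 / 60, rate, 0.004 * rate),
            )
            return point, D_actual

        covered = 0
        total = 0
        for _ in range(56):
            fit_pts = [draw_point(t)[0] for t in times]
            curve, _ = fit_power(fit_pts, "EBT3", "water")
            for t in times:
                p, d_true = draw_point(t)
                row = unc.budget_point(p, curve)
                half = 1.96 * row.sigma_total_pct * row.d_fit_gy / 100.0
                covered += abs(d_true - row.d_fit_gy) <= half
                total += 1
        assert total == 504
        assert 0.90 <= covered / total <= 0.99
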