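"""Hertz fitting, deflection calibration, G*(f) estimation and the two
power-law fit, each checked against generate-and-analyze roundtrips and
closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from pulmomech.afmmech import (ComplexModulus, PowerLawFit, aggregate_E,
                               calibrate_deflection, compute_gstar,
                               fit_hertz, fit_two_powerlaw, gstar_model,
                               simulate_gstar)
from pulmomech.errors import (AnalysisError, CalibrationError,
                              DegenerateExcitationError, InvalidSpecError)
from pulmomech.synthgen import (simulate_calibration_curve,
                                simulate_force_curve, simulate_multifreq)

WT9M = PowerLawFit(A=9.40, B=0.016, alpha=0.084)  # adult wild-type septum


class TestCalibration:
    def test_unit_slope_clean(self):
        z, d = simulate_calibration_curve(slope=1.0)
        cal = calibrate_deflection(z, d)
        assert cal.sensitivity == pytest.approx(1.0, rel=1e-9)
        assert cal.clean

    def test_noisy_slope_recovered(self):
        z, d = simulate_calibration_curve(slope=0.85, noise_sd=0.5, seed=1)
        cal = calibrate_deflection(z, d)
        # linear-regression sampling error on 100 contact points
        assert cal.sensitivity == pytest.approx(0.85, abs=0.01)

    def test_soft_contact_flagged_dirty(self):
        z, d = simulate_calibration_curve(slope=0.3, curvature=1.5e-3)
        cal = calibrate_deflection(z, d)
        assert not cal.clean

    def test_no_contact_raises(self):
        z = np.linspace(0, 1000, 200)
        d = np.full(200, 2.0)
        with pytest.raises(CalibrationError):
            calibrate_deflection(z, d)


class TestFitHertz:
    @pytest.mark.parametrize("e_true", [100.0, 1e3, 1e4, 1e5])
    def test_roundtrip_recovery(self, e_true):
        """Noiseless roundtrip recovers E to better than 0.1% across
        0.1-100 kPa."""
        fit = fit_hertz(simulate_force_curve(E_true=e_true))
        assert fit.converged
        assert fit.E == pytest.approx(e_true, rel=1e-3)
        assert fit.max_indentation_used <= 500.0 + 1.0

    def test_contact_point_recovery(self):
        fit = fit_hertz(simulate_force_curve(E_true=1e4, z0=1234.5, d0=7.5))
        assert fit.z0 == pytest.approx(1234.5, abs=0.5)
        assert fit.d0 == pytest.approx(7.5, abs=0.05)

    def test_force_invariance(self):
        """Scaling d by 2 and halving k leaves the force, hence E, unchanged."""
        fc = simulate_force_curve(E_true=1e4, d0=0.0, k=0.03)
        from pulmomech.afmmech import ForceCurve
        scaled = ForceCurve(z=fc.z, d=2.0 * fc.d, k=0.015,
                            theta=fc.theta, nu=fc.nu)
        # note: doubling d also doubles the deflection-vs-z geometry, so the
        # curve must be regenerated at the halved spring constant instead
        regen = simulate_force_curve(E_true=1e4, d0=0.0, k=0.015)
        assert fit_hertz(regen).E == pytest.approx(fit_hertz(fc).E, rel=1e-6)

    def test_shift_invariance(self):
        """Adding a constant to z and d together only moves the contact point."""
        fc = simulate_force_curve(E_true=5e3)
        from pulmomech.afmmech import ForceCurve
        shifted = ForceCurve(z=fc.z + 250.0, d=fc.d + 40.0, k=fc.k,
                             theta=fc.theta, nu=fc.nu)
        a, b = fit_hertz(fc), fit_hertz(shifted)
        assert b.E == pytest.approx(a.E, rel=1e-6)
        assert b.z0 - a.z0 == pytest.approx(250.0, abs=1.0)

    def test_precontact_only_not_converged(self):
        from pulmomech.afmmech import ForceCurve
        z = np.linspace(0, 1000, 200)
        curve = ForceCurve(z=z, d=np.full(200, 3.0))
        fit = fit_hertz(curve)
        assert not fit.converged

    def test_noisy_curve_still_close(self):
        fit = fit_hertz(simulate_force_curve(E_true=1e4, noise_sd=0.5, seed=3))
        assert fit.converged
        assert fit.E == pytest.approx(1e4, rel=0.05)


class TestAggregateE:
    def test_constant_curves(self):
        rows = [{"region": "pleura", "site": s, "point": p, "curve": c,
                 "E": 5000.0}
                for s in range(3) for p in range(5) for c in range(5)]
        hier = aggregate_E(pd.DataFrame(rows))
        assert float(hier.region_means["E"].iloc[0]) == 5000.0

    def test_point_mean_arithmetic(self):
        rows = [{"region": "septum", "site": 0, "point": 0, "curve": c, "E": e}
                for c, e in enumerate([4000, 5000, 6000, 5000, 5000])]
        hier = aggregate_E(pd.DataFrame(rows))
        assert float(hier.point_means["E"].iloc[0]) == 5000.0

    def test_failed_fits_excluded_and_missing_points_reported(self):
        rows = [{"region": "septum", "site": 0, "point": 0, "curve": 0,
                 "E": 5000.0, "converged": True},
                {"region": "septum", "site": 0, "point": 1, "curve": 0,
                 "E": 9e9, "converged": False}]
        hier = aggregate_E(pd.DataFrame(rows))
        assert hier.n_failed == 1
        assert hier.missing_points == [("septum", 0, 1)]
        assert float(hier.region_means["E"].iloc[0]) == 5000.0

    def test_full_design_sampling_bound(self, rng):
        """3 sites x 5 points x 5 curves with lognormal truth (CV 20%):
        region mean within 2 SE of 10 kPa."""
        sigma = np.sqrt(np.log1p(0.2**2))
        rows = []
        for s in range(3):
            for p in range(5):
                e_true = 1e4 * rng.lognormal(-0.5 * sigma**2, sigma)
                for c in range(5):
                    rows.append({"region": "septum", "site": s, "point": p,
                                 "curve": c, "E": e_true})
        hier = aggregate_E(pd.DataFrame(rows))
        se = 1e4 * 0.2 / np.sqrt(15)
        assert abs(float(hier.region_means["E"].iloc[0]) - 1e4) < 2 * se


class TestComputeGstar:
    def test_elastic_gain_closed_form(self):
        """Pure elastic force/indentation gain g maps to
        G' = (1-nu)*g/(3*delta0*tan(theta)), G'' = 0."""
        rec = simulate_multifreq(PowerLawFit(A=5.0, B=0.0, alpha=0.0),
                                 duration=20.0, fs=50.0, b_h=0.0)
        gs = compute_gstar(rec)
        g = 3.0 * 500e-9 * np.tan(np.radians(20.0)) / 0.5 * 5000.0  # N/m
        expected = 0.5 * g / (3.0 * 500e-9 * np.tan(np.radians(20.0)))
        assert np.allclose(gs.g_storage, expected, rtol=1e-9)
        assert np.allclose(gs.g_loss, 0.0, atol=1e-6 * expected)

    def test_roundtrip_table_parameters(self):
        """Noiseless record from the adult wild-type parameter set returns
        G', G'' equal to the model at the four stimulus frequencies."""
        rec = simulate_multifreq(WT9M, duration=140.0, fs=100.0)
        gs = compute_gstar(rec)
        model = gstar_model(gs.freqs, 9.40, 0.016, 0.084)
        assert np.allclose(gs.g_storage, model.real, rtol=1e-3)
        assert np.allclose(gs.g_loss, model.imag, rtol=1e-3)

    def test_drag_correction_cancels_exactly(self):
        with_drag = compute_gstar(simulate_multifreq(WT9M, b_h=5e-6,
                                                     duration=140.0, fs=100.0))
        without = compute_gstar(simulate_multifreq(WT9M, b_h=0.0,
                                                   duration=140.0, fs=100.0))
        assert np.allclose(with_drag.gstar, without.gstar, rtol=1e-10)

    def test_record_length_invariance(self):
        """Steady-state single-frequency data: G* identical for 3 vs 10
        periods (leakage-free regression)."""
        fit = PowerLawFit(A=5.0, B=0.05, alpha=0.1)
        a = compute_gstar(simulate_multifreq(fit, freqs=(1.15,), duration=3 / 1.15,
                                             fs=200.0))
        b = compute_gstar(simulate_multifreq(fit, freqs=(1.15,), duration=10 / 1.15,
                                             fs=200.0))
        assert np.allclose(a.gstar, b.gstar, rtol=1e-8)

    def test_zero_amplitude_degenerate(self):
        rec = simulate_multifreq(WT9M, amplitude=0.0, duration=20.0, fs=50.0,
                                 noise_sd=0.01)
        with pytest.raises(DegenerateExcitationError):
            compute_gstar(rec)


class TestFitTwoPowerlaw:
    def test_roundtrip_table_parameters(self):
        """Noiseless model data at the four stimulus frequencies recovers
        (A, B, alpha) to better than 1%."""
        fit = fit_two_powerlaw(simulate_gstar(WT9M))
        assert fit.A == pytest.approx(9.40, rel=0.01)
        assert fit.alpha == pytest.approx(0.084, rel=0.01)
        assert fit.B == pytest.approx(0.016, rel=0.01)

    @pytest.mark.parametrize("truth", [
        PowerLawFit(A=1.0, B=0.0, alpha=0.02),
        PowerLawFit(A=5.0, B=0.1, alpha=0.15),
        PowerLawFit(A=20.0, B=0.2, alpha=0.30),
    ])
    def test_roundtrip_range(self, truth):
        fit = fit_two_powerlaw(simulate_gstar(truth))
        assert fit.A == pytest.approx(truth.A, rel=0.01)
        assert fit.alpha == pytest.approx(truth.alpha, abs=0.003)
        assert fit.B == pytest.approx(truth.B, abs=0.01 * truth.A)

    def test_zero_b_boundary(self):
        fit = fit_two_powerlaw(simulate_gstar(PowerLawFit(A=8.0, B=0.0,
                                                          alpha=0.1)))
        assert fit.B <= 1e-3 * fit.A

    def test_elastic_solid_limit(self):
        """alpha = 0, B = 0: constant G' and zero G''; fit returns alpha ~ 0."""
        fit = fit_two_powerlaw(simulate_gstar(PowerLawFit(A=8.0, B=0.0,
                                                          alpha=0.0)))
        assert fit.alpha == pytest.approx(0.0, abs=1e-4)
        assert fit.A == pytest.approx(8.0, rel=1e-3)

    def test_alpha_three_quarters_degeneracy(self):
        """At alpha = 3/4 the two terms coincide: only A + B is identified."""
        fit = fit_two_powerlaw(simulate_gstar(PowerLawFit(A=4.0, B=2.0,
                                                          alpha=0.75)))
        assert fit.A + fit.B == pytest.approx(6.0, rel=1e-3)
        assert fit.rss < 1e-12  # a perfect fit despite the unidentifiable split

    def test_too_few_frequencies(self):
        gs = ComplexModulus(freqs=[0.35, 1.15], g_storage=[9e3, 9.5e3],
                            g_loss=[1e3, 1.2e3])
        with pytest.raises(AnalysisError):
            fit_two_powerlaw(gs)


def test_full_multifreq_chain_noiseless():
    """simulate -> compute_gstar -> fit_two_powerlaw recovers (A, B, alpha)
    to <= 1% over the documented parameter range."""
    for truth in (PowerLawFit(A=1.0, B=0.05, alpha=0.05),
                  WT9M,
                  PowerLawFit(A=20.0, B=0.2, alpha=0.3)):
        rec = simulate_multifreq(truth, duration=140.0, fs=50.0, b_h=2e-6)
        fit = fit_two_powerlaw(compute_gstar(rec))
        assert fit.A == pytest.approx(truth.A, rel=0.01)
        assert fit.alpha == pytest.approx(truth.alpha, abs=0.01 * max(truth.alpha, 0.1))
        assert fit.B == pytest.approx(truth.B, abs=0.01 * truth.A)
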