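"""Standards calibration, inversion, and the hydrogenation correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpiso import (
    IsotopeValue,
    PeakMeasurement,
    apply_calibration,
    calibration_diagnostics,
    fit_calibration,
    hydrogenation_correct,
    standard_ladder,
)
from bpiso.calibration import HYDROGENATION_N_ADDED, HYDROGENATION_N_TOTAL
from bpiso.exceptions import CalibrationError
from bpiso.synthetic import SyntheticConfig, dilute_with_added_h, generate_standards_run


def make_standards(offset=0.0, scale=1.0, size_coeff=0.0, seed=0, n_runs=2):
    """Noise-free standards with a planted instrument response."""
    rng = np.random.default_rng(seed)
    peaks = []
    for run in range(n_runs):
        for std in standard_ladder():
            amp = float(rng.uniform(800, 8000))
            raw = offset + scale * std.accepted_d2H + size_coeff * amp
            peaks.append(
                PeakMeasurement(
                    run_id=f"r{run}",
                    injection=1,
                    compound=std.compound,
                    amplitude=amp,
                    d2H_raw=raw,
                    is_standard=True,
                )
            )
    return peaks


class TestFitCalibration:
    def test_exact_offset_and_scale_recovery(self):
        peaks = make_standards(offset=-10.0, scale=0.98)
        fit = fit_calibration(peaks, standard_ladder())
        assert fit.offset == pytest.approx(-10.0, abs=1e-9)
        assert fit.scale == pytest.approx(0.98, abs=1e-9)

    def test_identity_instrument(self):
        peaks = make_standards()
        fit = fit_calibration(peaks, standard_ladder(), size_term=False)
        assert fit.offset == pytest.approx(0.0, abs=1e-9)
        assert fit.scale == pytest.approx(1.0, abs=1e-9)
        assert fit.residual_rmse == pytest.approx(0.0, abs=1e-9)

    def test_planted_size_coefficient_recovered(self):
        peaks = make_standards(offset=5.0, scale=0.97, size_coeff=0.002)
        fit = fit_calibration(peaks, standard_ladder(), size_term=True)
        size_idx = fit.terms.index("size")
        assert fit.coefficients[size_idx] == pytest.approx(0.002, abs=1e-9)

    def test_unmapped_compound_named_in_error(self):
        peaks = make_standards()
        peaks[0].compound = "mystery"
        with pytest.raises(CalibrationError, match="mystery"):
            fit_calibration(peaks, standard_ladder())

    def test_rank_deficient_design_rejected(self):
        # all standards share one accepted value
        defs = [d for d in standard_ladder() if d.compound == "nC15"]
        peaks = [p for p in make_standards() if p.compound == "nC15"]
        with pytest.raises(CalibrationError):
            fit_calibration(peaks, defs)

    def test_covariance_psd_and_count_invariant(self):
        cfg = SyntheticConfig()
        peaks = []
        for s in range(4):
            peaks += generate_standards_run(cfg, seed=s, run_id=f"r{s}")
        fit = fit_calibration(peaks, standard_ladder())
        eigs = np.linalg.eigvalsh(fit.covariance)
        assert np.all(eigs > -1e-12)
        assert fit.n_standards == len(peaks)


class TestApplyCalibration:
    def test_identity_fit_returns_raw_values(self):
        peaks = make_standards()
        fit = fit_calibration(peaks, standard_ladder(), size_term=False)
        sample = PeakMeasurement("s", 1, "BP-0", amplitude=3000.0, d2H_raw=-250.0)
        (out,) = apply_calibration(fit, [sample])
        assert out.value == pytest.approx(-250.0, abs=1e-9)

    def test_round_trip_with_planted_coefficients(self):
        offset, scale, size = 18.0, 0.96, 0.0015
        peaks = make_standards(offset=offset, scale=scale, size_coeff=size)
        fit = fit_calibration(peaks, standard_ladder())
        truths = [-280.0, -230.0, -180.0]
        samples = [
            PeakMeasurement(
                "s", 1, f"BP-{i}", amplitude=2500.0 + 500 * i,
                d2H_raw=offset + scale * t + size * (2500.0 + 500 * i),
            )
            for i, t in enumerate(truths)
        ]
        out = apply_calibration(fit, samples)
        for o, t in zip(out, truths):
            assert o.value == pytest.approx(t, abs=1e-9)

    def test_sigma_monotone_non_increasing_in_amplitude(self):
        cfg = SyntheticConfig()
        peaks = []
        for s in range(6):
            peaks += generate_standards_run(cfg, seed=s, run_id=f"r{s}")
        fit = fit_calibration(peaks, standard_ladder())
        amps = [900.0, 2000.0, 4000.0, 7500.0]
        sigmas = [
            apply_calibration(
                fit, [PeakMeasurement("s", 1, "BP-0", amplitude=a, d2H_raw=-250.0)]
            )[0].sigma
            for a in amps
        ]
        assert all(s2 <= s1 + 1e-9 for s1, s2 in zip(sigmas, sigmas[1:]))

    def test_two_sigma_coverage_on_noisy_peaks(self):
        """|calibrated − truth| ≤ 2σ for at least 93% of 1000 noisy peaks."""
        cfg = SyntheticConfig()
        rng = np.random.default_rng(42)
        std_peaks = []
        for s in range(40):
            std_peaks += generate_standards_run(cfg, seed=1000 + s, run_id=f"r{s}")
        fit = fit_calibration(std_peaks, standard_ladder())
        n = 1000
        truths = rng.uniform(-290.0, -150.0, size=n)
        amps = rng.uniform(900.0, 7500.0, size=n)
        noise_sigma = cfg.noise_base_sigma + cfg.noise_amplitude_coeff / amps
        raws = (
            cfg.cal_offset
            + cfg.cal_scale * truths
            + cfg.cal_size_coeff * amps
            + rng.normal(0.0, noise_sigma)
        )
        samples = [
            PeakMeasurement("s", 1, "BP-0", amplitude=float(a), d2H_raw=float(r))
            for a, r in zip(amps, raws)
        ]
        out = apply_calibration(fit, samples)
        covered = sum(
            abs(o.value - t) <= 2 * o.sigma for o, t in zip(out, truths)
        )
        assert covered / n >= 0.93

    def test_non_invertible_fit_rejected(self):
        defs = standard_ladder()
        rng = np.random.default_rng(0)
        peaks = [
            PeakMeasurement(
                "r", 1, d.compound, amplitude=float(rng.uniform(800, 8000)),
                d2H_raw=5.0,  # raw independent of accepted → scale 0
            )
            for d in defs
        ]
        fit = fit_calibration(peaks, defs, size_term=False)
        with pytest.raises(CalibrationError):
            apply_calibration(
                fit, [PeakMeasurement("s", 1, "BP-0", amplitude=3000.0, d2H_raw=-250.0)]
            )


class TestHydrogenation:
    def test_zero_added_h_is_identity(self):
        v = IsotopeValue(-250.0, 3.0)
        assert hydrogenation_correct(v, IsotopeValue(-750.0), 0, 82) is v

    def test_mass_balance_worked_example(self):
        out = hydrogenation_correct(
            IsotopeValue(-250.0), IsotopeValue(-750.0), 2, 82
        )
        assert out.value == pytest.approx((82 * -250.0 - 2 * -750.0) / 80)
        assert out.value == pytest.approx(-237.5)
        # correction magnitude lies inside the published 10.3–12.7‰ range
        assert out.correction == pytest.approx(12.5)

    def test_sigma_quadrature(self):
        out = hydrogenation_correct(
            IsotopeValue(-250.0, 3.0), IsotopeValue(-750.0, 50.0), 2, 82
        )
        expected = math.sqrt((82 / 80) ** 2 * 9 + (2 / 80) ** 2 * 2500)
        assert out.sigma == pytest.approx(expected)
        assert out.sigma - 3.0 < 1.9  # uncertainty inflation stays below 1.9‰

    def test_invalid_stoichiometry_rejected(self):
        with pytest.raises(ValueError):
            hydrogenation_correct(IsotopeValue(-250.0), IsotopeValue(-750.0), 82, 82)

    @given(
        true_delta=st.floats(-320, -150),
        delta_added=st.floats(-900, -300),
        n_added=st.integers(1, 10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_exactly_inverts_generator_dilution(self, true_delta, delta_added, n_added):
        diluted = dilute_with_added_h(true_delta, delta_added, n_added, 82)
        out = hydrogenation_correct(
            IsotopeValue(diluted), IsotopeValue(delta_added), n_added, 82
        )
        assert out.value == pytest.approx(true_delta, abs=1e-9)

    def test_correction_linear_in_measured_minus_added(self):
        slope = HYDROGENATION_N_ADDED / (HYDROGENATION_N_TOTAL - HYDROGENATION_N_ADDED)
        for measured, added in [(-250.0, -750.0), (-200.0, -500.0), (-300.0, -300.0)]:
            out = hydrogenation_correct(IsotopeValue(measured), IsotopeValue(added))
            assert out.correction == pytest.approx(slope * (measured - added))


class TestDiagnostics:
    def test_zero_noise_all_residuals_zero(self):
        peaks = make_standards(offset=-8.0, scale=0.97, size_coeff=0.001)
        fit = fit_calibration(peaks, standard_ladder())
        diag = calibration_diagnostics(fit, peaks, standard_ladder())
        assert np.allclose(diag.residuals, 0.0, atol=1e-9)

    def test_perturbed_standard_has_max_residual(self):
        peaks = make_standards(offset=-8.0, scale=0.97)
        peaks[3].d2H_raw += 20.0
        fit = fit_calibration(peaks, standard_ladder())
        diag = calibration_diagnostics(fit, peaks, standard_ladder())
        assert int(np.argmax(np.abs(diag.residuals))) == 3

    def test_rmse_tracks_configured_noise(self):
        """Residual RMSE ≈ σ at the median amplitude within 25% over 200 runs."""
        cfg = SyntheticConfig()
        peaks = []
        for s in range(200):
            peaks += generate_standards_run(cfg, seed=2000 + s, run_id=f"r{s}")
        fit = fit_calibration(peaks, standard_ladder())
        med_amp = float(np.median([p.amplitude for p in peaks]))
        sigma_med = cfg.noise_base_sigma + cfg.noise_amplitude_coeff / med_amp
        assert fit.residual_rmse == pytest.approx(sigma_med, rel=0.25)
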