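import numpy as np
import pytest

from beamtune.depth_dose import EnergySpectrum, simulate_idc
from beamtune import metrics
from beamtune.errors import DomainError, ExtractionError
from beamtune.optics import OpticsPlane, spot_fwhm_at
from beamtune.particles import PROTON
from beamtune.tuning import (
    TuningConfig,
    energy_objective,
    minimize_with_restarts,
    nelder_mead_minimize,
    optics_objective,
    regularization_term,
    regularized_optics_objective,
    spread_objective,
    tune_energy,
    tune_optics,
    tune_optics_sequence,
    tune_spectrum,
    tune_spread,
)


class TestObjectiveArithmetic:
    def test_energy_objective_squared_difference(self):
        assert energy_objective(1.0, 100.0, lambda e: 99.5) == pytest.approx(0.25)
        assert energy_objective(1.0, 100.0, lambda e: 100.0) == 0.0

    def test_energy_objective_orders_candidates_by_range_error(self):
        forward = lambda e: 1.8 * e  # noqa: E731 - linear surrogate
        close = energy_objective(100.1, 180.0, forward)
        far = energy_objective(101.0, 180.0, forward)
        assert close < far

    def test_spread_objective_squared_difference(self):
        assert spread_objective(0.5, 4.0, lambda s: 3.6) == pytest.approx(0.16)
        assert spread_objective(0.5, 4.0, lambda s: 4.0) == 0.0

    def test_optics_objective_sums_squared_fwhm_differences(self):
        plane = OpticsPlane(3.0, 2.0, 1.0)
        assert optics_objective(
            plane, [10.0, 12.0], lambda p: np.array([9.0, 13.0])
        ) == pytest.approx(2.0)
        assert optics_objective(
            plane, [10.0, 12.0], lambda p: np.array([10.0, 12.0])
        ) == 0.0

    def test_matched_extra_position_adds_nothing(self):
        plane = OpticsPlane(3.0, 2.0, 1.0)
        base = optics_objective(plane, [10.0, 12.0], lambda p: np.array([9.0, 13.0]))
        extended = optics_objective(
            plane, [10.0, 12.0, 8.0], lambda p: np.array([9.0, 13.0, 8.0])
        )
        assert extended == pytest.approx(base)

    def test_regularization_term_examples(self):
        assert regularization_term((3.0, 2.0, 10.0), (3.0, 2.0, 10.0)) == 0.0
        assert regularization_term((3.1, 2.2, 9.0), (3.0, 2.0, 10.0)) == pytest.approx(
            1.05
        )
        assert regularization_term((3.1, 2.2, 9.0), (3.0, 2.0, 10.0)) == pytest.approx(
            regularization_term((3.0, 2.0, 10.0), (3.1, 2.2, 9.0))
        )

    def test_regularized_objective_composition(self):
        plane = OpticsPlane(3.1, 2.2, 9.0)
        prev = OpticsPlane(3.0, 2.0, 10.0)
        forward = lambda p: np.array([9.0, 13.0])  # noqa: E731
        value = regularized_optics_objective(
            plane, [10.0, 12.0], forward, previous=prev, lambda_reg=0.1
        )
        assert value == pytest.approx(2.0 + 0.1 * 1.05)
        # lambda = 0 reduces to the plain data term
        assert regularized_optics_objective(
            plane, [10.0, 12.0], forward, previous=prev, lambda_reg=0.0
        ) == pytest.approx(2.0)
        # lowest energy: no regularization term at all
        assert regularized_optics_objective(
            plane, [10.0, 12.0], forward, previous=None, lambda_reg=0.1
        ) == pytest.approx(2.0)


class TestNelderMead:
    def test_one_dimensional_parabola(self):
        res = nelder_mead_minimize(lambda x: (x[0] - 3.0) ** 2, [0.0])
        assert res.x[0] == pytest.approx(3.0, abs=1e-4)

    def test_three_dimensional_quadratic(self):
        res = minimize_with_restarts(
            lambda x: np.sum((x - np.array([1.0, 2.0, 3.0])) ** 2),
            [0.0, 0.0, 0.0],
            TuningConfig(stop_param_change=1e-7, stop_objective=1e-14),
        )
        assert np.allclose(res.x, [1.0, 2.0, 3.0], atol=1e-3)

    def test_rosenbrock_under_relaxed_stops(self):
        rosen = lambda x: (1 - x[0]) ** 2 + 100 * (x[1] - x[0] ** 2) ** 2  # noqa: E731
        res = minimize_with_restarts(
            rosen,
            [-1.2, 1.0],
            TuningConfig(
                max_iterations=5000, stop_param_change=1e-10, stop_objective=1e-18
            ),
        )
        assert np.allclose(res.x, [1.0, 1.0], atol=1e-3)

    def test_agrees_with_scipy_reference_implementation(self):
        from scipy.optimize import minimize

        f = lambda x: (x[0] - 2) ** 4 + (x[1] + 1) ** 2 + x[0] * 0.1  # noqa: E731
        ours = minimize_with_restarts(
            f, [0.0, 0.0], TuningConfig(stop_param_change=1e-8, stop_objective=1e-16)
        )
        ref = minimize(f, [0.0, 0.0], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        assert ours.fun == pytest.approx(ref.fun, rel=1e-3, abs=1e-9)

    def test_deterministic_given_start_and_config(self):
        f = lambda x: (x[0] - 1) ** 2 + 0.5 * (x[1] - 2) ** 2  # noqa: E731
        a = nelder_mead_minimize(f, [5.0, 5.0])
        b = nelder_mead_minimize(f, [5.0, 5.0])
        assert np.array_equal(a.x, b.x) and a.nfev == b.nfev

    def test_non_finite_start_rejected(self):
        with pytest.raises(DomainError):
            nelder_mead_minimize(lambda x: float("nan"), [0.0])


class TestSpectrumTuning:
    def test_energy_recovery_from_synthetic_curve(self):
        truth = EnergySpectrum(150.0, 0.0)
        idc = simulate_idc(truth, PROTON)
        e_star, result, r80_meas = tune_energy(idc, PROTON, e0=145.0)
        r80_sim = metrics.r80(simulate_idc(EnergySpectrum(e_star, 0.0), PROTON))
        assert abs(r80_sim - r80_meas) < 0.05

    def test_start_at_truth_converges_immediately(self):
        truth = EnergySpectrum(150.0, 0.0)
        idc = simulate_idc(truth, PROTON)
        _, result, _ = tune_energy(idc, PROTON, e0=150.0)
        assert result.fun < 1e-5

    def test_result_independent_of_fixed_spread_guess_via_alternation(self):
        idc = simulate_idc(EnergySpectrum(150.0, 1.0), PROTON)
        fit = tune_spectrum(idc, PROTON, TuningConfig())
        assert abs(fit.r80_simulated - fit.r80_measured) < 0.05
        assert abs(fit.bpw80_simulated - fit.bpw80_measured) < 0.05
        assert fit.spectrum.sigma_e == pytest.approx(1.0, abs=0.05)
        assert fit.spectrum.energy == pytest.approx(150.0, abs=0.1)

    def test_degenerate_curve_propagates_extraction_error(self):
        from beamtune.depth_dose import DepthDoseCurve

        depths = np.arange(0, 10, 0.1)
        rising = DepthDoseCurve(depths=depths, dose=np.linspace(0.1, 1.0, depths.size))
        with pytest.raises(ExtractionError):
            tune_energy(rising, PROTON)

    def test_spread_recovery(self):
        idc = simulate_idc(EnergySpectrum(150.0, 1.0), PROTON)
        sigma, result, bpw_meas = tune_spread(idc, PROTON, 150.0)
        bpw_sim = metrics.bragg_peak_width(
            simulate_idc(EnergySpectrum(150.0, sigma), PROTON)
        )
        assert abs(bpw_sim - bpw_meas) < 0.05

    def test_zero_spread_truth_drives_sigma_to_boundary(self):
        idc = simulate_idc(EnergySpectrum(150.0, 0.0), PROTON)
        sigma, _, _ = tune_spread(idc, PROTON, 150.0)
        assert 0.0 <= sigma < 0.08


class TestOpticsTuning:
    def _measurement(self, plane, spectrum, geometry):
        z = np.array(geometry.measurement_positions_mm)
        return z, spot_fwhm_at(plane, geometry, spectrum.energy, PROTON, z)

    def test_noise_free_single_energy_recovery(self, zero_noise_machine):
        truth, ms = zero_noise_machine
        energy = float(ms.energies[2])
        spectrum = truth.spectrum(energy)
        spots = ms.spots_at(energy)
        fit = tune_optics(
            spots["position_mm"].to_numpy(),
            spots["fwhm_x_mm"].to_numpy(),
            ms.geometry,
            spectrum,
            PROTON,
            TuningConfig(),
        )
        rel = np.abs(fit.fwhm_simulated - fit.fwhm_measured) / fit.fwhm_measured
        assert rel.max() < 1e-3

    def test_objective_is_pure(self, zero_noise_machine):
        truth, ms = zero_noise_machine
        energy = float(ms.energies[0])
        plane = truth.optics(energy, "x")
        z = np.array(ms.geometry.measurement_positions_mm)
        forward = lambda p: spot_fwhm_at(  # noqa: E731
            p, ms.geometry, energy, PROTON, z
        )
        measured = forward(plane)
        v1 = optics_objective(plane, measured, forward)
        v2 = optics_objective(plane, measured, forward)
        assert v1 == v2 == 0.0

    def test_single_energy_sequence_equals_unregularized_fit(self, zero_noise_machine):
        truth, ms = zero_noise_machine
        from beamtune.synthetic import make_machine_truth, generate_measurements, ZERO_NOISE
        import dataclasses

        # restrict to the lowest energy only
        e0 = float(ms.energies[0])
        sub = dataclasses.replace(
            ms,
            energies=np.array([e0]),
            idcs={e0: ms.idcs[e0]},
            spots=ms.spots[ms.spots["energy_MeV"] == e0],
        )
        spectra = {e0: truth.spectrum(e0)}
        with_reg = tune_optics_sequence(sub, "x", spectra, TuningConfig(lambda_reg=0.1))
        without = tune_optics_sequence(sub, "x", spectra, TuningConfig(lambda_reg=0.0))
        assert with_reg[0].plane == without[0].plane

    def test_regularization_degrades_data_term_by_at_most_lambda_r(
        self, zero_noise_machine
    ):
        truth, ms = zero_noise_machine
        spectra = {float(e): truth.spectrum(float(e)) for e in ms.energies}
        reg = tune_optics_sequence(ms, "x", spectra, TuningConfig(lambda_reg=0.1))
        unreg = tune_optics_sequence(ms, "x", spectra, TuningConfig(lambda_reg=0.0))
        for i in range(1, len(reg)):
            r_term = regularization_term(reg[i].plane, reg[i - 1].plane)
            bound = unreg[i].data_term + 0.1 * r_term + 1e-6
            assert reg[i].data_term <= bound + 0.01  # optimizer tolerance

    def test_full_sequence_reproduces_measured_fwhm_within_noise(
        self, zero_noise_machine
    ):
        truth, ms = zero_noise_machine
        spectra = {float(e): truth.spectrum(float(e)) for e in ms.energies}
        fits = tune_optics_sequence(ms, "y", spectra, TuningConfig(lambda_reg=0.0))
        for fit in fits:
            rel = np.abs(fit.fwhm_simulated - fit.fwhm_measured) / fit.fwhm_measured
            assert rel.max() < 1e-3

    def test_too_few_positions_rejected(self, zero_noise_machine):
        truth, ms = zero_noise_machine
        with pytest.raises(DomainError):
            tune_optics(
                np.array([0.0]),
                np.array([10.0]),
                ms.geometry,
                truth.spectrum(100.0),
                PROTON,
            )
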