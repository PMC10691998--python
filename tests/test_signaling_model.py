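"""Deterministic ODE model: steady state, conservation, dose response,
response metrics, and the IKKbeta-deactivation perturbation."""

import numpy as np
import pytest

import nfkbcap as nc
from nfkbcap.exceptions import (
    CalibrationError,
    DoseResponseRangeError,
    UndefinedFoldChangeError,
    UnknownPerturbationError,
)
from nfkbcap.signaling_model import (
    PROTEINS,
    SPECIES,
    Trajectory,
    CALIBRATION_TARGETS,
    PRIMARY_ANCHORS,
    load_parameters,
    save_parameters,
    steady_state_fast,
    verify_calibration,
)


class TestParameterSet:
    def test_default_construction_contract(self, params):
        assert params.ikkb_deactivation_enabled
        assert all(v >= 0 for v in params.rates.values())
        assert all(v > 0 for v in params.nominal_totals.values())
        assert set(PROTEINS) <= set(params.nominal_totals)

    def test_missing_rate_rejected(self, params):
        rates = dict(params.rates)
        rates.pop("k_deact")
        with pytest.raises(ValueError, match="k_deact"):
            nc.KineticParameterSet(rates=rates, nominal_totals=params.nominal_totals)

    def test_yaml_roundtrip_and_tamper_guard(self, params, tmp_path):
        path = tmp_path / "params.yaml"
        save_parameters(params, path)
        again = load_parameters(path)
        assert again.rates == dict(params.rates)
        # silent edits of the stored constants must be detected
        text = path.read_text().replace(
            f"k_deact: {params.rates['k_deact']}", "k_deact: 99.0")
        path.write_text(text)
        with pytest.raises(CalibrationError, match="checksum"):
            load_parameters(path)


class TestSteadyState:
    def test_residual_criterion(self, params, steady_state):
        from nfkbcap.signaling_model import _steady_residual

        r = params.rate_vector(params.nominal_totals)
        assert _steady_residual(steady_state.vector(), r) < 1e-9

    def test_most_nfkb_sequestered(self, steady_state):
        c = steady_state.concentrations
        free = c["NFkBc"] + c["NFkBn"]
        assert free < 0.10 * steady_state.total_nfkb
        assert steady_state.nuclear_nfkb > 0

    def test_more_inhibitor_lowers_baseline(self, params):
        lo, _ = steady_state_fast(params, params.totals_or_nominal(None))
        hi_tot = params.totals_or_nominal(None)
        hi_tot["IkBa"] *= 10.0
        hi, _ = steady_state_fast(params, hi_tot)
        assert hi.nuclear_nfkb < lo.nuclear_nfkb

    def test_integrate_method_agrees(self, params, steady_state):
        ss2 = nc.pre_stimulation_steady_state(params, method="integrate")
        assert ss2.nuclear_nfkb == pytest.approx(steady_state.nuclear_nfkb, rel=1e-6)


class TestSimulation:
    def test_no_stimulus_keeps_steady_state(self, params, steady_state):
        traj = nc.simulate_response(params, steady_state, 0.0, t_end=300.0)
        y0 = steady_state.vector()
        scale = np.maximum(np.abs(y0), 1e-12)
        rel = np.abs(traj.states - y0) / scale
        assert rel.max() < 1e-6

    def test_saturating_transient_returns_toward_baseline(self, saturating_trajectory):
        nuc = saturating_trajectory.nuclear_nfkb
        baseline, peak, final = nuc[0], nuc.max(), nuc[-1]
        assert peak > 5 * baseline
        assert (final - baseline) < 0.25 * (peak - baseline)

    def test_conserved_totals_along_trajectory(self, saturating_trajectory):
        tr = saturating_trajectory
        groups = {
            "NFkB": ["CPLX", "NFkBc", "NFkBn"],
            "CAR": ["CAR", "AgCAR", "SIG", "SIGi"],
            "TRAF2": ["TRAF2", "SIG"],
            "RIP1": ["RIP1", "RIP1Ub"],
            "TAK": ["TAK", "TAKa"],
            "IKKb": ["IKKb", "IKKba", "IKKbi"],
        }
        for name, members in groups.items():
            total = sum(tr.species(m) for m in members)
            assert np.allclose(total, total[0], rtol=1e-6), name

    def test_dose_monotonicity_of_peaks(self, params, steady_state):
        peaks = [
            nc.simulate_response(params, steady_state, a, t_end=180.0).nuclear_nfkb.max()
            for a in (0.5, 1.0, 2.0, 4.0)
        ]
        assert np.all(np.diff(peaks) >= -1e-12)

    def test_negative_antigen_rejected(self, params, steady_state):
        with pytest.raises(ValueError):
            nc.simulate_response(params, steady_state, -1.0)


class TestResponseMetrics:
    @staticmethod
    def _traj_from(times, nuc, ikkba=None):
        states = np.zeros((len(times), len(SPECIES)))
        states[:, SPECIES.index("NFkBn")] = nuc
        if ikkba is not None:
            states[:, SPECIES.index("IKKba")] = ikkba
        return Trajectory(times=times, states=states, antigen=1.0)

    def test_flat_trajectory(self):
        t = np.arange(0.0, 120.5, 0.5)
        m = nc.response_metrics(self._traj_from(t, np.full(len(t), 0.7)))
        assert m.baseline_nuclear_nfkb == m.peak_nuclear_nfkb == 0.7
        assert m.fold_change == 1.0
        assert m.ikkb_pulse_width == 0.0

    def test_sinusoidal_bump_closed_form(self):
        t = np.arange(0.0, 60.5, 0.5)
        b = 0.3
        nuc = b * (1.0 + np.sin(np.pi * t / 60.0))
        m = nc.response_metrics(self._traj_from(t, nuc))
        assert m.peak_time == pytest.approx(30.0, abs=0.5)
        assert m.fold_change == pytest.approx(2.0, rel=1e-9)

    def test_zero_baseline_rejected(self):
        t = np.arange(0.0, 120.5, 0.5)
        nuc = np.zeros(len(t))
        nuc[10:] = 1.0
        with pytest.raises(UndefinedFoldChangeError):
            nc.response_metrics(self._traj_from(t, nuc))

    def test_pulse_width_runs_to_end_when_sustained(self):
        t = np.arange(0.0, 120.5, 0.5)
        ikk = np.where(t >= 10.0, 1.0, 0.0)
        m = nc.response_metrics(self._traj_from(t, np.full(len(t), 0.1), ikk))
        assert m.ikkb_pulse_width == pytest.approx(110.0, abs=1.0)


class TestDoseResponse:
    def test_grid_bottom_inactive_and_top_normalized(self, dose_curve):
        assert dose_curve.activation[0] < 0.01
        assert dose_curve.activation[-1] == pytest.approx(1.0)
        assert np.all(np.diff(dose_curve.activation) >= 0)

    def test_printed_anchor_concentrations(self, dose_curve):
        # 5.5% of saturation near 0.7 molecules/um^2, 96% near 70
        assert dose_curve.anchor_low == pytest.approx(0.7, rel=0.25)
        assert dose_curve.anchor_high == pytest.approx(70.0, rel=0.25)

    def test_inversion_midpoint(self, dose_curve):
        a = nc.invert_dose_response(dose_curve, 0.5)
        assert dose_curve.anchor_low < a < dose_curve.anchor_high
        assert float(dose_curve(a)) == pytest.approx(0.5, abs=1e-3)

    def test_inversion_endpoints_map_to_anchors(self, dose_curve):
        assert nc.invert_dose_response(dose_curve, 0.0) == dose_curve.anchor_low
        assert nc.invert_dose_response(dose_curve, 1.0) == dose_curve.anchor_high
        with pytest.raises(DoseResponseRangeError):
            nc.invert_dose_response(dose_curve, 1.5)

    def test_undersized_grid_rejected(self, params):
        with pytest.raises(ValueError):
            nc.dose_response(params, {"min": 0.1, "max": 10.0, "points": 10})


class TestPerturbation:
    def test_single_rate_zeroed(self, params, perturbed_params):
        diffs = [k for k in params.rates
                 if params.rates[k] != perturbed_params.rates[k]]
        assert diffs == ["k_deact"]
        assert perturbed_params.rates["k_deact"] == 0.0
        assert not perturbed_params.ikkb_deactivation_enabled

    def test_unknown_name_rejected(self, params):
        with pytest.raises(UnknownPerturbationError):
            nc.apply_perturbation(params, "turbo_mode")

    def test_sustained_kinase_activity(self, perturbed_params, steady_state):
        traj = nc.simulate_response(perturbed_params, steady_state, 100.0)
        ikk = traj.active_ikkb
        # without deactivation, active IKKbeta never returns to half-maximum
        assert ikk[-1] > 0.5 * ikk.max()

    def test_dose_curve_left_shift_and_dominance(self, dose_curve, perturbed_curve):
        assert perturbed_curve.anchor_low < dose_curve.anchor_low
        assert perturbed_curve.anchor_high < dose_curve.anchor_high
        probe = dose_curve.antigen_grid[::7]
        assert np.all(perturbed_curve(probe) >= dose_curve(probe) - 1e-3)


class TestCalibration:
    def test_primary_anchors_within_ten_percent(self, params):
        measured = verify_calibration(params)  # raises on any violation
        for name in PRIMARY_ANCHORS:
            target = CALIBRATION_TARGETS[name]
            assert abs(measured[name] - target) / target <= 0.10

    def test_anchor_measurement_is_deterministic(self, params, dose_curve,
                                                 saturating_trajectory):
        m = nc.response_metrics(saturating_trajectory)
        assert m.ikkb_pulse_width == pytest.approx(
            CALIBRATION_TARGETS["ikkb_pulse_fwhm_min"], rel=0.10)
        assert m.peak_time == pytest.approx(
            CALIBRATION_TARGETS["nuclear_peak_time_min"], rel=0.10)
        assert float(dose_curve(0.7)) == pytest.approx(0.055, rel=0.10)
        assert float(dose_curve(70.0)) == pytest.approx(0.96, rel=0.10)
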