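import numpy as np
import pytest

from ternabind.equilibrium import (
    DoseResponseCurve,
    equilibrium_dose_response,
    hook_metrics,
    simulate_kinetics,
    steady_state_solve,
    ternary_at_doses,
)
from ternabind.model import BindingParameters, ExperimentSetup, InvalidInputError, SystemState

from conftest import make_params, random_params


def quadratic_bound_complex(a_tot: float, b_tot: float, kd: float) -> float:
    """Closed-form 1:1 binding isotherm (independent oracle)."""
    s = a_tot + b_tot + kd
    return (s - np.sqrt(s * s - 4 * a_tot * b_tot)) / 2


def relative_gap(a: np.ndarray, b: np.ndarray, floor: float) -> float:
    denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), floor)
    return float(np.max(np.abs(a - b) / denom))


@pytest.fixture
def unit_setup():
    return ExperimentSetup(1, 1, 1, 1, 1.0, 150_000.0, dose_grid=(1.0,), t_max=1e6)


class TestSimulateKinetics:
    def test_all_rates_off_state_constant(self, unit_setup):
        p = make_params()  # every rate effectively zero
        init = SystemState(1.0, 2.0, 3.0, 0.5, 0.2, 0.1)
        traj = simulate_kinetics(unit_setup, p, init, t_max=1e4)
        assert np.abs(traj.states - init.as_array()[None, :]).max() <= 1e-9

    def test_one_to_one_matches_quadratic_closed_form(self, unit_setup):
        # only reaction pair 1/2 active, KD1 = 1 nM, 1 nM of each partner
        p = make_params(kf1=1.0, kr1=1.0)
        traj = simulate_kinetics(unit_setup, p, SystemState(1.0, 1.0, 0, 0, 0, 0))
        expected = quadratic_bound_complex(1.0, 1.0, 1.0)
        assert expected == pytest.approx(0.381966, rel=1e-5)
        assert traj.final_state.Tc_Ab == pytest.approx(expected, rel=1e-6)
        assert traj.equilibrium_reached

    def test_conservation_and_nonnegativity_along_trajectory(self, rng, unit_setup):
        for _ in range(15):
            p = random_params(rng)
            init = SystemState(*rng.uniform(0.01, 5.0, 3), 0, 0, 0)
            traj = simulate_kinetics(unit_setup, p, init, t_max=1e6)
            totals0 = np.array(init.conserved_totals())
            proj = np.array(
                [
                    traj.states[:, 0] + traj.states[:, 3] + traj.states[:, 5],
                    traj.states[:, 1] + traj.states[:, 3] + traj.states[:, 4] + traj.states[:, 5],
                    traj.states[:, 2] + traj.states[:, 4] + traj.states[:, 5],
                ]
            )
            drift = np.abs(proj - totals0[:, None]) / totals0[:, None]
            assert drift.max() <= 1e-8
            assert traj.states.min() >= -1e-12 * totals0.max()

    def test_equilibrium_not_reached_on_short_horizon(self, unit_setup):
        p = make_params(kf1=1e-6, kr1=1e-6)
        traj = simulate_kinetics(unit_setup, p, SystemState(1, 1, 0, 0, 0, 0), t_max=10.0)
        assert not traj.equilibrium_reached
        assert np.isnan(traj.time_to_equilibrium)

    def test_time_to_equilibrium_within_window(self, unit_setup):
        p = make_params(kf1=1.0, kr1=1.0)
        traj = simulate_kinetics(unit_setup, p, SystemState(1, 1, 0, 0, 0, 0), t_max=1e6)
        assert traj.equilibrium_reached
        assert 0 < traj.time_to_equilibrium < 1e6


class TestSteadyStateSolve:
    def test_no_antibody_means_no_complexes(self, unit_setup, moderate_params):
        s = steady_state_solve(unit_setup, moderate_params, (1.0, 0.0, 2.0))
        assert s.Tc_Ab == s.Ab_Tu == s.Tc_Ab_Tu == 0.0
        assert (s.Tc, s.Ab, s.Tu) == (1.0, 0.0, 2.0)

    def test_one_to_one_subsystem_closed_form(self, unit_setup):
        p = make_params(kf1=2.0, kr1=1.0)  # KD1 = 0.5
        s = steady_state_solve(unit_setup, p, (1.5, 0.8, 0.0))
        assert s.Tc_Ab == pytest.approx(quadratic_bound_complex(1.5, 0.8, 0.5), rel=1e-6)

    def test_against_long_time_integration(self, rng, unit_setup):
        for _ in range(10):
            p = random_params(rng)
            totals = tuple(rng.uniform(0.05, 5.0, 3))
            state = steady_state_solve(unit_setup, p, totals)
            init = SystemState(totals[0], totals[1], totals[2], 0, 0, 0)
            traj = simulate_kinetics(unit_setup, p, init, t_max=1e9)
            gap = relative_gap(
                state.as_array(), traj.final_state.as_array(), 1e-9 * max(totals)
            )
            assert gap <= 1e-6

    def test_totals_preserved(self, unit_setup, moderate_params):
        totals = (0.7, 1.3, 0.4)
        s = steady_state_solve(unit_setup, moderate_params, totals)
        np.testing.assert_allclose(s.conserved_totals(), totals, rtol=1e-8)

    def test_invalid_totals_rejected(self, unit_setup, moderate_params):
        with pytest.raises(InvalidInputError):
            steady_state_solve(unit_setup, moderate_params, (1.0, -0.5, 1.0))


class TestDoseResponse:
    def test_zero_dose_gives_exactly_zero(self, moderate_params):
        setup = ExperimentSetup(
            1e5, 2e5, 1e5, 1e4, 0.2, 150_000.0, dose_grid=(0.0, 0.01, 0.1), t_max=1e7
        )
        curve = equilibrium_dose_response(setup, moderate_params, method="root")
        assert curve.ternary[0] == 0.0
        assert np.all(curve.ternary[1:] > 0)

    def test_kinetic_and_root_routes_agree(self, simple_setup, moderate_params):
        doses = np.asarray(simple_setup.dose_grid)
        kin = ternary_at_doses(simple_setup, moderate_params, doses, method="kinetic")
        alg = ternary_at_doses(simple_setup, moderate_params, doses, method="root")
        assert relative_gap(kin, alg, 1e-9 * kin.max()) <= 1e-6

    def test_unimodal_on_fine_grid(self, rng):
        # brute-force scan: the discrete derivative changes sign at most once
        for _ in range(5):
            p = random_params(rng, decades=3.0)
            setup = ExperimentSetup(
                1e5, 2e5, 1e5, 1e5, 0.2, 150_000.0,
                dose_grid=tuple(np.geomspace(1e-4, 1e1, 80)), t_max=1e8,
            )
            tern = ternary_at_doses(setup, p, np.asarray(setup.dose_grid), method="root")
            diff = np.diff(tern)
            tol = 1e-9 * tern.max()
            signs = np.sign(np.where(np.abs(diff) <= tol, 0.0, diff))
            signs = signs[signs != 0]
            flips = np.count_nonzero(np.diff(signs) != 0)
            assert flips <= 1

    def test_hook_saturating_antibody_kills_ternary(self, simple_setup, moderate_params):
        totals_nM = max(simple_setup.effector_sites_molar(), simple_setup.target_sites_molar())
        big_dose = 1e4 * totals_nM * simple_setup.antibody_mw / 1e6  # 1e4x both receptor totals
        doses = np.asarray(list(simple_setup.dose_grid) + [big_dose])
        tern = ternary_at_doses(simple_setup, moderate_params, doses, method="root")
        assert tern[-1] < 0.01 * tern.max()

    def test_normalized_peak_is_one(self, simple_setup, moderate_params):
        curve = equilibrium_dose_response(simple_setup, moderate_params, method="root")
        assert curve.normalized.max() == 1.0
        assert np.all((curve.normalized >= 0) & (curve.normalized <= 1))

    def test_empty_grid_rejected(self, simple_setup, moderate_params):
        with pytest.raises(InvalidInputError):
            ternary_at_doses(simple_setup, moderate_params, np.array([]), method="root")

    def test_affinity_monotonicity_quick(self, simple_setup, moderate_params):
        # Tightening the receptor-antibody bond must not lower the peak.
        # That bond appears in reactions 1 and 4, so both reverse rates are
        # scaled together (keeping the binding cycle thermodynamically
        # consistent); changing kr1 alone drives a nonequilibrium cycle for
        # which this monotonicity provably fails.
        peaks = []
        for kr1 in (1e-1, 1e-2, 1e-3):
            p = moderate_params.replace(kr1=kr1, kr4=kr1)
            tern = ternary_at_doses(
                simple_setup, p, np.asarray(simple_setup.dose_grid), method="root"
            )
            peaks.append(tern.max())
        assert peaks[0] <= peaks[1] * (1 + 1e-9) and peaks[1] <= peaks[2] * (1 + 1e-9)


class TestHookMetrics:
    def test_simple_hook(self):
        m = hook_metrics(DoseResponseCurve(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.9, 0.2])))
        assert m.peak_dose == 2.0
        assert m.hook_detected
        assert m.effective_window == (2.0, 2.0)

    def test_monotone_increasing_no_hook(self):
        m = hook_metrics(DoseResponseCurve(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.9])))
        assert not m.hook_detected
        assert m.peak_dose == 3.0

    def test_all_zero_curve(self):
        m = hook_metrics(DoseResponseCurve(np.array([1.0, 2.0]), np.array([0.0, 0.0])))
        assert m.peak_ternary == 0.0
        assert not m.hook_detected
        assert m.peak_dose == 1.0

    def test_tie_break_smallest_dose(self):
        m = hook_metrics(DoseResponseCurve(np.array([1.0, 2.0, 3.0]), np.array([0.5, 0.5, 0.1])))
        assert m.peak_dose == 1.0

    def test_window_matches_brute_force_scan(self, rng):
        for _ in range(20):
            doses = np.sort(rng.uniform(0.1, 10.0, 15))
            tern = rng.uniform(0.0, 1.0, 15)
            m = hook_metrics(DoseResponseCurve(doses, tern))
            peak_idx = int(np.argmax(tern))
            half = 0.5 * tern[peak_idx]
            # independent linear scan for the contiguous >= 50% run around the peak
            lo = peak_idx
            for i in range(peak_idx, -1, -1):
                if tern[i] >= half:
                    lo = i
                else:
                    break
            hi = peak_idx
            for i in range(peak_idx, 15):
                if tern[i] >= half:
                    hi = i
                else:
                    break
            assert m.effective_window == (doses[lo], doses[hi])
            assert m.effective_window[0] <= m.peak_dose <= m.effective_window[1]

    def test_empty_curve_rejected(self):
        with pytest.raises(InvalidInputError):
            hook_metrics(DoseResponseCurve(np.array([]), np.array([])))
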