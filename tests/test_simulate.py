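import numpy as np
import pytest

from cartsim import (
    GEN1,
    GEN2,
    assemble_model,
    compute_activation,
    dose_response,
    simulate_trajectory,
)
from cartsim.simulate import (
    ActivationOutcome,
    SimulationSettings,
    Trajectory,
    batch_activation_times,
    first_crossing,
)
from cartsim.variability import KineticVariabilitySpec, sample_kinetics
from cartsim.network import PARAM_NAMES, pack_theta


class TestFirstCrossing:
    def test_linear_interpolation_midpoint(self):
        # fraction 0.4 at t=9, 0.6 at t=11 -> crossing of 0.5 at exactly 10
        t = np.array([0.0, 9.0, 11.0, 30.0])
        v = np.array([0.0, 0.4, 0.6, 0.9])
        assert first_crossing(t, v, 0.5) == pytest.approx(10.0)

    def test_no_crossing_returns_none(self):
        t = np.linspace(0, 30, 50)
        v = np.full(50, 0.2)
        assert first_crossing(t, v, 0.5) is None

    def test_crossing_at_first_point(self):
        t = np.linspace(0, 30, 50)
        v = np.linspace(0.6, 0.9, 50)
        assert first_crossing(t, v, 0.5) == 0.0


class TestActivationOutcome:
    def test_active_requires_time_in_horizon(self):
        with pytest.raises(ValueError):
            ActivationOutcome(active=True, activation_time=None, censoring_horizon=30)
        with pytest.raises(ValueError):
            ActivationOutcome(active=True, activation_time=31.0, censoring_horizon=30)

    def test_censored_carries_no_time(self):
        with pytest.raises(ValueError):
            ActivationOutcome(active=False, activation_time=5.0, censoring_horizon=30)


class TestSettings:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SimulationSettings(horizon=-1)
        with pytest.raises(ValueError):
            SimulationSettings(activation_threshold=1.5)


class TestTrajectories:
    def test_no_stimulus_never_activates(self, gen1_network, settings):
        traj = simulate_trajectory(gen1_network, 0.0, settings)
        assert traj.solver_ok
        assert np.all(traj.pperk_fraction < settings.activation_threshold)
        assert not compute_activation(traj, settings).active

    def test_basal_pperk_fraction_is_low(self, gen1_network, settings):
        traj = simulate_trajectory(gen1_network, 0.0, settings)
        assert np.all(traj.pperk_fraction < 0.05)

    @pytest.mark.parametrize("network_fixture", ["gen1_network", "gen2_network"])
    def test_high_antigen_activates_within_horizon(
        self, network_fixture, settings, request
    ):
        net = request.getfixturevalue(network_fixture)
        out = compute_activation(simulate_trajectory(net, 45.0, settings), settings)
        assert out.active
        assert 0 < out.activation_time <= settings.horizon

    def test_negative_antigen_rejected(self, gen1_network):
        with pytest.raises(ValueError):
            simulate_trajectory(gen1_network, -1.0)

    def test_conserved_totals_constant_along_trajectory(self, gen2_network):
        traj = simulate_trajectory(gen2_network, 45.0)
        drift = traj.moiety_drift(gen2_network)
        assert max(drift.values()) < 1e-4

    def test_pperk_fraction_bounded(self, gen1_network):
        traj = simulate_trajectory(gen1_network, 10.0)
        assert np.all(traj.pperk_fraction >= -1e-12)
        assert np.all(traj.pperk_fraction <= 1 + 1e-12)


class TestOracleEquivalence:
    def test_interpolated_time_matches_dense_grid_scan(self, gen1_network, registry):
        """Event-located times agree with 0.001-min brute force within 0.01."""
        fine = SimulationSettings(readout_dt=0.001)
        coarse = SimulationSettings()
        spec = KineticVariabilitySpec()
        draws = sample_kinetics(registry, spec, n=8, seed=99)
        base = pack_theta(registry)
        for i in range(len(draws)):
            theta = base.copy()
            for j, name in enumerate(PARAM_NAMES):
                if name in draws.columns:
                    theta[j] = draws[name].iloc[i]
            t_interp = compute_activation(
                simulate_trajectory(gen1_network, 6.0, coarse, theta), coarse
            )
            traj = simulate_trajectory(gen1_network, 6.0, fine, theta)
            above = traj.pperk_fraction >= 0.5
            t_scan = traj.times[np.argmax(above)] if above.any() else None
            if t_scan is None:
                assert not t_interp.active
            else:
                assert t_interp.active
                assert abs(t_interp.activation_time - t_scan) < 0.01


class TestScalingSanity:
    def test_lck_catalytic_boost_accelerates_activation(self, registry):
        slow = assemble_model(GEN1, registry)
        fast = assemble_model(
            GEN1, registry.with_values({"Kcat_LCKPU_CD3z": registry["Kcat_LCKPU_CD3z"] * 10})
        )
        t_slow = compute_activation(simulate_trajectory(slow, 4.5))
        t_fast = compute_activation(simulate_trajectory(fast, 4.5))
        assert t_fast.active
        assert t_fast.activation_time < t_slow.activation_time


class TestDoseResponse:
    def test_grid_validation(self, gen1_network):
        with pytest.raises(ValueError):
            dose_response(gen1_network, np.array([3.0, 1.0]))
        with pytest.raises(ValueError):
            dose_response(gen1_network, np.array([-1.0, 1.0]))

    def test_zero_antigen_row_inactive(self, gen1_network):
        df = dose_response(gen1_network, np.array([0.0, 45.0]))
        assert not df.iloc[0]["active"]
        assert df.iloc[1]["active"]

    def test_generation2_dose_curve_is_left_shifted(self, registry):
        """The CD28 construct activates at lower antigen density."""
        grid = np.geomspace(0.2, 45.0, 10)
        d1 = dose_response(assemble_model(GEN1, registry), grid)
        d2 = dose_response(assemble_model(GEN2, registry), grid)
        thr1 = d1[d1["active"]]["antigen"].min()
        thr2 = d2[d2["active"]]["antigen"].min()
        assert thr2 < thr1

    def test_activation_time_nonincreasing_in_antigen(self, gen1_network):
        grid = np.geomspace(2.5, 45.0, 8)
        df = dose_response(gen1_network, grid)
        times = df["activation_time"].to_numpy()
        assert df["active"].all()
        assert np.all(np.diff(times) <= 1e-9)


class TestBatchIntegration:
    def test_batch_matches_single_cell_path(self, gen1_network, settings):
        ag = np.array([3.0, 4.5, 45.0])
        times, status = batch_activation_times(gen1_network, ag, settings)
        for k, a in enumerate(ag):
            single = compute_activation(
                simulate_trajectory(gen1_network, float(a), settings), settings
            )
            assert (status[k] == 1) == single.active
            if single.active:
                assert times[k] == pytest.approx(single.activation_time, abs=0.02)

    def test_batch_censored_below_threshold_antigen(self, gen1_network, settings):
        times, status = batch_activation_times(
            gen1_network, np.array([0.0, 0.1]), settings
        )
        assert np.all(status == 0)
        assert np.all(np.isnan(times))
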