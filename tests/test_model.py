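"""Kinetic core: rate expressions, conservation laws, integrator contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_scenario
from denitkin import (
    ConfigurationError,
    IntegrationError,
    InvalidParameterError,
    KineticParams,
    OrganicsPool,
    SystemState,
    derivatives,
    growth_rate,
    monod_factor,
    nitrate_rate,
    simulate,
    substrate_rates,
    trajectory_frame,
)
from oracles import euler_trajectory


def single_pool_state(sS=2.0, sNO3=2.0, xB=1.0, label="plasticizer"):
    return SystemState(t=0.0, pools=(OrganicsPool(label, sS),), sNO3=sNO3, xB=xB)


class TestMonod:
    @pytest.mark.parametrize(
        "s, K, expected, tol",
        [(0.0, 0.02, 0.0, 0.0), (0.02, 0.02, 0.5, 1e-15), (2.0, 0.0002, 1.0, 1e-3)],
    )
    def test_reference_points(self, s, K, expected, tol):
        assert monod_factor(s, K) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("s, K", [(0.1, 0.0), (0.1, -1.0), (-0.1, 0.02)])
    def test_invalid_inputs_rejected(self, s, K):
        with pytest.raises(InvalidParameterError):
            monod_factor(s, K)

    @given(
        s=st.floats(0, 1e3, allow_nan=False),
        ds=st.floats(0, 1e3, allow_nan=False),
        K=st.floats(1e-6, 1e3, allow_nan=False),
    )
    def test_bounded_and_monotone(self, s, ds, K):
        f = monod_factor(s, K)
        assert 0.0 <= f < 1.0
        assert monod_factor(s + ds, K) >= f


class TestRates:
    def test_growth_saturated_reduces_to_exponential_rate(self):
        # both Monod factors ~1: net rate (k3 - bH) * xB with the in-situ constants
        p = KineticParams(k3_per_pool={"plasticizer": 0.1}, bH=0.005, f_recycle=0.0)
        state = single_pool_state(sS=200.0, sNO3=200.0, xB=1.0)
        assert growth_rate(state, p) == pytest.approx(0.095, rel=1e-3)

    def test_no_nitrate_means_death_only(self):
        p = KineticParams(f_recycle=0.0)
        state = single_pool_state(sNO3=0.0, xB=2.0)
        assert growth_rate(state, p) == pytest.approx(-p.bH * 2.0)

    def test_no_biomass_no_dynamics(self):
        p = KineticParams(f_recycle=0.0)
        state = single_pool_state(xB=0.0)
        assert growth_rate(state, p) == 0.0
        assert all(v == 0.0 for v in substrate_rates(state, p).values())

    def test_consumption_is_growth_over_yield(self):
        p = KineticParams(
            k3_per_pool={"plasticizer": 0.1}, x_yield=0.5, f_recycle=0.0
        )
        state = single_pool_state(sS=200.0, sNO3=200.0, xB=1.0)
        assert substrate_rates(state, p)["plasticizer"] == pytest.approx(-0.2, rel=1e-3)

    def test_pure_recycle_input(self):
        p = KineticParams(
            k3_per_pool={"biomass_derived": 0.02}, bH=0.005, f_recycle=1.0
        )
        state = single_pool_state(sS=0.0, sNO3=1.0, xB=2.0, label="biomass_derived")
        assert substrate_rates(state, p)["biomass_derived"] == pytest.approx(0.01)

    def test_recycle_without_sink_pool_rejected(self):
        p = KineticParams(f_recycle=0.5)
        state = single_pool_state(label="plasticizer")
        with pytest.raises(ConfigurationError):
            substrate_rates(state, p)
        with pytest.raises(ConfigurationError):
            derivatives(state, p)

    @pytest.mark.parametrize(
        "flux, z, expected",
        [(-0.2, 1.0, -0.2), (0.0, 1.0, 0.0), (-0.2, 0.5, -0.1)],
    )
    def test_nitrate_proportional_to_consumption(self, flux, z, expected):
        p = KineticParams(z_nc=z)
        dno3, dn2 = nitrate_rate(flux, p)
        assert dno3 == pytest.approx(expected)
        assert dn2 == pytest.approx(-expected)


class TestDerivatives:
    def test_carbon_and_nitrogen_sums_vanish(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            state, p = random_scenario(rng)
            d = derivatives(state, p)
            carbon = sum(d["sS"].values()) + d["xB"] + d["cumCO2"] + d["xI"]
            assert carbon == pytest.approx(0.0, abs=1e-15)
            assert d["sNO3"] + d["cumN2"] == pytest.approx(0.0, abs=1e-15)

    def test_empty_pools_leave_nitrate_untouched(self):
        p = KineticParams(f_recycle=0.0)
        state = single_pool_state(sS=0.0, xB=0.5)
        d = derivatives(state, p)
        assert d["sNO3"] == 0.0
        assert d["xB"] == pytest.approx(-p.bH * 0.5)

    def test_matches_euler_finite_difference(self):
        """One tiny Euler step of the independent oracle gives the derivative."""
        rng = np.random.default_rng(11)
        state, p = random_scenario(rng)
        h = 1e-7
        rows = euler_trajectory(state, p, [0.0, h], dt=h)
        y0, y1 = np.array(rows[0]), np.array(rows[1])
        fd = (y1 - y0) / h
        d = derivatives(state, p)
        vec = np.array(
            [d["sS"][lab] for lab in state.labels]
            + [d["sNO3"], d["xB"], d["cumN2"], d["cumCO2"], d["xI"]]
        )
        np.testing.assert_allclose(vec, fd, rtol=1e-6, atol=1e-12)


class TestSimulate:
    def test_no_biomass_is_a_fixed_point(self, default_params):
        state = SystemState(
            t=0.0,
            pools=(OrganicsPool("plasticizer", 0.2), OrganicsPool("biomass_derived", 0.0)),
            sNO3=0.1,
            xB=0.0,
        )
        for s in simulate(state, default_params, np.linspace(0, 10, 5)):
            assert s.xB == 0.0
            assert s.sNO3 == 0.1
            assert s.pool("plasticizer").sS == 0.2

    def test_saturated_growth_follows_closed_form(self):
        p = KineticParams(
            k3_per_pool={"plasticizer": 0.1},
            KsS_per_pool={"plasticizer": 1e-6},
            KsNO3=1e-6,
            bH=0.005,
            f_recycle=0.0,
        )
        state = single_pool_state(sS=100.0, sNO3=100.0, xB=0.01)
        t = np.linspace(0, 20, 9)
        traj = simulate(state, p, t)
        expected = 0.01 * np.exp((0.1 - 0.005) * t)
        np.testing.assert_allclose([s.xB for s in traj], expected, rtol=1e-4)

    def test_starvation_decay_is_exponential(self):
        p = KineticParams(k3_per_pool={"plasticizer": 0.1}, bH=0.01, f_recycle=0.0)
        state = single_pool_state(sS=0.5, sNO3=0.0, xB=0.05)
        t = np.linspace(0, 50, 6)
        traj = simulate(state, p, t)
        np.testing.assert_allclose(
            [s.xB for s in traj], 0.05 * np.exp(-0.01 * t), rtol=1e-4
        )

    def test_matches_fixed_step_euler_oracle(self):
        rng = np.random.default_rng(42)
        state, p = random_scenario(rng)
        t = np.linspace(0.0, 20.0, 6)
        traj = simulate(state, p, t, rtol=1e-8, atol=1e-12)
        ours = np.array(
            [[pool.sS for pool in s.pools] + [s.sNO3, s.xB, s.cumN2, s.cumCO2, s.xI] for s in traj]
        )
        ref = np.array(euler_trajectory(state, p, t, dt=1e-4))
        scale = state.total_carbon + state.total_nitrogen
        np.testing.assert_allclose(ours, ref, rtol=1e-3, atol=1e-3 * scale)

    def test_mass_closure_along_random_trajectories(self):
        rng = np.random.default_rng(3)
        rtol = 1e-8
        for _ in range(10):
            state, p = random_scenario(rng)
            traj = simulate(state, p, np.linspace(0, 30, 7), rtol=rtol)
            c0, n0 = state.total_carbon, state.total_nitrogen
            for s in traj:
                assert abs(s.total_carbon - c0) / c0 <= 10 * rtol
                assert abs(s.total_nitrogen - n0) / n0 <= 10 * rtol

    def test_cumulative_pools_monotone_and_pools_nonincreasing(self):
        rng = np.random.default_rng(5)
        state, p = random_scenario(rng)
        p = dataclasses.replace(p, f_recycle=0.0)
        traj = simulate(state, p, np.linspace(0, 30, 31))
        n2 = [s.cumN2 for s in traj]
        co2 = [s.cumCO2 for s in traj]
        assert all(b >= a - 1e-12 for a, b in zip(n2, n2[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(co2, co2[1:]))
        for lab in state.labels:
            series = [s.pool(lab).sS for s in traj]
            assert all(b <= a + 1e-12 for a, b in zip(series, series[1:]))

    def test_faster_donor_is_depleted_first(self):
        """Equal starting concentrations: the pool with larger k3 stays lower."""
        p = KineticParams(
            k3_per_pool={"glucose": 0.3, "humic": 0.05},
            KsS_per_pool={"glucose": 0.01, "humic": 0.01},
            f_recycle=0.0,
        )
        state = SystemState(
            t=0.0,
            pools=(OrganicsPool("glucose", 0.2), OrganicsPool("humic", 0.2)),
            sNO3=0.5,
            xB=0.02,
        )
        for s in simulate(state, p, np.linspace(0, 25, 26))[1:]:
            assert s.pool("glucose").sS <= s.pool("humic").sS

    def test_grid_validation(self, default_params, insitu_state):
        with pytest.raises(InvalidParameterError):
            simulate(insitu_state, default_params, [1.0, 2.0])  # does not start at t0
        with pytest.raises(InvalidParameterError):
            simulate(insitu_state, default_params, [0.0, 2.0, 1.0])  # not increasing

    def test_trajectory_frame_columns(self, default_params, insitu_state):
        traj = simulate(insitu_state, default_params, [0.0, 1.0, 2.0])
        frame = trajectory_frame(traj)
        assert list(frame.columns) == [
            "t", "sS.plasticizer", "sS.biomass_derived", "sNO3", "xB", "cumN2", "cumCO2", "xI",
        ]
        assert len(frame) == 3


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"bH": -0.1},
            {"KsNO3": 0.0},
            {"x_yield": 0.0},
            {"x_yield": 1.5},
            {"f_recycle": -0.1},
            {"z_nc": -1.0},
            {"k3_per_pool": {"humic": -0.1}},
            {"KsS_per_pool": {"humic": 0.0}},
        ],
    )
    def test_parameter_invariants(self, kwargs):
        with pytest.raises(InvalidParameterError):
            KineticParams(**kwargs)

    def test_state_invariants(self):
        with pytest.raises(InvalidParameterError):
            SystemState(t=0, pools=(OrganicsPool("humic", -0.1),), sNO3=0.1, xB=0.1)
        with pytest.raises(InvalidParameterError):
            SystemState(t=0, pools=(), sNO3=-0.1, xB=0.1)
        with pytest.raises(InvalidParameterError):
            SystemState(
                t=0,
                pools=(OrganicsPool("humic", 0.1), OrganicsPool("humic", 0.2)),
                sNO3=0.1,
                xB=0.1,
            )
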