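"""Discrete RBC tracking: kinematics, conservation, determinism, flux."""

import numpy as np
import pytest

from capnet.rheology import RheologyParams, tube_from_discharge_hematocrit
from capnet.solver import BoundaryConditions
from capnet.synthetic import generate_toy
from capnet.transport import (
    SimulationConfig,
    TransportState,
    advance_rbcs,
    simulate,
    steady_plasma_flow,
    update_hematocrit_and_viscosity,
)

from conftest import build_network


def _tube_state(diameter=4.0, length=100.0, dp=5.0, seed=0, **cfg):
    net = generate_toy("single_tube", diameter=diameter, length=length)
    bc = BoundaryConditions({0: 40.0 + dp, 1: 40.0})
    state = TransportState(
        net, bc, RheologyParams(), SimulationConfig(seed=seed, **cfg)
    )
    return net, state


class TestKinematics:
    def test_cell_advances_by_velocity_times_dt(self):
        net, state = _tube_state()
        state.rbc_vessel = np.array([0])
        state.rbc_pos = np.array([50.0])
        state.rbc_at_node = np.array([-1])
        state.rbc_blocked = np.array([False])
        state.counts = np.array([1])
        update_hematocrit_and_viscosity(state)
        v = state.v_rbc[0]  # µm/ms
        advance_rbcs(state, 1.0)
        assert state.rbc_pos[0] == pytest.approx(50.0 + v)

    def test_cell_clamps_at_node_then_exits(self):
        net, state = _tube_state()
        state.rbc_vessel = np.array([0])
        state.rbc_pos = np.array([99.5])
        state.rbc_at_node = np.array([-1])
        state.rbc_blocked = np.array([False])
        state.counts = np.array([1])
        update_hematocrit_and_viscosity(state)
        assert state.v_rbc[0] * 1.0 > 0.5  # would overrun the end node
        advance_rbcs(state, 1.0)
        assert state.rbc_pos[0] == pytest.approx(100.0)  # clamped at node_b
        assert state.rbc_at_node[0] == 1
        advance_rbcs(state, 1.0)  # boundary node: the cell leaves
        assert state.n_rbcs == 0 and state.exited == 1

    def test_tube_hematocrit_arithmetic(self):
        # vessel volume 1000 µm³ with 5 cells of 55 µm³ -> H_t = 0.275
        length = 100.0
        d = float(np.sqrt(4 * 1000.0 / (np.pi * length)))
        net, state = _tube_state(diameter=d, length=length)
        state.rbc_vessel = np.zeros(5, dtype=np.int64)
        state.rbc_pos = np.linspace(10, 90, 5)
        state.rbc_at_node = np.full(5, -1, dtype=np.int64)
        state.rbc_blocked = np.zeros(5, dtype=bool)
        state.counts = np.array([5])
        assert state.tube_hematocrit()[0] == pytest.approx(0.275)

    def test_empty_vessel_plasma_viscosity(self):
        net, state = _tube_state()
        state.seed_rbcs()
        state.rbc_vessel = state.rbc_vessel[:0]
        state.rbc_pos = state.rbc_pos[:0]
        state.rbc_at_node = state.rbc_at_node[:0]
        state.rbc_blocked = state.rbc_blocked[:0]
        state.counts[:] = 0
        update_hematocrit_and_viscosity(state)
        assert state.flow_state.tube_hematocrit[0] == 0.0
        assert state.flow_state.discharge_hematocrit[0] == 0.0

    def test_time_step_too_large_raises_with_bound(self):
        net = generate_toy("single_tube", diameter=10.0, length=30.0)
        bc = BoundaryConditions({0: 90.0, 1: 10.0})
        with pytest.raises(ValueError, match="time_step.*use time_step <="):
            simulate(net, bc, config=SimulationConfig(time_step=5.0, seed=0))


class TestSingleFileRouting:
    def test_routing_operator_picks_largest_pressure_force(self):
        # narrow parent (D < 10 µm): deterministic choice of the daughter
        # with the larger Δp/L at the bifurcation
        net = generate_toy(
            "divergent_Y",
            parent_diameter=5.0,
            daughter_diameters=(4.0, 4.0),
            daughter_lengths=(120.0, 120.0),
        )
        bc = BoundaryConditions({0: 50.0, 2: 10.0, 3: 30.0})  # branch 1 steeper
        state = TransportState(net, bc, RheologyParams(), SimulationConfig(seed=0))
        state.seed_rbcs()
        update_hematocrit_and_viscosity(state)
        out = state._outflows(1)
        assert len(out) == 2
        chosen = state._route_pressure_force(1, out)
        assert chosen[0] == 1  # towards the 10 mmHg outlet: ~3x the force

    def test_cells_overwhelmingly_follow_largest_pressure_force(self):
        # in a running simulation nearly all cells take the steep branch;
        # the only exceptions are overflow routings while the favoured
        # daughter sits at its hematocrit cap
        net = generate_toy(
            "divergent_Y",
            parent_diameter=5.0,
            daughter_diameters=(4.0, 4.0),
            daughter_lengths=(120.0, 120.0),
        )
        bc = BoundaryConditions({0: 50.0, 2: 10.0, 3: 30.0})
        taf = simulate(
            net, bc, config=SimulationConfig(duration=3.0, warm_up=1.0, seed=2)
        )
        f = taf.mean_rbc_flux
        assert f[1] / (f[1] + f[2]) > 0.9  # near-total cell capture
        # whereas the bulk flow split is far less extreme
        assert abs(taf.mean_flow[1]) < 2 * abs(taf.mean_flow[2])


class TestConservationAndDeterminism:
    def test_rbc_bookkeeping_exact(self, two_path_loop):
        bc = BoundaryConditions({0: 45.0, 3: 10.0})
        taf = simulate(
            two_path_loop, bc, config=SimulationConfig(duration=2.0, warm_up=0.5, seed=3)
        )
        d = taf.diagnostics
        assert d["final_count"] == d["initial_count"] + d["injected"] - d["exited"]

    def test_identical_seeds_identical_fields(self, two_path_loop):
        bc = BoundaryConditions({0: 45.0, 3: 10.0})
        cfg = SimulationConfig(duration=2.0, warm_up=0.5, seed=9)
        a = simulate(two_path_loop, bc, config=cfg)
        b = simulate(two_path_loop, bc, config=cfg)
        assert np.array_equal(a.mean_flow, b.mean_flow)
        assert np.array_equal(a.mean_rbc_flux, b.mean_rbc_flux)
        assert np.array_equal(a.mean_discharge_hematocrit, b.mean_discharge_hematocrit)

    def test_distinct_seeds_differ_only_slightly(self, two_path_loop):
        bc = BoundaryConditions({0: 45.0, 3: 10.0})
        a = simulate(two_path_loop, bc, config=SimulationConfig(duration=4.0, warm_up=1.0, seed=1))
        b = simulate(two_path_loop, bc, config=SimulationConfig(duration=4.0, warm_up=1.0, seed=2))
        assert not np.array_equal(a.mean_flow, b.mean_flow)
        assert np.allclose(a.mean_flow, b.mean_flow, rtol=0.2)

    def test_mean_flow_within_instantaneous_envelope(self, two_path_loop):
        bc = BoundaryConditions({0: 45.0, 3: 10.0})
        taf = simulate(two_path_loop, bc, config=SimulationConfig(duration=2.0, warm_up=0.5, seed=5))
        assert np.all(taf.mean_flow >= taf.flow_min - 1e-12)
        assert np.all(taf.mean_flow <= taf.flow_max + 1e-12)


class TestPlasmaAndFluxLimits:
    def test_zero_inflow_hematocrit_is_pure_plasma(self, single_tube):
        bc = BoundaryConditions({0: 45.0, 1: 40.0}, inflow_hematocrit=0.0)
        taf = simulate(single_tube, bc, config=SimulationConfig(duration=1.0, warm_up=0.2, seed=1))
        plasma = steady_plasma_flow(single_tube, BoundaryConditions({0: 45.0, 1: 40.0}))
        assert np.all(taf.mean_rbc_flux == 0.0)
        assert taf.mean_flow[0] == pytest.approx(plasma.mean_flow[0], rel=1e-9)

    def test_counted_flux_matches_flow_times_hematocrit(self):
        """Over a long run the counted cell flux equals time-averaged flow x
        discharge hematocrit / cell volume within 5%.

        A wide loop (many cells per vessel) is used so that hematocrit
        fluctuations are small; cells clamped at a node for one step count
        toward their vessel's hematocrit, which biases the product upward
        by O(dt / transit time), hence the halved time step here.
        """
        loop = generate_toy(
            "two_path_loop",
            inlet_diameter=12.0,
            path_diameters=(8.0, 7.0),
            path_lengths=(320.0, 420.0),
            tube_length=300.0,
        )
        bc = BoundaryConditions({0: 50.0, 3: 10.0})
        taf = simulate(loop, bc, config=SimulationConfig(seed=4, time_step=0.5))
        product = (
            np.abs(taf.mean_flow) * taf.mean_discharge_hematocrit / 55.0 * 1e3
        )
        for v in range(4):
            assert taf.mean_rbc_flux[v] == pytest.approx(product[v], rel=0.05)

    def test_seeding_matches_inflow_hematocrit(self, single_tube):
        bc = BoundaryConditions({0: 45.0, 1: 40.0})
        state = TransportState(
            single_tube, bc, RheologyParams(), SimulationConfig(seed=0)
        )
        state.seed_rbcs()
        expected_ht = tube_from_discharge_hematocrit(0.3, 6.0)
        vol = np.pi * 9.0 * 500.0
        assert state.n_rbcs == pytest.approx(expected_ht * vol / 55.0, abs=1.0)
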