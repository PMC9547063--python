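"""Discrete red blood cell tracking coupled to the pressure solver.

RBCs are tracked as particles moving along vessels at the cell velocity
(bulk velocity times the Fahraeus ratio H_d/H_t — cells travel faster
than bulk blood).  The instantaneous tube hematocrit of each vessel
follows from its current cell count; it feeds the effective viscosity,
which feeds the pressure field, which moves the cells: a two-way coupled
fluctuating system.  The quantity used for all comparisons between
scenarios is the *time-averaged* flow field over a fixed window after a
warm-up.

Routing at nodes:

* convergent node (one outflow): the cell follows the single outflow;
* divergent node, parent wider than the single-file threshold (10 µm):
  the cell is routed stochastically with the empirical phase-separation
  flux fractions (Zweifach–Fung effect);
* divergent node, narrow parent: cells travel in single file and follow
  the path of the largest pressure force, implemented as the largest
  Δp/L toward a candidate daughter;
* boundary node: the cell leaves the domain.

Cells are injected at every inflow boundary vessel as a Poisson stream
with rate flow × inflow hematocrit / RBC volume.  Everything is driven by
one seeded random stream, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import math

from .constants import DEFAULT_RBC_VOLUME
from .network import MicrovascularNetwork
from .rheology import (
    RheologyParams,
    _fahraeus_factor,
    discharge_hematocrit,
    phase_separation,
    relative_effective_viscosity,
    tube_from_discharge_hematocrit,
)
from .solver import BoundaryConditions, FlowState, compute_resistances, solve_pressures

def _phase_separation_scalar(df, hd, fqb, da, db):
    """Scalar fast path of :func:`capnet.rheology.phase_separation`."""
    hd = min(hd, 0.99)
    x0 = min(0.964 * (1.0 - hd) / df, 0.499)
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    b = 1.0 + 6.98 * (1.0 - hd) / df
    ratio2 = (da / db) ** 2
    a = -13.29 * ((ratio2 - 1.0) / (ratio2 + 1.0)) * (1.0 - hd) / df
    inner = (fqb - x0) / (1.0 - 2.0 * x0)
    inner = min(max(inner, 1e-15), 1.0 - 1e-15)
    logit = a + b * math.log(inner / (1.0 - inner))
    return 1.0 / (1.0 + math.exp(-logit))


__all__ = [
    "SimulationConfig",
    "TimeAveragedFlow",
    "TransportState",
    "simulate",
    "advance_rbcs",
    "update_hematocrit_and_viscosity",
    "steady_plasma_flow",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Discrete RBC simulation settings.

    duration : s — averaging window for the time-averaged flow field
        (default 15.4 s).
    warm_up : s — run before averaging starts so the cell distribution
        forgets its initial seeding; the default (5 s) is several network
        transit times for desk-scale networks.
    time_step : ms — cells move well under one segment length per step at
        the default; an error is raised if the first flow field implies a
        cell could jump a whole vessel in one step.
    coupling_interval : steps between hematocrit/viscosity/pressure
        updates (two-way coupling).
    """

    duration: float = 15.4  # s
    time_step: float = 1.0  # ms
    warm_up: float = 5.0  # s
    rbc_volume: float = DEFAULT_RBC_VOLUME  # µm³
    inflow_hematocrit: float | None = None  # None: use the boundary-condition value
    seed: int = 0
    coupling_interval: int = 10
    max_tube_hematocrit: float = 0.5

    def __post_init__(self):
        if self.duration <= 0 or self.time_step <= 0 or self.warm_up < 0:
            raise ValueError("duration and time_step must be > 0, warm_up >= 0")
        if self.inflow_hematocrit is not None and not 0 <= self.inflow_hematocrit <= 1:
            raise ValueError("inflow_hematocrit must lie in [0, 1]")
        if self.coupling_interval < 1:
            raise ValueError("coupling_interval must be >= 1")


@dataclass
class TimeAveragedFlow:
    """Per-vessel flow field averaged over the simulation window.

    mean_flow is signed (positive = node_a -> node_b), µm³/ms;
    mean_rbc_flux counts actual cell departures per vessel, RBCs/s;
    flow_min/flow_max bracket the instantaneous flows seen in the window.
    """

    mean_flow: np.ndarray
    mean_rbc_flux: np.ndarray
    mean_discharge_hematocrit: np.ndarray
    window: float  # s
    flow_min: np.ndarray = None  # type: ignore[assignment]
    flow_max: np.ndarray = None  # type: ignore[assignment]
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be > 0")


class TransportState:
    """Mutable state of a running RBC-tracking simulation."""

    def __init__(self, net: MicrovascularNetwork, bc: BoundaryConditions,
                 rheology: RheologyParams, config: SimulationConfig):
        self.net = net
        self.bc = bc
        self.rheology = rheology
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.h_in = (
            config.inflow_hematocrit
            if config.inflow_hematocrit is not None
            else bc.inflow_hematocrit
        )

        self.area = np.pi * net.diameter**2 / 4.0  # µm²
        self.volume = self.area * net.length  # µm³
        self.inv_f = 1.0 / _fahraeus_factor(net.diameter)  # dilute Fahraeus ratio

        # cell arrays
        self.rbc_vessel = np.empty(0, dtype=np.int64)
        self.rbc_pos = np.empty(0, dtype=np.float64)  # µm from node_a
        self.rbc_at_node = np.empty(0, dtype=np.int64)  # node index or -1
        # cells whose node has no admissible outflow wait; they are only
        # re-tried when the flow field is next updated
        self.rbc_blocked = np.empty(0, dtype=bool)

        self.flow_state: FlowState | None = None
        self.v_rbc = np.zeros(net.n_vessels)  # signed cell velocity, µm/ms
        self.injected = 0
        self.exited = 0
        self.initial_count = 0
        self.jam_steps = 0

        # accumulators (filled during the averaging window)
        m = net.n_vessels
        self.acc_flow = np.zeros(m)
        self.acc_hd = np.zeros(m)
        self.exit_counts = np.zeros(m, dtype=np.int64)
        self.acc_steps = 0
        self.flow_min = np.full(m, np.inf)
        self.flow_max = np.full(m, -np.inf)

        self._inflow_cache = None
        self._outflow_cache = {}
        self._solver_cache = {}
        self.inject_acc = np.zeros(net.n_vessels)
        # one random stream per divergent bifurcation: comparisons between
        # scenarios then share identical draw sequences wherever the local
        # arrival history is unchanged (paired realizations)
        self._node_rngs = {}
        # cell capacity per vessel (hematocrit cap); cells are not routed
        # into, or injected into, a vessel that is already at capacity
        self.capacity = np.maximum(
            np.floor(config.max_tube_hematocrit * self.volume / config.rbc_volume),
            1,
        ).astype(np.int64)
        self.counts = np.zeros(net.n_vessels, dtype=np.int64)

    # -- seeding ---------------------------------------------------------
    def seed_rbcs(self):
        """Populate vessels at the tube hematocrit matching the inflow
        discharge hematocrit (cells placed uniformly along each vessel)."""
        net, cfg = self.net, self.config
        ht = tube_from_discharge_hematocrit(
            np.full(net.n_vessels, self.h_in), net.diameter
        )
        lam = ht * self.volume / cfg.rbc_volume
        counts = np.floor(lam).astype(np.int64)
        counts += self.rng.random(net.n_vessels) < (lam - counts)
        vessels = np.repeat(np.arange(net.n_vessels), counts)
        pos = self.rng.random(len(vessels)) * net.length[vessels]
        self.rbc_vessel = vessels
        self.rbc_pos = pos
        self.rbc_at_node = np.full(len(vessels), -1, dtype=np.int64)
        self.rbc_blocked = np.zeros(len(vessels), dtype=bool)
        self.initial_count = len(vessels)
        self.counts = np.bincount(vessels, minlength=net.n_vessels).astype(np.int64)

    @property
    def n_rbcs(self) -> int:
        return len(self.rbc_vessel)

    def tube_hematocrit(self) -> np.ndarray:
        ht = self.counts * self.config.rbc_volume / self.volume
        over = ht > self.config.max_tube_hematocrit
        if over.any():
            self.jam_steps += 1
        return np.minimum(ht, self.config.max_tube_hematocrit)

    # -- field update (two-way coupling) ----------------------------------
    def update_field(self):
        net = self.net
        ht = self.tube_hematocrit()
        hd = discharge_hematocrit(ht, net.diameter)
        mu_rel = relative_effective_viscosity(net.diameter, hd, self.rheology)
        res = compute_resistances(net, mu_rel, self.rheology.plasma_viscosity)
        state = solve_pressures(net, res, self.bc, cache=self._solver_cache)
        state.tube_hematocrit = ht
        state.discharge_hematocrit = hd
        state.rbc_flux = (
            np.abs(state.flows) * hd / self.config.rbc_volume * 1e3
        )  # RBCs/s
        self.flow_state = state
        v_bulk = state.flows / self.area  # µm/ms, signed
        ratio = np.where(ht > 0, hd / np.where(ht > 0, ht, 1.0), self.inv_f)
        self.v_rbc = v_bulk * ratio
        self._inflow_cache = None  # inflow vessels depend on flow signs
        self._outflow_cache.clear()
        if len(self.rbc_blocked):
            self.rbc_blocked[:] = False

    def check_time_step(self):
        step_travel = np.abs(self.v_rbc) * self.config.time_step
        too_far = step_travel > self.net.length
        if too_far.any():
            worst = int(np.argmax(step_travel / self.net.length))
            bound = float(self.net.length[worst] / np.abs(self.v_rbc[worst]))
            raise ValueError(
                f"time_step {self.config.time_step} ms too large: an RBC "
                f"would jump vessel id {self.net.vessel_ids[worst]} in one "
                f"step; use time_step <= {bound:.3g} ms"
            )

    # -- routing ----------------------------------------------------------
    def _outflows(self, node: int):
        """(vessel, enters_at_a) pairs whose flow leaves ``node``; cached
        per flow-field epoch."""
        out = self._outflow_cache.get(node)
        if out is None:
            q = self.flow_state.flows
            out = []
            for v, _ in self.net.incidence()[node]:
                if int(self.net.node_a[v]) == node and q[v] > 0:
                    out.append((v, True))
                elif int(self.net.node_b[v]) == node and q[v] < 0:
                    out.append((v, False))
            self._outflow_cache[node] = out
        return out

    def _route_one(self, i):
        """Route cell i waiting at a node; returns False if it exits."""
        node = int(self.rbc_at_node[i])
        net = self.net
        parent = int(self.rbc_vessel[i])
        if net.is_boundary[node]:
            self.exit_counts[parent] += self._averaging
            self.exited += 1
            self.counts[parent] -= 1
            return False
        out = [c for c in self._outflows(node) if self.counts[c[0]] < self.capacity[c[0]]]
        if not out:
            self.rbc_blocked[i] = True  # re-tried after the next field update
            return True
        if len(out) == 1:
            choice = out[0]
        elif net.diameter[parent] > self.rheology.single_file_diameter_threshold:
            choice = self._route_empirical(parent, out, node)
        else:
            choice = self._route_pressure_force(node, out)
        self.exit_counts[parent] += self._averaging
        v, enters_at_a = choice
        self.counts[parent] -= 1
        self.counts[v] += 1
        self.rbc_vessel[i] = v
        self.rbc_pos[i] = 0.0 if enters_at_a else net.length[v]
        self.rbc_at_node[i] = -1
        return True

    def _node_rng(self, node):
        rng = self._node_rngs.get(node)
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence((self.config.seed, int(node)))
            )
            self._node_rngs[node] = rng
        return rng

    def _route_empirical(self, parent, out, node):
        """Stochastic routing by the phase-separation law; 3+ outflows are
        reduced to sequential binary splits ordered by flow."""
        rng = self._node_rng(node)
        q = self.flow_state.flows
        hd_parent = float(self.flow_state.discharge_hematocrit[parent])
        d_parent = float(self.net.diameter[parent])
        order = sorted(out, key=lambda c: -abs(q[c[0]]))
        while len(order) > 1:
            top = order[0]
            rest = order[1:]
            q_top = abs(q[top[0]])
            q_rest = sum(abs(q[v]) for v, _ in rest)
            total = q_top + q_rest
            frac = q_top / total if total > 0 else 0.5
            d_top = float(self.net.diameter[top[0]])
            d_rest = math.sqrt(
                sum(self.net.diameter[v] ** 2 for v, _ in rest) / len(rest)
            )
            p_top = _phase_separation_scalar(d_parent, hd_parent, frac, d_top, d_rest)
            if rng.random() < p_top:
                return top
            order = rest
        return order[0]

    def _route_pressure_force(self, node, out):
        """Single-file rule: largest pressure force = largest Δp/L."""
        p = self.flow_state.pressures
        best, best_force = None, -np.inf
        for v, enters_at_a in out:
            other = int(self.net.node_b[v]) if enters_at_a else int(self.net.node_a[v])
            force = (p[node] - p[other]) / self.net.length[v]
            if force > best_force or (force == best_force and best is not None and v < best[0]):
                best, best_force = (v, enters_at_a), force
        return best

    # -- kinematics --------------------------------------------------------
    def advance(self, dt: float):
        """One time step: route waiting cells, move all cells, clamp at nodes."""
        # route cells that reached a node last step (blocked cells wait for
        # the next field update)
        pending = self.rbc_at_node >= 0
        if pending.any():
            todo = np.flatnonzero(pending & ~self.rbc_blocked)
            if len(todo):
                keep = np.ones(self.n_rbcs, dtype=bool)
                removed = False
                dead_nodes = set()  # nodes found blocked this round
                for i in todo:
                    node = int(self.rbc_at_node[i])
                    if node in dead_nodes:
                        self.rbc_blocked[i] = True
                        continue
                    if not self._route_one(int(i)):
                        keep[i] = False
                        removed = True
                    elif self.rbc_blocked[i]:
                        dead_nodes.add(node)
                if removed:
                    self.rbc_vessel = self.rbc_vessel[keep]
                    self.rbc_pos = self.rbc_pos[keep]
                    self.rbc_at_node = self.rbc_at_node[keep]
                    self.rbc_blocked = self.rbc_blocked[keep]

        if self.n_rbcs:
            moving = self.rbc_at_node < 0
            v = self.v_rbc[self.rbc_vessel]
            self.rbc_pos = np.where(moving, self.rbc_pos + v * dt, self.rbc_pos)
            # clamp at nodes (cells stop at the bifurcation, routed next step)
            length = self.net.length[self.rbc_vessel]
            hit_a = moving & (self.rbc_pos <= 0.0)
            hit_b = moving & (self.rbc_pos >= length)
            self.rbc_pos = np.clip(self.rbc_pos, 0.0, length)
            if hit_a.any():
                self.rbc_at_node[hit_a] = self.net.node_a[self.rbc_vessel[hit_a]]
            if hit_b.any():
                self.rbc_at_node[hit_b] = self.net.node_b[self.rbc_vessel[hit_b]]

    # -- injection ----------------------------------------------------------
    def _inflow_vessels(self):
        """Boundary-node outflow vessels (flow entering the network), as
        (vessel array, enters-at-a array, injection rates per ms)."""
        if self._inflow_cache is None:
            net, q = self.net, self.flow_state.flows
            in_a = net.is_boundary[net.node_a] & (q > 0)
            in_b = net.is_boundary[net.node_b] & (q < 0)
            vess = np.concatenate([np.flatnonzero(in_a), np.flatnonzero(in_b)])
            at_a = np.concatenate(
                [np.ones(in_a.sum(), dtype=bool), np.zeros(in_b.sum(), dtype=bool)]
            )
            rates = np.abs(q[vess]) * self.h_in / self.config.rbc_volume
            self._inflow_cache = (vess, at_a, rates)
        return self._inflow_cache

    def inject(self, dt: float):
        """Regularly spaced arrivals at every inflow boundary vessel at the
        inflow hematocrit (cells enter a feeding vessel at a steady rate,
        so arrival spacing is deterministic: an accumulator per vessel
        releases a cell whenever flow x H_in x dt adds up to one cell
        volume).  Vessels already at their hematocrit cap accept no new
        cells."""
        vess, at_a, rates = self._inflow_vessels()
        if len(vess) == 0:
            return
        self.inject_acc[vess] += rates * dt
        n_new = np.floor(self.inject_acc[vess]).astype(np.int64)
        self.inject_acc[vess] -= n_new
        room = self.capacity[vess] - self.counts[vess]
        n_new = np.minimum(n_new, np.maximum(room, 0))
        total = int(n_new.sum())
        if total == 0:
            return
        v_arr = np.repeat(vess, n_new)
        a_arr = np.repeat(at_a, n_new)
        # stagger multiple arrivals evenly within the step
        if n_new.max() == 1:
            offsets = np.full(total, 0.5)
        else:
            offsets = np.concatenate(
                [(np.arange(k) + 0.5) / k for k in n_new if k > 0]
            )
        travel = np.minimum(
            np.abs(self.v_rbc[v_arr]) * dt * offsets, self.net.length[v_arr]
        )
        pos = np.where(a_arr, travel, self.net.length[v_arr] - travel)
        self.rbc_vessel = np.concatenate([self.rbc_vessel, v_arr])
        self.rbc_pos = np.concatenate([self.rbc_pos, pos])
        self.rbc_at_node = np.concatenate(
            [self.rbc_at_node, np.full(total, -1, dtype=np.int64)]
        )
        self.rbc_blocked = np.concatenate(
            [self.rbc_blocked, np.zeros(total, dtype=bool)]
        )
        np.add.at(self.counts, v_arr, 1)
        self.injected += total

    # -- accumulation --------------------------------------------------------
    _averaging = 0  # 1 while inside the averaging window

    def accumulate(self):
        q = self.flow_state.flows
        self.acc_flow += q
        self.acc_hd += self.flow_state.discharge_hematocrit
        self.acc_steps += 1
        np.minimum(self.flow_min, q, out=self.flow_min)
        np.maximum(self.flow_max, q, out=self.flow_max)


def advance_rbcs(state: TransportState, dt: float) -> TransportState:
    """Move every cell by v_rbc·dt and route cells that reach a node."""
    state.advance(dt)
    return state


def update_hematocrit_and_viscosity(state: TransportState) -> TransportState:
    """Recompute tube/discharge hematocrit, viscosity, pressures and flows."""
    state.update_field()
    return state


def simulate(
    net: MicrovascularNetwork,
    bc: BoundaryConditions,
    rheology: RheologyParams | None = None,
    config: SimulationConfig | None = None,
) -> TimeAveragedFlow:
    """Run a discrete RBC-tracking simulation; return the time-averaged field.

    Deterministic for a fixed ``config.seed``.  The averaging window of
    ``config.duration`` seconds starts after ``config.warm_up`` seconds.
    """
    rheology = rheology or RheologyParams()
    config = config or SimulationConfig()
    state = TransportState(net, bc, rheology, config)
    state.seed_rbcs()
    state.update_field()
    state.check_time_step()

    dt = config.time_step
    n_warm = int(round(config.warm_up * 1e3 / dt))
    n_avg = int(round(config.duration * 1e3 / dt))
    for step in range(n_warm + n_avg):
        state._averaging = 1 if step >= n_warm else 0
        if step > 0 and step % config.coupling_interval == 0:
            state.update_field()
        state.advance(dt)
        state.inject(dt)
        if state._averaging:
            state.accumulate()

    assert state.n_rbcs == state.initial_count + state.injected - state.exited, (
        "RBC bookkeeping violated"
    )
    mean_flow = state.acc_flow / state.acc_steps
    mean_hd = state.acc_hd / state.acc_steps
    flux = state.exit_counts / config.duration  # RBCs/s
    return TimeAveragedFlow(
        mean_flow=mean_flow,
        mean_rbc_flux=flux,
        mean_discharge_hematocrit=mean_hd,
        window=config.duration,
        flow_min=state.flow_min,
        flow_max=state.flow_max,
        diagnostics={
            "initial_count": state.initial_count,
            "injected": state.injected,
            "exited": state.exited,
            "final_count": state.n_rbcs,
            "jam_steps": state.jam_steps,
            "averaged_steps": state.acc_steps,
        },
    )


def steady_plasma_flow(
    net: MicrovascularNetwork,
    bc: BoundaryConditions,
    rheology: RheologyParams | None = None,
    window: float = 15.4,
) -> TimeAveragedFlow:
    """Pure-plasma steady field wrapped as a TimeAveragedFlow.

    With no cells the coupled system is steady, so the time average equals
    the single Poiseuille solve; useful as a cheap baseline for graph
    analyses that only need flow directions and magnitudes.
    """
    rheology = rheology or RheologyParams()
    mu_rel = np.ones(net.n_vessels)
    res = compute_resistances(net, mu_rel, rheology.plasma_viscosity)
    st = solve_pressures(net, res, bc)
    zeros = np.zeros(net.n_vessels)
    return TimeAveragedFlow(
        mean_flow=st.flows.copy(),
        mean_rbc_flux=zeros.copy(),
        mean_discharge_hematocrit=zeros.copy(),
        window=window,
        flow_min=st.flows.copy(),
        flow_max=st.flows.copy(),
        diagnostics={"plasma": True},
    )
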