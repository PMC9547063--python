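"""Steady Poiseuille pressure/flow solver on the vascular graph.

Reynolds numbers in the microvasculature are below 1, so flow in each
vessel is laminar Stokes flow and obeys Poiseuille's law,

    q_ij = (p_i - p_j) / R_ij,   R_ij = 128 L_ij µ µ_rel / (π D_ij⁴),

with an effective resistance that carries the hematocrit- and
diameter-dependent relative viscosity.  Mass conservation at every
interior node then yields a sparse symmetric positive-definite linear
system for the nodal pressures, with Dirichlet pressures at boundary
nodes.  Units: pressure mmHg, flow µm³/ms, geometry µm, viscosity Pa·s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import (
    ARTERIAL_TYPES,
    BLOOD_DENSITY,
    RESISTANCE_UNIT,
    VENOUS_TYPES,
)
from .network import MicrovascularNetwork

__all__ = [
    "BoundaryConditions",
    "FlowState",
    "compute_resistances",
    "solve_pressures",
    "assign_default_boundary_pressures",
    "reynolds_numbers",
]

#: interior-node flow balance is asserted to this relative tolerance
BALANCE_RTOL = 1e-10

#: above this many free nodes the solver switches to conjugate gradients
ITERATIVE_THRESHOLD = 200_000


@dataclass
class BoundaryConditions:
    """Dirichlet pressures at boundary nodes.

    pressure_nodes maps *node id* -> pressure in mmHg.  Every boundary
    node must carry exactly one condition; there must be at least one
    high-pressure (inflow) and one lower-pressure (outflow) node for a
    non-trivial flow field.
    """

    pressure_nodes: dict
    inflow_hematocrit: float = 0.3

    def __post_init__(self):
        if not 0 <= self.inflow_hematocrit <= 1:
            raise ValueError("inflow_hematocrit must lie in [0, 1]")
        if not self.pressure_nodes:
            raise ValueError("no pressure boundary conditions given")


@dataclass
class FlowState:
    """Instantaneous hemodynamic state of a network.

    pressures: per-node, mmHg.  flows: per-vessel signed flow rate in
    µm³/ms, positive when directed node_a -> node_b.  Hematocrits are
    fractions; rbc_flux is RBCs/s.
    """

    pressures: np.ndarray
    flows: np.ndarray
    tube_hematocrit: np.ndarray = field(default=None)  # type: ignore[assignment]
    discharge_hematocrit: np.ndarray = field(default=None)  # type: ignore[assignment]
    rbc_flux: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        m = len(self.flows)
        if self.tube_hematocrit is None:
            self.tube_hematocrit = np.zeros(m)
        if self.discharge_hematocrit is None:
            self.discharge_hematocrit = np.zeros(m)
        if self.rbc_flux is None:
            self.rbc_flux = np.zeros(m)


def compute_resistances(net: MicrovascularNetwork, viscosity_field, plasma_viscosity):
    """Per-vessel effective Poiseuille resistance, mmHg·ms/µm³.

    ``viscosity_field`` is the per-vessel relative effective viscosity
    µ_rel (dimensionless, >= 1); ``plasma_viscosity`` is µ in Pa·s.
    """
    mu_rel = np.asarray(viscosity_field, dtype=np.float64)
    if np.any(mu_rel <= 0):
        raise ValueError("relative viscosity must be > 0")
    r = (
        128.0
        * net.length
        * plasma_viscosity
        * mu_rel
        / (np.pi * net.diameter**4)
        * RESISTANCE_UNIT
    )
    return r


def _fixed_pressures(net: MicrovascularNetwork, bc: BoundaryConditions):
    id_to_idx = {int(i): k for k, i in enumerate(net.node_ids)}
    fixed_idx = []
    fixed_p = []
    for nid, p in bc.pressure_nodes.items():
        if int(nid) not in id_to_idx:
            raise KeyError(f"boundary condition on unknown node id {nid}")
        fixed_idx.append(id_to_idx[int(nid)])
        fixed_p.append(float(p))
    return np.asarray(fixed_idx, dtype=np.int64), np.asarray(fixed_p)


def solve_pressures(
    net: MicrovascularNetwork, resistances, bc: BoundaryConditions, cache: dict | None = None
) -> FlowState:
    """Solve nodal pressures and vessel flows for fixed boundary pressures.

    Raises if any connected component carries no pressure condition (the
    system would be singular there).  Interior-node flow balance is checked
    after every solve to ``BALANCE_RTOL`` (node-local relative).  When the
    same network/boundary pair is solved repeatedly with updated
    viscosities, pass a ``cache`` dict to reuse the static index work.
    """
    r = np.asarray(resistances, dtype=np.float64)
    g = 1.0 / r
    n = net.n_nodes
    if cache is not None and "fixed" in cache:
        fixed_idx, fixed_p, is_fixed = cache["fixed"]
    else:
        fixed_idx, fixed_p = _fixed_pressures(net, bc)
        is_fixed = np.zeros(n, dtype=bool)
        is_fixed[fixed_idx] = True
        if cache is not None:
            cache["fixed"] = (fixed_idx, fixed_p, is_fixed)

    a, b = net.node_a, net.node_b
    # weighted graph Laplacian
    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([a, b, b, a])
    vals = np.concatenate([g, g, -g, -g])
    lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    free = np.flatnonzero(~is_fixed)
    if free.size:
        if cache is None or not cache.get("components_checked"):
            _check_components_have_bc(net, is_fixed)
            if cache is not None:
                cache["components_checked"] = True
        p_full = np.zeros(n)
        p_full[fixed_idx] = fixed_p
        rhs = -lap[free][:, fixed_idx] @ fixed_p
        a_ff = lap[free][:, free].tocsc()
        if free.size <= ITERATIVE_THRESHOLD:
            lu = spla.splu(a_ff)
            p_free = lu.solve(rhs)
            # iterative refinement: conductances span ~6 orders of
            # magnitude, and node balance is asserted to 1e-10 relative
            scale = np.abs(g * (np.abs(fixed_p).max() if fixed_p.size else 1.0)).mean()
            for _ in range(5):
                resid = rhs - a_ff @ p_free
                if np.abs(resid).max() <= 1e-13 * max(scale, 1e-300):
                    break
                p_free = p_free + lu.solve(resid)
        else:
            ml = spla.spilu(a_ff, drop_tol=1e-5)
            prec = spla.LinearOperator(a_ff.shape, ml.solve)
            p_free, info = spla.cg(a_ff, rhs, rtol=1e-12, M=prec)
            if info != 0:
                raise RuntimeError(f"iterative pressure solve failed (info={info})")
        p_full[free] = p_free
    else:
        p_full = np.zeros(n)
        p_full[fixed_idx] = fixed_p

    flows = g * (p_full[a] - p_full[b])
    p_range = float(p_full.max() - p_full.min()) if n else 0.0
    if p_range > 1e-12 * max(abs(p_full).max(), 1.0):
        _assert_balance(net, flows, is_fixed)
    return FlowState(pressures=p_full, flows=flows)


def _check_components_have_bc(net, is_fixed):
    seen = np.zeros(net.n_nodes, dtype=bool)
    inc = net.incidence()
    for start in range(net.n_nodes):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = [start]
        has_bc = bool(is_fixed[start])
        while stack:
            u = stack.pop()
            for _, v in inc[u]:
                if not seen[v]:
                    seen[v] = True
                    has_bc = has_bc or bool(is_fixed[v])
                    comp.append(v)
                    stack.append(v)
        if not has_bc:
            ids = sorted(int(net.node_ids[k]) for k in comp[:5])
            raise ValueError(
                f"singular system: component containing node ids {ids} has no "
                "pressure boundary condition"
            )


def _node_imbalance(net, flows, is_fixed):
    """Per-interior-node |Σ signed flows| / Σ |incident flows| (the
    node-local relative conservation error)."""
    n = net.n_nodes
    net_in = np.zeros(n)
    np.subtract.at(net_in, net.node_a, flows)
    np.add.at(net_in, net.node_b, flows)
    thru = np.zeros(n)
    np.add.at(thru, net.node_a, np.abs(flows))
    np.add.at(thru, net.node_b, np.abs(flows))
    interior = ~is_fixed
    # scale by the local throughflow, floored at the network-mean |flow| so
    # that dead-end nodes (zero throughflow) do not divide by round-off
    floor = max(float(np.abs(flows).mean()), 1e-300)
    denom = np.maximum(thru[interior], floor)
    return np.abs(net_in[interior]) / denom


def _assert_balance(net, flows, is_fixed):
    if not (~is_fixed).any():
        return
    worst = _node_imbalance(net, flows, is_fixed).max() if (~is_fixed).any() else 0.0
    if worst > BALANCE_RTOL:
        raise RuntimeError(
            f"flow conservation violated: max interior imbalance {worst:.3e} "
            f"(relative to local throughflow) exceeds {BALANCE_RTOL:.0e}"
        )


def interior_imbalance(net: MicrovascularNetwork, flows, bc: BoundaryConditions):
    """Max node-local relative conservation error over interior nodes."""
    fixed_idx, _ = _fixed_pressures(net, bc)
    is_fixed = np.zeros(net.n_nodes, dtype=bool)
    is_fixed[fixed_idx] = True
    if not (~is_fixed).any():
        return 0.0
    rel = _node_imbalance(net, flows, is_fixed)
    return float(rel.max()) if rel.size else 0.0


def reynolds_numbers(net: MicrovascularNetwork, flows, mu_rel, plasma_viscosity):
    """Per-vessel Reynolds number; warns if any exceeds 1 (Stokes regime)."""
    area = np.pi * net.diameter**2 / 4.0  # µm²
    v = np.abs(flows) / area  # µm/ms == mm/s
    re = (
        BLOOD_DENSITY
        * (v * 1e-3)
        * (net.diameter * 1e-6)
        / (plasma_viscosity * np.asarray(mu_rel))
    )
    if np.any(re > 1.0):
        warnings.warn(
            f"{int((re > 1.0).sum())} vessel(s) above Re = 1; Poiseuille "
            "assumption questionable",
            stacklevel=2,
        )
    return re


def assign_default_boundary_pressures(
    net: MicrovascularNetwork, p_arterial: float = 60.0, p_venous: float = 10.0
) -> BoundaryConditions:
    """Default Dirichlet pressures for all flagged boundary nodes.

    Boundary nodes incident to an arterial-side vessel (pial artery or
    descending arteriole) receive ``p_arterial``; venous-side nodes
    (pial vein / ascending venule) receive ``p_venous``.  Capillary-side
    boundary nodes are interpolated between the two levels by relative
    topological distance to the arteriole and venule trees:
    p = p_ven + (p_art - p_ven) · d_ven/(d_art+d_ven), where d_art/d_ven
    are BFS hop counts to the nearest node of an arterial-/venous-typed
    vessel.  This mimics the pressure a cut capillary would see given how
    far along the arteriole-to-venule path the cut sits.  The levels are
    config-exposed defaults; all downstream comparisons are relative
    (dilated vs baseline), so only the overall perfusion scale depends on
    them.
    """
    if not net.is_boundary.any():
        raise ValueError("network has no boundary nodes")
    arterial_nodes, venous_nodes = set(), set()
    arterial_boundary, venous_boundary = set(), set()
    for v in range(net.n_vessels):
        t = net.vessel_type[v]
        for nidx in (int(net.node_a[v]), int(net.node_b[v])):
            if t in ARTERIAL_TYPES:
                arterial_nodes.add(nidx)
                if net.is_boundary[nidx]:
                    arterial_boundary.add(nidx)
            elif t in VENOUS_TYPES:
                venous_nodes.add(nidx)
                if net.is_boundary[nidx]:
                    venous_boundary.add(nidx)

    d_art = _hop_distances(net, arterial_nodes)
    d_ven = _hop_distances(net, venous_nodes)
    arterial_nodes, venous_nodes = arterial_boundary, venous_boundary

    pressures = {}
    for nidx in np.flatnonzero(net.is_boundary):
        nidx = int(nidx)
        if nidx in arterial_nodes:
            p = p_arterial
        elif nidx in venous_nodes:
            p = p_venous
        else:
            da, dv = d_art[nidx], d_ven[nidx]
            if np.isinf(da) and np.isinf(dv):
                frac = 0.5
            elif np.isinf(da):
                frac = 0.0
            elif np.isinf(dv):
                frac = 1.0
            else:
                frac = dv / (da + dv)
            p = p_venous + (p_arterial - p_venous) * frac
        pressures[int(net.node_ids[nidx])] = float(p)
    return BoundaryConditions(pressure_nodes=pressures)


def _hop_distances(net, sources):
    from collections import deque

    dist = np.full(net.n_nodes, np.inf)
    q = deque()
    for s in sources:
        dist[s] = 0.0
        q.append(s)
    inc = net.incidence()
    while q:
        u = q.popleft()
        for _, v in inc[u]:
            if np.isinf(dist[v]):
                dist[v] = dist[u] + 1.0
                q.append(v)
    return dist
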