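"""In silico focal pericyte-ablation protocol.

Pericyte loss is modelled purely geometrically: a contiguous set of
capillaries around a chosen "base capillary" is dilated by a fixed
increment (0.6 µm — the average response to pericyte ablation in adult
mice; 1.1 µm — the average in aged mice; 1.6 µm — the extreme aged
response).  This module selects eligible base capillaries, grows the
affected capillary set the way the in vivo ablations spread (outward from
the upstream bifurcation, then the downstream one, until at least 13
capillaries are in the set), and applies the dilation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MicrovascularNetwork
from .transport import TimeAveragedFlow

__all__ = [
    "SelectionCriteria",
    "AblationScenario",
    "select_base_capillaries",
    "build_affected_set",
    "apply_dilation",
    "dilate_vessels",
    "sample_base_capillaries",
    "DILATION_INCREMENTS",
]

#: dilation scenarios, µm: adult average, aged average, aged extreme
DILATION_INCREMENTS = (0.6, 1.1, 1.6)


@dataclass(frozen=True)
class SelectionCriteria:
    """Eligibility rules for a base capillary.

    The base must sit at a cortical depth of 20–120 µm, beyond four branch
    orders from the penetrating-arteriole main branch (0th order), beyond
    one branch from the ascending-venule main branch, at least two
    branches from the simulation-domain boundary, and closer than
    ``max_center_distance_factor`` times the mean x-y distance of all
    vessels to the network centre (the last two keep the dilated region
    away from the pressure boundary conditions).
    """

    depth_range: tuple = (20.0, 120.0)  # µm
    min_arteriole_branch_order: int = 5  # "beyond four branch orders"
    min_venule_branch_order: int = 2  # "beyond one branch"
    min_branches_from_boundary: int = 2
    max_center_distance_factor: float = 0.9

    def __post_init__(self):
        if self.depth_range[0] >= self.depth_range[1]:
            raise ValueError("depth_range must be ordered")
        if min(
            self.min_arteriole_branch_order,
            self.min_venule_branch_order,
            self.min_branches_from_boundary,
        ) < 0 or self.max_center_distance_factor <= 0:
            raise ValueError("criteria thresholds must be positive")


@dataclass
class AblationScenario:
    """One in silico ablation: a base capillary, its affected set, and the
    diameter increment applied to every member."""

    base_capillary: int  # vessel index
    affected_set: list  # ordered vessel indices, target size 13-15
    dilation_increment: float  # µm

    def validate(self, net: MicrovascularNetwork):
        if self.base_capillary not in self.affected_set:
            raise ValueError("affected_set must contain the base capillary")
        if len(self.affected_set) < 13:
            raise ValueError("affected_set must contain at least 13 capillaries")
        for v in self.affected_set:
            if net.vessel_type[v] != "capillary":
                raise ValueError(
                    f"affected vessel id {net.vessel_ids[v]} is not a capillary"
                )


def _require_orders(net):
    if (net.branch_order_art < 0).all() or (net.branch_order_ven < 0).all():
        raise ValueError(
            "branch orders unset; call assign_branch_orders() first"
        )


def select_base_capillaries(
    net: MicrovascularNetwork, criteria: SelectionCriteria | None = None
) -> np.ndarray:
    """Vessel indices of all capillaries satisfying the selection criteria.

    Deterministic and seed-free; an empty result is allowed.
    """
    c = criteria or SelectionCriteria()
    _require_orders(net)
    mid = net.midpoints()
    depth = mid[:, 2]
    bdist = net.boundary_branch_distance()

    xy = mid[:, :2]
    center_xy = xy.mean(axis=0)
    dxy = np.linalg.norm(xy - center_xy, axis=1)
    max_dxy = c.max_center_distance_factor * dxy.mean()

    ok = (
        (net.vessel_type == "capillary")
        & (depth >= c.depth_range[0])
        & (depth <= c.depth_range[1])
        & (net.branch_order_art >= c.min_arteriole_branch_order)
        & (net.branch_order_ven >= c.min_venule_branch_order)
        & (bdist >= c.min_branches_from_boundary)
        & (dxy < max_dxy)
    )
    return np.flatnonzero(ok)


def sample_base_capillaries(net, candidates, n, seed=0) -> np.ndarray:
    """Seeded random choice of ``n`` base capillaries from the candidates."""
    candidates = np.asarray(candidates)
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} qualifying base capillaries, need {n}"
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(candidates, size=n, replace=False))


class AffectedSetError(RuntimeError):
    """Raised when the expansion cannot reach the required set size."""


def _upstream_downstream(net, base, baseline: TimeAveragedFlow):
    """Base capillary endpoints ordered (upstream, downstream) by baseline
    flow direction; near-zero flow is broken toward the lower
    arteriole-branch-order endpoint."""
    q = float(baseline.mean_flow[base])
    a, b = int(net.node_a[base]), int(net.node_b[base])
    if q > 0:
        return a, b
    if q < 0:
        return b, a
    inc = net.incidence()

    def node_order(n):
        return min(net.branch_order_art[v] for v, _ in inc[n])

    return (a, b) if node_order(a) <= node_order(b) else (b, a)


def build_affected_set(
    net: MicrovascularNetwork,
    base_capillary: int,
    baseline: TimeAveragedFlow,
    upstream_quota: int = 6,
    total_quota: int = 13,
) -> list:
    """Grow the affected capillary set around a base capillary.

    Expansion proceeds in adjacency rings (generation 1 neighbours of the
    upstream bifurcation, then their neighbours, ...) until at least
    ``upstream_quota`` capillaries have been added; the same procedure is
    then initiated at the downstream node until the total set (including
    the base) reaches ``total_quota``.  Vessels that are 0th-order main
    branches, less than two branches from a descending-arteriole main
    branch, or less than two branches from the domain boundary are never
    added.  Within a ring, vessels are added in ascending index order (a
    deterministic tie-break), stopping as soon as the quota is met.
    """
    _require_orders(net)
    base = int(base_capillary)
    bdist = net.boundary_branch_distance()
    eligible = (
        (net.vessel_type == "capillary")
        & (net.branch_order_art >= 2)
        & (bdist >= 2)
    )
    inc = net.incidence()
    up, down = _upstream_downstream(net, base, baseline)

    selected = [base]
    in_set = {base}

    def expand(start_node, quota):
        added = 0
        frontier = {start_node}
        while added < quota:
            ring = sorted(
                {
                    v
                    for n in frontier
                    for v, _ in inc[n]
                    if v not in in_set and eligible[v]
                }
            )
            if not ring:
                raise AffectedSetError(
                    f"expansion exhausted eligible capillaries around vessel "
                    f"id {net.vessel_ids[base]}; choose a different base"
                )
            taken = []
            for v in ring:
                selected.append(v)
                in_set.add(v)
                taken.append(v)
                added += 1
                if added >= quota:
                    break
            frontier = {
                int(n) for v in taken for n in (net.node_a[v], net.node_b[v])
            }
        return added

    expand(up, upstream_quota)
    remaining = total_quota - len(selected)
    if remaining > 0:
        expand(down, remaining)
    return selected


def dilate_vessels(net: MicrovascularNetwork, vessels, increment: float):
    """Copy of ``net`` with ``increment`` µm added to the given diameters."""
    out = net.copy()
    idx = np.asarray(list(vessels), dtype=np.int64)
    out.diameter[idx] = out.diameter[idx] + increment
    return out


def apply_dilation(net: MicrovascularNetwork, scenario: AblationScenario):
    """Apply a dilation scenario; the original network is left untouched."""
    return dilate_vessels(net, scenario.affected_set, scenario.dilation_increment)
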