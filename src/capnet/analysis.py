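"""Pre/post comparison analytics for focal dilation experiments.

All comparisons act on magnitudes of the *time-averaged* flow field.
Because the RBC distribution makes the flow field fluctuate in time, two
guards are applied before a vessel is called "changed": an absolute
threshold of 0.1 µm³/ms on the flow difference (changes below it are set
to zero, so low-flow vessels cannot produce spuriously large relative
changes), and a 10% relative-change rule (only |change| > 10% of baseline
counts as an increase or decrease).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MicrovascularNetwork, dilation_center, euclidean_distance_to_center
from .transport import TimeAveragedFlow

__all__ = [
    "FlowChangeReport",
    "HeterogeneityReference",
    "relative_flow_change",
    "classify_neighbors",
    "flow_change_report",
    "distance_profile",
    "steal_at_divergent_bifurcations",
    "baseline_heterogeneity",
    "dilation_heterogeneity",
    "stall_census",
    "NEIGHBOR_CLASSES",
]

ABS_FLOW_THRESHOLD = 0.1  # µm³/ms
RELATIVE_CHANGE_RULE = 0.10  # fraction of baseline

NEIGHBOR_CLASSES = ("dilated", "gen1", "gen2", "other")


def relative_flow_change(
    baseline: TimeAveragedFlow,
    perturbed: TimeAveragedFlow,
    abs_threshold: float = ABS_FLOW_THRESHOLD,
) -> np.ndarray:
    """Per-vessel relative change of |time-averaged flow|.

    change = (|q_post| - |q_pre|) / |q_pre|, set to 0 wherever the
    absolute difference is below ``abs_threshold``.  A vessel with zero
    baseline flow but an above-threshold difference reports ±inf (it is
    an unambiguous change with no meaningful relative size).
    """
    q0 = np.abs(np.asarray(baseline.mean_flow, dtype=np.float64))
    q1 = np.abs(np.asarray(perturbed.mean_flow, dtype=np.float64))
    if q0.shape != q1.shape:
        raise ValueError("baseline and perturbed fields cover different vessels")
    dq = q1 - q0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(q0 > 0, dq / np.where(q0 > 0, q0, 1.0), np.sign(dq) * np.inf)
    rel = np.where(np.abs(dq) < abs_threshold, 0.0, rel)
    return rel


def classify_neighbors(net: MicrovascularNetwork, affected_set) -> np.ndarray:
    """Per-vessel class: dilated (in the set), gen1 (sharing a node with a
    dilated vessel), gen2 (sharing a node with a gen1 vessel), or other.

    Classes are mutually exclusive with precedence dilated > gen1 > gen2.
    """
    mask = np.zeros(net.n_vessels, dtype=bool)
    mask[np.asarray(list(affected_set), dtype=np.int64)] = True
    depth = net.vessel_bfs_orders(mask)
    out = np.full(net.n_vessels, "other", dtype=object)
    out[depth == 0] = "dilated"
    out[depth == 1] = "gen1"
    out[depth == 2] = "gen2"
    return out


@dataclass
class FlowChangeReport:
    """Per-vessel comparison between a baseline and a perturbed field."""

    net: MicrovascularNetwork
    affected_set: list
    relative_flow_change: np.ndarray
    relative_flux_change: np.ndarray
    neighbor_class: np.ndarray
    distance_to_center: np.ndarray
    abs_threshold: float = ABS_FLOW_THRESHOLD

    @property
    def increased(self) -> np.ndarray:
        return self.relative_flow_change > RELATIVE_CHANGE_RULE

    @property
    def decreased(self) -> np.ndarray:
        return self.relative_flow_change < -RELATIVE_CHANGE_RULE

    @property
    def unchanged(self) -> np.ndarray:
        return ~(self.increased | self.decreased)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vessel_id": self.net.vessel_ids,
                "vessel_type": self.net.vessel_type,
                "neighbor_class": self.neighbor_class,
                "distance_to_center_um": self.distance_to_center,
                "relative_flow_change": self.relative_flow_change,
                "relative_flux_change": self.relative_flux_change,
                "flag": np.where(
                    self.increased, "increased", np.where(self.decreased, "decreased", "unchanged")
                ),
            }
        )


def _relative_change_raw(x0, x1):
    x0, x1 = np.abs(x0), np.abs(x1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(x0 > 0, (x1 - x0) / np.where(x0 > 0, x0, 1.0), np.sign(x1 - x0) * np.inf)
    return np.where(x1 == x0, 0.0, rel)


def flow_change_report(
    net: MicrovascularNetwork,
    baseline: TimeAveragedFlow,
    perturbed: TimeAveragedFlow,
    affected_set,
    abs_threshold: float = ABS_FLOW_THRESHOLD,
) -> FlowChangeReport:
    """Bundle relative flow/flux changes with neighbour classes and
    distances to the centre of the dilated region."""
    rel_flow = relative_flow_change(baseline, perturbed, abs_threshold)
    rel_flux = _relative_change_raw(baseline.mean_rbc_flux, perturbed.mean_rbc_flux)
    return FlowChangeReport(
        net=net,
        affected_set=list(affected_set),
        relative_flow_change=rel_flow,
        relative_flux_change=rel_flux,
        neighbor_class=classify_neighbors(net, affected_set),
        distance_to_center=euclidean_distance_to_center(net, affected_set),
        abs_threshold=abs_threshold,
    )


def distance_profile(report: FlowChangeReport, bin_width: float = 50.0) -> pd.DataFrame:
    """Relative flow changes binned by distance to the dilation centre.

    Only vessels passing the 10% rule are included; increases and
    decreases are profiled separately.  Returns one row per (bin,
    direction) with count, median and quartiles of the relative change.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    rows = []
    for direction, mask in (("increase", report.increased), ("decrease", report.decreased)):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        d = report.distance_to_center[idx]
        rel = report.relative_flow_change[idx]
        bins = np.floor(d / bin_width).astype(int)
        for b in np.unique(bins):
            sel = rel[bins == b]
            rows.append(
                {
                    "bin_lo_um": b * bin_width,
                    "bin_hi_um": (b + 1) * bin_width,
                    "direction": direction,
                    "n": len(sel),
                    "median": float(np.median(sel)),
                    "q1": float(np.percentile(sel, 25)),
                    "q3": float(np.percentile(sel, 75)),
                }
            )
    return pd.DataFrame(
        rows, columns=["bin_lo_um", "bin_hi_um", "direction", "n", "median", "q1", "q3"]
    )


def steal_at_divergent_bifurcations(
    net: MicrovascularNetwork,
    baseline: TimeAveragedFlow,
    perturbed: TimeAveragedFlow,
    affected_set,
    abs_threshold: float = ABS_FLOW_THRESHOLD,
) -> pd.DataFrame:
    """Flow steal records at divergent bifurcations with exactly one
    dilated and one undilated outflow capillary (baseline orientation).

    Each record reports the relative flow and RBC-flux change of the
    *undilated* branch; the Zweifach–Fung effect makes the flux steal
    stronger than the flow steal.
    """
    dilated = np.zeros(net.n_vessels, dtype=bool)
    dilated[np.asarray(list(affected_set), dtype=np.int64)] = True
    q0 = baseline.mean_flow
    rel_flow = relative_flow_change(baseline, perturbed, abs_threshold)
    rel_flux = _relative_change_raw(baseline.mean_rbc_flux, perturbed.mean_rbc_flux)

    records = []
    inc = net.incidence()
    for node in range(net.n_nodes):
        outflows = []
        inflows = 0
        for v, _ in inc[node]:
            sign = q0[v] if int(net.node_a[v]) == node else -q0[v]
            if sign > 0:
                outflows.append(v)
            elif sign < 0:
                inflows += 1
        if inflows < 1 or len(outflows) != 2:
            continue
        d_out = [v for v in outflows if dilated[v]]
        u_out = [v for v in outflows if not dilated[v]]
        if len(d_out) == 1 and len(u_out) == 1:
            records.append(
                {
                    "node_id": int(net.node_ids[node]),
                    "dilated_vessel_id": int(net.vessel_ids[d_out[0]]),
                    "undilated_vessel_id": int(net.vessel_ids[u_out[0]]),
                    "undilated_flow_change": float(rel_flow[u_out[0]]),
                    "undilated_flux_change": float(rel_flux[u_out[0]]),
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "node_id",
            "dilated_vessel_id",
            "undilated_vessel_id",
            "undilated_flow_change",
            "undilated_flux_change",
        ],
    )


@dataclass
class HeterogeneityReference:
    """Expected baseline flow heterogeneity of capillary sets.

    ``set_sds`` holds the standard deviation of baseline flow for many
    undilated capillary sets built exactly like affected sets; the median
    is the reference, with the 0.75 quantile as a second guide level.
    """

    set_sds: np.ndarray
    set_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def reference(self) -> float:
        return float(np.median(self.set_sds))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.set_sds, q))


def baseline_heterogeneity(
    net: MicrovascularNetwork,
    baseline: TimeAveragedFlow,
    criteria=None,
    n_sets: int | None = None,
    seed: int = 0,
) -> HeterogeneityReference:
    """Distribution of baseline flow SDs over undilated capillary sets.

    Builds an affected-style set around every qualifying base capillary
    (or a seeded sample of ``n_sets`` of them) and records the standard
    deviation of baseline |flow| within each set.
    """
    from .ablation import (
        AffectedSetError,
        build_affected_set,
        select_base_capillaries,
    )

    candidates = select_base_capillaries(net, criteria)
    if len(candidates) == 0:
        raise ValueError("no qualifying base capillaries in network")
    if n_sets is not None and n_sets < len(candidates):
        rng = np.random.default_rng(seed)
        candidates = np.sort(rng.choice(candidates, size=n_sets, replace=False))
    sds, sizes = [], []
    for base in candidates:
        try:
            vset = build_affected_set(net, int(base), baseline)
        except AffectedSetError:
            continue
        flows = np.abs(baseline.mean_flow[np.asarray(vset)])
        sds.append(float(np.std(flows, ddof=1)))
        sizes.append(len(vset))
    if not sds:
        raise ValueError("no qualifying capillary sets could be built")
    return HeterogeneityReference(
        set_sds=np.asarray(sds), set_sizes=np.asarray(sizes)
    )


def dilation_heterogeneity(affected_flows_by_scenario: dict) -> dict:
    """Sample SD of |flow| over the affected set, per scenario label."""
    return {
        label: float(np.std(np.abs(np.asarray(flows)), ddof=1))
        for label, flows in affected_flows_by_scenario.items()
    }


def stall_threshold(
    net: MicrovascularNetwork, baseline: TimeAveragedFlow, depth_limit: float = 200.0
) -> float:
    """Lowest-5% baseline flow threshold among vessels in the upper cortex.

    The 5th percentile (linear interpolation between order statistics) of
    baseline |flow| over vessels whose midpoint lies within
    ``depth_limit`` µm of the pial surface.
    """
    depth = net.midpoints()[:, 2]
    upper = depth <= depth_limit
    if not upper.any():
        raise ValueError(f"no vessels in the upper {depth_limit} µm")
    return float(np.percentile(np.abs(baseline.mean_flow[upper]), 5.0))


def stall_census(
    net: MicrovascularNetwork,
    baseline: TimeAveragedFlow,
    scenarios: dict,
    affected_set,
    depth_limit: float = 200.0,
    radius: float = 200.0,
) -> pd.DataFrame:
    """Counts of stalled/low-flow capillaries per scenario.

    A capillary stalls when its time-averaged |flow| falls below the
    lowest-5% baseline threshold (computed over the upper ``depth_limit``
    µm).  Counts are reported per neighbour class (dilated/gen1/gen2) and
    within ``radius`` µm of the dilation centre.  ``scenarios`` maps a
    label to a TimeAveragedFlow; include the baseline itself to see the
    by-construction ~5% baseline count.
    """
    thr = stall_threshold(net, baseline, depth_limit)
    classes = classify_neighbors(net, affected_set)
    center = dilation_center(net, affected_set)
    dist = np.linalg.norm(net.midpoints() - center, axis=1)
    cap = net.vessel_type == "capillary"

    rows = []
    for label, taf in scenarios.items():
        low = np.abs(taf.mean_flow) < thr
        row = {"scenario": label, "threshold": thr}
        for cls in ("dilated", "gen1", "gen2"):
            row[f"n_low_{cls}"] = int((low & cap & (classes == cls)).sum())
        row["n_low_within_radius"] = int((low & cap & (dist <= radius)).sum())
        row["n_low_total"] = int((low & cap).sum())
        rows.append(row)
    return pd.DataFrame(rows)
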