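"""Vascular graph data model, validation, branch orders and file I/O.

A microvascular network is an undirected geometric graph: vessels (edges)
carry a diameter, a length and a vessel-type label; nodes are bifurcations
or endpoints with 3-D positions in µm (z = cortical depth, 0 at the pial
surface).  Edge tables are undirected — flow direction is a solver output,
carried by the sign of the flow rate (positive = ``node_a`` → ``node_b``).

Canonical on-disk form is a pair of CSV tables::

    nodes.csv: id,x,y,z,is_boundary
    edges.csv: id,node_a,node_b,diameter_um,length_um,vessel_type

Branch orders are derived quantities (recomputed, not persisted): the
arteriole-side order of a vessel is the number of bifurcations crossed on
the shortest vessel path to the nearest 0th-order arteriole main branch,
and analogously on the venule side.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import ARTERIAL_TYPES, VENOUS_TYPES, VESSEL_TYPES

__all__ = [
    "MicrovascularNetwork",
    "NetworkValidationError",
    "load_network",
    "save_network",
    "assign_branch_orders",
    "euclidean_distance_to_center",
]


class NetworkValidationError(ValueError):
    """A structural or geometric violation in a network table."""


NODE_COLUMNS = ("id", "x", "y", "z", "is_boundary")
EDGE_COLUMNS = ("id", "node_a", "node_b", "diameter_um", "length_um", "vessel_type")

_UNSET_ORDER = -1


@dataclass
class MicrovascularNetwork:
    """Undirected vascular graph with per-vessel geometry.

    ``node_a``/``node_b`` hold *indices* into the node arrays; external ids
    live in ``node_ids``/``vessel_ids`` and are preserved through I/O.
    """

    node_ids: np.ndarray
    positions: np.ndarray  # (n_nodes, 3) µm
    is_boundary: np.ndarray  # bool
    vessel_ids: np.ndarray
    node_a: np.ndarray  # node index
    node_b: np.ndarray  # node index
    diameter: np.ndarray  # µm
    length: np.ndarray  # µm
    vessel_type: np.ndarray  # str
    branch_order_art: np.ndarray = field(default=None)  # type: ignore[assignment]
    branch_order_ven: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.branch_order_art is None:
            self.branch_order_art = np.full(self.n_vessels, _UNSET_ORDER, dtype=np.int64)
        if self.branch_order_ven is None:
            self.branch_order_ven = np.full(self.n_vessels, _UNSET_ORDER, dtype=np.int64)
        self._incidence = None

    # -- basic shape -----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_vessels(self) -> int:
        return len(self.vessel_ids)

    def copy(self) -> "MicrovascularNetwork":
        return MicrovascularNetwork(
            node_ids=self.node_ids.copy(),
            positions=self.positions.copy(),
            is_boundary=self.is_boundary.copy(),
            vessel_ids=self.vessel_ids.copy(),
            node_a=self.node_a.copy(),
            node_b=self.node_b.copy(),
            diameter=self.diameter.copy(),
            length=self.length.copy(),
            vessel_type=self.vessel_type.copy(),
            branch_order_art=self.branch_order_art.copy(),
            branch_order_ven=self.branch_order_ven.copy(),
        )

    # -- derived adjacency ----------------------------------------------
    def incidence(self) -> list:
        """Node index -> list of (vessel index, other-node index)."""
        if self._incidence is None:
            inc = [[] for _ in range(self.n_nodes)]
            for v in range(self.n_vessels):
                a, b = int(self.node_a[v]), int(self.node_b[v])
                inc[a].append((v, b))
                inc[b].append((v, a))
            self._incidence = inc
        return self._incidence

    def degree(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.node_a, 1)
        np.add.at(deg, self.node_b, 1)
        return deg

    def midpoints(self) -> np.ndarray:
        """(n_vessels, 3) midpoint of each vessel's endpoints, µm."""
        return 0.5 * (self.positions[self.node_a] + self.positions[self.node_b])

    def endpoint_distance(self) -> np.ndarray:
        d = self.positions[self.node_a] - self.positions[self.node_b]
        return np.sqrt((d * d).sum(axis=1))

    def vessel_index(self, vessel_id) -> int:
        idx = np.flatnonzero(self.vessel_ids == vessel_id)
        if idx.size == 0:
            raise KeyError(f"no vessel with id {vessel_id!r}")
        return int(idx[0])

    # -- validation ------------------------------------------------------
    def validate(self) -> list:
        """Check all structural invariants; raise on violations.

        Returns a list of non-fatal warnings (currently: interior
        degree-1 nodes, which are flagged but allowed).
        """
        if len(np.unique(self.node_ids)) != self.n_nodes:
            raise NetworkValidationError("duplicate node ids")
        if len(np.unique(self.vessel_ids)) != self.n_vessels:
            raise NetworkValidationError("duplicate vessel ids")
        if not np.all(np.isfinite(self.positions)):
            bad = int(np.flatnonzero(~np.isfinite(self.positions).all(axis=1))[0])
            raise NetworkValidationError(
                f"non-finite position at node id {self.node_ids[bad]}"
            )
        for name, arr in (("diameter", self.diameter), ("length", self.length)):
            bad = np.flatnonzero(~(arr > 0) | ~np.isfinite(arr))
            if bad.size:
                raise NetworkValidationError(
                    f"non-positive {name} on vessel id {self.vessel_ids[bad[0]]}"
                )
        bad = np.flatnonzero(self.node_a == self.node_b)
        if bad.size:
            raise NetworkValidationError(
                f"self-loop on vessel id {self.vessel_ids[bad[0]]}"
            )
        unknown = set(np.unique(self.vessel_type)) - set(VESSEL_TYPES)
        if unknown:
            raise NetworkValidationError(f"unknown vessel types {sorted(unknown)}")
        # tortuosity >= 1 (tiny tolerance for round-off on straight vessels)
        euclid = self.endpoint_distance()
        bad = np.flatnonzero(self.length < euclid * (1.0 - 1e-9))
        if bad.size:
            raise NetworkValidationError(
                f"length shorter than endpoint distance on vessel id "
                f"{self.vessel_ids[bad[0]]}"
            )
        if self.n_nodes and not self._connected():
            raise NetworkValidationError("network is not a connected graph")
        warn = []
        deg = self.degree()
        loose = np.flatnonzero((deg == 1) & ~self.is_boundary)
        for n in loose:
            warn.append(f"interior node id {self.node_ids[n]} has degree 1")
        if warn:
            warnings.warn(
                f"{len(warn)} interior degree-1 node(s) in network", stacklevel=2
            )
        return warn

    def _connected(self) -> bool:
        seen = np.zeros(self.n_nodes, dtype=bool)
        stack = [0]
        seen[0] = True
        inc = self.incidence()
        while stack:
            n = stack.pop()
            for _, other in inc[n]:
                if not seen[other]:
                    seen[other] = True
                    stack.append(other)
        return bool(seen.all())

    # -- vessel-graph BFS ------------------------------------------------
    def vessel_bfs_orders(self, source_mask: np.ndarray) -> np.ndarray:
        """Multi-source BFS over vessels (adjacency = shared node).

        Source vessels get 0; each bifurcation crossed adds 1.  Unreachable
        vessels get -1.
        """
        order = np.full(self.n_vessels, -1, dtype=np.int64)
        sources = np.flatnonzero(source_mask)
        if sources.size == 0:
            return order
        inc = self.incidence()
        q = deque()
        for v in sources:
            order[v] = 0
            q.append(int(v))
        while q:
            v = q.popleft()
            for n in (int(self.node_a[v]), int(self.node_b[v])):
                for w, _ in inc[n]:
                    if order[w] < 0:
                        order[w] = order[v] + 1
                        q.append(w)
        return order

    def boundary_branch_distance(self) -> np.ndarray:
        """Per-vessel count of bifurcations to the nearest boundary node.

        A vessel touching a boundary node is 0 branches apart from the
        boundary; its neighbours are 1 apart, and so on.
        """
        touches = self.is_boundary[self.node_a] | self.is_boundary[self.node_b]
        return self.vessel_bfs_orders(touches)

    def to_networkx(self):
        """Export to a networkx multigraph (for visualisation/inspection)."""
        import networkx as nx

        g = nx.MultiGraph()
        for i in range(self.n_nodes):
            g.add_node(
                int(self.node_ids[i]),
                x=float(self.positions[i, 0]),
                y=float(self.positions[i, 1]),
                z=float(self.positions[i, 2]),
                is_boundary=bool(self.is_boundary[i]),
            )
        for v in range(self.n_vessels):
            g.add_edge(
                int(self.node_ids[self.node_a[v]]),
                int(self.node_ids[self.node_b[v]]),
                id=int(self.vessel_ids[v]),
                diameter_um=float(self.diameter[v]),
                length_um=float(self.length[v]),
                vessel_type=str(self.vessel_type[v]),
            )
        return g


# -- I/O -----------------------------------------------------------------

def load_network(node_table, edge_table) -> MicrovascularNetwork:
    """Read a network from node/edge CSV tables (paths or file-likes).

    Units are taken as µm.  The resulting network is validated; dangling
    endpoints and non-positive geometry are rejected with the offending
    record named.
    """
    nodes = pd.read_csv(node_table, float_precision="round_trip")
    edges = pd.read_csv(edge_table, float_precision="round_trip")
    for cols, df, what in ((NODE_COLUMNS, nodes, "node"), (EDGE_COLUMNS, edges, "edge")):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise NetworkValidationError(f"{what} table missing column(s) {missing}")

    node_ids = nodes["id"].to_numpy(dtype=np.int64)
    id_to_idx = {int(i): k for k, i in enumerate(node_ids)}
    if len(id_to_idx) != len(node_ids):
        raise NetworkValidationError("duplicate node ids in node table")

    def endpoints(col):
        out = np.empty(len(edges), dtype=np.int64)
        for k, nid in enumerate(edges[col].to_numpy(dtype=np.int64)):
            if int(nid) not in id_to_idx:
                raise NetworkValidationError(
                    f"edge id {edges['id'].iloc[k]} references missing node {nid}"
                )
            out[k] = id_to_idx[int(nid)]
        return out

    net = MicrovascularNetwork(
        node_ids=node_ids,
        positions=nodes[["x", "y", "z"]].to_numpy(dtype=np.float64),
        is_boundary=nodes["is_boundary"].to_numpy().astype(bool),
        vessel_ids=edges["id"].to_numpy(dtype=np.int64),
        node_a=endpoints("node_a"),
        node_b=endpoints("node_b"),
        diameter=edges["diameter_um"].to_numpy(dtype=np.float64),
        length=edges["length_um"].to_numpy(dtype=np.float64),
        vessel_type=edges["vessel_type"].to_numpy(dtype=object),
    )
    net.validate()
    return net


def save_network(net: MicrovascularNetwork, node_table, edge_table) -> None:
    """Write nodes.csv / edges.csv; float fields round-trip bit-exactly."""
    nodes = pd.DataFrame(
        {
            "id": net.node_ids,
            "x": net.positions[:, 0],
            "y": net.positions[:, 1],
            "z": net.positions[:, 2],
            "is_boundary": net.is_boundary.astype(int),
        }
    )
    edges = pd.DataFrame(
        {
            "id": net.vessel_ids,
            "node_a": net.node_ids[net.node_a],
            "node_b": net.node_ids[net.node_b],
            "diameter_um": net.diameter,
            "length_um": net.length,
            "vessel_type": net.vessel_type,
        }
    )
    # 17 significant digits round-trip float64 exactly
    nodes.to_csv(node_table, index=False, float_format="%.17g")
    edges.to_csv(edge_table, index=False, float_format="%.17g")


# -- branch orders -------------------------------------------------------

def assign_branch_orders(net: MicrovascularNetwork) -> MicrovascularNetwork:
    """Label every vessel with arteriole- and venule-side branch orders.

    Main branches (penetrating/descending arterioles and their pial feeders,
    and ascending venules with their pial drains) are 0th order on their
    respective side; every bifurcation crossed on the shortest vessel path
    adds one.  Modifies ``net`` in place and returns it.
    """
    types = net.vessel_type
    art0 = np.isin(types, ARTERIAL_TYPES)
    ven0 = np.isin(types, VENOUS_TYPES)
    if not art0.any():
        raise NetworkValidationError("no arteriole main branch (0th order) in network")
    if not ven0.any():
        raise NetworkValidationError("no venule main branch (0th order) in network")
    net.branch_order_art = net.vessel_bfs_orders(art0)
    net.branch_order_ven = net.vessel_bfs_orders(ven0)
    return net


# -- geometry ------------------------------------------------------------

def euclidean_distance_to_center(net: MicrovascularNetwork, vessel_set) -> np.ndarray:
    """Distance of every vessel's midpoint to the centre of ``vessel_set``.

    The centre is the averaged coordinate of all bifurcations (unique
    endpoint nodes) of the vessels in the set.  Returns a per-vessel array
    over the whole network, µm.
    """
    vset = np.asarray(list(vessel_set), dtype=np.int64)
    if vset.size == 0:
        raise ValueError("vessel_set is empty")
    nodes = np.unique(np.concatenate([net.node_a[vset], net.node_b[vset]]))
    center = net.positions[nodes].mean(axis=0)
    d = net.midpoints() - center
    return np.sqrt((d * d).sum(axis=1))


def dilation_center(net: MicrovascularNetwork, vessel_set) -> np.ndarray:
    """Averaged coordinate of all bifurcations of the given vessels, µm."""
    vset = np.asarray(list(vessel_set), dtype=np.int64)
    if vset.size == 0:
        raise ValueError("vessel_set is empty")
    nodes = np.unique(np.concatenate([net.node_a[vset], net.node_b[vset]]))
    return net.positions[nodes].mean(axis=0)
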