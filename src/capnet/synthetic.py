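"""Seeded generator of synthetic cortical microvascular networks and toys.

Real cortical vascular graphs are dominated by capillaries (94–96% of all
vessels) with narrow lumens (3.04 ± 0.59 µm, range 2.17–4.81 µm), fed by a
small number of penetrating (descending) arterioles and drained by
ascending venules, both running from the pial surface down into cortex.
The generator emulates those summary statistics at desk scale:

* a connected, mostly degree-3 capillary mesh built from a jittered 3-D
  lattice (random spanning tree + extra chords, pass-through joints merged
  so every edge is a true inter-bifurcation segment with a tortuous path
  length),
* arteriole/venule trees descending from the pia, coupled to the mesh
  through short arteriole-capillary (resp. capillary-venule) transition
  paths of 1–3 segments,
* capillary diameters drawn from a truncated normal,
* boundary nodes flagged on the lateral and bottom faces of the domain and
  at the pial root of each tree.

Everything is deterministic for a given seed (one named random stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import MicrovascularNetwork
from .rheology import LAW_VERSION

__all__ = ["GeneratorConfig", "generate_cortical_mvn", "generate_toy", "provenance"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic cortical network generation.

    Capillary diameter statistics default to the in vivo pre-ablation
    distribution (3.04 ± 0.59 µm, truncated to 2.17–4.81 µm); the default
    network size (~3,000 vessels in a ~(550 µm)³ domain) is a desk-scale
    reduction of the 12k–19k-vessel acquired networks, chosen so that a
    full RBC-tracking simulation runs in well under a minute.
    """

    domain_size: tuple = (550.0, 550.0, 550.0)  # µm
    target_vessel_count: int = 3000
    capillary_fraction_target: float = 0.96
    capillary_diameter_mean: float = 3.04  # µm
    capillary_diameter_sd: float = 0.59  # µm
    capillary_diameter_range: tuple = (2.17, 4.81)  # µm
    n_penetrating_arterioles: int = 3
    n_ascending_venules: int = 3
    seed: int = 0
    # free parameters (not constrained by any reported statistic):
    min_cortical_depth: float = 40.0  # µm, depth of the uppermost mesh layer
    tortuosity_range: tuple = (1.05, 1.2)
    arteriole_trunk_diameter: float = 15.0  # µm, tapering geometrically
    arteriole_tip_diameter: float = 9.0
    venule_trunk_diameter: float = 20.0
    venule_tip_diameter: float = 11.0
    pial_artery_diameter: float = 25.0
    pial_vein_diameter: float = 30.0

    def __post_init__(self):
        lo, hi = self.capillary_diameter_range
        if not (0 < lo < hi):
            raise ValueError("capillary_diameter_range must be positive and ordered")
        if not lo <= self.capillary_diameter_mean <= hi:
            raise ValueError("capillary_diameter_mean must lie within the range")
        if self.capillary_diameter_sd <= 0:
            raise ValueError("capillary_diameter_sd must be > 0")
        if min(self.n_penetrating_arterioles, self.n_ascending_venules) < 1:
            raise ValueError("need at least one arteriole and one venule tree")
        if self.target_vessel_count < 50:
            raise ValueError("target_vessel_count too small for a 3-D mesh")
        if any(s <= 0 for s in self.domain_size):
            raise ValueError("domain_size must be positive")


def provenance(config: GeneratorConfig) -> dict:
    """Provenance record (config + seed + law version) for archival output."""
    from dataclasses import asdict

    d = asdict(config)
    d["generator"] = "capnet.synthetic.generate_cortical_mvn"
    d["law_version"] = LAW_VERSION
    return d


def capillary_diameter_distribution(config: GeneratorConfig):
    """Frozen truncated normal whose *mean* equals the configured mean.

    Truncation is asymmetric (the lower bound sits ~1.5 sd below the mean,
    the upper ~3 sd above), so the underlying normal location is shifted
    slightly so that the expected value of a draw matches
    ``capillary_diameter_mean`` exactly.
    """
    from scipy import stats
    from scipy.optimize import brentq

    lo, hi = config.capillary_diameter_range
    sd = config.capillary_diameter_sd
    target = config.capillary_diameter_mean

    def excess(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target

    loc = brentq(excess, lo - 4 * sd, hi + 4 * sd, xtol=1e-10)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def _diameter_sampler(config: GeneratorConfig):
    """Rejection sampler (loc-adjusted) bound to a config; see above."""
    dist = capillary_diameter_distribution(config)
    loc = float(dist.kwds["loc"])
    lo, hi = config.capillary_diameter_range

    def draw(rng, size):
        return sample_truncated_normal(
            rng, loc, config.capillary_diameter_sd, lo, hi, size
        )

    return draw


def sample_truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection sampling from a normal truncated to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# capillary mesh
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def _build_mesh(config: GeneratorConfig, rng, n_nodes_target, n_edges_target):
    """Jittered-lattice capillary mesh; returns (positions, is_boundary, edges).

    edges are (a, b, path_length) with pass-through (degree-2, interior)
    joints already merged away, so each edge is an inter-bifurcation
    segment whose path length includes the tortuosity of the removed
    intermediate points.
    """
    lx, ly, lz = config.domain_size
    z0 = config.min_cortical_depth
    vol = lx * ly * (lz - z0)
    s = (vol / max(n_nodes_target, 8)) ** (1.0 / 3.0)
    nx = max(4, int(round(lx / s)) + 1)
    ny = max(4, int(round(ly / s)) + 1)
    nz = max(3, int(round((lz - z0) / s)) + 1)
    hx, hy, hz = lx / (nx - 1), ly / (ny - 1), (lz - z0) / (nz - 1)

    idx = np.arange(nx * ny * nz).reshape(nx, ny, nz)
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    pos = np.stack(
        [ii.ravel() * hx, jj.ravel() * hy, z0 + kk.ravel() * hz], axis=1
    ).astype(np.float64)
    jitter = rng.uniform(-0.3, 0.3, size=pos.shape) * np.array([hx, hy, hz])
    pos = pos + jitter
    n = len(pos)

    boundary = (
        (ii == 0) | (ii == nx - 1) | (jj == 0) | (jj == ny - 1) | (kk == nz - 1)
    ).ravel()

    cand = []
    cand.append(np.stack([idx[:-1].ravel(), idx[1:].ravel()], axis=1))
    cand.append(np.stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()], axis=1))
    cand.append(np.stack([idx[:, :, :-1].ravel(), idx[:, :, 1:].ravel()], axis=1))
    cand = np.concatenate(cand, axis=0)
    rng.shuffle(cand)

    # random spanning tree, then chords preferring low-degree endpoints
    uf = _UnionFind(n)
    deg = np.zeros(n, dtype=np.int64)
    adj = [dict() for _ in range(n)]  # neighbour -> number of parallel edges
    edges = []

    def add_edge(a, b):
        edges.append((int(a), int(b)))
        deg[a] += 1
        deg[b] += 1
        adj[a][b] = adj[a].get(b, 0) + 1
        adj[b][a] = adj[b].get(a, 0) + 1

    rest = []
    for a, b in cand:
        if uf.union(int(a), int(b)):
            add_edge(a, b)
        else:
            rest.append((int(a), int(b)))

    budget = n_edges_target - len(edges)
    for max_deg in (1, 2, 3):
        if budget <= 0:
            break
        for a, b in rest:
            if budget <= 0:
                break
            if b in adj[a]:
                continue
            if min(deg[a], deg[b]) <= max_deg and max(deg[a], deg[b]) <= 3:
                add_edge(a, b)
                budget -= 1

    # resolve interior dead ends: reconnect if a free lattice neighbour
    # exists, otherwise prune the stub
    neighbor_offsets = []
    removed = np.zeros(n, dtype=bool)
    changed = True
    while changed:
        changed = False
        for a in range(n):
            if removed[a] or boundary[a] or deg[a] != 1:
                continue
            i0, j0, k0 = a // (ny * nz), (a // nz) % ny, a % nz
            options = []
            for di, dj, dk in (
                (1, 0, 0),
                (-1, 0, 0),
                (0, 1, 0),
                (0, -1, 0),
                (0, 0, 1),
                (0, 0, -1),
            ):
                i1, j1, k1 = i0 + di, j0 + dj, k0 + dk
                if 0 <= i1 < nx and 0 <= j1 < ny and 0 <= k1 < nz:
                    b = int(idx[i1, j1, k1])
                    if not removed[b] and b not in adj[a] and deg[b] <= 3:
                        options.append(b)
            if options:
                b = options[int(rng.integers(len(options)))]
                add_edge(a, b)
            else:
                (b,) = adj[a].keys()
                deg[a] -= 1
                deg[b] -= 1
                del adj[a][b]
                del adj[b][a]
                edges.remove((a, b) if (a, b) in edges else (b, a))
                removed[a] = True
            changed = True

    removed[deg == 0] = True  # stubs whose whole chain was pruned

    # merge degree-2 interior joints into tortuous segments: walk maximal
    # chains between terminals (bifurcations, boundary nodes, dead ends)
    elen = [float(np.linalg.norm(pos[a] - pos[b])) for a, b in edges]
    incid = [[] for _ in range(n)]
    for ei, (a, b) in enumerate(edges):
        incid[a].append(ei)
        incid[b].append(ei)
    passthrough = np.array(
        [not removed[u] and not boundary[u] and deg[u] == 2 for u in range(n)]
    )
    visited = np.zeros(len(edges), dtype=bool)
    merged_edges = []

    def other(ei, u):
        a, b = edges[ei]
        return b if a == u else a

    for u in range(n):
        if removed[u] or passthrough[u]:
            continue
        for ei in incid[u]:
            if visited[ei]:
                continue
            # walk the chain starting with edge ei out of terminal u
            chain_nodes = [u]
            total = 0.0
            cur_edge, cur = ei, u
            while True:
                visited[cur_edge] = True
                total += elen[cur_edge]
                nxt = other(cur_edge, cur)
                chain_nodes.append(nxt)
                if not passthrough[nxt]:
                    break
                e1, e2 = incid[nxt]
                cur_edge = e2 if e1 == cur_edge else e1
                if visited[cur_edge]:  # closed back on itself
                    break
                cur = nxt
            v = chain_nodes[-1]
            interior = chain_nodes[1:-1]
            if u == v and interior:
                # cycle hanging on one terminal: keep the middle joint so
                # the collapse yields two parallel edges, not a self-loop
                mid = interior[len(interior) // 2]
                passthrough[mid] = False
                left = chain_nodes[: chain_nodes.index(mid) + 1]
                right = chain_nodes[chain_nodes.index(mid) :]
                for part in (left, right):
                    plen = sum(
                        float(np.linalg.norm(pos[part[i]] - pos[part[i + 1]]))
                        for i in range(len(part) - 1)
                    )
                    merged_edges.append((part[0], part[-1], plen))
                    for w in part[1:-1]:
                        removed[w] = True
            else:
                merged_edges.append((u, v, total))
                for w in interior:
                    removed[w] = True

    keep = ~removed
    remap = -np.ones(n, dtype=np.int64)
    remap[keep] = np.arange(keep.sum())
    out_edges = [(int(remap[a]), int(remap[b]), l) for a, b, l in merged_edges]
    return pos[keep], boundary[keep], out_edges


# ---------------------------------------------------------------------------
# full cortical network
# ---------------------------------------------------------------------------


def generate_cortical_mvn(config: GeneratorConfig) -> MicrovascularNetwork:
    """Generate a synthetic cortical microvascular network.

    Deterministic for a given ``config.seed``.  The returned network
    passes :meth:`MicrovascularNetwork.validate` and has branch orders
    unset (call :func:`capnet.network.assign_branch_orders`).
    """
    rng = np.random.default_rng(config.seed)
    n_trees = config.n_penetrating_arterioles + config.n_ascending_venules
    # trunk segmentation chosen so non-capillary vessels make up roughly
    # (1 - capillary_fraction_target) of the network
    n_trunk = int(
        np.clip(
            round(
                (1.0 - config.capillary_fraction_target)
                * config.target_vessel_count
                / n_trees
            )
            - 1,
            5,
            16,
        )
    )
    # venules drain more capillaries than arterioles feed; couple venule
    # trunks at every node, arteriole trunks at every other node
    couple_every = {"arteriole": 2, "venule": 1}
    n_couplings = n_trees * n_trunk
    n_noncap = n_trees * (n_trunk + 1)
    n_transition = int(round(n_couplings * 1.7))  # ~1-3 segments per coupling
    mesh_target = config.target_vessel_count - n_noncap - n_transition
    if mesh_target < 30:
        raise ValueError(
            "infeasible config: target_vessel_count too small for the "
            "requested arteriole/venule trees"
        )

    # calibrate lattice size so the merged mesh hits the edge target
    n_nodes = int(mesh_target / 1.55)
    mesh_rngs = rng.spawn(3)
    pos = bnd = edges = None
    for attempt, mrng in enumerate(mesh_rngs):
        pos, bnd, edges = _build_mesh(
            config, mrng, n_nodes, int(n_nodes * 1.45)
        )
        got = len(edges)
        if abs(got - mesh_target) / mesh_target < 0.12 or attempt == len(mesh_rngs) - 1:
            break
        n_nodes = max(60, int(n_nodes * mesh_target / max(got, 1)))

    positions = [pos]
    is_boundary = [bnd]
    n_mesh = len(pos)
    next_node = n_mesh
    vessels = []  # (a, b, diameter, path_length, type)

    lo, hi = config.capillary_diameter_range
    draw_diameters = _diameter_sampler(config)
    mesh_diam = draw_diameters(rng, len(edges))
    t_lo, t_hi = config.tortuosity_range
    for (a, b, plen), d in zip(edges, mesh_diam):
        vessels.append((a, b, float(d), plen * rng.uniform(t_lo, t_hi), "capillary"))

    # tree sites: spread in the central region, arterioles/venules alternating
    lx, ly, lz = config.domain_size
    sites = _spread_sites(rng, n_trees, lx, ly)
    kinds = []
    na, nv = config.n_penetrating_arterioles, config.n_ascending_venules
    while len(kinds) < n_trees:
        if na > 0:
            kinds.append("arteriole")
            na -= 1
        if nv > 0 and len(kinds) < n_trees:
            kinds.append("venule")
            nv -= 1

    mesh_pos = pos
    mesh_deg = np.zeros(n_mesh, dtype=np.int64)
    for a, b, _ in edges:
        mesh_deg[a] += 1
        mesh_deg[b] += 1
    attach_used = np.zeros(n_mesh, dtype=bool)
    attach_used |= bnd  # never couple trees straight onto the domain boundary
    attach_used |= mesh_deg > 3  # keep couplings at simple bifurcations
    extra_pos = []
    extra_bnd = []

    def new_node(p, boundary_flag=False):
        nonlocal next_node
        extra_pos.append(np.asarray(p, dtype=np.float64))
        extra_bnd.append(bool(boundary_flag))
        next_node += 1
        return next_node - 1

    trunk_depth = 0.7 * lz
    for (sx, sy), kind in zip(sites, kinds):
        if kind == "arteriole":
            d_top, d_tip = config.arteriole_trunk_diameter, config.arteriole_tip_diameter
            pial_d, trunk_type, pial_type = (
                config.pial_artery_diameter,
                "descending_arteriole",
                "pial_artery",
            )
        else:
            d_top, d_tip = config.venule_trunk_diameter, config.venule_tip_diameter
            pial_d, trunk_type, pial_type = (
                config.pial_vein_diameter,
                "ascending_venule",
                "pial_vein",
            )
        # pial root (boundary, pressure inlet/outlet) and pial vessel
        root = new_node(
            (sx + rng.uniform(-30, 30), sy + rng.uniform(-30, 30), 0.0), True
        )
        top = new_node((sx, sy, 0.0))
        pial_len = max(float(np.linalg.norm(extra_pos[root - n_mesh] - extra_pos[top - n_mesh])), 20.0)
        vessels.append((root, top, pial_d, pial_len * 1.05, pial_type))

        taper = (d_tip / d_top) ** (1.0 / max(n_trunk - 1, 1))
        prev = top
        trunk_nodes = []
        for k in range(1, n_trunk + 1):
            zk = trunk_depth * k / n_trunk
            node = new_node(
                (sx + rng.uniform(-8, 8), sy + rng.uniform(-8, 8), zk)
            )
            seg_len = float(
                np.linalg.norm(extra_pos[node - n_mesh] - extra_pos[prev - n_mesh])
            )
            vessels.append((prev, node, d_top * taper ** (k - 1), seg_len, trunk_type))
            trunk_nodes.append(node)
            prev = node

        # couple trunk nodes (always including the tip) to nearby free mesh
        # bifurcations through short transition paths; transition vessels
        # are drawn from the upper half of the capillary distribution (the
        # arteriole-capillary transition zone is wider than the mid-bed)
        s_est = float(np.median([e[2] for e in edges]))
        for k, tn in enumerate(trunk_nodes):
            if k % couple_every[kind] != 0 and k != len(trunk_nodes) - 1:
                continue
            tp = extra_pos[tn - n_mesh]
            dists = np.linalg.norm(mesh_pos - tp, axis=1)
            dists[attach_used] = np.inf
            dists[dists < 0.5 * s_est] = np.inf  # avoid degenerate couplings
            target = int(np.argmin(dists))
            if not np.isfinite(dists[target]):
                continue
            attach_used[target] = True
            n_seg = int(rng.integers(1, 4)) if kind == "arteriole" else int(
                rng.integers(1, 3)
            )
            path_nodes = [tn]
            for s_i in range(1, n_seg):
                frac = s_i / n_seg
                p = tp + frac * (mesh_pos[target] - tp) + rng.uniform(-6, 6, 3)
                path_nodes.append(new_node(p))
            path_nodes.append(target)
            # upper-half draws: rejection against the capillary distribution
            diams = np.empty(n_seg)
            got = 0
            while got < n_seg:
                d = draw_diameters(rng, 1)[0]
                if d >= config.capillary_diameter_mean:
                    diams[got] = d
                    got += 1
            for s_i in range(n_seg):
                a, b = path_nodes[s_i], path_nodes[s_i + 1]
                pa = extra_pos[a - n_mesh] if a >= n_mesh else mesh_pos[a]
                pb = extra_pos[b - n_mesh] if b >= n_mesh else mesh_pos[b]
                seg = max(float(np.linalg.norm(pa - pb)), 25.0)
                vessels.append(
                    (a, b, float(diams[s_i]), seg * rng.uniform(t_lo, t_hi), "capillary")
                )

    all_pos = np.vstack([mesh_pos] + [np.asarray(extra_pos)]) if extra_pos else mesh_pos
    all_bnd = np.concatenate([bnd, np.asarray(extra_bnd, dtype=bool)]) if extra_bnd else bnd

    m = len(vessels)
    net = MicrovascularNetwork(
        node_ids=np.arange(len(all_pos), dtype=np.int64),
        positions=all_pos,
        is_boundary=all_bnd,
        vessel_ids=np.arange(m, dtype=np.int64),
        node_a=np.array([v[0] for v in vessels], dtype=np.int64),
        node_b=np.array([v[1] for v in vessels], dtype=np.int64),
        diameter=np.array([v[2] for v in vessels]),
        length=np.array([v[3] for v in vessels]),
        vessel_type=np.array([v[4] for v in vessels], dtype=object),
    )
    # guard against degenerate short segments from jitter: a 15 µm floor on
    # path length (still >= the endpoint distance, i.e. extra tortuosity)
    net.length = np.maximum(
        np.maximum(net.length, 15.0), net.endpoint_distance() + 1e-9
    )
    net.validate()
    return net


def _spread_sites(rng, k, lx, ly, n_trials=60):
    """k xy sites in the central region, maximising the minimum separation."""
    best, best_score = None, -1.0
    for _ in range(n_trials):
        pts = np.stack(
            [rng.uniform(0.22 * lx, 0.78 * lx, k), rng.uniform(0.22 * ly, 0.78 * ly, k)],
            axis=1,
        )
        if k == 1:
            return pts
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        score = np.min(d[np.triu_indices(k, 1)])
        if score > best_score:
            best, best_score = pts, score
    return best


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------


def generate_toy(name: str, **params) -> MicrovascularNetwork:
    """Exact small networks for solver/transport demonstrations.

    Names: ``single_tube``, ``divergent_Y``, ``convergent_Y``,
    ``two_path_loop``, ``honeycomb_sheet``.
    """
    builders = {
        "single_tube": _toy_single_tube,
        "divergent_Y": _toy_divergent_y,
        "convergent_Y": _toy_convergent_y,
        "two_path_loop": _toy_two_path_loop,
        "honeycomb_sheet": _toy_honeycomb,
    }
    if name not in builders:
        raise ValueError(f"unknown toy network {name!r}; choose from {sorted(builders)}")
    net = builders[name](**params)
    net.validate()
    return net


def _assemble(nodes, edges):
    """nodes: list of (x, y, z, is_boundary); edges: (a, b, D, L, type)."""
    pos = np.array([n[:3] for n in nodes], dtype=np.float64)
    return MicrovascularNetwork(
        node_ids=np.arange(len(nodes), dtype=np.int64),
        positions=pos,
        is_boundary=np.array([n[3] for n in nodes], dtype=bool),
        vessel_ids=np.arange(len(edges), dtype=np.int64),
        node_a=np.array([e[0] for e in edges], dtype=np.int64),
        node_b=np.array([e[1] for e in edges], dtype=np.int64),
        diameter=np.array([e[2] for e in edges], dtype=np.float64),
        length=np.array([e[3] for e in edges], dtype=np.float64),
        vessel_type=np.array([e[4] for e in edges], dtype=object),
    )


def _toy_single_tube(diameter=4.0, length=100.0, vessel_type="capillary"):
    nodes = [(0, 0, 50, True), (length, 0, 50, True)]
    edges = [(0, 1, diameter, length, vessel_type)]
    return _assemble(nodes, edges)


def _toy_divergent_y(
    parent_diameter=12.0,
    daughter_diameters=(8.0, 8.0),
    parent_length=100.0,
    daughter_lengths=(120.0, 120.0),
    parent_type="capillary",
    daughter_type="capillary",
):
    d1, d2 = daughter_diameters
    l1, l2 = daughter_lengths
    nodes = [
        (0, 0, 50, True),
        (parent_length, 0, 50, False),
        (parent_length + l1 * 0.8, l1 * 0.6, 50, True),
        (parent_length + l2 * 0.8, -l2 * 0.6, 50, True),
    ]
    edges = [
        (0, 1, parent_diameter, parent_length, parent_type),
        (1, 2, d1, l1, daughter_type),
        (1, 3, d2, l2, daughter_type),
    ]
    return _assemble(nodes, edges)


def _toy_convergent_y(
    parent_diameter=12.0,
    feeder_diameters=(8.0, 8.0),
    parent_length=100.0,
    feeder_lengths=(120.0, 120.0),
):
    d1, d2 = feeder_diameters
    l1, l2 = feeder_lengths
    nodes = [
        (-l1 * 0.8, l1 * 0.6, 50, True),
        (-l2 * 0.8, -l2 * 0.6, 50, True),
        (0, 0, 50, False),
        (parent_length, 0, 50, True),
    ]
    edges = [
        (0, 2, d1, l1, "capillary"),
        (1, 2, d2, l2, "capillary"),
        (2, 3, parent_diameter, parent_length, "capillary"),
    ]
    return _assemble(nodes, edges)


def _toy_two_path_loop(
    inlet_diameter=6.0,
    path_diameters=(5.0, 4.0),
    path_lengths=(130.0, 170.0),
    tube_length=100.0,
):
    da, db = path_diameters
    la, lb = path_lengths
    nodes = [
        (0, 0, 50, True),
        (tube_length, 0, 50, False),
        (2 * tube_length, 0, 50, False),
        (3 * tube_length, 0, 50, True),
    ]
    edges = [
        (0, 1, inlet_diameter, tube_length, "capillary"),
        (1, 2, da, la, "capillary"),
        (1, 2, db, lb, "capillary"),
        (2, 3, inlet_diameter, tube_length, "capillary"),
    ]
    return _assemble(nodes, edges)


def _toy_honeycomb(rows=8, cols=8, edge_length=60.0, depth=60.0, diameter=4.0):
    """Planar hexagonal capillary sheet at fixed cortical depth.

    One penetrating-arteriole trunk feeds a corner, one ascending venule
    drains the opposite corner; nodes that remain degree-2 (the sheet's
    open perimeter) are flagged as domain boundary.
    """
    import networkx as nx

    g = nx.hexagonal_lattice_graph(rows, cols)
    mapping = {n: i for i, n in enumerate(sorted(g.nodes()))}
    xy = {mapping[n]: g.nodes[n]["pos"] for n in g.nodes()}
    edges_ll = [(mapping[a], mapping[b]) for a, b in g.edges()]
    n = len(xy)
    pos = np.zeros((n, 3))
    for i in range(n):
        pos[i] = (xy[i][0] * edge_length, xy[i][1] * edge_length, depth)
    deg = np.zeros(n, dtype=int)
    for a, b in edges_ll:
        deg[a] += 1
        deg[b] += 1

    nodes = [(pos[i, 0], pos[i, 1], pos[i, 2], bool(deg[i] <= 2)) for i in range(n)]
    edges = []
    for a, b in edges_ll:
        seg = float(np.linalg.norm(pos[a] - pos[b]))
        edges.append((a, b, diameter, seg * 1.05, "capillary"))

    # feed one corner, drain the opposite one, via short vertical trunks
    corner_in = int(np.argmin(pos[:, 0] + pos[:, 1]))
    corner_out = int(np.argmax(pos[:, 0] + pos[:, 1]))
    k = len(nodes)
    nodes.append((pos[corner_in, 0], pos[corner_in, 1], 0.0, True))  # pial art root
    nodes.append((pos[corner_in, 0] + 5.0, pos[corner_in, 1], 0.0, False))
    nodes.append((pos[corner_out, 0], pos[corner_out, 1], 0.0, True))  # pial vein root
    nodes.append((pos[corner_out, 0] + 5.0, pos[corner_out, 1], 0.0, False))
    edges.append((k, k + 1, 25.0, 10.0, "pial_artery"))
    edges.append((k + 1, corner_in, 12.0, depth * 1.05, "descending_arteriole"))
    edges.append((k + 2, k + 3, 30.0, 10.0, "pial_vein"))
    edges.append((k + 3, corner_out, 15.0, depth * 1.05, "ascending_venule"))
    # the trunk attachment corners are interior now
    nodes[corner_in] = (*nodes[corner_in][:3], False)
    nodes[corner_out] = (*nodes[corner_out][:3], False)
    return _assemble(nodes, edges)
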