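"""Vascular graph model: validation, I/O round-trip, branch orders, geometry."""

import io

import numpy as np
import pytest

from capnet.network import (
    NetworkValidationError,
    assign_branch_orders,
    euclidean_distance_to_center,
    load_network,
    save_network,
)

from conftest import build_network


def _y_tables():
    nodes = "id,x,y,z,is_boundary\n0,0,0,50,1\n1,100,0,50,0\n2,200,80,50,1\n3,200,-80,50,1\n"
    edges = (
        "id,node_a,node_b,diameter_um,length_um,vessel_type\n"
        "0,0,1,4,100,capillary\n1,1,2,3,130,capillary\n2,1,3,3,130,capillary\n"
    )
    return io.StringIO(nodes), io.StringIO(edges)


class TestLoadValidate:
    def test_smallest_divergent_bifurcation(self):
        net = load_network(*_y_tables())
        assert net.n_nodes == 4 and net.n_vessels == 3
        interior = ~net.is_boundary
        assert interior.sum() == 1 and net.degree()[interior][0] == 3

    def test_dangling_endpoint_names_edge_and_node(self):
        nodes = io.StringIO("id,x,y,z,is_boundary\n0,0,0,0,1\n1,10,0,0,1\n")
        edges = io.StringIO(
            "id,node_a,node_b,diameter_um,length_um,vessel_type\n7,0,99,4,10,capillary\n"
        )
        with pytest.raises(NetworkValidationError, match="7.*99"):
            load_network(nodes, edges)

    def test_missing_column_rejected(self):
        nodes = io.StringIO("id,x,y,is_boundary\n0,0,0,1\n")
        edges = io.StringIO(
            "id,node_a,node_b,diameter_um,length_um,vessel_type\n"
        )
        with pytest.raises(NetworkValidationError, match="missing column"):
            load_network(nodes, edges)

    @pytest.mark.parametrize(
        "mutate,match",
        [
            (lambda n: n.diameter.__setitem__(1, -1.0), "non-positive diameter"),
            (lambda n: n.length.__setitem__(0, 0.0), "non-positive length"),
            (lambda n: n.node_b.__setitem__(0, n.node_a[0]), "self-loop"),
            (lambda n: n.length.__setitem__(2, 1.0), "shorter than"),
            (lambda n: n.positions.__setitem__((0, 2), np.nan), "non-finite"),
            (lambda n: n.vessel_ids.__setitem__(1, n.vessel_ids[0]), "duplicate"),
        ],
    )
    def test_constructed_violations_rejected(self, mutate, match):
        net = load_network(*_y_tables())
        mutate(net)
        with pytest.raises(NetworkValidationError, match=match):
            net.validate()

    def test_disconnected_rejected(self):
        net = build_network(
            [(0, 0, 0, 0, True), (1, 10, 0, 0, True), (2, 50, 0, 0, True), (3, 60, 0, 0, True)],
            [(0, 0, 1, 4, 10, "capillary"), (1, 2, 3, 4, 10, "capillary")],
        )
        with pytest.raises(NetworkValidationError, match="connected"):
            net.validate()

    def test_interior_dead_end_flagged_not_rejected(self):
        net = build_network(
            [(0, 0, 0, 0, True), (1, 10, 0, 0, False), (2, 20, 0, 0, False)],
            [(0, 0, 1, 4, 10, "capillary"), (1, 1, 2, 4, 10, "capillary")],
        )
        with pytest.warns(UserWarning, match="degree-1"):
            warn = net.validate()
        assert len(warn) == 1

    def test_generator_output_accepted(self, mvn):
        assert mvn.validate() == []


class TestRoundTrip:
    def test_save_load_bit_equal(self, mvn, tmp_path):
        save_network(mvn, tmp_path / "nodes.csv", tmp_path / "edges.csv")
        back = load_network(tmp_path / "nodes.csv", tmp_path / "edges.csv")
        assert np.array_equal(back.node_ids, mvn.node_ids)
        assert np.array_equal(back.positions, mvn.positions)  # bit-exact floats
        assert np.array_equal(back.is_boundary, mvn.is_boundary)
        assert np.array_equal(back.vessel_ids, mvn.vessel_ids)
        assert np.array_equal(back.node_a, mvn.node_a)
        assert np.array_equal(back.node_b, mvn.node_b)
        assert np.array_equal(back.diameter, mvn.diameter)
        assert np.array_equal(back.length, mvn.length)
        assert np.array_equal(back.vessel_type.astype(str), mvn.vessel_type.astype(str))


def _hand_tree():
    """12-vessel arteriole/venule tree with hand-countable branch orders."""
    nodes = [
        (0, 0, 0, 0, True),  # pial artery root
        (1, 50, 0, 0, False),
        (2, 50, 0, 50, False),  # trunk node
        (3, 50, 0, 100, False),  # trunk tip
        (4, 120, 0, 50, False),
        (5, 190, 0, 50, False),
        (6, 120, 40, 100, False),
        (7, 260, 0, 50, False),
        (8, 260, 80, 50, False),
        (9, 320, 0, 50, False),
        (10, 320, 0, 0, False),
        (11, 380, 0, 0, True),  # pial vein root
    ]
    edges = [
        (0, 0, 1, 25, 55, "pial_artery"),
        (1, 1, 2, 15, 55, "descending_arteriole"),
        (2, 2, 3, 12, 55, "descending_arteriole"),
        (3, 2, 4, 4, 75, "capillary"),  # art order 1
        (4, 4, 5, 4, 75, "capillary"),  # art order 2
        (5, 4, 6, 4, 90, "capillary"),  # art order 2
        (6, 5, 7, 4, 75, "capillary"),  # art order 3
        (7, 7, 8, 4, 85, "capillary"),  # art order 4
        (8, 7, 9, 4, 65, "capillary"),  # art order 4, ven order 1
        (9, 9, 10, 14, 55, "ascending_venule"),
        (10, 10, 11, 28, 65, "pial_vein"),
        (11, 8, 9, 4, 105, "capillary"),  # ven order 1
    ]
    return build_network(nodes, edges)


class TestBranchOrders:
    def test_hand_counted_tree(self):
        net = assign_branch_orders(_hand_tree())
        art = dict(zip(net.vessel_ids.tolist(), net.branch_order_art.tolist()))
        ven = dict(zip(net.vessel_ids.tolist(), net.branch_order_ven.tolist()))
        assert art[0] == art[1] == art[2] == 0  # main branches
        assert art[3] == 1  # direct offshoot of the penetrating arteriole
        assert art[4] == art[5] == 2
        assert art[6] == 3 and art[7] == 4 and art[8] == 4
        assert ven[9] == ven[10] == 0
        assert ven[8] == 1 and ven[11] == 1
        assert ven[7] == 2 and ven[6] == 2

    def test_matches_networkx_bfs_oracle(self, mvn):
        import networkx as nx

        g = nx.Graph()
        for v in range(mvn.n_vessels):
            g.add_node(v)
        node_to_vessels = {}
        for v in range(mvn.n_vessels):
            for n in (int(mvn.node_a[v]), int(mvn.node_b[v])):
                node_to_vessels.setdefault(n, []).append(v)
        for vs in node_to_vessels.values():
            for i in range(len(vs)):
                for j in range(i + 1, len(vs)):
                    g.add_edge(vs[i], vs[j])
        sources = [
            v
            for v in range(mvn.n_vessels)
            if mvn.vessel_type[v] in ("pial_artery", "descending_arteriole")
        ]
        lengths = nx.multi_source_dijkstra_path_length(g, sources)
        expected = np.array([lengths.get(v, -1) for v in range(mvn.n_vessels)])
        assert np.array_equal(expected, mvn.branch_order_art)

    def test_invariant_to_enumeration_order(self):
        net = assign_branch_orders(_hand_tree())
        rng = np.random.default_rng(4)
        perm = rng.permutation(net.n_vessels)
        shuffled = net.copy()
        for arr in ("vessel_ids", "node_a", "node_b", "diameter", "length", "vessel_type"):
            setattr(shuffled, arr, getattr(net, arr)[perm])
        shuffled.branch_order_art = None
        shuffled.branch_order_ven = None
        shuffled.__post_init__()
        assign_branch_orders(shuffled)
        assert np.array_equal(shuffled.branch_order_art, net.branch_order_art[perm])
        assert np.array_equal(shuffled.branch_order_ven, net.branch_order_ven[perm])

    def test_missing_main_branch_errors(self):
        net = build_network(
            [(0, 0, 0, 0, True), (1, 10, 0, 0, True)],
            [(0, 0, 1, 4, 10, "capillary")],
        )
        with pytest.raises(NetworkValidationError, match="0th order"):
            assign_branch_orders(net)


class TestDistanceToCenter:
    def test_single_vessel_set_distance_zero(self):
        net = build_network(
            [(0, 0, 0, 0, True), (1, 10, 0, 0, True)],
            [(0, 0, 1, 4, 10, "capillary")],
        )
        d = euclidean_distance_to_center(net, [0])
        assert d[0] == pytest.approx(0.0)

    def test_symmetric_cross_equal_distances(self):
        nodes = [
            (0, 0, 0, 0, False),
            (1, 100, 0, 0, True),
            (2, -100, 0, 0, True),
            (3, 0, 100, 0, True),
            (4, 0, -100, 0, True),
        ]
        edges = [(i, 0, i + 1, 4, 100, "capillary") for i in range(4)]
        net = build_network(nodes, edges)
        d = euclidean_distance_to_center(net, [0, 1, 2, 3])
        assert np.allclose(d, d[0])

    def test_five_vessel_fixture_hand_arithmetic(self):
        # chain 0-1-2-3-4-5 on the x axis at 0,10,30,60,100,150
        xs = [0, 10, 30, 60, 100, 150]
        nodes = [(i, x, 0, 0, i in (0, 5)) for i, x in enumerate(xs)]
        edges = [
            (i, i, i + 1, 4, xs[i + 1] - xs[i], "capillary") for i in range(5)
        ]
        net = build_network(nodes, edges)
        vset = [1, 2]  # bifurcation nodes 1,2,3 -> centre x = (10+30+60)/3
        cx = (10 + 30 + 60) / 3
        d = euclidean_distance_to_center(net, vset)
        mids = [(xs[i] + xs[i + 1]) / 2 for i in range(5)]
        assert np.allclose(d, [abs(m - cx) for m in mids])

    def test_empty_set_errors(self, mvn):
        with pytest.raises(ValueError, match="empty"):
            euclidean_distance_to_center(mvn, [])
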