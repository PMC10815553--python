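import logging
import math

import networkx as nx
import numpy as np
import pytest

from actnet.dynamical_network import (
    CorrelationNetwork,
    Node,
    NodeSet,
    assign_nodes,
    build_network,
    contact_mask,
    correlation_matrix,
    helix_hops,
    ligand_anchor,
    optimal_paths,
    suboptimal_paths,
)
from actnet.io_formats import Trajectory
from actnet.synthetic_data import (
    TrajectorySpec,
    amplitude_for_correlation,
    make_correlated_trajectory,
)


def _traj_from_frames(frames, names, elements, res_ids, res_names):
    return Trajectory(
        coords=np.asarray(frames, dtype=float),
        atom_names=np.array(names),
        elements=np.array(elements),
        res_ids=np.array(res_ids),
        res_names=np.array(res_names),
        chain_ids=np.array(["A"] * len(names)),
    )


def _net_from_graph(G: nx.Graph) -> CorrelationNetwork:
    """Wrap an arbitrary weighted graph for the path machinery."""
    n = len(G)
    nodes = NodeSet([Node(nid, "residue", k) for k, nid in enumerate(sorted(G))])
    return CorrelationNetwork(nodes=nodes, C=np.eye(n), mask=np.zeros((n, n), bool), graph=G)


def _enumeration_oracle(G, source, sink, offset):
    """Exhaustive simple-path enumeration; distances summed in path order to
    match the implementation's floating-point arithmetic bit for bit."""
    paths, dists = [], []
    for p in nx.all_simple_paths(G, source, sink):
        d = 0.0
        for u, v in zip(p, p[1:]):
            d += G.edges[u, v]["weight"]
        paths.append(p)
        dists.append(d)
    if not paths:
        return [], []
    d_opt = min(dists)
    keep = [
        (d, p)
        for p, d in zip(paths, dists)
        if d <= d_opt + 1e-9 or (offset > 0 and d < d_opt + offset)
    ]
    keep.sort(key=lambda t: (t[0], t[1]))
    return [p for _, p in keep], [d for d, _ in keep]


class TestAssignNodes:
    def test_protein_plus_ligand_counts(self):
        traj = _traj_from_frames(
            np.zeros((1, 6, 3)),
            ["CA"] * 5 + ["N1"],
            ["C"] * 5 + ["N"],
            [1, 2, 3, 4, 5, 9],
            ["GLY", "ALA", "GLY", "SER", "GLY", "LIG"],
        )
        nodes = assign_nodes(traj, "LIG", "N1")
        assert len(nodes) == 6
        assert nodes.ligand_ids() == {9}

    def test_missing_ligand_nitrogen_rejected(self):
        traj = _traj_from_frames(
            np.zeros((1, 2, 3)),
            ["CA", "N2"],
            ["C", "N"],
            [1, 9],
            ["GLY", "LIG"],
        )
        with pytest.raises(KeyError, match="N1"):
            assign_nodes(traj, "LIG", "N1")

    def test_glycine_uses_ca_like_any_residue(self):
        traj = _traj_from_frames(
            np.zeros((1, 2, 3)), ["CA", "CA"], ["C", "C"], [1, 2], ["GLY", "GLY"]
        )
        nodes = assign_nodes(traj)
        assert [n.kind for n in nodes.nodes] == ["residue", "residue"]


class TestCorrelationMatrix:
    def test_identical_displacements_give_one(self, rng):
        disp = rng.normal(size=(20, 1, 3))
        base = np.zeros((20, 2, 3))
        base[:, 0] = disp[:, 0]
        base[:, 1] = disp[:, 0] + 5.0  # same motion, offset position
        traj = _traj_from_frames(base, ["CA", "CA"], ["C", "C"], [1, 2], ["GLY", "GLY"])
        C = correlation_matrix(traj, assign_nodes(traj))
        assert C[0, 1] == pytest.approx(1.0)

    def test_negated_displacements_give_minus_one(self, rng):
        disp = rng.normal(size=(20, 3))
        base = np.zeros((20, 2, 3))
        base[:, 0] = disp
        base[:, 1] = -disp + 5.0
        traj = _traj_from_frames(base, ["CA", "CA"], ["C", "C"], [1, 2], ["GLY", "GLY"])
        C = correlation_matrix(traj, assign_nodes(traj))
        assert C[0, 1] == pytest.approx(-1.0)

    def test_hand_evaluated_covariance_formula(self, rng):
        """3-node, 4-frame toy equals the explicit covariance formula."""
        coords = rng.normal(size=(4, 3, 3))
        traj = _traj_from_frames(
            coords, ["CA"] * 3, ["C"] * 3, [1, 2, 3], ["GLY"] * 3
        )
        C = correlation_matrix(traj, assign_nodes(traj))
        delta = coords - coords.mean(axis=0)
        for i in range(3):
            for j in range(3):
                num = sum(float(delta[f, i] @ delta[f, j]) for f in range(4)) / 4
                den = math.sqrt(
                    (sum(float(delta[f, i] @ delta[f, i]) for f in range(4)) / 4)
                    * (sum(float(delta[f, j] @ delta[f, j]) for f in range(4)) / 4)
                )
                assert C[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        coords = rng.normal(size=(30, 5, 3))
        traj = _traj_from_frames(
            coords, ["CA"] * 5, ["C"] * 5, list(range(1, 6)), ["GLY"] * 5
        )
        C = correlation_matrix(traj, assign_nodes(traj))
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)
        assert np.all(np.abs(C) <= 1.0 + 1e-12)

    def test_frozen_node_rejected(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 0, 0] = np.arange(5)
        traj = _traj_from_frames(
            coords, ["CA", "CA"], ["C", "C"], [1, 2], ["GLY", "GLY"]
        )
        with pytest.raises(ValueError, match="zero total fluctuation"):
            correlation_matrix(traj, assign_nodes(traj))


class TestContactMask:
    def _two_residue_traj(self, dists):
        frames = np.zeros((len(dists), 2, 3))
        frames[:, 1, 0] = dists
        return _traj_from_frames(
            frames, ["CA", "CA"], ["C", "C"], [1, 5], ["GLY", "GLY"]
        )

    def test_contact_rules(self):
        traj = self._two_residue_traj([3.0] * 4)
        nodes = assign_nodes(traj)
        assert contact_mask(traj, nodes)[0, 1]
        # 50% of frames in contact < 75% requirement
        traj2 = self._two_residue_traj([3.0, 3.0, 9.0, 9.0])
        assert not contact_mask(traj2, assign_nodes(traj2))[0, 1]

    def test_mask_symmetric(self, rng):
        coords = rng.uniform(0, 10, size=(6, 4, 3))
        traj = _traj_from_frames(
            coords, ["CA"] * 4, ["C"] * 4, [1, 3, 5, 7], ["GLY"] * 4
        )
        mask = contact_mask(traj, assign_nodes(traj))
        np.testing.assert_array_equal(mask, mask.T)

    def test_hydrogens_excluded_from_distance(self):
        # hydrogen 3 Å away but heavy atoms 8 Å apart -> no contact
        frames = np.zeros((2, 3, 3))
        frames[:, 1, 0] = 3.0  # H of residue 1
        frames[:, 2, 0] = 8.0  # CA of residue 5
        traj = _traj_from_frames(
            frames, ["CA", "HA", "CA"], ["C", "H", "C"], [1, 1, 5], ["GLY", "GLY", "GLY"]
        )
        assert not contact_mask(traj, assign_nodes(traj))[0, 1]


class TestBuildNetwork:
    def _simple(self, C, mask, res_ids):
        nodes = NodeSet(
            [Node(rid, "residue", k) for k, rid in enumerate(res_ids)]
        )
        return build_network(np.asarray(C, float), np.asarray(mask, bool), nodes)

    def test_sequence_neighbours_excluded(self):
        C = [[1, 0.9], [0.9, 1]]
        mask = [[False, True], [True, False]]
        net = self._simple(C, mask, [4, 5])
        assert net.graph.number_of_edges() == 0

    def test_weight_values(self):
        C = [[1, 1.0, 0.5], [1.0, 1, 0.0], [0.5, 0.0, 1]]
        mask = [[False, True, True], [True, False, True], [True, True, False]]
        net = self._simple(C, mask, [1, 5, 9])
        assert net.weight(1, 5) == pytest.approx(0.0)  # |C|=1
        assert net.weight(1, 9) == pytest.approx(math.log(2), abs=1e-12)  # -ln 0.5
        assert not net.graph.has_edge(5, 9)  # |C|=0 -> no edge

    def test_weight_monotone_in_correlation(self):
        cs = np.linspace(0.05, 1.0, 12)
        ws = []
        for c in cs:
            net = self._simple(
                [[1, c], [c, 1]], [[False, True], [True, False]], [1, 9]
            )
            ws.append(net.weight(1, 9))
        assert all(w1 >= w2 - 1e-12 for w1, w2 in zip(ws, ws[1:]))
        assert all(w >= 0 for w in ws)


class TestPathsAgainstEnumeration:
    def _random_graph(self, rng, n):
        G = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
        H = nx.Graph()
        H.add_nodes_from(G.nodes)
        for u, v in G.edges:
            H.add_edge(u, v, weight=float(rng.uniform(0.05, 3.0)))
        return H

    def test_source_equals_sink(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        ps = optimal_paths(_net_from_graph(G), 0, 0)
        assert ps.paths == [[0]]
        assert ps.optimal_distance == 0.0

    def test_two_node_graph(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=0.7)
        ps = optimal_paths(_net_from_graph(G), 0, 1)
        assert ps.paths == [[0, 1]]
        assert ps.optimal_distance == pytest.approx(0.7)

    def test_disconnected_is_flagged_not_raised(self):
        G = nx.Graph()
        G.add_nodes_from([0, 1])
        ps = optimal_paths(_net_from_graph(G), 0, 1)
        assert ps.disconnected
        assert ps.paths == []

    def test_optimal_matches_enumeration_on_random_graphs(self, rng):
        for _ in range(40):
            G = self._random_graph(rng, int(rng.integers(4, 9)))
            net = _net_from_graph(G)
            src, snk = 0, max(G.nodes)
            ps = optimal_paths(net, src, snk)
            oracle_paths, oracle_d = _enumeration_oracle(G, src, snk, 0.0)
            assert ps.paths == oracle_paths
            assert ps.distances == oracle_d

    def test_suboptimal_matches_enumeration_on_random_graphs(self, rng):
        for _ in range(40):
            G = self._random_graph(rng, int(rng.integers(4, 9)))
            net = _net_from_graph(G)
            offset = float(rng.uniform(0.0, 6.0))
            src, snk = 0, max(G.nodes)
            ps = suboptimal_paths(net, src, snk, offset)
            oracle_paths, oracle_d = _enumeration_oracle(G, src, snk, offset)
            assert ps.paths == oracle_paths
            assert ps.distances == oracle_d

    def test_five_node_toy_graph_exact(self):
        G = nx.Graph()
        for u, v, w in [
            (0, 1, 1.0), (1, 4, 1.0), (0, 2, 1.5), (2, 4, 1.5),
            (0, 3, 0.5), (3, 4, 4.0), (1, 2, 0.2),
        ]:
            G.add_edge(u, v, weight=w)
        net = _net_from_graph(G)
        ps = suboptimal_paths(net, 0, 4, offset=1.5)
        oracle_paths, oracle_d = _enumeration_oracle(G, 0, 4, 1.5)
        assert ps.paths == oracle_paths
        assert ps.optimal == [0, 1, 4]
        assert ps.optimal_distance == pytest.approx(2.0)

    def test_offset_zero_only_optimal(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_edge(0, 2, weight=1.0)
        G.add_edge(2, 1, weight=0.5)
        net = _net_from_graph(G)
        ps = suboptimal_paths(net, 0, 1, offset=0.0)
        assert ps.paths == [[0, 1]]

    def test_tied_optima_all_reported(self):
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_edge(0, 2, weight=0.5)
        G.add_edge(2, 1, weight=0.5)
        ps = optimal_paths(_net_from_graph(G), 0, 1)
        assert ps.paths == [[0, 1], [0, 2, 1]]
        assert ps.N == 2

    def test_strict_offset_bound(self):
        # alternative path exactly offset longer must be excluded
        G = nx.Graph()
        G.add_edge(0, 1, weight=1.0)
        G.add_edge(0, 2, weight=1.5)
        G.add_edge(2, 1, weight=1.5)
        net = _net_from_graph(G)
        ps = suboptimal_paths(net, 0, 1, offset=2.0)  # alt = 3.0 = 1.0 + 2.0
        assert ps.paths == [[0, 1]]
        ps2 = suboptimal_paths(net, 0, 1, offset=2.0 + 1e-6)
        assert len(ps2.paths) == 2

    def test_suboptimal_set_shrinks_with_offset(self, rng):
        G = self._random_graph(rng, 8)
        net = _net_from_graph(G)
        counts = [
            suboptimal_paths(net, 0, 7, off).N for off in (6.0, 3.0, 1.0, 0.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_distances_within_bound_invariant(self, rng):
        G = self._random_graph(rng, 8)
        net = _net_from_graph(G)
        ps = suboptimal_paths(net, 0, 7, offset=4.0)
        if not ps.disconnected:
            for d in ps.distances:
                assert ps.optimal_distance - 1e-9 <= d
                assert d < ps.optimal_distance + 4.0 + 1e-9


class TestLigandAnchor:
    def _net(self, weights):
        G = nx.Graph()
        for rid, w in weights.items():
            G.add_edge(900, rid, weight=w)
        return _net_from_graph(G)

    def test_single_edge(self):
        assert ligand_anchor(self._net({115: 0.4}), 900) == 115

    def test_argmin_weight(self):
        net = self._net({110: 0.9, 115: 0.3, 120: 1.2})
        assert ligand_anchor(net, 900) == 115

    def test_tie_breaks_to_lower_residue_id(self, caplog):
        net = self._net({120: 0.3, 115: 0.3})
        with caplog.at_level(logging.INFO):
            assert ligand_anchor(net, 900) == 115

    def test_isolated_ligand_rejected(self):
        G = nx.Graph()
        G.add_nodes_from([900, 1])
        with pytest.raises(ValueError, match="no network edges"):
            ligand_anchor(_net_from_graph(G), 900)


class TestHelixHops:
    def test_single_helix_path(self, bw_map):
        path = [332, 336, 340]  # all TMH3 in the toy numbering
        hh = helix_hops(path, bw_map)
        assert hh.segments == [("TMH3", [332, 336, 340])]
        assert hh.n_transfers == 0

    def test_ligand_and_two_helices(self, bw_map):
        path = [900, 336, 340, 644, 629]
        hh = helix_hops(path, bw_map, ligand_ids={900})
        assert [label for label, _ in hh.segments] == ["ligand", "TMH3", "TMH6"]
        assert hh.segments[1][1] == [336, 340]
        assert hh.n_transfers == 2

    def test_concatenation_reproduces_path(self, bw_map, rng):
        ids = [e.residue_id for e in bw_map.entries]
        path = [900] + list(rng.choice(ids, size=5, replace=False))
        hh = helix_hops(path, bw_map, ligand_ids={900})
        assert hh.flatten() == path

    def test_empty_path_rejected(self, bw_map):
        with pytest.raises(ValueError):
            helix_hops([], bw_map)


class TestCorrelationRecovery:
    def test_planted_correlation_recovered(self):
        """Estimated C converges to the planted ρ within 3 standard errors."""
        sigma = 0.15
        for rho in (0.2, 0.5, 0.8):
            a = amplitude_for_correlation(rho, sigma)
            spec = TrajectorySpec(
                node_ids=[1, 5, 9],
                n_frames=5000,
                noise_sd=sigma,
                groups=[([1, 5], a)],
                seed=int(rho * 100),
            )
            traj = make_correlated_trajectory(spec)
            nodes = assign_nodes(traj)
            C = correlation_matrix(traj, nodes)
            se = (1 - rho**2) / np.sqrt(spec.n_frames)
            assert abs(C[0, 1] - rho) < 3 * se, f"rho={rho}: got {C[0, 1]}"

    def test_planted_pathway_traversed(self):
        """Optimal path follows the dominantly correlated chain."""
        sigma = 0.15
        a = amplitude_for_correlation(0.8, sigma)
        # a six-membered contact ring: strong correlations on one side,
        # weak on the other; the optimal path must take the strong side
        spec = TrajectorySpec(
            node_ids=[101, 103, 105, 107, 109, 111],
            n_frames=2000,
            noise_sd=sigma,
            groups=[
                ([101, 103], a), ([103, 105], a), ([105, 107], a),
                ([101, 109], 0.3 * a), ([109, 111], 0.3 * a), ([111, 107], 0.3 * a),
            ],
            contacts=[
                (101, 103), (103, 105), (105, 107),
                (101, 109), (109, 111), (111, 107),
            ],
            seed=99,
        )
        traj = make_correlated_trajectory(spec)
        nodes = assign_nodes(traj)
        net = build_network(
            correlation_matrix(traj, nodes), contact_mask(traj, nodes), nodes
        )
        ps = optimal_paths(net, 101, 107)
        assert ps.optimal == [101, 103, 105, 107]
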