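"""Dynamical network analysis of residue–ligand communication.

A trajectory is reduced to a weighted graph: one node per protein residue
(anchored at its Cα) plus one node for the ligand (anchored at its basic
nitrogen).  Edges connect node pairs whose residues stay in heavy-atom
contact for most of the trajectory, excluding pairs within the same residue
and sequence nearest neighbours; each admitted edge carries the weight

    w_ij = -log |C_ij|

where C_ij is the normalised correlation of the two anchor atoms' motion.
Strongly (anti)correlated contacts are short edges, so shortest paths in
this graph are the most probable routes of mechanical information transfer.
The path machinery reports the optimal (minimum total weight) simple path
between a source and sink together with every suboptimal simple path whose
length stays within a fixed offset of the optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bw_mapping import BWMapping
from .io_formats import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "NodeSet",
    "CorrelationNetwork",
    "PathSet",
    "HelixHopSummary",
    "PathCountError",
    "assign_nodes",
    "correlation_matrix",
    "contact_mask",
    "build_network",
    "optimal_paths",
    "suboptimal_paths",
    "ligand_anchor",
    "helix_hops",
]

#: float slack when comparing path distances for ties
_TIE_TOL = 1e-9


class PathCountError(RuntimeError):
    """Raised when path enumeration exceeds the configured cap."""


@dataclass(frozen=True)
class Node:
    node_id: int  # residue sequence id (ligand keeps its own residue id)
    kind: str  # "residue" | "ligand"
    anchor_atom: int  # index into the trajectory's atom arrays


@dataclass
class NodeSet:
    nodes: list[Node]

    def __post_init__(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("node ids must be unique")

    @property
    def ids(self) -> list[int]:
        return [n.node_id for n in self.nodes]

    @property
    def anchor_atoms(self) -> np.ndarray:
        return np.array([n.anchor_atom for n in self.nodes], dtype=int)

    def __len__(self) -> int:
        return len(self.nodes)

    def index_of(self, node_id: int) -> int:
        for i, n in enumerate(self.nodes):
            if n.node_id == node_id:
                return i
        raise KeyError(f"no node with id {node_id}")

    def ligand_ids(self) -> set[int]:
        return {n.node_id for n in self.nodes if n.kind == "ligand"}


@dataclass
class CorrelationNetwork:
    """Node set, motion-correlation matrix and the admitted weighted edges."""

    nodes: NodeSet
    C: np.ndarray
    mask: np.ndarray
    graph: nx.Graph = field(repr=False)

    def weight(self, u: int, v: int) -> float:
        return self.graph.edges[u, v]["weight"]


@dataclass
class PathSet:
    """Optimal and suboptimal communication paths between two nodes.

    ``paths`` is sorted by (distance, node sequence); optimal paths come
    first.  ``n`` is the node count of the optimal path, ``N`` the number of
    paths listed — the per-complex path degeneracy.
    """

    source: int
    sink: int
    paths: list[list[int]]
    distances: list[float]
    optimal_distance: float | None
    offset: float
    disconnected: bool = False

    @property
    def n(self) -> int | None:
        return len(self.paths[0]) if self.paths else None

    @property
    def N(self) -> int:
        return len(self.paths)

    @property
    def optimal(self) -> list[int] | None:
        return self.paths[0] if self.paths else None


@dataclass
class HelixHopSummary:
    """A path segmented into helix runs and inter-segment transfers."""

    segments: list[tuple[str, list[int]]]  # (label, node ids)
    n_transfers: int

    def flatten(self) -> list[int]:
        return [nid for _, seg in self.segments for nid in seg]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def assign_nodes(
    traj: Trajectory,
    ligand_resname: str = "LIG",
    ligand_nitrogen: str = "N1",
) -> NodeSet:
    """One node per protein residue (Cα anchor) plus one ligand node.

    The ligand node is anchored at its basic (protonated) nitrogen, named
    explicitly because a ligand may carry several nitrogens.
    """
    nodes: list[Node] = []
    ligand_found = False
    for rid in traj.residue_ids():
        resname = traj.residue_name(rid)
        if resname == ligand_resname:
            try:
                anchor = traj.atom_index(rid, ligand_nitrogen)
            except KeyError:
                raise KeyError(
                    f"ligand residue {rid} ({ligand_resname}) has no atom "
                    f"{ligand_nitrogen!r}"
                ) from None
            nodes.append(Node(rid, "ligand", anchor))
            ligand_found = True
        else:
            try:
                anchor = traj.atom_index(rid, "CA")
            except KeyError:
                raise KeyError(f"residue {rid} ({resname}) has no CA atom") from None
            nodes.append(Node(rid, "residue", anchor))
    if not ligand_found:
        logger.info("assign_nodes: no ligand residue %r found", ligand_resname)
    return NodeSet(nodes)


def correlation_matrix(traj: Trajectory, nodes: NodeSet) -> np.ndarray:
    """Normalised motion correlation of the node anchor atoms.

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>) with Δr_i(t) the anchor
    atom's 3-D displacement from its trajectory-mean position (the classic
    dynamical cross-correlation map).  Symmetric with unit diagonal.
    """
    if traj.n_frames < 2:
        raise ValueError("correlation requires at least two frames")
    coords = traj.coords[:, nodes.anchor_atoms, :]  # (F, n, 3)
    delta = coords - coords.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", delta, delta) / traj.n_frames
    var = np.diag(cov)
    frozen = [nodes.ids[i] for i in np.flatnonzero(var <= 0)]
    if frozen:
        raise ValueError(
            f"nodes with zero total fluctuation (correlations undefined): {frozen}"
        )
    denom = np.sqrt(np.outer(var, var))
    C = cov / denom
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def contact_mask(
    traj: Trajectory,
    nodes: NodeSet,
    cutoff: float = 4.5,
    frame_fraction: float = 0.75,
) -> np.ndarray:
    """Persistent heavy-atom contact mask between node residues.

    mask_ij is true iff the minimum heavy-atom distance between the two
    nodes' residues is ≤ ``cutoff`` Å in at least ``frame_fraction`` of the
    frames.  Only heavy (non-hydrogen) atoms enter the distance.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be positive")
    if not 0 < frame_fraction <= 1:
        raise ValueError("frame_fraction must be in (0, 1]")
    n = len(nodes)
    heavy = traj.heavy_mask
    # heavy atoms grouped by node, contiguous for a reduceat-style reduction
    atom_idx: list[np.ndarray] = []
    for node in nodes.nodes:
        idx = traj.atoms_of_residue(node.node_id, heavy_only=True)
        if idx.size == 0:
            raise ValueError(f"node {node.node_id} has no heavy atoms")
        atom_idx.append(idx)
    flat = np.concatenate(atom_idx)
    starts = np.cumsum([0] + [len(a) for a in atom_idx])[:-1]
    counts = np.zeros((n, n), dtype=int)
    cut2 = cutoff * cutoff
    for f in range(traj.n_frames):
        pts = traj.coords[f][flat]
        diff = pts[:, None, :] - pts[None, :, :]
        d2 = (diff**2).sum(axis=-1)
        red = np.minimum.reduceat(d2, starts, axis=0)
        red = np.minimum.reduceat(red, starts, axis=1)
        counts += red <= cut2
    mask = counts >= math.ceil(frame_fraction * traj.n_frames)
    np.fill_diagonal(mask, False)
    return mask


def build_network(
    C: np.ndarray,
    mask: np.ndarray,
    nodes: NodeSet,
    min_sequence_separation: int = 2,
) -> CorrelationNetwork:
    """Admit edges and assign weights w = -log|C|.

    An edge i–j is admitted when the contact mask is true, the pair is not a
    sequence nearest-neighbour pair of protein residues (|res_i - res_j| ≥
    ``min_sequence_separation``), and |C_ij| > 0.  Perfect correlation gives
    weight 0; weaker correlation gives longer edges.
    """
    n = len(nodes)
    if C.shape != (n, n) or mask.shape != (n, n):
        raise ValueError("C and mask must be square over the node set")
    G = nx.Graph()
    G.add_nodes_from(nodes.ids)
    ids = nodes.ids
    kinds = [nd.kind for nd in nodes.nodes]
    for i in range(n):
        for j in range(i + 1, n):
            if not mask[i, j]:
                continue
            if (
                kinds[i] == "residue"
                and kinds[j] == "residue"
                and abs(ids[i] - ids[j]) < min_sequence_separation
            ):
                continue
            c = abs(C[i, j])
            if c <= 0.0:
                continue
            w = max(0.0, -math.log(min(c, 1.0)))
            G.add_edge(ids[i], ids[j], weight=w, correlation=float(C[i, j]))
    return CorrelationNetwork(nodes=nodes, C=C, mask=mask, graph=G)


# ---------------------------------------------------------------------------
# path search
# ---------------------------------------------------------------------------


def _path_distance(G: nx.Graph, path: list[int]) -> float:
    d = 0.0
    for u, v in zip(path, path[1:]):
        d += G.edges[u, v]["weight"]
    return d


def _enumerate_bounded(
    G: nx.Graph,
    source: int,
    sink: int,
    bound: float,
    strict_extra: float,
    max_paths: int,
) -> tuple[list[list[int]], list[float]]:
    """All simple paths with distance admitted by the bound.

    A path is admitted when its distance d satisfies d < bound + strict_extra
    (strict) or d ≤ bound (ties with the optimum, tolerance ``_TIE_TOL``).
    Branch-and-bound pruning uses exact Dijkstra potentials to the sink.
    """
    # exact shortest distance from every node to the sink (undirected graph)
    potential = nx.single_source_dijkstra_path_length(G, sink, weight="weight")
    limit = bound + strict_extra
    paths: list[list[int]] = []
    dists: list[float] = []
    frames: list[tuple[int, float, list[int]]] = []
    if source in potential:
        frames.append((source, 0.0, [source]))
    while frames:
        node, dist, cur = frames.pop()
        if node == sink:
            # optimal paths (dist == bound, within tolerance) are always
            # admitted; suboptimal paths must be strictly below the limit
            if dist <= bound + _TIE_TOL or (strict_extra > 0.0 and dist < limit):
                paths.append(cur)
                dists.append(dist)
                if len(paths) > max_paths:
                    raise PathCountError(
                        f"more than {max_paths} paths within the offset; "
                        "raise max_paths to enumerate them all"
                    )
            continue
        for nbr in G.neighbors(node):
            if nbr in cur:
                continue
            h = potential.get(nbr)
            if h is None:
                continue
            nd = dist + G.edges[node, nbr]["weight"]
            if nd + h > limit + _TIE_TOL:
                # no completion through nbr can be admitted
                continue
            frames.append((nbr, nd, cur + [nbr]))
    return paths, dists


def _sorted_pathset(paths, dists):
    order = sorted(range(len(paths)), key=lambda k: (dists[k], paths[k]))
    return [paths[k] for k in order], [dists[k] for k in order]


def optimal_paths(
    net: CorrelationNetwork, source: int, sink: int, max_paths: int = 100000
) -> PathSet:
    """All minimum-total-weight simple paths between source and sink.

    Ties are all reported (sorted by node sequence).  An unreachable sink
    yields a ``disconnected`` PathSet rather than an exception.
    """
    G = net.graph
    for nid in (source, sink):
        if nid not in G:
            raise KeyError(f"node {nid} not in network")
    if source == sink:
        return PathSet(source, sink, [[source]], [0.0], 0.0, 0.0)
    try:
        d_opt = nx.dijkstra_path_length(G, source, sink, weight="weight")
    except nx.NetworkXNoPath:
        logger.info("optimal_paths: %s and %s are disconnected", source, sink)
        return PathSet(source, sink, [], [], None, 0.0, disconnected=True)
    paths, dists = _enumerate_bounded(G, source, sink, d_opt, 0.0, max_paths)
    paths, dists = _sorted_pathset(paths, dists)
    return PathSet(source, sink, paths, dists, d_opt, 0.0)


def suboptimal_paths(
    net: CorrelationNetwork,
    source: int,
    sink: int,
    offset: float = 20.0,
    max_paths: int = 100000,
) -> PathSet:
    """Optimal plus all suboptimal simple paths within ``offset`` of optimal.

    Suboptimal paths must be *strictly* less than ``offset`` longer than the
    optimal path; optimal paths themselves are always included (so offset 0
    degenerates to :func:`optimal_paths`).  Paths are sorted by distance and
    then lexicographically by node sequence.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    G = net.graph
    for nid in (source, sink):
        if nid not in G:
            raise KeyError(f"node {nid} not in network")
    if source == sink:
        return PathSet(source, sink, [[source]], [0.0], 0.0, offset)
    try:
        d_opt = nx.dijkstra_path_length(G, source, sink, weight="weight")
    except nx.NetworkXNoPath:
        logger.info("suboptimal_paths: %s and %s are disconnected", source, sink)
        return PathSet(source, sink, [], [], None, offset, disconnected=True)
    paths, dists = _enumerate_bounded(G, source, sink, d_opt, offset, max_paths)
    paths, dists = _sorted_pathset(paths, dists)
    return PathSet(source, sink, paths, dists, d_opt, offset)


def ligand_anchor(net: CorrelationNetwork, ligand_node: int) -> int:
    """The ligand-adjacent residue with the lightest (strongest) edge.

    Communication is assumed to start at the residue whose contact with the
    ligand the network weights most strongly, i.e. the minimum-weight ligand
    edge.  Ties break toward the lower residue id (logged).
    """
    G = net.graph
    nbrs = list(G.neighbors(ligand_node))
    if not nbrs:
        raise ValueError(f"ligand node {ligand_node} has no network edges")
    weights = {nbr: G.edges[ligand_node, nbr]["weight"] for nbr in nbrs}
    best_w = min(weights.values())
    best = sorted(nbr for nbr, w in weights.items() if abs(w - best_w) <= _TIE_TOL)
    if len(best) > 1:
        logger.info(
            "ligand_anchor: tie between %s at weight %.6f; choosing %s",
            best,
            best_w,
            best[0],
        )
    return best[0]


def helix_hops(
    path: list[int], mapping: BWMapping, ligand_ids: set[int] | frozenset[int] = frozenset()
) -> HelixHopSummary:
    """Segment a path into maximal same-helix runs.

    Transitions between consecutive segments are inter-helix (or
    helix↔ligand/loop) signal transfers.  Ligand and loop nodes each form
    their own singleton segment.
    """
    if not path:
        raise ValueError("path must be non-empty")
    segments: list[tuple[str, list[int]]] = []
    for nid in path:
        if nid in ligand_ids:
            label = "ligand"
        else:
            helix = mapping.helix_of(nid)
            label = f"TMH{helix}" if helix is not None else "loop"
        if (
            segments
            and segments[-1][0] == label
            and label.startswith("TMH")
        ):
            segments[-1][1].append(nid)
        else:
            segments.append((label, [nid]))
    return HelixHopSummary(segments=segments, n_transfers=len(segments) - 1)
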