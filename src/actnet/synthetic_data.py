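"""Synthetic inputs for every stage of the pipeline.

Real inputs of this analysis are 100-ns all-atom MD trajectories and
quantum-chemical (FMO) energy tables, neither of which can be produced at
desk scale.  The generators here emulate exactly the statistical structure
the downstream analyses consume:

* :func:`make_correlated_trajectory` — point-residue trajectories with
  planted pairwise motion correlations (shared Gaussian modes along fixed
  directions plus isotropic noise) and planted persistent contacts, with an
  analytically known correlation for recovery tests;
* :func:`make_toy_gpcr` — a minimal seven-helix Cα-plus-side-chain receptor
  whose six activation-microswitch distances equal prescribed active- or
  inactive-state targets, optionally with a planted ligand→R6.29
  communication chain;
* :func:`make_pieda_tables` — per-residue interaction-energy tables with
  controlled contact probabilities, component mixtures and a prescribed
  minority of repulsive contacts.

All generators are bit-deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bw_mapping import BWEntry, BWMapping
from .io_formats import PIEDATable, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectorySpec",
    "GeometrySpec",
    "PIEDASpec",
    "amplitude_for_correlation",
    "planted_correlation",
    "make_correlated_trajectory",
    "make_toy_gpcr",
    "make_pieda_tables",
    "ACTIVE_TARGETS",
    "INACTIVE_TARGETS",
]


# ---------------------------------------------------------------------------
# correlated point trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySpec:
    """Recipe for a planted-correlation trajectory.

    Node ids are residue sequence ids; the optional ligand node gets residue
    name ``LIG`` with a single nitrogen atom ``N1``, every other node is a
    one-Cα glycine.  ``groups`` are (member ids, amplitude a) shared-motion
    modes: every member of a group is displaced by a·s(t) along the group's
    fixed unit direction, where s(t) is standard normal per frame.  On top,
    every node gets isotropic Gaussian noise of standard deviation σ per
    coordinate.  ``contacts`` pairs are placed within ``contact_distance`` Å
    in the base geometry (and therefore in essentially all frames).
    """

    node_ids: list[int]
    n_frames: int = 1000
    frame_interval: float = 0.1  # ns
    groups: list[tuple[list[int], float]] = field(default_factory=list)
    noise_sd: float = 0.15  # Å per coordinate; correlations depend only on
    # the amplitude/noise ratio, and this scale keeps planted contacts
    # persistent under the default 4.5 Å cutoff
    contacts: list[tuple[int, int]] = field(default_factory=list)
    contact_distance: float = 3.2  # Å between planted-contact anchors
    ligand_id: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValueError("node ids must be unique")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if any(a < 0 for _, a in self.groups):
            raise ValueError("group amplitudes must be non-negative")
        ids = set(self.node_ids)
        for members, _ in self.groups:
            if not set(members) <= ids:
                raise ValueError(f"group members {members} not all in node_ids")
        seen = set()
        for i, j in self.contacts:
            if {i, j} - ids:
                raise ValueError(f"contact pair ({i}, {j}) not in node_ids")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(
                    f"contact pair ({i}, {j}) planted twice; constraints are "
                    "jointly infeasible or redundant"
                )
            seen.add(key)
        if self.ligand_id is not None and self.ligand_id not in ids:
            raise ValueError("ligand_id must be one of node_ids")


def planted_correlation(a_i: float, a_j: float, shared_a: float, sigma: float) -> float:
    """Implied 3-D motion correlation of two nodes sharing one mode.

    For nodes whose total mode amplitudes (root-sum-square over their groups)
    are a_i and a_j, sharing exactly one mode of amplitude ``shared_a`` along
    a common direction, the displacement-dot-product correlation estimated by
    the network module is

        ρ = shared_a² / sqrt((a_i² + 3σ²)(a_j² + 3σ²)),

    since the shared mode contributes variance a² along one axis while the
    isotropic noise contributes σ² per axis.
    """
    return shared_a**2 / np.sqrt((a_i**2 + 3 * sigma**2) * (a_j**2 + 3 * sigma**2))


def amplitude_for_correlation(rho: float, sigma: float) -> float:
    """Mode amplitude giving 3-D correlation ρ for a two-node, one-mode group.

    Inverts ρ = a²/(a² + 3σ²): a = σ·sqrt(3ρ/(1−ρ)).
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    return sigma * np.sqrt(3.0 * rho / (1.0 - rho))


#: minimum base-geometry distance between non-contact nodes of one cluster,
#: kept a safe margin above the default 4.5 Å contact cutoff
_MIN_SEPARATION = 5.5


def _layout_component(
    members: list[int],
    pairs: list[tuple[int, int]],
    distance: float,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Embed one contact component in 3-D by constrained least squares.

    Planted pairs are placed at exactly ``distance``; all other member pairs
    are pushed beyond ``_MIN_SEPARATION`` by a hinge penalty.  Raises when no
    embedding satisfies both (jointly infeasible constraints).
    """
    from scipy.optimize import least_squares

    m = len(members)
    index = {nid: k for k, nid in enumerate(members)}
    planted = [(index[i], index[j]) for i, j in pairs]
    others = [
        (a, b)
        for a in range(m)
        for b in range(a + 1, m)
        if (a, b) not in planted and (b, a) not in planted
    ]

    def residuals(x):
        p = x.reshape(m, 3)
        res = []
        for a, b in planted:
            res.append(np.linalg.norm(p[a] - p[b]) - distance)
        for a, b in others:
            gap = _MIN_SEPARATION - np.linalg.norm(p[a] - p[b])
            res.append(0.3 * max(0.0, gap))
        return np.array(res)

    for _attempt in range(8):
        x0 = rng.normal(scale=distance * max(1.0, m / 3.0), size=m * 3)
        sol = least_squares(residuals, x0)
        p = sol.x.reshape(m, 3)
        ok_planted = all(
            abs(np.linalg.norm(p[a] - p[b]) - distance) < 0.05 for a, b in planted
        )
        ok_others = all(
            np.linalg.norm(p[a] - p[b]) > _MIN_SEPARATION - 1.0 for a, b in others
        )
        if ok_planted and ok_others:
            return {nid: p[index[nid]] for nid in members}
    raise ValueError(
        f"planted contacts among nodes {members} are jointly infeasible: no "
        f"3-D embedding keeps planted pairs at {distance} Å and the rest "
        f"separated"
    )


def _base_positions(
    spec: TrajectorySpec, rng: np.random.Generator
) -> dict[int, np.ndarray]:
    """Deterministic base geometry: wide grid, planted contacts clustered."""
    ids = list(spec.node_ids)
    pos: dict[int, np.ndarray] = {}
    # coarse grid, 40 Å spacing, deterministic order
    grid = 40.0
    for k, nid in enumerate(ids):
        pos[nid] = np.array(
            [grid * (k % 8), grid * ((k // 8) % 8), grid * (k // 64)], dtype=float
        )
    # union of contact pairs -> connected components, each embedded locally
    adj: dict[int, set[int]] = {nid: set() for nid in ids}
    for i, j in spec.contacts:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    for nid in ids:
        if nid in seen or not adj[nid]:
            continue
        members = []
        queue = [nid]
        seen.add(nid)
        while queue:
            cur = queue.pop(0)
            members.append(cur)
            for nbr in sorted(adj[cur]):
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        pairs = [(i, j) for i, j in spec.contacts if i in members]
        local = _layout_component(members, pairs, spec.contact_distance, rng)
        anchor = pos[members[0]]
        centre = np.mean(list(local.values()), axis=0)
        for member in members:
            pos[member] = anchor + local[member] - centre
    return pos


def make_correlated_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Generate a trajectory with planted correlations and contacts.

    Node i's position at frame t is base_i + Σ_g a_g·s_g(t)·u_g + ε_i(t)
    over the groups containing i, with s_g standard normal per frame, u_g a
    fixed unit direction per group and ε isotropic normal(0, σ²).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = _base_positions(spec, rng)
    ids = list(spec.node_ids)
    n = len(ids)
    idx = {nid: k for k, nid in enumerate(ids)}

    coords = np.empty((spec.n_frames, n, 3))
    for k, nid in enumerate(ids):
        coords[:, k, :] = base[nid]

    # fixed unit directions per group, deterministic under seed
    for members, amplitude in spec.groups:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        s = rng.standard_normal(spec.n_frames)
        for nid in members:
            coords[:, idx[nid], :] += amplitude * s[:, None] * u[None, :]
    coords += rng.normal(scale=spec.noise_sd, size=coords.shape) if spec.noise_sd > 0 else 0.0

    atom_names = np.array(
        ["N1" if nid == spec.ligand_id else "CA" for nid in ids]
    )
    elements = np.array(["N" if nid == spec.ligand_id else "C" for nid in ids])
    res_names = np.array(["LIG" if nid == spec.ligand_id else "GLY" for nid in ids])
    return Trajectory(
        coords=coords,
        atom_names=atom_names,
        elements=elements,
        res_ids=np.array(ids, dtype=int),
        res_names=res_names,
        chain_ids=np.array(["A"] * n),
        frame_interval=spec.frame_interval,
    )


# ---------------------------------------------------------------------------
# toy GPCR geometry
# ---------------------------------------------------------------------------

#: illustrative state targets (Å) for the six microswitch descriptors; the
#: ionic-lock and NPxxY hydrogen-bond scales follow the published active
#: (~20 Å lock opening) and inactive (~5 Å broken H-bond) magnitudes, the
#: rest are crystal-structure-plausible values.
ACTIVE_TARGETS = {
    "lbs_tightening": 11.0,
    "npxxy_hbond": 2.8,
    "npxxy_ca": 7.0,
    "pif_36": 9.0,
    "pif_56": 11.0,
    "edry_ionic": 20.0,
}
INACTIVE_TARGETS = {
    "lbs_tightening": 13.0,
    "npxxy_hbond": 5.0,
    "npxxy_ca": 9.0,
    "pif_36": 11.5,
    "pif_56": 9.5,
    "edry_ionic": 3.5,
}


@dataclass
class GeometrySpec:
    """Recipe for the toy seven-helix receptor.

    ``targets`` overrides individual descriptor distances; unset descriptors
    take the state defaults above.  ``jitter_sd`` is the per-coordinate
    Gaussian jitter (Å) applied to every atom independently per frame; with
    zero jitter every descriptor equals its target exactly in every frame.
    ``plant_pathway`` adds side-chain contacts and shared motion modes along
    the chain ligand → C3.36 → I3.40 → F6.44 → R6.29 so the network stage
    finds a dominant communication path on the toy complex.
    """

    state: str = "inactive"  # "active" | "inactive"
    targets: dict[str, float] = field(default_factory=dict)
    jitter_sd: float = 0.0
    n_frames: int = 100
    frame_interval: float = 1.0  # ns
    include_ligand: bool = True
    plant_pathway: bool = False
    pathway_amplitude: float = 0.5
    seed: int = 0

    def resolved_targets(self) -> dict[str, float]:
        if self.state not in ("active", "inactive"):
            raise ValueError("state must be 'active' or 'inactive'")
        base = dict(ACTIVE_TARGETS if self.state == "active" else INACTIVE_TARGETS)
        base.update(self.targets)
        if any(v <= 0 for v in base.values()):
            raise ValueError("descriptor targets must be positive")
        return base


# (generic, helix, res name, expected one-letter)
_TOY_RESIDUES = [
    ("1.50", 1, "ASN", "N"),
    ("2.50", 2, "ASP", "D"),
    ("3.32", 3, "ASP", "D"),
    ("3.33", 3, "VAL", "V"),
    ("3.36", 3, "CYS", "C"),
    ("3.39", 3, "SER", "S"),
    ("3.40", 3, "ILE", "I"),
    ("3.44", 3, "CYS", "C"),
    ("3.50", 3, "ARG", "R"),
    ("4.50", 4, "TRP", "W"),
    ("5.39", 5, "VAL", "V"),
    ("5.42", 5, "SER", "S"),
    ("5.43", 5, "SER", "S"),
    ("5.46", 5, "SER", "S"),
    ("5.50", 5, "PRO", "P"),
    ("6.29", 6, "ARG", "R"),
    ("6.30", 6, "GLU", "E"),
    ("6.44", 6, "PHE", "F"),
    ("6.48", 6, "TRP", "W"),
    ("6.51", 6, "PHE", "F"),
    ("6.52", 6, "PHE", "F"),
    ("6.55", 6, "HIS", "H"),
    ("7.39", 7, "THR", "T"),
    ("7.42", 7, "ALA", "A"),
    ("7.43", 7, "TYR", "Y"),
    ("7.49", 7, "ASN", "N"),
    ("7.53", 7, "TYR", "Y"),
]

LIGAND_RES_ID = 900


def _toy_res_id(generic: str) -> int:
    helix, pos = generic.split(".")
    return int(helix) * 100 + int(pos)


def toy_bw_mapping() -> BWMapping:
    """The BW mapping matching :func:`make_toy_gpcr` (ids = helix·100+pos)."""
    return BWMapping(
        [
            BWEntry(gen, helix, _toy_res_id(gen), one)
            for gen, helix, _, one in _TOY_RESIDUES
        ]
    )


def make_toy_gpcr(spec: GeometrySpec) -> tuple[Trajectory, BWMapping]:
    """Build the toy receptor trajectory and its matching BW mapping.

    The structure is organised as disjoint spatial clusters, one per
    descriptor, so each target distance can be set independently; every
    remaining mapped residue is a Cα-only placeholder on a distant line.
    Descriptor-defining atoms are placed so that each of the six distances
    equals its target exactly in the jitter-free base geometry.
    """
    targets = spec.resolved_targets()
    rng = np.random.default_rng(spec.seed)

    atoms: list[tuple[int, str, str, str]] = []  # (res_id, res_name, atom, element)
    base: list[np.ndarray] = []

    def add(res_gen: str, res_name: str, atom: str, element: str, xyz) -> None:
        atoms.append((_toy_res_id(res_gen), res_name, atom, element))
        base.append(np.asarray(xyz, dtype=float))

    # cluster 1 (y=0): binding-cavity tightening, Cα 5.46 – Cα 7.42
    add("5.46", "SER", "CA", "C", (0, 0, 0))
    add("5.46", "SER", "OG", "O", (0, 0, 1.4))
    add("7.42", "ALA", "CA", "C", (targets["lbs_tightening"], 0, 0))

    # cluster 2 (y=50): NPxxY H-bond, OG(3.39) – ND2(7.49)
    add("3.39", "SER", "CA", "C", (-1.5, 50, -1.0))
    add("3.39", "SER", "OG", "O", (0, 50, 0))
    add("7.49", "ASN", "ND2", "N", (targets["npxxy_hbond"], 50, 0))
    add("7.49", "ASN", "CA", "C", (targets["npxxy_hbond"] + 1.5, 50, -1.0))

    # cluster 3 (y=100): NPxxY Cα pair, Cα 3.44 – Cα 7.53
    add("3.44", "CYS", "CA", "C", (0, 100, 0))
    add("7.53", "TYR", "CA", "C", (targets["npxxy_ca"], 100, 0))

    # cluster 4 (y=150): P-I-F triangle around Cα 6.44
    d36, d56 = targets["pif_36"], targets["pif_56"]
    add("6.44", "PHE", "CA", "C", (0, 150, 0))
    add("3.40", "ILE", "CA", "C", (d36, 150, 0))
    add("5.50", "PRO", "CA", "C", (-d56, 150, 0))

    # cluster 5 (y=200): ionic lock, R3.50 guanidinium – E6.30 carboxylate;
    # the minimum pair is NH1…OE1, the remaining atoms sit strictly behind
    d = targets["edry_ionic"]
    add("3.50", "ARG", "NH1", "N", (0, 200, 0))
    add("3.50", "ARG", "NH2", "N", (-1.0, 200, 1.0))
    add("3.50", "ARG", "NE", "N", (-1.5, 200, -1.0))
    add("3.50", "ARG", "CZ", "C", (-0.8, 200, 0.0))
    add("3.50", "ARG", "CA", "C", (-3.5, 200, 0))
    add("6.30", "GLU", "OE1", "O", (d, 200, 0))
    add("6.30", "GLU", "OE2", "O", (d + 1.0, 200, 1.0))
    add("6.30", "GLU", "CD", "C", (d + 1.2, 200, -0.5))
    add("6.30", "GLU", "CA", "C", (d + 3.5, 200, 0))

    chain_members: list[str] = []
    if spec.plant_pathway:
        # side chains bridging cluster 4 plus ligand and R6.29 above/below it
        mid = d36 / 2.0
        add("6.44", "PHE", "CB", "C", (min(1.5, mid - 1.75), 150, 0))
        add("6.44", "PHE", "CG", "C", (mid - 1.75, 150, 0))
        add("3.40", "ILE", "CB", "C", (max(d36 - 1.5, mid + 1.75), 150, 0))
        add("3.40", "ILE", "CG1", "C", (mid + 1.75, 150, 0))
        add("6.29", "ARG", "CA", "C", (0, 150, 8.0))
        add("6.29", "ARG", "CB", "C", (0, 150, 6.5))
        add("6.29", "ARG", "CG", "C", (0, 150, 5.0))
        add("6.29", "ARG", "CD", "C", (0, 150, 3.5))
        add("3.36", "CYS", "CA", "C", (d36, 150, 8.0))
        add("3.36", "CYS", "CB", "C", (d36, 150, 5.75))
        add("3.36", "CYS", "SG", "S", (d36, 150, 3.5))
        chain_members = ["ligand", "3.36", "3.40", "6.44", "6.29"]
    else:
        add("6.29", "ARG", "CA", "C", (0, 150, 30.0))
        add("3.36", "CYS", "CA", "C", (d36, 150, 30.0))

    if spec.include_ligand:
        if spec.plant_pathway:
            lig_xyz = (d36, 150, 11.5)  # 3.5 Å above the C3.36 Cα
        else:
            lig_xyz = (0, -50, 0)
        atoms.append((LIGAND_RES_ID, "LIG", "N1", "N"))
        base.append(np.asarray(lig_xyz, dtype=float))

    # remaining mapped residues: Cα-only placeholders on a distant line
    placed = {rid for rid, *_ in atoms}
    for k, (gen, helix, res_name, _one) in enumerate(_TOY_RESIDUES):
        rid = _toy_res_id(gen)
        if rid in placed:
            continue
        add(gen, res_name, "CA", "C", (10.0 * k, -100, 0))

    # order atoms by residue id so residues are contiguous
    order = np.argsort([rid for rid, *_ in atoms], kind="stable")
    atoms = [atoms[k] for k in order]
    base_arr = np.stack([base[k] for k in order])

    coords = np.repeat(base_arr[None, :, :], spec.n_frames, axis=0)
    if spec.plant_pathway:
        mapping_tmp = {gen: _toy_res_id(gen) for gen, *_ in _TOY_RESIDUES}
        res_of_atom = np.array([rid for rid, *_ in atoms])
        chain_ids = [
            LIGAND_RES_ID if m == "ligand" else mapping_tmp[m] for m in chain_members
        ]
        for u_pair in zip(chain_ids, chain_ids[1:]):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            s = rng.standard_normal(spec.n_frames)
            for rid in u_pair:
                sel = res_of_atom == rid
                coords[:, sel, :] += (
                    spec.pathway_amplitude * s[:, None, None] * u[None, None, :]
                )
    if spec.jitter_sd > 0:
        coords = coords + rng.normal(scale=spec.jitter_sd, size=coords.shape)

    traj = Trajectory(
        coords=coords,
        atom_names=np.array([a for _, _, a, _ in atoms]),
        elements=np.array([e for _, _, _, e in atoms]),
        res_ids=np.array([rid for rid, *_ in atoms], dtype=int),
        res_names=np.array([rn for _, rn, _, _ in atoms]),
        chain_ids=np.array(["A"] * len(atoms)),
        frame_interval=spec.frame_interval,
    )
    return traj, toy_bw_mapping()


#: descriptor pairs plotted/classified together by default
DEFAULT_DESCRIPTOR_PAIRS = [
    ("edry_ionic", "npxxy_hbond"),
    ("pif_36", "pif_56"),
    ("lbs_tightening", "npxxy_ca"),
]


def default_state_regions(half_width: float = 1.0):
    """Illustrative active/inactive rectangles centred on the state targets.

    The published reference regions are drawn, not tabulated, so these serve
    as a self-consistent default for synthetic data: each rectangle extends
    ``half_width`` Å around the corresponding generator target.
    """
    from .trajectory_metrics import StateRegion

    regions = {}
    for x_name, y_name in DEFAULT_DESCRIPTOR_PAIRS:
        rects = {}
        for label, targets in (("active", ACTIVE_TARGETS), ("inactive", INACTIVE_TARGETS)):
            rects[label] = (
                targets[x_name] - half_width,
                targets[x_name] + half_width,
                targets[y_name] - half_width,
                targets[y_name] + half_width,
            )
        regions[(x_name, y_name)] = StateRegion(x_name, y_name, rects)
    return regions


def write_regions_yaml(regions, path) -> None:
    """Serialise state regions to the ``regions.yaml`` schema."""
    import yaml

    payload = [
        {
            "x": region.x_name,
            "y": region.y_name,
            "rectangles": {
                label: {"x": [float(r[0]), float(r[1])], "y": [float(r[2]), float(r[3])]}
                for label, r in region.rectangles.items()
            },
        }
        for region in regions.values()
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# PIEDA tables
# ---------------------------------------------------------------------------

#: conserved aminergic binding-site residues used as the synthetic fragment set
_BINDING_SITE = [
    "2.50", "3.32", "3.33", "3.36", "5.39", "5.42", "5.43",
    "5.46", "6.48", "6.51", "6.52", "6.55", "7.39", "7.43",
]
_BS_NAMES = {
    "2.50": "ASP", "3.32": "ASP", "3.33": "VAL", "3.36": "CYS",
    "5.39": "VAL", "5.42": "SER", "5.43": "SER", "5.46": "SER",
    "6.48": "TRP", "6.51": "PHE", "6.52": "PHE", "6.55": "HIS",
    "7.39": "THR", "7.43": "TYR",
}


@dataclass
class PIEDASpec:
    """Recipe for synthetic per-residue PIEDA tables.

    Contact probabilities per functional class encode the planted occupancy
    difference (the published pattern has antagonists engaging more
    binding-site residues than agonists).  Energy components are Gaussian
    with the given means/sds (kcal/mol); attractive contacts then receive a
    strongly negative electrostatic salt-bridge-like term at D3.32, and a
    ``repulsive_fraction`` of contacted non-3.32 residues is pushed to a
    positive total PIE through exchange repulsion.
    """

    contact_prob: dict[str, float] = field(
        default_factory=lambda: {"agonist": 0.5, "antagonist": 0.75}
    )
    repulsive_fraction: float = 0.15
    component_means: dict[str, float] = field(
        default_factory=lambda: {
            "e_es": -4.0, "e_ex": 2.0, "e_ct": -1.5, "e_disp": -2.5, "dg_solv": 1.0
        }
    )
    component_sds: dict[str, float] = field(
        default_factory=lambda: {
            "e_es": 2.0, "e_ex": 1.0, "e_ct": 0.8, "e_disp": 1.2, "dg_solv": 1.0
        }
    )
    residues: list[str] = field(default_factory=lambda: list(_BINDING_SITE))
    seed: int = 0

    def validate(self) -> None:
        for cls, p in self.contact_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"contact probability for {cls} must be in [0,1]")
        if not 0 <= self.repulsive_fraction <= 1:
            raise ValueError("repulsive_fraction must be in [0,1]")


def make_pieda_tables(
    spec: PIEDASpec, n_per_class: dict[str, int] | None = None
) -> list[PIEDATable]:
    """Generate PIEDA tables for several complexes per functional class.

    Defaults to the published study shape: 7 agonist and 10 antagonist
    complexes.  Contacts are drawn per class probability; the D3.32 salt
    bridge is always contacted with a ~−100 kcal/mol electrostatic PIE.
    """
    spec.validate()
    if n_per_class is None:
        n_per_class = {"agonist": 7, "antagonist": 10}
    rng = np.random.default_rng(spec.seed)
    tables: list[PIEDATable] = []
    for cls in sorted(n_per_class):
        p_contact = spec.contact_prob.get(cls, 0.5)
        for k in range(n_per_class[cls]):
            cid = f"{cls[:2].upper()}{k + 1}"
            rows = []
            contacted_generics = [
                g
                for g in spec.residues
                if g == "3.32" or rng.random() < p_contact
            ]
            n_rep = int(round(
                spec.repulsive_fraction
                * len([g for g in contacted_generics if g != "3.32"])
            ))
            repulsive = set(
                rng.choice(
                    [g for g in contacted_generics if g != "3.32"],
                    size=n_rep,
                    replace=False,
                ).tolist()
                if n_rep > 0
                else []
            )
            for gen in spec.residues:
                contacted = gen in contacted_generics
                comp = {
                    c: rng.normal(spec.component_means[c], spec.component_sds[c])
                    for c in ("e_es", "e_ex", "e_ct", "e_disp", "dg_solv")
                }
                if not contacted:
                    # distant residues interact only marginally
                    comp = {c: 0.05 * v for c, v in comp.items()}
                    dist = rng.uniform(5.0, 9.0)
                else:
                    dist = rng.uniform(2.6, 4.4)
                if gen == "3.32":
                    comp["e_es"] = rng.normal(-100.0, 5.0)  # the salt bridge
                    dist = rng.uniform(2.6, 3.2)
                pie = sum(comp.values())
                if contacted and gen in repulsive and pie <= 0:
                    comp["e_ex"] += abs(pie) + rng.uniform(0.5, 2.0)
                    pie = sum(comp.values())
                if contacted and gen not in repulsive and pie >= 0:
                    comp["e_es"] -= pie + rng.uniform(0.5, 2.0)
                    pie = sum(comp.values())
                rows.append(
                    {
                        "residue_id": _toy_res_id(gen),
                        "residue_name": _BS_NAMES.get(gen, "GLY"),
                        "pie": pie,
                        **comp,
                        "min_dist": dist,
                    }
                )
            tables.append(
                PIEDATable(
                    records=pd.DataFrame(rows),
                    complex_id=cid,
                    ligand_id=f"L{cid}",
                    func_class=cls,
                )
            )
    return tables
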