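"""Stability metrics and activation-state geometric descriptors.

Class-A GPCR activation is tracked through a handful of microswitch
geometries: tightening of the ligand-binding site (Cα 5.46–Cα 7.42), the
NPxxY motif at the intracellular end of TMH7 (S3.39…N7.49 hydrogen bond and
the C3.44–Y7.53 Cα distance), the P-I-F connector between TMH3/5/6 (Cα
triangle P5.50 / I3.40 / residue 6.44), and the E/DRY ionic lock between
R3.50 and E6.30 whose rupture opens the G-protein cavity.  Each descriptor
is a per-frame distance in Å; trajectories are summarised as medians over
contiguous 10-ns blocks and each block is classified against user-supplied
active/inactive reference rectangles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .bw_mapping import BWMapping
from .io_formats import Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "DescriptorSeries",
    "BlockSummary",
    "StateRegion",
    "StateCall",
    "DESCRIPTOR_NAMES",
    "rmsd_series",
    "rmsf_series",
    "motif_distance",
    "block_medians",
    "classify_blocks",
    "load_regions",
]

DESCRIPTOR_NAMES = (
    "lbs_tightening",
    "npxxy_hbond",
    "npxxy_ca",
    "pif_36",
    "pif_56",
    "edry_ionic",
)


@dataclass
class DescriptorSeries:
    """A per-frame scalar descriptor (Å)."""

    name: str
    values: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"descriptor {self.name!r} contains non-finite values")


@dataclass
class BlockSummary:
    """Per-block medians of a descriptor over contiguous equal-length blocks."""

    name: str
    block_length: float  # ns
    medians: np.ndarray
    spans: list[tuple[float, float]]  # (start ns, end ns) per block

    def __post_init__(self) -> None:
        self.medians = np.asarray(self.medians, dtype=float)
        if len(self.medians) != len(self.spans):
            raise ValueError("one span per median required")


@dataclass
class StateRegion:
    """Reference rectangles in a 2-D descriptor plane, one per state label.

    Rectangles are closed: a point on an edge belongs to the region.
    Rectangles of different labels must not overlap in their interiors.
    """

    x_name: str
    y_name: str
    rectangles: dict[str, tuple[float, float, float, float]]  # label -> (x0,x1,y0,y1)

    def __post_init__(self) -> None:
        labels = list(self.rectangles)
        for a_i in range(len(labels)):
            for b_i in range(a_i + 1, len(labels)):
                ra, rb = self.rectangles[labels[a_i]], self.rectangles[labels[b_i]]
                if _interiors_overlap(ra, rb):
                    raise ValueError(
                        f"state rectangles {labels[a_i]!r} and {labels[b_i]!r} overlap"
                    )

    def label_point(self, x: float, y: float) -> str:
        for label in sorted(self.rectangles):
            x0, x1, y0, y1 = self.rectangles[label]
            if x0 <= x <= x1 and y0 <= y <= y1:
                return label
        return "intermediate"


def _interiors_overlap(a, b) -> bool:
    ax0, ax1, ay0, ay1 = a
    bx0, bx1, by0, by1 = b
    return max(ax0, bx0) < min(ax1, bx1) and max(ay0, by0) < min(ay1, by1)


@dataclass
class StateCall:
    """Block labels and their per-trajectory fractions."""

    labels: list[str]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# superposition metrics
# ---------------------------------------------------------------------------


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    """Accept None (default Cα), a boolean mask, or a per-atom predicate."""
    if selection is None:
        mask = traj.atom_names == "CA"
    elif callable(selection):
        mask = np.array(
            [
                selection(traj.atom_names[i], traj.elements[i], traj.res_ids[i])
                for i in range(traj.n_atoms)
            ],
            dtype=bool,
        )
    else:
        mask = np.asarray(selection, dtype=bool)
        if mask.shape != (traj.n_atoms,):
            raise ValueError("selection mask must have length n_atoms")
    if not mask.any():
        raise ValueError("atom selection is empty")
    return mask


def _kabsch_aligned(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (N,3)."""
    ref_c = reference - reference.mean(axis=0)
    mob_c = mobile - mobile.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    return rot.apply(mob_c) + reference.mean(axis=0)


def rmsd_series(
    traj: Trajectory, reference_frame: int = 0, selection=None
) -> DescriptorSeries:
    """Per-frame Cα RMSD after optimal rigid (Kabsch) superposition.

    The reference is a frame of the same trajectory; any rigid-body motion of
    a frame therefore contributes nothing to its RMSD.
    """
    mask = _resolve_selection(traj, selection)
    ref = traj.coords[reference_frame][mask]
    ref_c = ref - ref.mean(axis=0)
    n = ref.shape[0]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mob = traj.coords[f][mask]
        mob_c = mob - mob.mean(axis=0)
        _, rssd = Rotation.align_vectors(ref_c, mob_c)
        values[f] = rssd / np.sqrt(n)
    return DescriptorSeries("rmsd", values, traj.frame_interval)


def rmsf_series(traj: Trajectory, selection=None, superpose: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure (Å).

    With ``superpose=True`` every frame is first rigidly fitted onto the mean
    structure (one refinement pass: fit to the frame-0-aligned mean, then
    recompute the mean).  With ``superpose=False`` the fluctuation of the raw
    coordinates is returned, i.e. the population standard deviation of each
    atom's position series.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least two frames")
    mask = _resolve_selection(traj, selection)
    frames = traj.coords[:, mask, :]
    if superpose:
        ref = frames[0]
        aligned = np.stack([_kabsch_aligned(fr, ref) for fr in frames])
        mean = aligned.mean(axis=0)
        aligned = np.stack([_kabsch_aligned(fr, mean) for fr in frames])
        frames = aligned
    mean = frames.mean(axis=0)
    return np.sqrt(((frames - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# motif descriptors
# ---------------------------------------------------------------------------


def _ca_pair(traj, mapping, gen_a, gen_b):
    ia = traj.atom_index(_rid(traj, mapping, gen_a), "CA")
    ib = traj.atom_index(_rid(traj, mapping, gen_b), "CA")
    return _pair_distance(traj, [ia], [ib])


def _rid(traj: Trajectory, mapping: BWMapping, generic: str) -> int:
    rid = mapping.resolve(generic)
    if rid not in traj.res_ids:
        raise KeyError(f"residue {rid} (BW {generic}) absent from trajectory")
    mapping.resolve(generic, structure_residue_name=traj.residue_name(rid))
    return rid


def _pair_distance(traj, idx_a: Sequence[int], idx_b: Sequence[int]) -> np.ndarray:
    """Per-frame minimum distance between two atom groups."""
    a = traj.coords[:, list(idx_a), :]  # (F, na, 3)
    b = traj.coords[:, list(idx_b), :]
    diff = a[:, :, None, :] - b[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return d.reshape(traj.n_frames, -1).min(axis=1)


def _atoms_or_error(traj, rid, names, descriptor) -> list[int]:
    idx = []
    for nm in names:
        try:
            idx.append(traj.atom_index(rid, nm))
        except KeyError:
            raise KeyError(
                f"descriptor {descriptor!r}: residue {rid} lacks atom {nm!r}"
            ) from None
    return idx


def motif_distance(
    traj: Trajectory, mapping: BWMapping, descriptor: str
) -> DescriptorSeries:
    """Per-frame distance series of one activation microswitch descriptor.

    Descriptors
    -----------
    ``lbs_tightening``  Cα(5.46)–Cα(7.42), contraction of the binding cavity.
    ``npxxy_hbond``     Ser 3.39 side-chain hydroxyl O to the nearest Asn 7.49
                        side-chain amide hydrogen; falls back to the amide N
                        (logged) on hydrogen-stripped structures.
    ``npxxy_ca``        Cα(3.44)–Cα(7.53).
    ``pif_36``          Cα(3.40)–Cα(6.44), the TMH3↔TMH6 leg of the P-I-F triangle.
    ``pif_56``          Cα(5.50)–Cα(6.44), the TMH5↔TMH6 leg.
    ``edry_ionic``      minimum distance between the R3.50 guanidinium heavy
                        atoms (NH1, NH2, NE, CZ) and the E6.30 carboxylate
                        heavy atoms (OE1, OE2, CD) — the ionic lock.
    """
    if descriptor == "lbs_tightening":
        values = _ca_pair(traj, mapping, "5.46", "7.42")
    elif descriptor == "npxxy_ca":
        values = _ca_pair(traj, mapping, "3.44", "7.53")
    elif descriptor == "pif_36":
        values = _ca_pair(traj, mapping, "3.40", "6.44")
    elif descriptor == "pif_56":
        values = _ca_pair(traj, mapping, "5.50", "6.44")
    elif descriptor == "npxxy_hbond":
        rid_s = _rid(traj, mapping, "3.39")
        rid_n = _rid(traj, mapping, "7.49")
        io = _atoms_or_error(traj, rid_s, ["OG"], descriptor)
        h_idx = [
            traj.atom_index(rid_n, nm)
            for nm in ("HD21", "HD22")
            if nm in traj.atom_names[traj.res_ids == rid_n]
        ]
        if h_idx:
            values = _pair_distance(traj, io, h_idx)
        else:
            logger.warning(
                "npxxy_hbond: no amide hydrogens on residue %d, "
                "falling back to O...N distance",
                rid_n,
            )
            nn = _atoms_or_error(traj, rid_n, ["ND2"], descriptor)
            values = _pair_distance(traj, io, nn)
    elif descriptor == "edry_ionic":
        rid_r = _rid(traj, mapping, "3.50")
        rid_e = _rid(traj, mapping, "6.30")
        guan = _atoms_or_error(traj, rid_r, ["NH1", "NH2", "NE", "CZ"], descriptor)
        carb = _atoms_or_error(traj, rid_e, ["OE1", "OE2", "CD"], descriptor)
        values = _pair_distance(traj, guan, carb)
    else:
        raise ValueError(
            f"unknown descriptor {descriptor!r}; expected one of {DESCRIPTOR_NAMES}"
        )
    return DescriptorSeries(descriptor, values, traj.frame_interval)


# ---------------------------------------------------------------------------
# block reduction & classification
# ---------------------------------------------------------------------------


def block_medians(series: DescriptorSeries, block_length: float = 10.0) -> BlockSummary:
    """Medians over contiguous ``block_length``-ns blocks anchored at t=0.

    A trailing partial block is dropped (and logged).  The median of an even
    count is the midpoint of the two central values.
    """
    frames_per_block = int(round(block_length / series.frame_interval))
    if frames_per_block < 1:
        raise ValueError("block shorter than one frame")
    n_blocks = len(series.values) // frames_per_block
    if n_blocks < 1:
        raise ValueError(
            f"series of {len(series.values)} frames shorter than one "
            f"{block_length}-ns block ({frames_per_block} frames)"
        )
    dropped = len(series.values) - n_blocks * frames_per_block
    if dropped:
        logger.info(
            "block_medians(%s): dropping %d trailing frames (partial block)",
            series.name,
            dropped,
        )
    blocks = series.values[: n_blocks * frames_per_block].reshape(
        n_blocks, frames_per_block
    )
    medians = np.median(blocks, axis=1)
    spans = [
        (i * block_length, (i + 1) * block_length) for i in range(n_blocks)
    ]
    return BlockSummary(series.name, block_length, medians, spans)


def classify_blocks(
    x: BlockSummary, y: BlockSummary, regions: StateRegion
) -> StateCall:
    """Label each block's (median_x, median_y) point by containing rectangle.

    Points in no rectangle are ``intermediate``.  Rectangles are closed, so a
    point on an edge belongs to the region.
    """
    if len(x.medians) != len(y.medians):
        raise ValueError(
            f"block count mismatch: {len(x.medians)} vs {len(y.medians)}"
        )
    if {regions.x_name, regions.y_name} != {x.name, y.name}:
        raise ValueError(
            f"regions are defined for ({regions.x_name}, {regions.y_name}), "
            f"got ({x.name}, {y.name})"
        )
    if regions.x_name != x.name:  # caller may pass the pair swapped
        x, y = y, x
    labels = [
        regions.label_point(xv, yv) for xv, yv in zip(x.medians, y.medians)
    ]
    n = len(labels)
    all_labels = sorted(set(regions.rectangles) | {"intermediate"})
    fractions = {lab: labels.count(lab) / n for lab in all_labels}
    return StateCall(labels, fractions)


def load_regions(path: str | Path) -> dict[tuple[str, str], StateRegion]:
    """Load ``regions.yaml``: per descriptor pair, named rectangles in Å.

    Schema::

        - x: edry_ionic
          y: npxxy_hbond
          rectangles:
            active:   {x: [15.0, 25.0], y: [2.0, 4.0]}
            inactive: {x: [2.0, 6.0],  y: [4.0, 7.0]}
    """
    raw = yaml.safe_load(Path(path).read_text())
    out: dict[tuple[str, str], StateRegion] = {}
    for item in raw:
        rects = {
            label: (
                float(spec["x"][0]),
                float(spec["x"][1]),
                float(spec["y"][0]),
                float(spec["y"][1]),
            )
            for label, spec in item["rectangles"].items()
        }
        region = StateRegion(item["x"], item["y"], rects)
        out[(item["x"], item["y"])] = region
    return out
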