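"""Post-processing of per-residue FMO/PIEDA interaction energies.

The fragment molecular orbital method decomposes each ligand–residue pair
interaction energy (PIE) into electrostatic (E_es), exchange-repulsion
(E_ex), charge-transfer (E_ct), dispersion (E_disp) and solvation (ΔG_solv)
contributions.  This module derives the quantities a medicinal chemist reads
off such tables: the polar share of each contact,

    %E_es+ct = (|E_es| + |E_ct|) / (|E_es| + |E_ct| + |E_disp|) · 100,

which is 100% for a purely polar interaction and 0% for a strictly
hydrophobic (pure-dispersion) one; the attractive/repulsive/no-contact
classification behind the interaction heat map (contacts are residues within
4.5 Å of the ligand, the boundary inclusive); the heat-map matrix across
complexes; and the agonist-vs-antagonist comparison of binding-site residue
occupancy with a label-permutation significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import permutation_test

from .bw_mapping import BWMapping
from .io_formats import PIEDATable

logger = logging.getLogger(__name__)

__all__ = [
    "PolarityShare",
    "InteractionCall",
    "HeatmapMatrix",
    "OccupancySummary",
    "polarity_share",
    "polarity_table",
    "classify_interaction",
    "build_heatmap",
    "occupancy_stats",
]

DEFAULT_CONTACT_CUTOFF = 4.5  # Å

_CLASS_ORDER = {"agonist": 0, "antagonist": 1, "unknown": 2}


@dataclass(frozen=True)
class PolarityShare:
    residue_id: int
    value: float | None  # percentage in [0, 100]; None when undefined
    defined: bool

    def __post_init__(self) -> None:
        if self.defined and not 0.0 <= self.value <= 100.0:
            raise ValueError("polarity share must lie in [0, 100]")


@dataclass(frozen=True)
class InteractionCall:
    residue_id: int
    category: str  # attractive | repulsive | no_contact


@dataclass
class HeatmapMatrix:
    """PIE matrix: complexes (rows, agonists then antagonists) × residues."""

    matrix: pd.DataFrame  # NaN cells mark no contact
    row_classes: dict[str, str]
    excluded: list[str]


@dataclass
class OccupancySummary:
    counts: dict[str, int]  # complex id -> contacted-residue count
    per_class: dict[str, dict[str, float]]  # class -> {mean, median, n}
    contact_frequency: pd.DataFrame  # residue × class contact frequencies
    mean_difference: float | None  # first class minus second, class-name order
    p_value: float | None
    comparison: tuple[str, str] | None


# ---------------------------------------------------------------------------
# per-record statistics
# ---------------------------------------------------------------------------


def _record_fields(record) -> dict:
    if isinstance(record, pd.Series):
        return record.to_dict()
    if isinstance(record, dict):
        return record
    return {k: getattr(record, k) for k in ("residue_id", "pie", "e_es", "e_ct", "e_disp", "min_dist")}


def polarity_share(record) -> PolarityShare:
    """Polar percentage share of one ligand–residue interaction.

    Absolute values of the electrostatic, charge-transfer and dispersion
    contributions enter the ratio, so the statistic is always in [0, 100]
    regardless of component signs.  When all three components vanish the
    share is undefined and flagged rather than raised.
    """
    r = _record_fields(record)
    num = abs(r["e_es"]) + abs(r["e_ct"])
    den = num + abs(r["e_disp"])
    if den == 0.0:
        return PolarityShare(int(r["residue_id"]), None, defined=False)
    # ratio first so the zero-dispersion limit is exactly 100; num <= den
    # mathematically, so clamp only guards float round-up
    value = min(100.0, 100.0 * (num / den))
    return PolarityShare(int(r["residue_id"]), value, defined=True)


def polarity_table(table: PIEDATable) -> pd.DataFrame:
    """Polarity share of every record of a table (NaN where undefined)."""
    rows = [polarity_share(rec) for rec in table.records.itertuples(index=False)]
    return pd.DataFrame(
        {
            "complex_id": table.complex_id,
            "residue_id": [p.residue_id for p in rows],
            "polar_share_pct": [p.value if p.defined else np.nan for p in rows],
        }
    )


def classify_interaction(record, cutoff: float = DEFAULT_CONTACT_CUTOFF) -> InteractionCall:
    """Attractive/repulsive/no-contact call for one record.

    A residue farther than ``cutoff`` Å from the ligand (or with a missing
    distance) is ``no_contact``; the boundary itself counts as contact.
    Contacted residues are ``attractive`` when PIE < 0 and ``repulsive`` when
    PIE > 0; the measure-zero PIE = 0 case goes to the attractive branch and
    is logged.
    """
    r = _record_fields(record)
    dist = r["min_dist"]
    rid = int(r["residue_id"])
    if dist is None or (isinstance(dist, float) and np.isnan(dist)) or dist > cutoff:
        return InteractionCall(rid, "no_contact")
    pie = r["pie"]
    if pie == 0.0:
        logger.info("classify_interaction: PIE exactly 0 for residue %d, "
                    "classifying as attractive", rid)
    return InteractionCall(rid, "attractive" if pie <= 0.0 else "repulsive")


# ---------------------------------------------------------------------------
# cross-complex assembly
# ---------------------------------------------------------------------------


def _column_key(col: str):
    try:
        helix, pos = col.split(".")
        return (0, int(helix), int(pos))
    except (ValueError, AttributeError):
        return (1, 0, 0, str(col))


def build_heatmap(
    tables: list[PIEDATable],
    mapping: BWMapping,
    exclude: list[str] = ("3.32",),
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> HeatmapMatrix:
    """Assemble the PIE heat map across complexes.

    Rows are complexes, grouped agonists first, then antagonists, then
    unknown, alphabetical within a group.  Columns are the union of contacted
    residues across complexes, addressed by generic number (raw residue id,
    with a warning, when unmapped) and ordered by helix.position.  Cells hold
    the total PIE (kcal/mol) for contacted pairs and NaN otherwise; cell
    values are copied, never transformed.  Excluded generic numbers (by
    default D3.32, whose ~−100 kcal/mol salt bridge would drown the colour
    scale) are dropped and recorded.
    """
    exclude = list(exclude)
    rows: dict[str, dict[str, float]] = {}
    row_classes: dict[str, str] = {}
    for table in tables:
        cells: dict[str, float] = {}
        for rec in table.records.itertuples(index=False):
            call = classify_interaction(rec, cutoff)
            if call.category == "no_contact":
                continue
            generic = mapping.generic_of(int(rec.residue_id))
            if generic is None:
                generic = str(int(rec.residue_id))
                logger.warning(
                    "build_heatmap: residue %s of %s not in BW mapping; "
                    "keeping raw residue id",
                    generic,
                    table.complex_id,
                )
            if generic in exclude:
                continue
            cells[generic] = float(rec.pie)
        rows[table.complex_id] = cells
        row_classes[table.complex_id] = table.func_class
    columns = sorted({c for cells in rows.values() for c in cells}, key=_column_key)
    row_order = sorted(rows, key=lambda cid: (_CLASS_ORDER[row_classes[cid]], cid))
    matrix = pd.DataFrame(
        [[rows[cid].get(col, np.nan) for col in columns] for cid in row_order],
        index=row_order,
        columns=columns,
    )
    matrix.index.name = "complex_id"
    return HeatmapMatrix(matrix=matrix, row_classes=row_classes, excluded=exclude)


def occupancy_stats(
    tables: list[PIEDATable],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    n_resamples: int = 9999,
    rng: np.random.Generator | int | None = None,
) -> OccupancySummary:
    """Binding-site residue occupancy per complex, compared between classes.

    Occupancy is the number of residues within ``cutoff`` Å of the ligand.
    When exactly two functional classes are present, the difference of class
    mean occupancies is tested with a two-sided label-permutation test
    (Monte-Carlo, seeded); with fewer/more classes only per-class summaries
    are produced and the comparison is marked unavailable.
    """
    counts: dict[str, int] = {}
    classes: dict[str, str] = {}
    freq_rows = []
    for table in tables:
        contacted = [
            int(rec.residue_id)
            for rec in table.records.itertuples(index=False)
            if classify_interaction(rec, cutoff).category != "no_contact"
        ]
        counts[table.complex_id] = len(contacted)
        classes[table.complex_id] = table.func_class
        for rid in contacted:
            freq_rows.append({"residue_id": rid, "func_class": table.func_class})

    present = sorted(set(classes.values()))
    per_class: dict[str, dict[str, float]] = {}
    for cls in present:
        vals = [counts[cid] for cid, c in classes.items() if c == cls]
        per_class[cls] = {
            "mean": float(np.mean(vals)),
            "median": float(np.median(vals)),
            "n": len(vals),
        }

    if freq_rows:
        freq = pd.DataFrame(freq_rows)
        class_sizes = {cls: per_class[cls]["n"] for cls in present}
        contact_frequency = (
            freq.groupby(["residue_id", "func_class"]).size().unstack(fill_value=0)
        )
        for cls in present:
            contact_frequency[cls] = contact_frequency.get(cls, 0) / class_sizes[cls]
        contact_frequency = contact_frequency[present].sort_index()
    else:
        contact_frequency = pd.DataFrame(columns=present)

    mean_difference = p_value = comparison = None
    if len(present) == 2 and all(per_class[c]["n"] >= 1 for c in present):
        a_cls, b_cls = present
        a = np.array([counts[cid] for cid, c in classes.items() if c == a_cls], dtype=float)
        b = np.array([counts[cid] for cid, c in classes.items() if c == b_cls], dtype=float)
        mean_difference = float(a.mean() - b.mean())
        comparison = (a_cls, b_cls)
        if len(a) >= 2 and len(b) >= 2:
            res = permutation_test(
                (a, b),
                lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
                permutation_type="independent",
                alternative="two-sided",
                n_resamples=n_resamples,
                vectorized=True,
                rng=rng,
            )
            p_value = float(res.pvalue)
        else:
            logger.info("occupancy_stats: a class has < 2 complexes, no p-value")
    else:
        logger.info("occupancy_stats: need exactly two classes for a comparison")

    return OccupancySummary(
        counts=counts,
        per_class=per_class,
        contact_frequency=contact_frequency,
        mean_difference=mean_difference,
        p_value=p_value,
        comparison=comparison,
    )
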