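"""Ballesteros–Weinstein generic numbering.

Class-A GPCR residues are addressed as ``helix.position`` strings where
position 50 marks the most conserved residue of each transmembrane helix
(D3.32 = helix 3, position 32).  The mapping between generic numbers and
sequence residue ids is an *input* of the pipeline (``bw_map.csv``), never
computed from alignment.  Generic numbers are kept as strings throughout:
"6.48" and "6.480" are distinct tokens and only lexical identity counts.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["BWEntry", "BWMapping", "read_bw_map", "write_bw_map"]


@dataclass(frozen=True)
class BWEntry:
    generic: str  # "helix.position"
    helix: int  # 1..7
    residue_id: int
    residue_name: str = ""  # expected one-letter code, may be empty


@dataclass
class BWMapping:
    """Bidirectional map generic number ↔ sequence residue id."""

    entries: list[BWEntry]
    _by_generic: dict = field(init=False, repr=False)
    _by_residue: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        generics = [e.generic for e in self.entries]
        res_ids = [e.residue_id for e in self.entries]
        if len(set(generics)) != len(generics):
            raise ValueError("generic numbers must be unique in a BW mapping")
        if len(set(res_ids)) != len(res_ids):
            raise ValueError("residue ids must be unique in a BW mapping")
        for e in self.entries:
            head = e.generic.split(".", 1)[0]
            if str(e.helix) != head:
                raise ValueError(
                    f"helix index {e.helix} inconsistent with generic {e.generic!r}"
                )
        self._by_generic = {e.generic: e for e in self.entries}
        self._by_residue = {e.residue_id: e for e in self.entries}

    def resolve(self, generic: str, structure_residue_name: str | None = None) -> int:
        """Residue sequence id of a generic number.

        If the mapping records an expected residue name and the caller passes
        the structure's actual residue name, a mismatch is logged as a warning
        but the lookup still succeeds.  An unknown generic number raises a
        ``KeyError`` listing near misses.
        """
        entry = self._by_generic.get(generic)
        if entry is None:
            near = difflib.get_close_matches(generic, self._by_generic, n=3)
            raise KeyError(
                f"generic number {generic!r} not in mapping"
                + (f"; close matches: {near}" if near else "")
            )
        if (
            structure_residue_name
            and entry.residue_name
            and not _names_match(entry.residue_name, structure_residue_name)
        ):
            logger.warning(
                "BW %s expects residue %s but structure has %s at id %d",
                generic,
                entry.residue_name,
                structure_residue_name,
                entry.residue_id,
            )
        return entry.residue_id

    def helix_of(self, residue_id: int) -> int | None:
        """Helix index of a residue, or None for loop/ligand/unmapped ids."""
        entry = self._by_residue.get(residue_id)
        return None if entry is None else entry.helix

    def generic_of(self, residue_id: int) -> str | None:
        entry = self._by_residue.get(residue_id)
        return None if entry is None else entry.generic

    def __contains__(self, generic: str) -> bool:
        return generic in self._by_generic


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _names_match(expected_one: str, structure_name: str) -> bool:
    s = structure_name.strip().upper()
    one = _THREE_TO_ONE.get(s, s)
    return one == expected_one.strip().upper()


def read_bw_map(path: str | Path) -> BWMapping:
    """Read a ``bw_map.csv`` (generic_number,helix,residue_id,residue_name)."""
    df = pd.read_csv(path, dtype={"generic_number": str, "residue_name": str})
    req = ["generic_number", "helix", "residue_id"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    entries = [
        BWEntry(
            generic=str(r.generic_number),
            helix=int(r.helix),
            residue_id=int(r.residue_id),
            residue_name=str(getattr(r, "residue_name", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]
    return BWMapping(entries)


def write_bw_map(mapping: BWMapping, path: str | Path) -> None:
    pd.DataFrame(
        {
            "generic_number": [e.generic for e in mapping.entries],
            "helix": [e.helix for e in mapping.entries],
            "residue_id": [e.residue_id for e in mapping.entries],
            "residue_name": [e.residue_name for e in mapping.entries],
        }
    ).to_csv(path, index=False)
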