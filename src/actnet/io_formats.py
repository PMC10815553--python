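"""Readers and writers for every external representation of the pipeline.

Trajectories travel as multi-model PDB files (one ``MODEL``/``ENDMDL`` block
per frame), per-residue interaction-energy decompositions as a canonical CSV
schema, and analysis results as CSV/JSON with deterministic ordering.  All
distances are Å and all energies kcal/mol throughout the package; no unit
conversion is offered.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "PIEDATable",
    "TrajectoryParseError",
    "PIEDAParseError",
    "read_trajectory",
    "write_trajectory",
    "read_pieda_table",
    "write_pieda_table",
    "write_results",
    "read_pathset",
    "PIEDA_COLUMNS",
]

#: canonical column order of the per-residue PIEDA CSV
PIEDA_COLUMNS = [
    "complex_id",
    "ligand_id",
    "class",
    "residue_id",
    "residue_name",
    "pie",
    "e_es",
    "e_ex",
    "e_ct",
    "e_disp",
    "dg_solv",
    "min_dist",
]

_ENERGY_COLUMNS = ["pie", "e_es", "e_ex", "e_ct", "e_disp", "dg_solv"]


class TrajectoryParseError(ValueError):
    """Raised when a multi-model PDB file violates the trajectory contract."""


class PIEDAParseError(ValueError):
    """Raised when a PIEDA CSV violates the table contract."""


@dataclass
class Trajectory:
    """Cartesian coordinates of one receptor–ligand complex over time.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Å.
    atom_names, elements, res_ids, res_names, chain_ids
        Per-atom annotation arrays of length ``n_atoms``.  Residue ids follow
        the author numbering of the source PDB, 1-based, and are never
        renumbered.
    frame_interval
        Time between consecutive frames in ns.
    """

    coords: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    frame_interval: float = 0.1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1 or self.n_atoms < 1:
            raise ValueError("trajectory needs at least one frame and one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("trajectory coordinates must all be finite")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        for name in ("atom_names", "elements", "res_ids", "res_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (self.n_atoms,):
                raise ValueError(f"{name} must have length n_atoms={self.n_atoms}")
            setattr(self, name, arr)
        self.res_ids = self.res_ids.astype(int)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return np.char.upper(self.elements.astype(str)) != "H"

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def residue_ids(self) -> np.ndarray:
        """Unique residue ids in order of first appearance."""
        _, idx = np.unique(self.res_ids, return_index=True)
        return self.res_ids[np.sort(idx)]

    def atom_index(self, res_id: int, atom_name: str) -> int:
        """Index of the named atom in the given residue.

        Raises ``KeyError`` naming residue and atom when absent.
        """
        hits = np.flatnonzero((self.res_ids == res_id) & (self.atom_names == atom_name))
        if hits.size == 0:
            raise KeyError(f"residue {res_id} has no atom named {atom_name!r}")
        return int(hits[0])

    def atoms_of_residue(self, res_id: int, heavy_only: bool = False) -> np.ndarray:
        mask = self.res_ids == res_id
        if heavy_only:
            mask &= self.heavy_mask
        return np.flatnonzero(mask)

    def residue_name(self, res_id: int) -> str:
        idx = np.flatnonzero(self.res_ids == res_id)
        if idx.size == 0:
            raise KeyError(f"no residue with id {res_id}")
        return str(self.res_names[idx[0]])


@dataclass
class PIEDATable:
    """Per-residue pair interaction energies of one ligand–receptor complex.

    ``records`` is a DataFrame with the columns of :data:`PIEDA_COLUMNS`
    (minus the three complex-level fields, which are carried separately).
    ``min_dist`` is the minimum heavy-atom distance between the ligand and
    the residue in Å; missing distances are NaN, never zero.
    """

    records: pd.DataFrame
    complex_id: str
    ligand_id: str
    func_class: str = "unknown"

    def __post_init__(self) -> None:
        req = ["residue_id", "residue_name"] + _ENERGY_COLUMNS + ["min_dist"]
        missing = [c for c in req if c not in self.records.columns]
        if missing:
            raise PIEDAParseError(f"PIEDA table missing columns: {missing}")
        if self.func_class not in ("agonist", "antagonist", "unknown"):
            raise PIEDAParseError(f"unknown functional class {self.func_class!r}")
        rid = self.records["residue_id"]
        if rid.duplicated().any():
            dups = sorted(rid[rid.duplicated()].unique().tolist())
            raise PIEDAParseError(f"duplicate residue id(s) {dups} in table {self.complex_id}")
        energies = self.records[_ENERGY_COLUMNS].to_numpy(dtype=float)
        if not np.all(np.isfinite(energies)):
            raise PIEDAParseError(f"non-finite energy in table {self.complex_id}")
        md = self.records["min_dist"].to_numpy(dtype=float)
        if np.any(md[np.isfinite(md)] <= 0):
            raise PIEDAParseError("min_dist must be positive where present")
        self.records = self.records.reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PIEDATable):
            return NotImplemented
        if (self.complex_id, self.ligand_id, self.func_class) != (
            other.complex_id,
            other.ligand_id,
            other.func_class,
        ):
            return False
        try:
            pd.testing.assert_frame_equal(
                self.records, other.records, check_dtype=False, check_exact=False
            )
        except AssertionError:
            return False
        return True


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------


def read_trajectory(
    path: str | Path, dialect: str = "pdb_multimodel", frame_interval: float = 0.1
) -> Trajectory:
    """Read a trajectory from a multi-model PDB file.

    Frame order follows ``MODEL`` order; a file without ``MODEL`` records is a
    single-frame trajectory.  Every model must contain the same atoms in the
    same order, otherwise a :class:`TrajectoryParseError` names the offending
    model.
    """
    if dialect != "pdb_multimodel":
        raise ValueError(f"unsupported trajectory dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TrajectoryParseError(f"{path}: empty trajectory file")

    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite's error already names the model
        raise TrajectoryParseError(f"{path}: {exc}") from exc
    if stack.array_length() == 0:
        raise TrajectoryParseError(f"{path}: no atoms found")
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name),
        elements=np.asarray(stack.element),
        res_ids=np.asarray(stack.res_id, dtype=int),
        res_names=np.asarray(stack.res_name),
        chain_ids=np.asarray(stack.chain_id),
        frame_interval=frame_interval,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (coordinates to 3 decimals)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    arr = struc.AtomArray(n)
    arr.atom_name = traj.atom_names.astype(str)
    arr.element = traj.elements.astype(str)
    arr.res_id = traj.res_ids
    arr.res_name = traj.res_names.astype(str)
    arr.chain_id = traj.chain_ids.astype(str)
    arr.hetero = np.isin(traj.res_names.astype(str), ["LIG"])
    frames = []
    for f in range(traj.n_frames):
        a = arr.copy()
        a.coord = traj.coords[f].astype(np.float32)
        frames.append(a)
    stack = struc.stack(frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# PIEDA CSV I/O
# ---------------------------------------------------------------------------


def read_pieda_table(path: str | Path) -> PIEDATable:
    """Read a per-residue PIEDA table from the canonical CSV schema.

    Missing ``min_dist`` cells are parsed as missing (NaN), not zero.  A
    non-numeric energy raises :class:`PIEDAParseError` naming the row; a
    duplicated residue id raises as well.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"complex_id": str, "ligand_id": str, "class": str})
    missing = [c for c in PIEDA_COLUMNS if c not in df.columns]
    if missing:
        raise PIEDAParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise PIEDAParseError(f"{path}: empty PIEDA table")
    for col in _ENERGY_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            # +2: header line and 1-based counting
            row = int(bad.idxmax()) + 2
            raise PIEDAParseError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at line {row}"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise PIEDAParseError(f"{path}: missing energy in column {col!r} at line {row}")
        df[col] = parsed
    df["min_dist"] = pd.to_numeric(df["min_dist"], errors="coerce")
    df["residue_id"] = pd.to_numeric(df["residue_id"], errors="raise").astype(int)
    complex_id = str(df["complex_id"].iloc[0])
    ligand_id = str(df["ligand_id"].iloc[0])
    func_class = str(df["class"].iloc[0])
    body = df[["residue_id", "residue_name"] + _ENERGY_COLUMNS + ["min_dist"]].copy()
    return PIEDATable(
        records=body, complex_id=complex_id, ligand_id=ligand_id, func_class=func_class
    )


def write_pieda_table(table: PIEDATable, path: str | Path) -> None:
    df = table.records.copy()
    df.insert(0, "complex_id", table.complex_id)
    df.insert(1, "ligand_id", table.ligand_id)
    df.insert(2, "class", table.func_class)
    df[PIEDA_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(obj: Any, path: str | Path, format: str = "json") -> None:
    """Export a result object with deterministic ordering.

    JSON export accepts any of the package's result dataclasses (PathSet,
    state calls, occupancy summaries, ...).  CSV export accepts descriptor
    series, block summaries and heat-map matrices.
    """
    # local imports keep module dependencies one-directional
    from .trajectory_metrics import BlockSummary, DescriptorSeries
    from .pieda import HeatmapMatrix

    path = Path(path)
    if format == "json":
        payload = _jsonable(obj)
        if not isinstance(payload, (dict, list)):
            raise TypeError(f"cannot export {type(obj).__name__} as JSON")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    if format == "csv":
        if isinstance(obj, DescriptorSeries):
            df = pd.DataFrame(
                {
                    "frame": np.arange(len(obj.values)),
                    "time_ns": np.arange(len(obj.values)) * obj.frame_interval,
                    obj.name: obj.values,
                }
            )
            df.to_csv(path, index=False)
            return
        if isinstance(obj, BlockSummary):
            df = pd.DataFrame(
                {
                    "start_ns": [s for s, _ in obj.spans],
                    "end_ns": [e for _, e in obj.spans],
                    "median": obj.medians,
                }
            )
            df.to_csv(path, index=False)
            return
        if isinstance(obj, HeatmapMatrix):
            obj.matrix.to_csv(path)
            return
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
            return
        raise TypeError(f"cannot export {type(obj).__name__} as CSV")
    raise ValueError(f"unsupported export format {format!r}")


def read_pathset(path: str | Path):
    """Re-read a PathSet written by :func:`write_results` (JSON)."""
    from .dynamical_network import PathSet

    data = json.loads(Path(path).read_text())
    return PathSet(
        source=data["source"],
        sink=data["sink"],
        paths=[list(p) for p in data["paths"]],
        distances=[float(d) for d in data["distances"]],
        optimal_distance=data["optimal_distance"],
        offset=float(data["offset"]),
        disconnected=bool(data["disconnected"]),
    )
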