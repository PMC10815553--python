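"""End-to-end orchestration over one or many receptor–ligand complexes.

One YAML config drives the workflow shape of the study: per complex,
activation descriptors → block medians → state calls → communication
network/paths; then PIEDA heat map, polarity and occupancy across all
complexes.  Each complex is isolated — a failing stage is recorded in the
manifest and the run continues — and the manifest carries a checksum per
artifact so identical config + seed reproduce identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dynamical_network as dn
from . import pieda as pieda_mod
from . import trajectory_metrics as tm
from .bw_mapping import BWMapping, read_bw_map
from .io_formats import read_pieda_table, read_trajectory, write_results

logger = logging.getLogger(__name__)

__all__ = ["ComplexEntry", "RunConfig", "run_all", "load_config"]

VALID_CLASSES = ("agonist", "antagonist", "unknown")


@dataclass
class ComplexEntry:
    complex_id: str
    trajectory: Path | None
    pieda: Path | None
    func_class: str = "unknown"
    ligand_resname: str = "LIG"
    ligand_atom: str = "N1"
    frame_interval: float = 0.1


@dataclass
class RunConfig:
    complexes: list[ComplexEntry]
    bw_map: Path
    out_dir: Path
    regions: Path | None = None
    descriptor_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: [("edry_ionic", "npxxy_hbond")]
    )
    block_ns: float = 10.0
    network_cutoff: float = 4.5
    network_frame_fraction: float = 0.75
    network_offset: float = 20.0
    sink: str = "6.29"
    pieda_cutoff: float = 4.5
    pieda_exclude: list[str] = field(default_factory=lambda: ["3.32"])
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.bw_map).exists():
            raise FileNotFoundError(self.bw_map)
        if self.regions is not None and not Path(self.regions).exists():
            raise FileNotFoundError(self.regions)
        ids = [c.complex_id for c in self.complexes]
        if len(set(ids)) != len(ids):
            raise ValueError("complex ids must be unique")
        for c in self.complexes:
            if c.func_class not in VALID_CLASSES:
                raise ValueError(
                    f"{c.complex_id}: class must be one of {VALID_CLASSES}"
                )
            for p in (c.trajectory, c.pieda):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent

    def _p(v):
        return None if v is None else (base / v if not Path(v).is_absolute() else Path(v))

    complexes = [
        ComplexEntry(
            complex_id=str(c["id"]),
            trajectory=_p(c.get("trajectory")),
            pieda=_p(c.get("pieda")),
            func_class=c.get("class", "unknown"),
            ligand_resname=c.get("ligand_resname", "LIG"),
            ligand_atom=c.get("ligand_atom", "N1"),
            frame_interval=float(c.get("frame_interval", 0.1)),
        )
        for c in raw["complexes"]
    ]
    net = raw.get("network", {})
    pie = raw.get("pieda", {})
    return RunConfig(
        complexes=complexes,
        bw_map=_p(raw["bw_map"]),
        regions=_p(raw.get("regions")),
        out_dir=_p(raw["out_dir"]),
        descriptor_pairs=[tuple(p) for p in raw.get("descriptor_pairs", [["edry_ionic", "npxxy_hbond"]])],
        block_ns=float(raw.get("block_ns", 10.0)),
        network_cutoff=float(net.get("cutoff", 4.5)),
        network_frame_fraction=float(net.get("frame_fraction", 0.75)),
        network_offset=float(net.get("offset", 20.0)),
        sink=str(net.get("sink", "6.29")),
        pieda_cutoff=float(pie.get("cutoff", 4.5)),
        pieda_exclude=[str(x) for x in pie.get("exclude", ["3.32"])],
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _descriptor_stage(traj, mapping, entry, config, out):
    artifacts = {}
    region_cfg = (
        tm.load_regions(config.regions) if config.regions is not None else {}
    )
    summaries: dict[str, tm.BlockSummary] = {}
    for name in tm.DESCRIPTOR_NAMES:
        series = tm.motif_distance(traj, mapping, name)
        path = out / f"{entry.complex_id}_{name}.csv"
        write_results(series, path, format="csv")
        artifacts[f"descriptor:{name}"] = path
        summaries[name] = tm.block_medians(series, config.block_ns)
    calls = {}
    for (xn, yn), region in region_cfg.items():
        if xn in summaries and yn in summaries:
            call = tm.classify_blocks(summaries[xn], summaries[yn], region)
            calls[f"{xn}|{yn}"] = {
                "labels": call.labels,
                "fractions": call.fractions,
            }
    if calls:
        path = out / f"{entry.complex_id}_state_calls.json"
        write_results(calls, path, format="json")
        artifacts["state_calls"] = path
    return artifacts


def _network_stage(traj, mapping, entry, config, out):
    nodes = dn.assign_nodes(traj, entry.ligand_resname, entry.ligand_atom)
    ligand_ids = nodes.ligand_ids()
    if not ligand_ids:
        raise ValueError(f"{entry.complex_id}: no ligand node for network stage")
    ligand = min(ligand_ids)
    C = dn.correlation_matrix(traj, nodes)
    mask = dn.contact_mask(
        traj, nodes, config.network_cutoff, config.network_frame_fraction
    )
    net = dn.build_network(C, mask, nodes)
    sink = mapping.resolve(config.sink)
    pathset = dn.suboptimal_paths(net, ligand, sink, config.network_offset)
    anchor = None
    if net.graph.degree(ligand) > 0:
        anchor = dn.ligand_anchor(net, ligand)
    payload = {
        "source": pathset.source,
        "sink": pathset.sink,
        "paths": pathset.paths,
        "distances": pathset.distances,
        "optimal_distance": pathset.optimal_distance,
        "offset": pathset.offset,
        "disconnected": pathset.disconnected,
        "n": pathset.n,
        "N": pathset.N,
        "ligand_anchor": anchor,
        "helix_hops": [
            {
                "segments": dn.helix_hops(p, mapping, ligand_ids).segments,
                "n_transfers": dn.helix_hops(p, mapping, ligand_ids).n_transfers,
            }
            for p in pathset.paths[:50]
        ],
    }
    path = out / f"{entry.complex_id}_paths.json"
    write_results(payload, path, format="json")
    return {"paths": path}


def run_all(config: RunConfig) -> dict:
    """Run descriptors, network and PIEDA stages over all complexes.

    Returns the manifest: per complex, the produced artifacts with sha256
    checksums, or the recorded failure reason; plus the cross-complex PIEDA
    artifacts.  Identical config and seed give identical checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mapping = read_bw_map(config.bw_map)
    manifest: dict = {"complexes": {}, "cross_complex": {}, "failures": {}}
    artifact_paths: dict[str, Path] = {}

    pieda_tables = []
    for entry in config.complexes:
        arts: dict[str, Path] = {}
        if entry.trajectory is not None:
            try:
                traj = read_trajectory(
                    entry.trajectory, frame_interval=entry.frame_interval
                )
                arts.update(_descriptor_stage(traj, mapping, entry, config, out))
                arts.update(_network_stage(traj, mapping, entry, config, out))
            except Exception as exc:
                logger.error("complex %s trajectory stages failed: %s", entry.complex_id, exc)
                manifest["failures"][entry.complex_id] = str(exc)
        else:
            logger.info("complex %s: no trajectory, skipping MD stages", entry.complex_id)
        if entry.pieda is not None:
            try:
                table = read_pieda_table(entry.pieda)
                table.func_class = entry.func_class
                pieda_tables.append(table)
            except Exception as exc:
                logger.error("complex %s PIEDA read failed: %s", entry.complex_id, exc)
                manifest["failures"][entry.complex_id] = str(exc)
        else:
            logger.info("complex %s: no PIEDA table, stage skipped", entry.complex_id)
        manifest["complexes"][entry.complex_id] = {
            k: str(p.name) for k, p in arts.items()
        }
        artifact_paths.update({f"{entry.complex_id}:{k}": p for k, p in arts.items()})

    if pieda_tables:
        heat = pieda_mod.build_heatmap(
            pieda_tables, mapping, config.pieda_exclude, config.pieda_cutoff
        )
        heat_path = out / "heatmap.csv"
        write_results(heat, heat_path, format="csv")
        occ = pieda_mod.occupancy_stats(
            pieda_tables,
            config.pieda_cutoff,
            rng=np.random.default_rng(config.seed),
        )
        occ_path = out / "occupancy.json"
        write_results(
            {
                "counts": occ.counts,
                "per_class": occ.per_class,
                "mean_difference": occ.mean_difference,
                "p_value": occ.p_value,
                "comparison": list(occ.comparison) if occ.comparison else None,
            },
            occ_path,
            format="json",
        )
        import pandas as pd

        polarity = pd.concat(
            [pieda_mod.polarity_table(t) for t in pieda_tables], ignore_index=True
        )
        pol_path = out / "polarity.csv"
        write_results(polarity, pol_path, format="csv")
        manifest["cross_complex"] = {
            "heatmap": heat_path.name,
            "occupancy": occ_path.name,
            "polarity": pol_path.name,
        }
        artifact_paths.update(
            {"heatmap": heat_path, "occupancy": occ_path, "polarity": pol_path}
        )

    manifest["checksums"] = {
        key: _sha256(p) for key, p in sorted(artifact_paths.items())
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
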