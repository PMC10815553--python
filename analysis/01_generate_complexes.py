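#!/usr/bin/env python
"""Generate the synthetic study set: 7 agonist and 10 antagonist complexes.

Each complex gets a 100-frame toy-receptor trajectory (1 ns per frame, so
the same 100-ns span and 10-ns block structure as a production run) with a
planted ligand→R6.29 communication chain, plus a synthetic PIEDA table.
Agonist complexes are built on the active-state geometry, antagonist
complexes on the inactive one, and antagonist tables draw more binding-site
contacts than agonist ones.  Inputs land under scratch/complexes/ (they are
regenerated, never stored); the BW map and state-region config are written
alongside.
"""

from pathlib import Path

from actnet.bw_mapping import write_bw_map
from actnet.io_formats import write_pieda_table, write_trajectory
from actnet.synthetic_data import (
    GeometrySpec,
    PIEDASpec,
    default_state_regions,
    make_pieda_tables,
    make_toy_gpcr,
    write_regions_yaml,
)

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "complexes"
SEED = 2024

N_AGONISTS = 7
N_ANTAGONISTS = 10


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mapping = None
    entries = []
    for state, prefix, count, seed_base in (
        ("active", "AG", N_AGONISTS, 0),
        ("inactive", "AN", N_ANTAGONISTS, 100),
    ):
        for k in range(count):
            cid = f"{prefix}{k + 1}"
            traj, mapping = make_toy_gpcr(
                GeometrySpec(
                    state=state,
                    jitter_sd=0.1,
                    n_frames=100,
                    frame_interval=1.0,
                    plant_pathway=True,
                    seed=SEED + seed_base + k,
                )
            )
            write_trajectory(traj, OUT / f"{cid}.pdb")
            entries.append((cid, state))
            print(f"  {cid}: {state} trajectory, {traj.n_frames} frames")

    tables = make_pieda_tables(
        PIEDASpec(seed=SEED), {"agonist": N_AGONISTS, "antagonist": N_ANTAGONISTS}
    )
    for table in tables:
        write_pieda_table(table, OUT / f"{table.complex_id}_pieda.csv")

    write_bw_map(mapping, OUT / "bw_map.csv")
    write_regions_yaml(default_state_regions(), OUT / "regions.yaml")
    print(f"wrote {len(entries)} complexes + {len(tables)} PIEDA tables to {OUT}")


if __name__ == "__main__":
    main()
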