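# actnet

Post-simulation analysis of GPCR–ligand molecular-dynamics trajectories and
FMO/PIEDA interaction-energy tables, built around the dopamine D4 receptor
question: *what distinguishes how agonists and antagonists engage the
receptor?* The package provides, as a tested library plus a thin CLI:

1. **Activation-state descriptors** — the class-A microswitch geometries
   that separate active from inactive conformations: ligand-binding-site
   tightening (Cα 5.46–Cα 7.42), the NPxxY motif (S3.39⋯N7.49 hydrogen bond,
   C3.44–Y7.53 Cα distance), the P-I-F connector (Cα distances of I3.40 and
   P5.50 to residue 6.44) and the E/DRY ionic lock (R3.50 guanidinium to
   E6.30 carboxylate).  Residues are addressed by Ballesteros–Weinstein
   generic numbers through a user-supplied mapping.  Per-frame series are
   reduced to 10-ns block medians and classified against active/inactive
   reference rectangles, plus standard RMSD/RMSF stability metrics.
2. **Dynamical network analysis** — residues (Cα) and the ligand (basic
   nitrogen) become nodes; pairs in persistent heavy-atom contact
   (≤ 4.5 Å in ≥ 75 % of frames, sequence neighbours excluded) are joined
   by edges weighted w = −log |C|, where C is the motion cross-correlation.
   The module finds the ligand's anchor residue (its strongest-weighted
   contact) and enumerates **all** optimal and suboptimal simple paths to a
   sink residue (default R6.29 at the intracellular end of TMH6) within an
   edge-length offset of 20, exactly — depth-first search with
   branch-and-bound pruning, not sampling.
3. **PIEDA post-processing** — per-residue pair interaction energies (PIE)
   decomposed into E_es, E_ex, E_ct, E_disp and ΔG_solv are turned into the
   polar percentage share

   ```
   %E_es+ct = (|E_es| + |E_ct|) / (|E_es| + |E_ct| + |E_disp|) · 100
   ```

   (100 % = purely polar, 0 % = purely dispersive/hydrophobic), the
   attractive / repulsive / no-contact classification (contact = min
   heavy-atom distance ≤ 4.5 Å, boundary inclusive), the cross-complex
   heat-map matrix (D3.32 excluded by default — its ~−100 kcal/mol salt
   bridge would drown the scale) and an agonist-vs-antagonist comparison of
   binding-site residue occupancy with a seeded label-permutation test.

Because the real inputs (100-ns all-atom MD, MP2-level FMO energies) cannot
be produced at desk scale, a first-class synthetic-data module generates
every input with planted, analytically known structure: correlated-motion
trajectories, a toy seven-helix receptor whose six descriptors hit
prescribed targets, and PIEDA tables with controlled component mixtures.
All generators are bit-deterministic under a seed.

## Worked example

The `analysis/` scripts run the full study shape on a synthetic set of
7 agonist and 10 antagonist complexes:

```sh
python analysis/01_generate_complexes.py   # inputs under scratch/complexes/
python analysis/02_activation_descriptors.py
python analysis/03_communication_paths.py
python analysis/04_pieda_analysis.py
```

Script 02 prints, per class, the fraction of 10-ns blocks classified by the
ionic-lock × NPxxY plane:

```
mean state fractions by class:
            frac_active  frac_inactive
class
agonist             1.0            0.0
antagonist          0.0            1.0
```

i.e. every agonist block sits in the active region (ionic lock open near
20 Å) and every antagonist block in the inactive one (lock closed at
~3.5 Å) — the planted geometries are recovered exactly. Script 03 reports
the communication route of each complex:

```
AN9: anchor 3.36, n=5, N=1, d=2.52 (ligand -> TMH3 -> TMH6)
```

the ligand anchors at C3.36 and the optimal path (n = 5 nodes, N = 1 path
within the offset, total distance 2.52) runs ligand → C3.36 → I3.40 →
F6.44 → R6.29, the planted relay through the P-I-F motif.  Script 04 ends
with the occupancy contrast:

```
occupancy: agonists 8.1 residues (n=7), antagonists 10.3 (n=10);
difference 2.2 in favour of antagonists, permutation p = 0.0082
```

antagonists engage significantly more binding-site residues than agonists,
the planted analogue of the published contrast. Summary tables land under
`results/`.

The same stages are available as a CLI for single complexes:

```sh
actnet descriptors --traj traj.pdb --bw bw_map.csv --regions regions.yaml --out out/
actnet network --traj traj.pdb --bw bw_map.csv --sink 6.29 --offset 20 --out paths.json
actnet pieda --tables pieda1.csv --tables pieda2.csv --bw bw_map.csv --out out/
actnet run --config run.yaml          # full multi-complex pipeline
```

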