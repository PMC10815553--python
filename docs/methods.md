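# Methods

## Scope and model

The package post-processes receptor–ligand MD trajectories and per-residue
FMO/PIEDA energy tables; it never produces them.  Trajectories enter as
multi-model PDB (author residue numbering, 1-based, never renumbered;
energies kcal/mol, distances Å throughout, no unit options).  Ballesteros–
Weinstein generic numbers ("helix.position", position 50 = most conserved
residue of the helix) are an input table, not computed from alignment, and
are handled as strings so "6.48" and "6.480" can never collide.

## Activation descriptors

Six per-frame distances track the class-A microswitches:

| descriptor | atoms | active vs inactive signature |
|---|---|---|
| `lbs_tightening` | Cα 5.46 – Cα 7.42 | cavity contracts on activation |
| `npxxy_hbond` | Ser 3.39 OG – Asn 7.49 amide H (falls back to ND2 without hydrogens, logged) | ~2.8 Å bond vs ~5 Å broken |
| `npxxy_ca` | Cα 3.44 – Cα 7.53 | TMH7 repacking |
| `pif_36` | Cα 3.40 – Cα 6.44 | TMH3/TMH6 approach |
| `pif_56` | Cα 5.50 – Cα 6.44 | TMH5/TMH6 splay |
| `edry_ionic` | min over R3.50 {NH1,NH2,NE,CZ} × E6.30 {OE1,OE2,CD} | ionic lock ~3.5 Å closed, ~20 Å open |

RMSD uses optimal rigid (Kabsch) superposition via
`scipy.spatial.transform.Rotation.align_vectors`; RMSF is measured about
the mean structure after an iterated fit (fit to frame-0-aligned mean,
recompute mean, refit), with a `superpose=False` escape for pre-aligned
input.  Series are reduced to medians over contiguous blocks anchored at
t = 0 (default 10 ns; trailing partial blocks dropped and logged; the
median of an even count is the midpoint of the central pair).  Block
(x, y) median points are classified against closed rectangles per state;
points in no rectangle are *intermediate*.  Rectangles are user
configuration (`regions.yaml`): the published reference regions are drawn,
not tabulated, so the shipped defaults are illustrative rectangles of
±1 Å around the synthetic generator's state targets.  A point on two
touching rectangle edges is resolved by alphabetical label order —
a measure-zero tie made deterministic rather than meaningful.

The residue 6.44 naming follows the P-I-F literature convention of
addressing the residue by its generic number; the package takes no
position on its one-letter identity (the source material itself alternates
between P6.44 and F6.44) and everything is resolved through the mapping.

## Dynamical network

Nodes: one per protein residue anchored at Cα, one for the ligand anchored
at a *named* basic nitrogen (ligands can carry several nitrogens; the
choice is explicit input, not a guess).  The correlation matrix is the
standard dynamical cross-correlation map over 3-D anchor displacements,
C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩).  Edges are admitted where the
two residues' heavy atoms stay within 4.5 Å in ≥ 75 % of frames (both
configurable; the criterion itself is the package's choice, matching the
4.5 Å contact convention used for the energy tables and the standard
network-analysis protocol), excluding sequence nearest neighbours, and
carry weight w = −log |C| (natural log).  The magnitude |C| is used rather
than signed anti-correlation: the two conventions disagree for positively
correlated pairs, and magnitude is the one the underlying network
methodology defines.  A frozen node (zero total fluctuation) is an error
naming the node, not a silent NaN.

Path search: the optimal distance comes from Dijkstra (networkx); the
complete optimal and suboptimal path sets come from an exact depth-first
enumeration with branch-and-bound pruning on precomputed
Dijkstra-to-sink potentials.  The suboptimal bound is *strict*
(distance < optimal + offset, default offset 20), with optimal paths always
included, so offset 0 degenerates to the optimal set; ties are compared at
1e-9 tolerance, all tied optima are reported, and ordering is by
(distance, node sequence).  A configurable path cap (default 10⁵) raises
rather than truncating silently.  Disconnected source/sink yields a
flagged empty result, not an exception.  The ligand anchor is the
minimum-weight ligand edge, ties to the lower residue id (logged).  Paths
are summarised as maximal same-helix runs; transitions between runs count
as inter-helix transfers (a 3-segment path has 2 transfers); ligand and
loop nodes form singleton segments.

## PIEDA post-processing

The polar share is computed on absolute values,
(|E_es|+|E_ct|)/(|E_es|+|E_ct|+|E_disp|)·100, evaluated ratio-first so the
zero-dispersion limit is *exactly* 100 %; an all-zero denominator is a
flagged undefined result.  E_ex and ΔG_solv ride through I/O and totals
but do not enter the share.  Contact classification is closed at the
cutoff (4.5 Å counts as contact; "no contact" means strictly farther, or a
missing distance); attractive means PIE < 0, repulsive PIE > 0, and the
measure-zero PIE = 0 goes to the attractive branch with a log line.  The
heat map copies PIE values untransformed, rows grouped agonists →
antagonists → unknown (alphabetical within groups), columns ordered by
helix.position; unmapped residues keep their raw id with a warning;
excluded generics (default 3.32) are recorded.  Occupancy (contacted
residues per complex) is compared between exactly two classes by the
difference of means under a two-sided label-permutation test
(`scipy.stats.permutation_test`, Monte-Carlo, seeded Generator,
configurable resamples) — chosen because it is distribution-free at the
7–10-complexes-per-class scale where t-approximations are doubtful.

## Synthetic data: what it emulates, and what it does not

`make_correlated_trajectory` plants pairwise motion correlation through
shared Gaussian modes: node i at frame t is
base_i + Σ_g a_g s_g(t) u_g + ε_i(t) with s_g ~ N(0,1) per frame, u_g a
fixed unit direction per group, ε isotropic N(0, σ²) per coordinate
(default σ = 0.15 Å — correlations depend only on a/σ, and this scale keeps
planted contacts persistent under the 4.5 Å cutoff).  For two nodes sharing
one mode the 3-D displacement correlation measured by the estimator is

    ρ = a² / √((a_i² + 3σ²)(a_j² + 3σ²))        (= a²/(a²+3σ²) for a two-node group)

— the 3σ² because the shared mode adds variance along one axis while noise
adds σ² per axis.  `amplitude_for_correlation` inverts this closed form;
recovery tests assert the estimate within 3 standard errors (Fisher-type
SE (1−ρ²)/√F) at 5000 frames.  Planted contacts are embedded by
constrained least squares: planted pairs at exactly the contact distance
(3.2 Å), all other pairs of the same cluster pushed beyond 5.5 Å; an
embedding that cannot satisfy both (e.g. a 4-cycle of short contacts whose
diagonals cannot both clear the floor) raises an infeasibility error.

`make_toy_gpcr` builds a minimal seven-helix receptor as disjoint spatial
clusters, one per descriptor, so each of the six targets is set
independently and exactly (zero jitter reproduces them to 1e-6 Å).  State
target defaults: the ionic lock (active 20 Å / inactive 3.5 Å) and the
broken NPxxY H-bond (inactive 5 Å) follow the published magnitudes; the
remaining four (lbs 11/13, npxxy_ca 7/9, pif_36 9/11.5, pif_56 11/9.5 Å)
are crystal-structure-plausible values chosen once and labelled
illustrative.  With `plant_pathway=True` the ligand, C3.36, I3.40, F6.44
and R6.29 are bridged by side-chain contacts and given chained shared
modes, so the network stage recovers the route ligand → TMH3 → TMH6
through the P-I-F motif.  `make_pieda_tables` defaults to the study shape
(7 agonists, 10 antagonists), always-contacted D3.32 at ~−100 kcal/mol,
per-class contact probabilities 0.5/0.75 (the planted occupancy contrast)
and a 15 % repulsive minority.

None of this is force-field physics: no solvent, no membrane, no realistic
ligand chemistry, residues jitter independently rather than as bonded
chains.  Passing tests therefore demonstrate that the *analysis* recovers
planted geometric, correlational and energetic structure at realistic
problem sizes — not that any receptor behaves this way.

## Problem sizes and numerics

The test suite runs the generators at 2–5000 frames and ≤ 30 residues; the
acceptance properties use 200 random graphs (≤ 10 nodes) against
exhaustive enumeration, 100 seeded replicates for anchor/pathway recovery
at 500 frames, and 500 replicates for permutation-test calibration
(199 resamples each) — sizes at which the brute-force oracles stay exact
and the whole suite completes in well under a minute apiece.  Floating
comparisons: path-distance ties at 1e-9; correlation matrices clipped into
[−1, 1] and symmetrised against rounding; PDB round-trips are exact to the
format's three decimals.

## Known limitations

- Suboptimal-path enumeration is exponential in the worst case; the cap
  turns pathological offsets into an explicit error instead of an endless
  run.
- The no-contact rule trusts the `min_dist` column of the energy table; no
  geometric re-measurement is attempted there.
- `helix_of` knows only what the mapping holds: loop residues and ligands
  are indistinguishable without the caller passing ligand ids.
- Binary trajectory formats (DCD etc.) are not read; the multi-model PDB
  reader contract is the extension point.
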