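# Methods

This note documents the models, conventions and numerical choices behind
`betacorner`, in the order the pipeline applies them.

## The motif and its detection

A 3β-corner is a triple-stranded β-sheet folded onto itself: the first two
strands (A, B) form one β-hairpin, the last two (B, C) another, the two
hairpins pack roughly orthogonally in different layers, and the shared
central strand B bends by about 90° with right-handed chirality as it
crosses between layers. Viewed from the concave face the sheet traces a Z.

Detection is a sequence filter followed by a geometry filter.

**Sequence stage.** Per-residue secondary-structure labels are scanned for
the pattern strand → coil → strand → coil → strand, with strand runs of
4–10 residues, non-strand separators of 3–12 residues, and a total span of
25–55 residues (the length statistics of corners excised from β-barrel
proteins; loops of 3–7 residues form turns, 8–12 unstructured connections —
the loop class is reported, not filtered on). All consecutive triples of
qualifying strand runs are enumerated; overlapping candidates are each
geometry-tested and no non-maximum suppression is applied.

**Geometry stage.** All measurements use Cα coordinates only.

* *Hairpin planes.* Hairpin-AB is strand A pooled with the N-terminal half
  of B; hairpin-BC is the C-terminal half of B pooled with C. Each plane
  normal is the smallest-variance principal direction of the pooled,
  centred Cα scatter; a hairpin whose second principal extent is below 1 Å
  is rejected as degenerate. The interplanar angle is the angle between the
  two normals folded into [0°, 90°] (normals are sign-free).
* *Central-strand bend.* Strand B is split at its midpoint (`len // 2`);
  each half's axis is its largest-variance principal direction oriented
  N→C (for a 2-residue half, the end-to-end direction). The bend angle is
  the angle between the two half axes.
* *Handedness.* With b₁, b₂ the half axes and w the vector from the
  hairpin-AB Cα centroid to the hairpin-BC centroid, the bend is
  right-handed iff (b₁ × b₂) · w > 0. Mirror reflection of the coordinates
  flips exactly this sign, so mirror decoys are rejected here (the
  secondary-structure stage is deliberately handedness-blind for the
  H-bond assigner; the torsion assigner rejects mirrors earlier because
  reflected φ/ψ leave the β box).

Acceptance windows default to interplanar ∈ [55°, 125°] ("roughly
orthogonal") and bend ∈ [50°, 130°] ("≈90°"). The definition is
qualitative and no published tolerances exist, so both windows are
configuration (`MotifWindows`) and should be treated as sensitivity
parameters.

## Secondary-structure assignment

Two independent assigners are provided; the motif detector defaults to the
torsion assigner (robust on idealised and Cα-level inputs), and a majority
`consensus` with a unanimity match rate makes assigner disagreement
measurable (real assigners agree on only about half of residues).

* **H-bond assigner** — Kabsch–Sander electrostatic model: amide hydrogens
  are taken from the file or reconstructed on the bisector of N−C(prev)
  and N−CA at 1.01 Å; a bond exists when
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol.
  Parallel/antiparallel bridge patterns label E, two consecutive
  i→i+4 turns label H, isolated 3/4/5-turns label T, everything else C.
  Bridges, not full DSSP ladders/sheets, are implemented; π-helices,
  bends and STRIDE's empirical potentials are out of scope.
* **Torsion assigner** — E iff φ ∈ [−180°, −45°] and ψ ∈ [45°, 180°] ∪
  [−180°, −170°]; H iff φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; else C;
  residues with an undefined torsion (termini, chain breaks) are C. A
  smoothing pass removes singleton runs: a singleton takes its neighbours'
  label when they agree and at least one neighbour is a genuine run;
  singletons flanked by singletons or by disagreeing neighbours become C
  (so alternating label noise collapses to coil). Box bounds live in
  `TorsionSSBoxes`.

## The stability metric battery

* **RMSD** — least root-mean-square deviation over proper rotations and
  translations (Kabsch via scipy's `align_vectors`; the residual is
  recomputed from the rotated coordinates for full precision). Default
  atom selection: backbone N, CA, C, O.
* **Radius of gyration** — mass-weighted by default (the MD-utility
  convention), stored in Å, reported in nm in tables.
* **SASA** — Shrake–Rupley with probe 1.4 Å and 960 deterministic
  golden-spiral sphere points per atom; Bondi-type van der Waals radii
  (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) from `config.VDW_RADII`;
  hydrogens ignored (heavy-atom convention). The estimate converges to the
  analytic sphere for an isolated atom and to the spherical-cap formula
  for two overlapping spheres (both tested).
* **Hydrogen bonds** — geometric criterion. Without explicit hydrogens
  (the usual case): donor…acceptor heavy-atom distance ≤ 3.5 Å and
  angle(acceptor, donor, donor-antecedent) ≥ 90°. With explicit H:
  D…A ≤ 3.5 Å and D−H…A ≥ 150°. Donors are backbone N plus standard
  side-chain donors; acceptors backbone O/OXT plus side-chain O/N
  acceptors; same-residue pairs and the covalently adjacent backbone
  N(i)…O(i−1) pair are excluded.
* **Torsions** — IUPAC sign convention, wrapped to (−180°, 180°];
  undefined (never an exception) at termini or missing neighbour atoms.
* **Ramachandran classification** — point-in-polygon against editable
  allowed-region polygons (`data/rama_polygons.txt`) with four category
  maps: general, glycine (the general map plus its point reflection —
  glycine's map is centro-symmetric), pre-proline (narrowed α), proline
  (φ pinned near −65°). The polygons are deliberately coarse rectangles:
  they are configuration standing in for contour maps, not a fitted
  density. Classification is invariant under ±360° wraps.

Delta metrics compare an experimental (reference) structure with the
simulated one: ΔSASA = SASA(exp) − SASA(sim), ΔRg = Rg(exp) − Rg(sim),
ΔH_B = H_B(exp) − H_B(sim), plus the relative change ΔRg/Rg(exp) used by
the verdict.

## Conformer-ensemble analysis

Multi-model PDB files stand in for MD trajectories (binary trajectory
formats are out of scope; convert upstream).

* **GROMOS clustering** — all-against-all backbone RMSD (vectorised batch
  Kabsch); the frame with the most neighbours within the cutoff founds a
  cluster, it and its neighbours are removed, repeat. Equal neighbour
  counts are broken by lowest frame index, making the partition
  deterministic.
* **Adaptive cutoff** — start at 0.3 nm; while the partition has more than
  12 clusters raise the cutoff by 0.01 nm, while fewer than 8 lower it;
  accept on landing in [8, 12]; stop after 30 attempts or if the cutoff
  would reach zero, returning the attempt closest to the band (ties →
  fewer clusters) flagged non-converged. The band and schedule are
  configuration: ensembles with only a few genuine conformers (like the
  planted two-state fixtures) cannot reach 8 clusters at any meaningful
  cutoff and are legitimately flagged.
* **Major cluster** — the largest cluster; it is *major* when it holds at
  least 80% of the frames. Simulated ("MD") metric values are averaged
  over the major cluster's frames only; when the 80% rule fails the
  average is still computed over the largest cluster and the flag is
  surfaced.
* **Replicates** — independent ensembles aggregated as mean ± sample SD of
  the replicate means.

## Stability verdict

A structure is judged stable when all three hold:

1. mean backbone RMSD (replicate-averaged, whole trajectory) < 5 Å;
2. |ΔRg| / Rg(exp) ≤ 5%;
3. every residue in an allowed Ramachandran region in the reference stays
   allowed in the simulation.

Worsening any criterion can never flip an unstable verdict to stable
(property-tested). Thresholds are configuration
(`StabilityThresholds`).

For criterion 3 the pipeline classifies the *mean* structure of the major
cluster rather than a single frame: frame-level coordinate noise scrambles
individual dihedrals without any conformational change, and averaging over
the cluster suppresses it. A residue that crossed a polygon edge is
counted as a violation only when its torsions moved by more than
max(10°, 3×SEM), where the SEM of the mean torsion is estimated from the
circular standard deviation of the per-frame torsions across the cluster.
Region boundaries are configuration; hair-width crossings within the noise
of the estimator are classification noise, not lost structure. The strict
class-based comparison remains available as
`trajectory_analysis.rama_retained`.

## Hydrophobic contact analysis

The hydrophobic set defaults to {ALA, VAL, LEU, ILE, MET, PHE, TRP, CYS};
proline is excluded because its cyclic side chain is handled separately in
the torsion analysis and published hydrophobicity scales disagree about
it. The pair distance defaults to side-chain heavy-atom centroids (CA for
glycine), with Cβ–Cβ and closest-heavy-atom alternatives; the contact
cutoff defaults to 12 Å and the histogram bin width to 0.2 Å (left-closed,
right-open, from zero). Contacts are classed by strand membership alone:
inside-strand, A–B, B–C, A–C, or "other" when a loop residue is involved.
A–C contacts bridge the two orthogonal layers and are systematically the
longest — on synthetic corners the pooled distance distribution is bimodal
with a short mode near 6.7 Å and a long A–C-dominated mode; the long
mode's position depends on the layer spacing and side-chain model, so only
its existence and ordering, not its exact position, generalise. No
published contact criterion exists; the defaults are a documented
sensitivity choice.

## Synthetic data: what it emulates and what it does not

The generator produces every input the test battery uses.

* **Ideal segments** are built by sequential natural-extension frames with
  ideal bond geometry (N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231 Å;
  trans peptides); torsions round-trip exactly. Strands use the flat
  two-fold β conformation (φ, ψ) = (−120°, 120°), which keeps assembled
  sheets planar and H-bond ladders well-formed; side chains stop at Cβ.
* **Corners and hairpins** are assembled rigidly: ideal strands placed on
  target lines (sheet spacing 4.9 Å, hairpins in orthogonal planes, the
  central strand's second half bent 90° up for right-handed and down for
  left-handed corners), then joined by loops closed with cyclic
  coordinate descent. Loop ψ values are clamped out of the β box while the
  residue's φ is in the β φ-arc, peptide ω may flex ±15°, the downstream
  strand may slide ±2 Å along its axis to the most reachable placement,
  and candidate closures are selected for junction-torsion safety so the
  generated label pattern matches the construction exactly. Ground truth
  (strand/loop residue ranges, handedness) is emitted with each corner.
* **Decoys**: genuinely left-handed corners (bend reversed, L-residues),
  mirror reflections, coplanar three-strand sheets, random coils
  (torsions sampled outside both boxes) and ideal helices.
* **Ensembles**: states are hinge-rotated copies of a base conformer
  (rotations about one or more chain hinges — multi-hinge grids give many
  well-separated states); frames add isotropic Gaussian coordinate noise.
  Frame counts per state are allocated deterministically
  (round(fraction·n), remainder to the largest state), so planted
  occupancies are exact and only the noise is stochastic. Everything is
  reproducible from a single seed.

Study conditions used by the tests and the acceptance script, chosen once:
two-state occupancy recovery uses 0.85/0.15 at 200 frames with σ = 0.5 Å
noise and a 60° hinge (cross-state backbone RMSD ≈ 5 Å, far above the
0.3 nm cutoff; intra-state ≈ 1.2 Å, far below); the adaptive-loop exercise
uses 10 hinge-grid states at σ = 1.3 Å (fragmented above 12 clusters at
0.3 nm, re-coalescing to 10 within a few raised attempts); stability
analyses use 3 replicate ensembles of 30–40 frames at σ = 0.4–0.5 Å.

What passing these tests shows: the detector, metric battery, clustering
and verdict logic behave correctly on geometry whose ground truth is known
exactly. What it does not show: performance on real crystal structures
(twisted strands, bulges, missing atoms, alternate conformations beyond
simple altlocs) or on real MD (correlated, anisotropic fluctuations rather
than iid noise; solvent effects). The iid noise model in particular makes
per-frame dihedrals noisier, and cluster separations cleaner, than real
trajectories.

## Known limitations

* Strand twist is absent from the generator, so the torsion assigner's β
  box and the geometric windows are exercised near their centres, not
  their edges.
* The H-bond assigner implements bridges and 4-turns only; its strand
  boundaries on real structures will differ from full DSSP at strand
  edges.
* The adaptive cluster band [8, 12] reflects long explicit-solvent
  trajectories; small synthetic ensembles need a narrower band (exposed
  via configuration and the `--cluster-min/--cluster-max` CLI options).
* mmCIF, GROMACS binary trajectories and occupancy refinement are out of
  scope; PDB is the only coordinate format.
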