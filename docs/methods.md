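# Methods

This note records the models, conventions and numerical choices behind
`nrtraj`, what the synthetic generators do and do not emulate, and the
limitations a user should know before applying the package to real
simulation data.

## Helix axes and the two monitoring angles

A helix axis is the segment between two anchor points: the centroid of the
first four and of the last four Cα atoms of the helix's residue span, taken
in increasing residue-number order.  "Center of mass" is computed with unit
masses throughout (a centroid): the point sets are either Cα-only or whole
spans of chemically similar backbone atoms, where mass weighting changes
nothing material, and a centroid keeps the definition free of a mass table.

Two angles monitor H12 displacement:

* **Ang2** is the angle between the H12 and H10 axis vectors,
  `arccos` of the normalised dot product, clamped to [0, 180]°.  It is
  symmetric in its arguments and exact under rigid motion.
* **Ang1** is a vertex angle at the H10/H12 inflection point — the end
  anchor of the H10 axis — between the midpoint of the H3b axis and the end
  anchor of the H12 axis, computed by the law of cosines on the three
  pairwise Euclidean distances.  The three anchor points (H3b midpoint,
  H10 end, H12 end) are one defensible convention for "the shift of H12
  relative to H3b"; they are parameters of the implementation, not
  hard-coded geometry, so an alternative convention can be matched by
  passing different anchors.  Any downstream comparison should hold the
  convention fixed.

Axes shorter than 0.1 Å are rejected as degenerate; cosines are clamped to
[−1, 1] against round-off.  Spans must resolve to ≥ 8 Cα atoms (four per
anchor point).

RMSD uses least-squares rigid superposition (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) on the requested selection
when `superpose_first` is set.  RMSF is the per-atom root-mean-square
fluctuation about the time-average position; the reference is the
time-average structure after aligning every frame to frame 0 on the chosen
selection (the caller aligns explicitly with `superpose_trajectory`, keeping
the alignment selection visible in user code).

## Helicity (SSE%)

A residue is helical when its backbone dihedrals fall in the α-region —
φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°] — and at least one flanking residue's
dihedrals do too; isolated α-region residues are not counted, since a single
residue cannot form a helical turn.  Terminal residues of a span, which lack
one dihedral, inherit their single neighbour's state.  When backbone N/C
atoms are absent, a Cα-only fallback uses the virtual dihedral over
Cα(i−1…i+2), helical in [40°, 70°].  The window bounds are fixed constants,
not tunables: the readout is a deliberately coarse folded/other dichotomy
for the mobile activation helix.  This assignment is simpler than H-bond
based secondary-structure algorithms (DSSP and kin); absolute SSE%
values from other tools are therefore not comparable at the percent level,
but the contrast between a folded and a partially unfolded helix — the
quantity the classification uses — is robust to the choice.

## Interaction detection

All criteria live in `InteractionCriteria` with these defaults:

| interaction | distance | angles |
|---|---|---|
| H-bond | H···A ≤ 2.5 Å | donor (D–H···A) ≥ 120°, acceptor (H···A–X) ≥ 90° |
| hydrophobic | C···C ≤ 3.6 Å | — |
| π–π face-to-face | centroid ≤ 4.4 Å | interplanar ≤ 30° |
| π–π edge-to-face | centroid ≤ 5.5 Å | interplanar ≥ 60° |
| water bridge | H···A ≤ 2.8 Å per leg | donor ≥ 110°, acceptor ≥ 90° |

The 2.5 Å H-bond cutoff is interpreted as the hydrogen–acceptor distance
(the convention under which the 2.5/120/90 triple is a standard default).
The acceptor antecedent X is the nearest covalently bonded partner of the
acceptor (heavy preferred, ≤ 1.9 Å; hydrogen fallback ≤ 1.25 Å); an acceptor
with no bonded partner skips the acceptor-angle test.  Attached hydrogens
are found by distance (≤ 1.25 Å) within the donor's residue, so explicit
hydrogens must be present on donors — the synthetic fixtures place them.  A
protein donor without an attached hydrogen is a hard error; ligand/water
atoms are donor-typed by element (N/O), which over-approximates, so a
hydrogen-less ligand oxygen silently degrades to acceptor-only.

Ring planes are fit by SVD over the ring atoms; the interplanar angle is
folded to [0°, 90°].  The two π–π thresholds and the 30°/60° split are
common-practice values exposed as criteria fields.  Aromatic pairs that also
satisfy the hydrophobic carbon test are reported under both kinds; the
categories are independent counts, not a partition.

Occupancy is per (residue, interaction kind): the fraction of trajectory
frames with at least one event, with the full replica frame count as the
denominator.  Multi-replica aggregation, where used, is the unweighted mean
of per-replica occupancies.

## Energetics post-processing

Binding energies are *inputs*: per-frame totals plus lipophilic, Coulomb and
H-bond terms from an upstream end-point method (MM/GBSA).  The package
applies, in order: end-anchored every-`stride`-th-frame subsampling
(indices `stride−1, 2·stride−1, …`, so a 5000-frame stream at stride 10
keeps exactly 500 frames); ligand-efficiency normalisation
LE = ΔG / (1 + ln HAC); per-replica mean ± SD (SDs over frames, n−1
denominator); and outlier-replica flagging.  The flag rule formalises the
usual by-inspection exclusion of wild replicas: a replica is flagged when
its mean LE deviates from the median of replica means by more than
k × (1.4826 × MAD) of those means, k = 3 by default.  Flags are always
reported and pooled statistics cover only unflagged replicas; if every
replica is flagged the summary errors out rather than report an empty pool.

## Ligand conformations and shape

Frames are superposed on the protein backbone before ligand RMSD, so the
matrix measures ligand motion in the receptor frame with no fit on the
ligand itself.  Clustering is agglomerative with average linkage, cut at a
linkage height of 1 Å (the cutoff is a parameter); clusters are ranked by
occupancy, ties broken toward the lower medoid frame index, with at most
five ranked clusters and the remainder pooled.  The representative of a
cluster is its medoid (minimum summed within-cluster distance).  Molecular
surface is a Shrake–Rupley solvent-accessible area with probe 1.4 Å, 960
deterministic golden-spiral points per atom and Bondi-style vdW radii
(C 1.70, N 1.55, O 1.52, S 1.80, Cl 1.75 Å…); doubling the point count
changes fixture values by < 1%.

## Statistics and classification

Group comparisons use the tie-corrected Kruskal–Wallis H with a χ² p-value
(identical data across groups short-circuits to H = 0, p = 1) followed by
Dunn's pairwise z on mean ranks with the standard tie correction.  Raw and
Bonferroni-adjusted p-values are both reported, with reports defaulting to
adjusted; Cliff's delta accompanies every pair because trajectory samples
run to thousands of frames, where vanishing shifts reach formal
significance — the effect size, not the p-value, carries the information.

Descriptors are autoscaled (zero mean, unit n−1 SD) before PCA/SOM;
constant columns are dropped with a warning.  PCA is an exact SVD with a
fixed sign convention (the largest-magnitude loading of each component is
positive) so scores are reproducible across numerics backends.  The SOM is
batch-trained on a 10 × 10 grid with a Gaussian neighborhood whose radius
decays exponentially from half the grid diagonal to 0.5 and a blending rate
decaying 0.5 → 0.01 over the epochs; the seed controls only weight
initialisation, and identical seeds give identical maps.  Quantization
error is recorded per epoch: it decreases monotonically during the
fine-tuning phase, but the large-radius ordering phase can transiently
raise it above a lucky random initialisation — that is expected SOM
behavior, and the tests assert convergence over the second half of training
rather than global monotonicity.

## The synthetic generators

`simulate_bundle` emulates exactly one thing: a three-helix scaffold whose
*measured* H12 descriptors follow prescribed distributions.  H3b and H10
are ideal helices with small per-frame Gaussian jitter; each frame draws
(Ang1, Ang2, H12–H10 distance) i.i.d. from truncated normals and places a
per-frame H12 template rigidly so the measured values equal the draws
exactly — the placement solves for the H12 orientation (Ang2 against the
measured H10 axis), the axis-end direction (Ang1 at the measured vertex)
and the radial position (a quadratic in the centroid-distance constraint).
Infeasible draws are redrawn; more than 10% redraws aborts generation.
Helicity is dialed by rebuilding the H12 backbone with a regime-controlled
number of helical (−57°, −47°) versus extended (−139°, 135°) residues.

Regime defaults: agonist-like Ang1 70 ± 3°, Ang2 55 ± 4°, helix content
0.95; antagonist-like Ang1 100 ± 12°, Ang2 135 ± 20°, helix content 0.6.
The H12–H10 centroid distances are 12 ± 0.5 Å (docked) and 22 ± 2 Å
(displaced): the docked value and the narrow/broad SD contrast reflect how
tightly H12 packs against H10 in an active LBD versus its loose excursions
once displaced, while the displaced mean is set large enough that the
rigid-placement geometry of this particular scaffold is almost always
feasible — it is a property of the synthetic bundle, not a claim about any
receptor.  Because draws are realised exactly, measured means and SDs are
estimates of the truncated-normal population values; for the antagonist
Ang2 (135 ± 20 truncated to [0, 180]) the truncation shifts the population
mean by about −0.6°, and recovery checks compare against the truncated
mean.

What the bundle does *not* emulate: correlated frame-to-frame dynamics
(frames are i.i.d.), side chains, solvent, any force field, and coupling
between folding and placement beyond the shared regime.  Passing tests
demonstrate that the descriptor estimators recover known inputs under the
stated geometry — not that any receptor behaves this way.

`plant_complex` builds a toy pocket (Glu/Leu/Phe/Ser side-chain fragments,
one water) and a toy ligand whose interaction-bearing atoms move
*independently*: each interaction kind has its own moving atoms, realised
at qualifying geometry in exactly `round(presence_fraction × n_frames)`
frames (chosen by seeded permutation) and parked far outside the criteria
otherwise, with planted geometries at least 0.05 Å / 2° inside or outside
every threshold.  The ligand is therefore not a rigid molecule, and its
shape descriptors (Rg, surface) describe the dispersed toy arrangement;
they are placeholders that vary consistently, not chemistry.  Occupancy
recovery on these fixtures is exact by construction.

`synth_energy_table` draws per-frame totals from a Gaussian per replica
(outlier replicas get replacement means) and splits terms by fixed
fractions (lipophilic 0.6, Coulomb 0.3, H-bond 0.1 of the total).

## The synthetic cohort and problem sizes

The end-to-end cohort pairs each system with a bundle trajectory, a planted
complex and an energy table, with regime-linked settings (agonist-like:
high H-bond occupancy 0.9, ΔG mean −20 kcal/mol; antagonist-like: 0.3 and
−14) plus per-system jitter so rows are not replicates.  Default problem
sizes — 150 frames per bundle, 100 interaction frames, 3 × 200 energy
frames, 12 systems — are chosen so a full cohort run completes in seconds
on one CPU while keeping every recovery check comfortably inside its
statistical tolerance; the acceptance script uses 500-frame bundles for the
parameter-recovery measurements.  With descriptors this strongly
regime-linked, PC1 of the autoscaled table separates the two classes with a
clean threshold; the paper-scale subtlety of partially overlapping real
compounds is out of reach of these fixtures by design.

## Known limitations

* Multi-model PDB is the only trajectory dialect; binary formats must be
  converted upstream.  Coordinates round-trip at PDB precision (10⁻³ Å).
* Donor/acceptor/hydrophobic typing is template- and element-based; exotic
  ligand chemotypes (thiols as donors, halogen bonds, cation–π) are not
  covered.
* Ring perception is template-based for protein aromatics; ligand rings
  must be registered explicitly in the topology.
* The Ang1 anchor-point convention is configurable but has no ground truth
  here; cross-study comparisons must pin it.
* Statistical tests assume exchangeable frames; autocorrelated real
  trajectories violate this, which is another reason effect sizes are
  reported beside p-values.
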