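# nrtraj

Descriptor extraction and chemometric classification for molecular-dynamics
trajectories of nuclear-receptor ligand-binding domains (LBDs).

## The problem

Whether a steroid-hormone receptor such as ERα or GR behaves as activated or
repressed hinges on the position and folding of its C-terminal helix 12
(H12): docked against H3/H10 it completes the coactivator-binding AF-2
surface (agonist state); displaced or unfolded it does not (antagonist
state).  Endocrine-disrupting chemicals (EDCs) perturb this equilibrium, and
MD simulations of ligand-bound LBDs are a standard way to probe which way a
compound pushes it.  `nrtraj` implements the post-simulation analysis layer
for this workflow:

* **H12 geometry** — helix-axis vectors from Cα centroids, the two
  monitoring angles (Ang1: vertex angle at the H10/H12 inflection point
  toward H3b, by the law of cosines on Cα-centroid distances; Ang2: angle
  between the H12 and H10 axis vectors), inter-helix center-of-mass
  distances, RMSD and RMSF.
* **H12 folding** — per-residue helicity from backbone φ/ψ windows
  (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°], with a flanking-residue requirement
  and a Cα-only fallback), summarised as the span's folded fraction (SSE%).
* **Interaction fingerprints** — geometric detectors for hydrogen bonds
  (H···A ≤ 2.5 Å, donor angle ≥ 120°, acceptor angle ≥ 90°), hydrophobic
  carbon contacts (≤ 3.6 Å), π–π stacking (face-to-face ≤ 4.4 Å / ≤ 30°,
  edge-to-face ≤ 5.5 Å / ≥ 60°) and water bridges (2.8 Å / 110° / 90° on
  both legs), aggregated into per-residue occupancies (fraction of frames).
* **Energetics post-processing** — ingestion of per-frame MM/GBSA tables,
  the every-10th-frame subsampling rule, ligand efficiency
  LE = ΔG / (1 + ln HAC), per-replica summaries and MAD-based outlier-replica
  flagging.  (The energies themselves come from upstream tools; `nrtraj`
  never computes force-field terms.)
* **Ligand conformations** — protein-superposed heavy-atom RMSD matrices,
  average-linkage clustering cut at 1 Å (up to five ranked clusters, medoid
  representatives), radius of gyration and probe-rolled molecular surface.
* **Statistics & classification** — Kruskal–Wallis + Dunn post hoc tests
  with Cliff's delta, ECDF/quantile summaries, autoscaled PCA and a 10×10
  Gaussian-neighborhood self-organizing map over the assembled
  system × descriptor feature table.

A first-class synthetic generator (`nrtraj.synthetic`) produces helical
bundles whose measured H12 descriptors follow prescribed agonist-like or
antagonist-like distributions, complexes with interactions planted at exact
occupancies, and replica-structured energy tables — so the whole pipeline is
testable without any simulation data.

## Worked example

```python
import nrtraj as nt

anchors = nt.synthetic_anchors()
for maker in (nt.agonist_params, nt.antagonist_params):
    params = maker(n_frames=500, seed=1)
    traj = nt.simulate_bundle(params, anchors)
    ang = nt.angle_series(traj, anchors)
    sse = nt.sse_fraction(traj, anchors.h12).mean_fraction
    print(params.regime, round(ang.ang1.mean(), 1), round(ang.ang2.mean(), 1),
          round(100 * sse, 1))
```

prints (see `examples/helix_descriptors.py` for the full script):

```
regime               Ang1 (deg)     Ang2 (deg)   H12-H10 (A)   SSE%
agonist_like        69.9 +/-  2.9    55.1 +/-  3.8   12.0 +/- 0.5   99.7
antagonist_like     99.7 +/- 11.8   134.0 +/- 18.4   22.0 +/- 2.0   60.2
```

The measured angle means/SDs recover the generator's regime parameters
(agonist 70 ± 3° / 55 ± 4°, antagonist 100 ± 12° / 135 ± 20°), and the
agonist-like H12 stays essentially fully folded while the antagonist-like
one partially unfolds.  Running the end-to-end cohort classification
(`examples/classify_cohort.py`) on 6 + 6 systems yields PC1 scores around
−3.9 for every agonist-regime system and +3.9 for every antagonist-regime
system — separable by a threshold with zero misclassifications.

The other `examples/` scripts each demonstrate one capability and print
what the numbers mean: `interaction_occupancy.py` (planted occupancies
recovered exactly), `energy_postprocessing.py` (outlier replica flagged,
pooled LE), `ligand_clustering.py` (60/40 conformer split recovered).

A thin CLI wraps the same pipeline: `nrtraj all --seed 3 --out run/`, with
`synth`/`featurize`/`classify` subcommands and a YAML config
(`nrtraj synth --config cohort.yaml`).

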