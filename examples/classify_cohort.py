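"""End-to-end cohort classification: synth -> featurize -> PCA/SOM.

Generates a 12-system synthetic cohort (6 agonist-regime, 6
antagonist-regime), extracts the full descriptor registry for each system,
autoscales, and classifies with PCA and a 10x10 Gaussian-neighborhood SOM.
Prints the PC1 scores by activity class and the separation result.
"""

import json

import nrtraj as nt

config = nt.RunConfig(
    cohort=nt.CohortSpec(n_agonist=6, n_antagonist=6, frames_per_system=120,
                         interaction_frames=100, energy_replicas=3,
                         energy_frames=200),
    seed=11, som_epochs=30, output_dir="cohort_run")
report = nt.run_pipeline(config)

print(f"systems: {report['n_systems']}   "
      f"PC1 explains {100 * report['explained_fraction'][0]:.1f}% of variance")
for cls, scores in report["pc1_by_class"].items():
    formatted = ", ".join(f"{s:6.2f}" for s in scores)
    print(f"  PC1 {cls:<11}: {formatted}")
print(f"misclassifications at the best PC1 threshold: {nt.pc1_separation(report)}")
print(f"SOM quantization error: {report['som_quantization_error']:.3f}")
print(f"\nOutputs written under {config.output_dir}/ "
      "(features.csv, pca_scores.csv, som_assignments.csv, report.json).")
print("A single PC1 threshold separates the two binding regimes because the "
      "angle, distance, folding, occupancy and energy descriptors all shift "
      "together between the docked and displaced H12 states.")
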