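"""Post-process a replica-structured binding-energy stream.

Generates five replicas of per-frame total binding energies (one replica
planted as an outlier), applies the every-10th-frame rule, converts to
ligand efficiency LE = dG / (1 + ln HAC) and prints per-replica and pooled
summaries with the outlier flag.
"""

import nrtraj as nt

table = nt.synth_energy_table(n_replicas=5, frames_per_replica=500,
                              mean=-15.0, sd=1.5, hac=20,
                              outlier_replicas=[(2, 21.0)], seed=3)
print(f"HAC = {table.hac}; LE = dG / (1 + ln {table.hac})"
      f" = dG / {1 + __import__('math').log(table.hac):.4f}\n")

summary = nt.summarize_energies(table, subsample=True, stride=10, outlier_k=3.0)
cols = ["le_mean", "le_std", "dg_lipo_mean", "dg_coulomb_mean", "n"]
print(summary.as_frame()[cols].round(3).to_string())
print()
for flag in summary.flagged_replicas:
    print(f"flagged replica {flag['replica']}: {flag['reason']}")
print("\nThe pooled row covers only the retained replicas, so the planted "
      "+21 kcal/mol replica does not drag the ligand-efficiency mean; "
      "each replica keeps 50 of its 500 frames after subsampling.")
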