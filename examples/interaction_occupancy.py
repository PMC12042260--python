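"""Detect planted protein-ligand interactions and recover their occupancies.

Builds a toy pocket/ligand complex in which an H-bond, a hydrophobic
contact, a pi-pi stack and a water bridge are each present in an exact,
known fraction of frames, runs all four geometric detectors over the
trajectory and prints the per-residue occupancy table.
"""

import nrtraj as nt

planted = {"hbond": 0.38, "hydrophobic": 0.70, "pipi": 0.50, "water_bridge": 0.25}
specs = [nt.InteractionPlantSpec(kind=k, presence_fraction=p)
         for k, p in planted.items()]
traj = nt.plant_complex(specs, n_frames=100, seed=7)

occ = nt.occupancy_series(traj)
print(occ.to_string(index=False))
print()
for row in occ.itertuples():
    target = planted[row.kind]
    print(f"{row.kind:<13} planted {target:.2f}  recovered {row.fraction:.2f}")
print("\nEach occupancy is the fraction of the 100 frames in which the "
      "residue forms at least one interaction of that kind with the ligand; "
      "on these noise-free fixtures the planted presence fraction is "
      "recovered exactly.")
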