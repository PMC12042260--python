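"""Helix-12 geometry descriptors on regime-controlled synthetic bundles.

Generates one agonist-like and one antagonist-like trajectory (500 frames
each), measures the two inter-helix angles, the H12-H10 centroid distance
and the H12 folded fraction, and compares the per-frame Ang2 distributions
with a Kruskal-Wallis + Dunn test.
"""

import numpy as np

import nrtraj as nt

anchors = nt.synthetic_anchors()

print(f"{'regime':<16} {'Ang1 (deg)':>14} {'Ang2 (deg)':>14} "
      f"{'H12-H10 (A)':>13} {'SSE%':>6}")
series = {}
for maker in (nt.agonist_params, nt.antagonist_params):
    params = maker(n_frames=500, seed=1)
    traj = nt.simulate_bundle(params, anchors)
    ang = nt.angle_series(traj, anchors)
    dist = nt.com_distance_series(traj, anchors.h12, anchors.h10).values
    sse = nt.sse_fraction(traj, anchors.h12).mean_fraction
    series[params.regime] = ang.ang2
    print(f"{params.regime:<16} "
          f"{ang.ang1.mean():7.1f} +/- {ang.ang1.std(ddof=1):4.1f} "
          f"{ang.ang2.mean():7.1f} +/- {ang.ang2.std(ddof=1):4.1f} "
          f"{np.mean(dist):6.1f} +/- {np.std(dist, ddof=1):3.1f} "
          f"{100 * sse:6.1f}")

res = nt.kruskal_dunn([series["agonist_like"], series["antagonist_like"]])
row = res.pairwise.iloc[0]
print(f"\nKruskal-Wallis on Ang2: H = {res.h_statistic:.1f}, p = {res.p_value:.3g}")
print(f"Dunn z = {row['z']:.1f}, adjusted p = {row['p_adjusted']:.3g}, "
      f"Cliff's delta = {row['cliffs_delta']:.2f}")
print("\nThe agonist-like regime sits at a narrow docked geometry "
      "(small Ang2, short H12-H10 distance, high helicity); the "
      "antagonist-like regime is broad and displaced, and the rank test "
      "separates the two Ang2 distributions decisively.")
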