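"""Sholl analysis of synthetic cell masks with a per-radius group test.

Builds two groups of star-shaped cells — ramified (microglia-like, many
processes) and simplified (engrafted-macrophage-like, few processes) —
profiles them on 2-60 um circles and compares groups radius by radius.
"""

import numpy as np

from bemkit.morphometry import ShollConfig, compare_profiles, sholl_profile
from bemkit.synthdata import MorphTruth, gen_cell_mask

rng = np.random.default_rng(31)
config = ShollConfig(center=(64, 64))
profiles = []
for group, ray_range, length_range in [("ramified", (5, 8), (30, 45)), ("simplified", (2, 4), (18, 30))]:
    for i in range(8):
        truth = MorphTruth(int(rng.integers(*ray_range)), float(rng.uniform(*length_range)), (64, 64))
        mask = gen_cell_mask(truth, (129, 129), seed=1000 + len(profiles))
        profiles.append(sholl_profile(mask, config, cell_id=f"{group}_{i}", group=group))

table = compare_profiles(profiles)
print("radius_um  mean_ramified  mean_simplified        p")
for _, row in table[table["radius_um"] <= 30].iterrows():
    print(
        f"{row['radius_um']:>8.0f}  {row['mean_ramified']:>13.1f}  "
        f"{row['mean_simplified']:>15.1f}  {row['p']:>8.2g}"
    )
sig = table[(table["p"] < 0.05)]
print(f"\nradii with p < 0.05 (unpaired Welch t, unadjusted): {len(sig)} of {len(table)}")
print("# ramified cells keep more intersections at mid radii; the profile drop-off")
print("# past each group's process length drives the separation")
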