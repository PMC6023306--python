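"""Compute all pairwise voxel correlations as one condensed array.

Builds a tiny 3-voxel matrix whose rows are perfectly (anti)correlated,
runs the engine, and shows how condensed positions map back to voxel
pairs.
"""

import voxcorr as vc

ts = vc.TimeSeriesMatrix([[1, 2, 3], [3, 2, 1], [1, 2, 3]],
                         voxel_order_tag="example")
condensed, plan = vc.compute_condensed(ts, budget_elements=1000, precision="f64")

print(f"{ts.n_voxels} voxels -> {vc.triangle_size(ts.n_voxels)} distinct pairs")
for k, r in enumerate(condensed.values):
    i, j = vc.linear_to_pair(k, ts.n_voxels)
    print(f"  position {k}: voxels ({i},{j})  r = {r:+.1f}")
# Rows 0 and 2 are identical (r=+1); row 1 runs backwards (r=-1 with both).
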