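"""Seed-based causality mapping on a synthetic voxel grid.

Builds an 8x8x8 volume with six contiguous modules where module 1's
latent drives module 2's, extracts voxel time series through a mask,
detects the two-level community structure, and maps which voxels the
module-1 seed region drives.
"""

import numpy as np

from pcgc import (
    RunConfig,
    build_hier_partition,
    correlation_matrix,
    generate_voxel_fixture,
    read_volume_series,
    seed_map,
)

img, mask, labels = generate_voxel_fixture((6, 6, 6), 4, 400, seed=1, coupling=0.8)
ts = read_volume_series(img, mask)
flat = labels.grid.ravel(order="F")

w = np.abs(correlation_matrix(ts))
np.fill_diagonal(w, 0.0)
hier = build_hier_partition(w, restarts=10, seed=1)

seed_vox = list(np.flatnonzero(flat == 1))
smap = seed_map(ts, seed_vox, hier, RunConfig(), direction="out")

for m in range(1, 5):
    members = np.flatnonzero(flat == m)
    members = [v for v in members if v not in seed_vox]
    if not members:
        print(f"module {m}: (seed region)")
        continue
    frac = np.mean(smap.significant[members])
    print(f"module {m}: {frac:.0%} of voxels significantly driven by the seed")
print()
print("Only the planted target module shows widespread incoming influence;")
print("voxels in the uncoupled modules stay at the false-positive floor.")
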