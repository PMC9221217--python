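"""Image-space feature extraction on a simulated cohort.

Simulates a small two-group cohort (4D BOLD-like volumes plus modulated
GM-like maps) on a toy lattice atlas, then extracts the two feature families
the classifier consumes: per-region mean Hurst exponent and per-region
gray-matter volume.
"""

import numpy as np

from atlasfusion import (
    CohortSpec,
    VoxelSeriesSet,
    hurst_map,
    make_lattice_atlas,
    roi_reduce,
    roi_volumes,
    simulate_cohort,
)

atlas = make_lattice_atlas((8, 8, 8), (2, 2, 2))  # 8 regions, 3 mm voxels
spec = CohortSpec(
    n_positive=4,
    n_negative=4,
    effect_regions={"GMV": [1], "HE": [8]},
    effect_size=2.0,  # atrophy of 2 voxel-SDs in region 1 (patients)
    h_by_group=(0.75, 0.5),  # persistent BOLD in region 8 (patients)
    n_timepoints=128,
    seed=7,
)
cohort = simulate_cohort(spec, atlas)
mask = atlas.labels > 0

he_rows, gmv_rows = [], []
for series4d, gm in zip(cohort.bold, cohort.gm_maps):
    ts = VoxelSeriesSet.from_4d(series4d, mask, tr_seconds=spec.tr_seconds)
    he_rows.append(roi_reduce(hurst_map(ts), atlas, reducer="mean"))
    gmv_rows.append(roi_volumes(gm, atlas))

he = np.array(he_rows)
gmv = np.array(gmv_rows)
patients = cohort.labels == 1

print("per-region group means (8 lattice regions):")
print("  mean HE,  patients:", np.round(he[patients].mean(axis=0), 3))
print("  mean HE,  controls:", np.round(he[~patients].mean(axis=0), 3))
print("  GMV (ml), patients:", np.round(gmv[patients].mean(axis=0), 3))
print("  GMV (ml), controls:", np.round(gmv[~patients].mean(axis=0), 3))
print(
    "\nRegion 8 (last column) carries the planted persistence contrast:"
    "\npatients' mean HE exceeds controls' there. Region 1 (first column)"
    "\ncarries the planted atrophy: patients' GM volume is lower."
)
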