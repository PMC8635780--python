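"""Calibration of the random-field cluster correction on null fields.

Simulates smooth Gaussian null volumes (6 mm FWHM on 2 mm voxels),
forms |z| > 3.29 clusters and counts how often any cluster reaches
corrected p < 0.05.  A calibrated procedure stays at or below the
nominal 5%; the classical extent distribution is deliberately a little
conservative.
"""

import numpy as np
from scipy import ndimage, stats

from corticovar import rft

voxel, fwhm, grid, n_fields = 2.0, 6.0, (32, 32, 32), 300
sigma = fwhm / np.sqrt(8 * np.log(2)) / voxel
mask = np.ones(grid, bool)
zthr = stats.norm.isf(0.001 / 2)
geom = rft.RftGeometry.from_fwhm(mask.sum(), voxel ** 3, (fwhm,) * 3)

rng = np.random.default_rng(0)
hits = 0
for _ in range(n_fields):
    f = ndimage.gaussian_filter(rng.standard_normal(grid), sigma, mode="wrap")
    f /= f.std()
    comps = rft.label_clusters(f, zthr, mask)
    if comps and rft.cluster_p(len(comps[0]), 0.001, geom) < 0.05:
        hits += 1

print(f"search region: {geom.search_voxels} voxels, {geom.resels:.0f} resels")
print(f"family-wise false-positive rate at corrected p<0.05: "
      f"{hits / n_fields:.3f} over {n_fields} null fields")
print("A value near (or somewhat below) 0.05 means the correction controls "
      "false positives at the cluster level.")
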