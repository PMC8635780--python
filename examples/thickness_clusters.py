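"""Vertex-wise thickness group GLM with cluster extraction.

Builds a spherical toy cortex, injects a +0.45 mm patch of thicker
cortex in patients (3x the 0.15 mm between-subject noise), smooths each
map at 10 mm FWHM, fits thickness ~ group + sex + age per vertex and
reports sign-homogeneous clusters with p < 0.001 and area >= 30 mm^2.
"""

import numpy as np

from corticovar import synthetic, surface

mesh = synthetic.make_toy_surface(subdivisions=3, radius=50.0)
meta = synthetic.make_cohort_meta(11, 24, seed=1)
d = np.linalg.norm(mesh.vertices - mesh.vertices[100], axis=1)
patch = np.where(d < 12)[0]
data = synthetic.simulate_thickness_dataset(
    mesh, meta, effect_patches=[(patch, 0.45)], noise_sd=0.15, seed=3)

stats = surface.vertex_group_glm(data, fwhm=10.0)
clusters = surface.find_surface_clusters(stats, p_thresh=0.001, min_area=30.0)
print(surface.cluster_report(clusters, data).to_string(index=False))
print(f"\npeak inside injected patch: {clusters[0].peak_index in patch}")
print("Each row: peak coordinate, surface extent (mm^2), peak p, and group "
      "mean (sd) smoothed thickness at the peak vertex.")
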