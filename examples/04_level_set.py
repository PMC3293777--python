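"""Step 3: seed a 3D geodesic active contour from salient contours.

Eroded contour interiors seed a fast march through the probability map;
the geodesic active contour (advection 160, curvature 6.75, propagation
1) then snaps the front to organelle boundaries and smooths it in 3D.
"""

import numpy as np
from scipy.ndimage import gaussian_filter

from mitoseg import LevelSetParams, PipelineConfig, detect_isocontours, filter_by_perimeter
from mitoseg.levelset import edge_potential, run_geodesic_active_contour, seeds_from_contours
from mitoseg.patches import ProbabilityMap

# an ideal probability blob standing in for step-1 output on one organelle
nz, ny, nx = 9, 120, 120
zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
truth = (((xx - 60) / 35.0) ** 2 + ((yy - 60) / 30.0) ** 2 + ((zz - 4) / 3.2) ** 2) <= 1
prob = gaussian_filter(truth.astype(np.float32), sigma=(0, 1.5, 1.5))
spacing = (50.0, 10.0, 10.0)

cfg = PipelineConfig()
contours = []
for z in range(nz):
    cs = detect_isocontours(prob[z], cfg.iso_levels, spacing[1:], plane_i=z, ref_value=1.0)
    contours += filter_by_perimeter(cs, cfg.perimeter_min_um, cfg.perimeter_max_um)

seeds = seeds_from_contours(contours, (nz, ny, nx), spacing, cfg.erosion_px)
speed = edge_potential(ProbabilityMap(prob, spacing))
out = run_geodesic_active_contour(
    seeds, speed, LevelSetParams(), spacing, fast_march_speed=prob
).data.astype(bool)

tpr = (out & truth).sum() / truth.sum()
fpr = (out & ~truth).sum() / (~truth).sum()
print(f"{len(contours)} contours -> {int(seeds.sum())} seed voxels after 10 px erosion")
print(f"level-set output: TPR {tpr:.3f}, FPR {fpr:.4f} against the ideal blob")
# the front recovers the whole organelle from the eroded seeds and stops
# at the probability boundary instead of leaking into background
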