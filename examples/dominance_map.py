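"""Where does each sub-model drive the fused evolution?

On a clean two-phase disk the fusion weight w = exp(-sigma_3x3/d) equals
1 in flat areas (ADPLS drives) and drops near intensity edges (LBF
drives).  This script measures, on the first iteration, how the
LBF-dominant pixels concentrate around the true object boundary.
"""

import numpy as np
from scipy import ndimage

from fuseseg import FusionParams, initialize_phi, make_initial_region, make_scene, weight_map
from fuseseg.adpls import EdgeIndicatorField, adpls_step
from fuseseg.lbf import lbf_step

scene = make_scene(bias_strength=0.0, noise_sigma=0.0, seed=7)
region = make_initial_region(scene, "straddling", seed=7)
p = FusionParams()

phi0 = initialize_phi(scene.image.shape, region)
w = weight_map(scene.image, p.d)
a = adpls_step(phi0, EdgeIndicatorField.from_image(scene.image, p.adpls), p.adpls)
l = lbf_step(phi0, scene.image, p.lbf)
dominant = (1 - w) * np.abs(l) > w * np.abs(a)

edge = scene.truth_mask & ~ndimage.binary_erosion(scene.truth_mask)
dist = ndimage.distance_transform_edt(~edge)
print(f"mean fusion weight w        : {w.mean():.3f} (1.0 in perfectly flat areas)")
print(f"LBF-dominant pixels         : {int(dominant.sum())}")
print(f"edge pixels covered         : {100 * (dominant & edge).sum() / edge.sum():.1f}%")
print(f"dominant within 3px of edge : {100 * (dominant & (dist <= 3)).sum() / max(dominant.sum(), 1):.1f}%")
print("The local-fitting force concentrates exactly where accuracy matters: the boundary.")
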