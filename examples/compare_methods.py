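"""Fused vs pure-ADPLS vs pure-LBF on the same scene and initialization.

The edge-based ADPLS flow is fast but blind to local statistics; the LBF
region flow is locally accurate but initialization sensitive.  The fused
evolution blends them per pixel and outscores both.
"""

from fuseseg import FusionParams, dice_jaccard, make_initial_region, make_scene, run_segmentation

scene = make_scene(seed=7)
region = make_initial_region(scene, "straddling", seed=7)
params = FusionParams(iter_max=200)

for method in ("fusion", "adpls", "lbf"):
    res = run_segmentation(scene.image, region, params, method=method)
    dice, _ = dice_jaccard(res.mask, scene.truth_mask)
    print(f"{method:6s}  Dice = {dice:.4f}")
print("The fused evolution should clearly dominate both sub-models here:")
print("ADPLS stalls/collapses in the noisy flats, LBF sticks in a local minimum.")
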