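"""Segment a bias-corrupted disk with the fused evolution.

Builds the standard test scene -- a disk (intensity 180) on background 70
under a 40% multiplicative shading ramp plus Gaussian noise -- and runs
the fused level-set evolution from a rectangle straddling the boundary.
"""

from fuseseg import FusionParams, dice_jaccard, make_initial_region, make_scene, run_segmentation

scene = make_scene(seed=7)  # 128x128 disk, ramp bias 0.4, noise sigma 5
region = make_initial_region(scene, "straddling", seed=7)

result = run_segmentation(scene.image, region, FusionParams(iter_max=200), method="fusion")
dice, jaccard = dice_jaccard(result.mask, scene.truth_mask)

print(f"iterations run : {result.iterations_run}")
print(f"foreground px  : {int(result.mask.sum())} (truth {int(scene.truth_mask.sum())})")
print(f"Dice           : {dice:.4f}")
print(f"Jaccard        : {jaccard:.4f}")
print("Dice ~ 1 means the recovered mask almost exactly matches the ground-truth disk")
print("despite the shading gradient that defeats global thresholds.")
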