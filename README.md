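# fuseseg

Adaptive fused level-set segmentation for 2-D grayscale images with
intensity inhomogeneity (the smooth multiplicative shading typical of MR
and X-ray acquisition).

Active-contour segmentation embeds a closed contour as the zero set of a
scalar field φ (negative inside) and evolves φ until the contour locks
onto object boundaries. Two classical evolutions have complementary
failure modes:

- **ADPLS** (adaptive distance preserving level set), an edge-based flow

  Δφ_ADPLS = { α[∇²φ − div(∇φ/|∇φ|)] + β δ_ε₁(φ) div(g ∇φ/|∇φ|) + v(I) g δ_ε₁(φ) } Δt

  with edge indicator g = exp(−|∇G_σ∗I|^m) and a signed, image-adaptive
  balloon coefficient v(I) = c · sgn(ΔG_σ∗I) · |∇G_σ∗I|. It is fast
  (large time step) and insensitive to where the initial contour is
  placed, but it knows nothing about local intensity statistics and
  fails under strong shading.

- **LBF** (local binary fitting), a region-based flow that fits two
  spatially varying intensity functions f₁ (outside) and f₂ (inside)
  through Gaussian-window weighted means and moves the contour downhill
  on the local fitting energy

  Δφ_LBF = { −δ_ε₂(φ)(λ₁e₁ − λ₂e₂) + ν δ_ε₂(φ) div(∇φ/|∇φ|) + μ[∇²φ − div(∇φ/|∇φ|)] } Δt.

  It handles inhomogeneity well but is slow and sensitive to the initial
  contour (local minima).

**fuseseg** combines them per pixel with a weight derived from the local
intensity standard deviation in a 3×3 window,

    w(I) = exp(−σ₃ₓ₃(I) / d),        Δφ = w(I) Δφ_ADPLS + (1 − w(I)) Δφ_LBF,

so the robust edge-based flow drives the evolution in homogeneous areas
(w → 1) and the accurate local-fitting flow takes over near boundaries
and in high-variance regions (w → 0). The package also ships a seeded
synthetic-scene generator (disks, annuli, branching vessel-like tubes,
multi-object grids, multiplicative bias fields, Gaussian noise, ground
truth), overlap metrics (Dice/Jaccard/Hausdorff), YAML configuration and
a small CLI.

## Worked example

```python
from fuseseg import FusionParams, dice_jaccard, make_initial_region, make_scene, run_segmentation

scene = make_scene(seed=7)            # 128x128 disk, 40% shading ramp, noise sigma 5
region = make_initial_region(scene, "straddling", seed=7)
result = run_segmentation(scene.image, region, FusionParams(iter_max=200), method="fusion")
dice, jaccard = dice_jaccard(result.mask, scene.truth_mask)
print(result.iterations_run, round(dice, 4), round(jaccard, 4))
```

prints

```
200 0.9981 0.9963
```

a near-perfect recovery of the ground-truth disk (3216 of 3228 true
pixels) despite shading that tilts the object's intensity by ~19% across
its width. Under identical conditions the pure sub-models reach Dice
0.0399 (ADPLS, collapses in the noisy flats) and 0.7839 (LBF, stuck in a
local minimum) — run `python examples/compare_methods.py` to reproduce.
The other scripts in `examples/` demonstrate initialization robustness
(fused Dice range 0.037 over four placements vs 0.368 for LBF), the
model-dominance map (the LBF force concentrates on the true boundary,
81% edge coverage) and the scene generator.

The same pipeline is available from the shell:

```bash
fuseseg synth --kind disk --seed 7 --out-prefix /tmp/scene
fuseseg segment --input /tmp/scene_image.png --init-rect 40,40,88,88 --method fusion --out-mask /tmp/pred.png
fuseseg eval --pred /tmp/pred.png --truth /tmp/scene_mask.png
```

## Scope

2-D single-channel images only; no multi-phase or color extensions, no
narrow-band acceleration, no DICOM/NIfTI I/O. See `docs/methods.md` for
the model details, parameter defaults and known limitations.
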