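"""Ground-truthed synthetic scenes with intensity inhomogeneity.

Scenes are piecewise-constant objects (disk, two disks, annulus,
branching vessel-like tube, grid of squares) rendered at two intensity
levels, corrupted by a smooth multiplicative bias field -- the shading
artifact typical of MR and X-ray acquisition -- and additive Gaussian
noise:

    image = clip(base * bias + noise, 0, 255)

The bias field has spatial mean 1 and peak-to-trough ratio
``(1 + bias_strength) / (1 - bias_strength)``.  At the default strength
of 0.4 the foreground and background intensity histograms of the disk
scene overlap, the regime in which global-threshold (and purely
edge-based) segmentation fails.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so identical seed and parameters reproduce a scene bit for bit on any
platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

SCENE_KINDS = ("disk", "two_disks", "ring", "vessel", "checker")
PLACEMENTS = ("inside", "outside", "straddling", "corner")


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray
    truth_mask: np.ndarray  # boolean
    bias_field: np.ndarray
    noise_sigma: float
    seed: int
    scene_kind: str
    params: dict = field(default_factory=dict)


def _grid_dist(h: int, w: int, center: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:h, 0:w]
    return np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)


def _shape_mask(kind: str, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    s = min(h, w)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    if kind == "disk":
        return _grid_dist(h, w, center) <= s / 4.0
    if kind == "two_disks":
        d1 = _grid_dist(h, w, (h / 2.0, w / 3.0)) <= s / 6.0
        d2 = _grid_dist(h, w, (h / 2.0, 2.0 * w / 3.0)) <= s / 8.0
        return d1 | d2
    if kind == "ring":
        r = _grid_dist(h, w, center)
        return (r >= s / 5.0) & (r <= s / 3.0)
    if kind == "checker":
        mask = np.zeros((h, w), dtype=bool)
        cell_h, cell_w = h // 7, w // 7
        for i in (1, 3, 5):
            for j in (1, 3, 5):
                mask[i * cell_h : (i + 1) * cell_h, j * cell_w : (j + 1) * cell_w] = True
        return mask
    if kind == "vessel":
        return _vessel_mask(h, w, rng)
    raise ValueError(f"kind must be one of {SCENE_KINDS}, got {kind!r}")


def _stamp_tube(mask: np.ndarray, path: list[tuple[float, float]], radius: float) -> None:
    h, w = mask.shape
    rr, cc = np.mgrid[0:h, 0:w]
    for r, c in path:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def _vessel_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth random-walk tube, ~5 px wide, with one thinner branch."""
    margin = 6.0
    mask = np.zeros((h, w), dtype=bool)
    row = h / 2.0 + rng.uniform(-h / 10.0, h / 10.0)
    drift = 0.0
    path = []
    for col in np.arange(margin, w - margin, 1.0):
        drift = 0.85 * drift + rng.normal(0.0, 0.35)
        row = float(np.clip(row + drift, margin, h - margin))
        path.append((row, col))
    _stamp_tube(mask, path, 2.4)
    # one branch leaving the midpoint at a diagonal
    mid_row, mid_col = path[len(path) // 2]
    brow, bdrift = mid_row, -1.0 if mid_row > h / 2.0 else 1.0
    branch = []
    for col in np.arange(mid_col, min(mid_col + w / 3.0, w - margin), 1.0):
        bdrift = 0.9 * bdrift + rng.normal(0.0, 0.25)
        brow = float(np.clip(brow + bdrift, margin, h - margin))
        branch.append((brow, col))
    _stamp_tube(mask, branch, 1.7)
    return mask


def _bias_field(kind: str, h: int, w: int, strength: float) -> np.ndarray:
    if strength == 0.0 or kind == "none":
        return np.ones((h, w))
    lo, hi = 1.0 - strength, 1.0 + strength
    if kind == "ramp":
        b = np.tile(np.linspace(lo, hi, w), (h, 1))
    elif kind == "gaussian_bump":
        # bump peaked off-center in the background so part of the object
        # sits near the trough: maximal fg/bg histogram mixing
        q = (0.15 * (h - 1), 0.15 * (w - 1))
        sb = 0.22 * min(h, w)
        b = lo + (hi - lo) * np.exp(-(_grid_dist(h, w, q) ** 2) / (2.0 * sb**2))
    else:
        raise ValueError(f"bias_kind must be none|ramp|gaussian_bump, got {kind!r}")
    return b / b.mean()


def make_scene(
    kind: str = "disk",
    height: int = 128,
    width: int = 128,
    fg_intensity: float = 180.0,
    bg_intensity: float = 70.0,
    bias_kind: str = "ramp",
    bias_strength: float = 0.4,
    noise_sigma: float = 5.0,
    seed: int = 0,
) -> SyntheticScene:
    """Render a ground-truthed scene under the stated corruption model.

    With ``bias_strength=0`` and ``noise_sigma=0`` the image takes exactly
    the two values {fg_intensity, bg_intensity}.
    """
    if height < 32 or width < 32:
        raise ValueError("scene dimensions must be at least 32 pixels")
    if fg_intensity == bg_intensity:
        raise ValueError("foreground and background intensities must differ")
    if not 0.0 <= bias_strength < 1.0:
        raise ValueError(f"bias_strength must be in [0, 1), got {bias_strength}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be nonnegative, got {noise_sigma}")
    rng = np.random.default_rng(seed)
    mask = _shape_mask(kind, height, width, rng)
    bias = _bias_field(bias_kind if bias_strength > 0 else "none", height, width, bias_strength)
    base = np.where(mask, float(fg_intensity), float(bg_intensity))
    noise = rng.normal(0.0, noise_sigma, size=base.shape) if noise_sigma > 0 else 0.0
    image = np.clip(base * bias + noise, 0.0, 255.0)
    return SyntheticScene(
        image=image,
        truth_mask=mask,
        bias_field=bias,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
        scene_kind=kind,
        params=dict(
            kind=kind,
            height=height,
            width=width,
            fg_intensity=float(fg_intensity),
            bg_intensity=float(bg_intensity),
            bias_kind=bias_kind,
            bias_strength=float(bias_strength),
            noise_sigma=float(noise_sigma),
            seed=int(seed),
        ),
    )


def make_initial_region(scene: SyntheticScene, placement: str = "straddling", seed: int = 0) -> np.ndarray:
    """Seeded rectangular initial region in a stated relation to the truth.

    ``inside`` is contained in the object, ``outside`` is disjoint from
    it, ``straddling`` overlaps the object boundary, and ``corner`` sits
    in an image corner (the stress case for initialization-sensitive
    models).  The rectangle is at least 8x8 pixels.
    """
    if placement not in PLACEMENTS:
        raise ValueError(f"placement must be one of {PLACEMENTS}, got {placement!r}")
    rng = np.random.default_rng(seed)
    truth = scene.truth_mask
    h, w = truth.shape
    region = np.zeros((h, w), dtype=bool)

    if placement == "corner":
        size = 12
        corners = [(2, 2), (2, w - size - 2), (h - size - 2, 2), (h - size - 2, w - size - 2)]
        r0, c0 = corners[int(rng.integers(len(corners)))]
        region[r0 : r0 + size, c0 : c0 + size] = True
        return region

    if placement == "straddling":
        boundary = truth & ~ndimage.binary_erosion(truth)
        cand = np.argwhere(boundary)
        if len(cand) == 0:
            raise ValueError("scene has no object boundary to straddle")
        r, c = cand[int(rng.integers(len(cand)))]
        half = 8
        r0, c0 = int(np.clip(r - half, 0, h - 2 * half)), int(np.clip(c - half, 0, w - 2 * half))
        region[r0 : r0 + 2 * half, c0 : c0 + 2 * half] = True
        if not (region & truth).any() or not (region & ~truth).any():
            raise ValueError("could not place a straddling rectangle for this scene")
        return region

    target = truth if placement == "inside" else ~truth
    dist = ndimage.distance_transform_edt(target)
    if placement == "outside":  # keep clear of the frame border
        border = np.zeros_like(dist, dtype=bool)
        border[8:-8, 8:-8] = True
        dist = np.where(border, dist, 0.0)
    min_half = 4
    cand = np.argwhere(dist >= min_half * np.sqrt(2.0) + 1.0)
    cand = cand[
        (cand[:, 0] >= min_half)
        & (cand[:, 0] <= h - min_half)
        & (cand[:, 1] >= min_half)
        & (cand[:, 1] <= w - min_half)
    ]
    if len(cand) == 0:
        raise ValueError(f"cannot fit an 8x8 rectangle with placement={placement!r}")
    r, c = cand[int(rng.integers(len(cand)))]
    half = int(min((dist[r, c] - 1.0) / np.sqrt(2.0), 12, r, c, h - r, w - c))
    region[r - half : r + half, c - half : c + half] = True
    return region


def save_scene(scene: SyntheticScene, out_prefix: str | Path) -> dict[str, Path]:
    """Write the scene as 8-bit PNGs plus a JSON parameter sidecar."""
    import imageio.v3 as iio

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": prefix.with_name(prefix.name + "_image.png"),
        "mask": prefix.with_name(prefix.name + "_mask.png"),
        "meta": prefix.with_name(prefix.name + "_meta.json"),
    }
    iio.imwrite(paths["image"], np.round(scene.image).astype(np.uint8))
    iio.imwrite(paths["mask"], scene.truth_mask.astype(np.uint8) * 255)
    paths["meta"].write_text(json.dumps(scene.params, indent=2) + "\n")
    return paths
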