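"""Synthetic canopy and single-leaf imagery with exact ground-truth masks.

The real imagery this emulates — top-view photographs of dense lettuce
canopies in a plant factory, plus single-leaf disease datasets — is not
redistributable, so the generators below provide the statistical structure
the method relies on:

* a dense, locally smooth green texture built from overlapping randomized
  elliptical "leaves" with gentle shading (any crop of it looks like a
  canopy, which is what lets one classifier serve every scale);
* rare, sparse, small yellow-brown lesions (count Poisson with mean 3 by
  default, diameters roughly 4-12 px) whose rendered pixels define the
  ground-truth mask exactly;
* single leaves: one elliptical leaf on a near-uniform dull background,
  kept clear of the image corners so corner patches are pure background,
  with optional lesion spots on the leaf.

Everything is driven by a :class:`numpy.random.Generator`, so a fixed seed
reproduces every artifact bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.color import hsv2rgb
from skimage.draw import disk, ellipse
from skimage.filters import gaussian


@dataclass(frozen=True)
class CanopySpec:
    rows: int = 352
    cols: int = 576
    leaf_density: float = 0.004            # ellipses per pixel
    leaf_axis_range: tuple[float, float] = (6.0, 18.0)
    green_hue_range: tuple[float, float] = (0.22, 0.38)
    noise_sigma: float = 0.02              # per-pixel value noise, pre-blur
    lesion_count: int | None = None        # fixed count; None -> Poisson
    lesion_rate: float = 3.0               # Poisson mean when count is None
    lesion_radius_range: tuple[float, float] = (2.0, 6.0)   # diameter 4-12 px
    lesion_hue_range: tuple[float, float] = (0.07, 0.13)    # yellow-brown


@dataclass(frozen=True)
class LeafSpec:
    rows: int = 256
    cols: int = 256
    background_value: float = 0.35         # dull brown-grey backdrop
    corner_margin: int = 16                # leaf keeps clear of corners
    lesion_count: int = 3
    lesion_radius_range: tuple[float, float] = (4.0, 10.0)


@dataclass
class CanopySample:
    image: np.ndarray                      # (rows, cols, 3) float in [0, 1]
    mask: np.ndarray                       # bool lesion mask
    lesions: list[tuple[int, int, float]]  # (row, col, radius)


def _canopy_texture(shape: tuple[int, int], spec: CanopySpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Dense green leaf texture: overlapping shaded ellipses, light noise."""
    rows, cols = shape
    base_hue = rng.uniform(*spec.green_hue_range)
    img = np.empty((rows, cols, 3))
    img[:] = hsv2rgb(np.array([[[base_hue, 0.7, 0.35]]]))
    n_leaves = max(1, int(spec.leaf_density * rows * cols))
    for _ in range(n_leaves):
        r0, c0 = rng.uniform(0, rows), rng.uniform(0, cols)
        a, b = rng.uniform(*spec.leaf_axis_range, size=2)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, a, b, shape=shape, rotation=rot)
        hue = np.clip(base_hue + rng.normal(0, 0.02), *spec.green_hue_range)
        sat = rng.uniform(0.55, 0.85)
        val = rng.uniform(0.30, 0.75)
        img[rr, cc] = hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0]
    img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = gaussian(img, sigma=1.0, channel_axis=-1)
    return np.clip(img, 0.0, 1.0)


def _place_lesions(shape: tuple[int, int], count: int, radius_range, rng,
                   margin: float = 2.0, max_tries: int = 200):
    """Sample non-overlapping lesion centres/radii fully inside the image."""
    rows, cols = shape
    placed: list[tuple[int, int, float]] = []
    for _ in range(count):
        for _try in range(max_tries):
            radius = rng.uniform(*radius_range)
            r = rng.uniform(radius + margin, rows - radius - margin)
            c = rng.uniform(radius + margin, cols - radius - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 > (radius + prad + 2 * margin) ** 2
                   for pr, pc, prad in placed):
                placed.append((int(round(r)), int(round(c)), radius))
                break
    return placed


def generate_canopy(spec: CanopySpec | None = None,
                    rng: np.random.Generator | int | None = None) -> CanopySample:
    """Render one canopy image with lesions and its exact ground-truth mask."""
    spec = spec or CanopySpec()
    rng = np.random.default_rng(rng)
    shape = (spec.rows, spec.cols)
    img = _canopy_texture(shape, spec, rng)
    count = spec.lesion_count if spec.lesion_count is not None else int(
        rng.poisson(spec.lesion_rate)
    )
    lesions = _place_lesions(shape, count, spec.lesion_radius_range, rng)
    mask = np.zeros(shape, dtype=bool)
    for r, c, radius in lesions:
        rr, cc = disk((r, c), radius, shape=shape)
        hue = rng.uniform(*spec.lesion_hue_range)
        sat = rng.uniform(0.6, 0.9)
        val = rng.uniform(0.45, 0.8)
        color = hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0]
        jitter = rng.normal(0.0, 0.02, size=(len(rr), 3))
        img[rr, cc] = np.clip(color + jitter, 0.0, 1.0)
        mask[rr, cc] = True
    return CanopySample(image=img, mask=mask, lesions=lesions)


def generate_leaf(spec: LeafSpec | None = None,
                  rng: np.random.Generator | int | None = None):
    """One leaf on a near-uniform background; returns (image, leaf mask, lesion mask)."""
    spec = spec or LeafSpec()
    rng = np.random.default_rng(rng)
    rows, cols = spec.rows, spec.cols
    img = np.empty((rows, cols, 3))
    img[:] = spec.background_value + np.array([0.05, 0.0, -0.05])
    img += rng.normal(0, 0.01, size=img.shape)

    leaf_mask = np.zeros((rows, cols), dtype=bool)
    # Ellipse inscribed well inside the frame so 8x8 corner patches stay clean.
    m = spec.corner_margin
    a = rng.uniform(0.28, 0.38) * rows
    b = rng.uniform(0.28, 0.42) * cols
    r0 = rows / 2 + rng.uniform(-0.03, 0.03) * rows
    c0 = cols / 2 + rng.uniform(-0.03, 0.03) * cols
    a = min(a, rows / 2 - m - abs(r0 - rows / 2) - 1)
    b = min(b, cols / 2 - m - abs(c0 - cols / 2) - 1)
    rr, cc = ellipse(r0, c0, a, b, shape=(rows, cols), rotation=rng.uniform(0, np.pi))
    leaf_mask[rr, cc] = True
    green = hsv2rgb(np.array([[[rng.uniform(0.24, 0.34), 0.7, 0.55]]]))[0, 0]
    img[leaf_mask] = green + rng.normal(0, 0.015, size=(leaf_mask.sum(), 3))

    lesion_mask = np.zeros((rows, cols), dtype=bool)
    interior = gaussian(leaf_mask.astype(float), sigma=6) > 0.9
    coords = np.argwhere(interior)
    for _ in range(spec.lesion_count):
        if len(coords) == 0:
            break
        r, c = coords[rng.integers(len(coords))]
        radius = rng.uniform(*spec.lesion_radius_range)
        rr, cc = disk((r, c), radius, shape=(rows, cols))
        keep = leaf_mask[rr, cc]
        rr, cc = rr[keep], cc[keep]
        brown = hsv2rgb(np.array([[[rng.uniform(0.06, 0.11), 0.8, 0.45]]]))[0, 0]
        img[rr, cc] = np.clip(brown + rng.normal(0, 0.02, size=(len(rr), 3)), 0, 1)
        lesion_mask[rr, cc] = True
    return np.clip(img, 0.0, 1.0), leaf_mask, lesion_mask


def generate_patch_training_set(
    rng: np.random.Generator | int | None = None,
    n_per_class: int = 200,
    patch_size: int = 64,
    spec: CanopySpec | None = None,
):
    """Labelled 64x64 canopy patches: class 0 healthy texture, class 1 lesion.

    Lesion patches contain exactly one lesion at a uniform random position
    fully inside the patch.  Returns ``(patches, labels)`` with patches in
    a single ``(2 n, p, p, 3)`` float array, healthy first.
    """
    spec = spec or CanopySpec()
    rng = np.random.default_rng(rng)
    shape = (patch_size, patch_size)
    patches = np.empty((2 * n_per_class, patch_size, patch_size, 3))
    for i in range(n_per_class):
        patches[i] = _canopy_texture(shape, spec, rng)
    for i in range(n_per_class):
        img = _canopy_texture(shape, spec, rng)
        (lesion,) = _place_lesions(shape, 1, spec.lesion_radius_range, rng) or [
            (patch_size // 2, patch_size // 2, np.mean(spec.lesion_radius_range))
        ]
        r, c, radius = lesion
        rr, cc = disk((r, c), radius, shape=shape)
        color = hsv2rgb(
            np.array([[[rng.uniform(*spec.lesion_hue_range),
                        rng.uniform(0.6, 0.9), rng.uniform(0.45, 0.8)]]])
        )[0, 0]
        img[rr, cc] = np.clip(color + rng.normal(0, 0.02, size=(len(rr), 3)), 0, 1)
        patches[n_per_class + i] = img
    labels = np.repeat([0, 1], n_per_class)
    return patches, labels


def to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)


def write_patch_folders(path, patches: np.ndarray, labels: np.ndarray,
                        class_names: tuple[str, str] = ("healthy", "lesion")) -> None:
    """Emit the one-directory-per-class PNG layout the trainer consumes."""
    path = Path(path)
    for cls, name in enumerate(class_names):
        (path / name).mkdir(parents=True, exist_ok=True)
    counters = [0] * len(class_names)
    for patch, label in zip(patches, labels):
        name = class_names[label]
        iio.imwrite(path / name / f"{name}_{counters[label]:05d}.png", to_uint8(patch))
        counters[label] += 1


def read_patch_folders(path):
    """Read a class-folder patch layout back into (patches, labels, class names)."""
    path = Path(path)
    class_dirs = sorted(d for d in path.iterdir() if d.is_dir())
    patches, labels = [], []
    for cls, d in enumerate(class_dirs):
        for f in sorted(d.glob("*.png")):
            patches.append(np.asarray(iio.imread(f), dtype=np.float64) / 255.0)
            labels.append(cls)
    return np.array(patches), np.array(labels), [d.name for d in class_dirs]
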