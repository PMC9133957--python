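"""Single-leaf dataset preprocessing: foreground extraction and cropping.

Single-leaf disease datasets place one leaf on a near-uniform background.
Before splitting and classification, the background must be removed (it is
set to pure black so it cannot influence the classifier) and the image
tightened to the leaf's bounding box — this keeps the crop consistent with
the decomposition principle and avoids background-driven overfitting.

Supervision is free: 8x8 patches from the four image corners are labelled
background and six 8x8 patches from the image centre are labelled
foreground; a small MLP over the flattened 192-value patches learns the
separation.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.measure import label, regionprops
from skimage.transform import resize
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)

PATCH = 8
N_CENTER = 6


def sample_training_patches(
    image: np.ndarray, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Corner/centre patch supervision for one image.

    Returns 10 patches of shape (8, 8, 3) and labels: the 4 corner patches
    are background (0), 6 patches drawn near the image centre are
    foreground (1).  Centre positions are sampled from ``rng`` within the
    central third of the image, so a fixed seed fixes the patch set.
    """
    rows, cols = image.shape[:2]
    if rows < 3 * PATCH or cols < 3 * PATCH:
        raise ValueError(f"image {rows}x{cols} too small to sample 8x8 patches")
    rng = np.random.default_rng(rng)
    corners = [
        image[:PATCH, :PATCH],
        image[:PATCH, -PATCH:],
        image[-PATCH:, :PATCH],
        image[-PATCH:, -PATCH:],
    ]
    centers = []
    for _ in range(N_CENTER):
        r = int(rng.integers(rows // 3, 2 * rows // 3 - PATCH + 1))
        c = int(rng.integers(cols // 3, 2 * cols // 3 - PATCH + 1))
        centers.append(image[r : r + PATCH, c : c + PATCH])
    patches = np.stack(corners + centers)
    labels = np.array([0] * 4 + [1] * N_CENTER)
    return patches, labels


def train_foreground_model(
    images: list[np.ndarray], seed: int = 0
) -> MLPClassifier:
    """Pooled foreground/background MLP over corner+centre patches.

    Training samples from all images are pooled (per-dataset training);
    the model maps a flattened 8x8x3 patch to a foreground probability.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for img in images:
        p, l = sample_training_patches(img, rng)
        xs.append(p.reshape(len(p), -1))
        ys.append(l)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    model = MLPClassifier(
        hidden_layer_sizes=(64, 32), max_iter=500, random_state=seed, tol=1e-4
    )
    model.fit(x, y)
    return model


def _block_mask(image: np.ndarray, model: MLPClassifier, threshold: float) -> np.ndarray:
    """Classify every non-overlapping 8x8 block; returns a pixel-level mask."""
    rows, cols = image.shape[:2]
    gr, gc = rows // PATCH, cols // PATCH
    blocks = (
        image[: gr * PATCH, : gc * PATCH]
        .reshape(gr, PATCH, gc, PATCH, 3)
        .swapaxes(1, 2)
        .reshape(gr * gc, -1)
    )
    prob = model.predict_proba(blocks)[:, 1].reshape(gr, gc)
    mask = np.zeros((rows, cols), dtype=bool)
    mask[: gr * PATCH, : gc * PATCH] = np.kron(
        prob >= threshold, np.ones((PATCH, PATCH), dtype=bool)
    )
    return mask


def remove_background(
    image: np.ndarray,
    model: MLPClassifier,
    target_size: tuple[int, int] | None = (256, 256),
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero the background, crop to the foreground bounding box, resize.

    The foreground mask is the largest connected component of the 8x8-block
    classification (speckle suppression); background pixels are set to
    exactly (0, 0, 0).  Returns ``(cleaned image, pixel foreground mask)``.
    If no block is classified foreground, the uncropped zeroed image is
    returned with a warning.
    """
    mask = _block_mask(image, model, threshold)
    if mask.any():
        lab = label(mask)
        largest = max(regionprops(lab), key=lambda r: r.area)
        mask = lab == largest.label
    cleaned = np.where(mask[:, :, None], image, 0.0)
    if not mask.any():
        logger.warning("no foreground detected; returning uncropped image")
        out = cleaned
    else:
        rs, cs = np.nonzero(mask)
        out = cleaned[rs.min() : rs.max() + 1, cs.min() : cs.max() + 1]
    if target_size is not None:
        out = resize(out, target_size, anti_aliasing=True, preserve_range=True)
    return out, mask
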