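"""Reconstructed attention map (RAM) assembly and node re-splitting.

Each patch of the overlapping split carries one class probability.  Those
probabilities are projected back onto the image plane (every patch pixel
deposits its patch's probability at its source location) and averaged by the
per-pixel overlap count: ``RAM* = RAM / A_overlap``.  With patch 64 and
stride 8 each interior pixel is covered by 64 patches, and the averaged map
is piecewise constant on 8x8 blocks — the "probability resolution" of the
attention map, which motivates re-splitting image and map into 8x8 nodes for
graph refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patchwork import (
    GeometryError,
    SplitSpec,
    accumulate_overlap,
    collapse_to_image,
    split_image,
)


@dataclass
class AttentionMap:
    """Raw accumulated sums, overlap counts, and the overlap-averaged map."""

    raw: np.ndarray        # (M, N) accumulated probability sums
    averaged: np.ndarray   # (M, N) raw / overlap; 0 where never covered
    overlap: np.ndarray    # (M, N) integer cover counts

    @property
    def covered(self) -> np.ndarray:
        return self.overlap > 0


@dataclass
class NodeGrid:
    """Non-overlapping 8x8 re-split of an image and its attention map.

    ``images`` has shape ``(w, v, 8, 8, 3)`` (the new patch configuration),
    ``probs`` shape ``(w, v)`` — one summary probability per node, the mean
    of the node's 8x8 block of the averaged attention map.
    """

    images: np.ndarray
    probs: np.ndarray
    node_size: int = 8

    def __post_init__(self) -> None:
        if self.images.shape[:2] != self.probs.shape:
            raise GeometryError("image grid and probability grid shapes differ")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.probs.shape

    @property
    def n_nodes(self) -> int:
        return self.probs.size


def build_ram(cop: np.ndarray, spec: SplitSpec) -> AttentionMap:
    """Assemble the attention map from the probability configuration.

    ``cop`` is the ``(k1, k2)`` grid of per-patch probabilities; every pixel
    of patch ``(r, c)`` deposits ``cop[r, c]`` at its mapped image location.
    """
    cop = np.asarray(cop, dtype=np.float64)
    if cop.shape != (spec.k1, spec.k2):
        raise GeometryError(f"CoP shape {cop.shape} != grid ({spec.k1}, {spec.k2})")
    raw = collapse_to_image(cop, spec, reduce="sum")
    overlap = accumulate_overlap(spec)
    averaged = np.zeros_like(raw)
    np.divide(raw, overlap, out=averaged, where=overlap > 0)
    return AttentionMap(raw=raw, averaged=averaged, overlap=overlap)


def threshold_ram(ram: AttentionMap, tau: float) -> np.ndarray:
    """Binary baseline segmentation: averaged map >= tau on covered pixels."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {tau}")
    return (ram.averaged >= tau) & ram.covered


def resplit(image: np.ndarray, ram: AttentionMap, node_size: int = 8) -> NodeGrid:
    """Re-split image and attention map into non-overlapping nodes.

    Both are tiled with stride = patch = ``node_size`` (no overlap); each
    node's probability is the mean of its block of the averaged map.  For
    the canonical 352x576 geometry this yields a 44x72 grid of 3168 nodes.
    """
    m, n = ram.averaged.shape
    if image.shape[:2] != (m, n):
        raise GeometryError("image and attention map dimensions differ")
    if m % node_size or n % node_size:
        raise GeometryError(f"dimensions {(m, n)} not divisible by {node_size}")
    spec = SplitSpec(m, n, image.shape[2], node_size, node_size, node_size, node_size)
    images = split_image(image, spec).patches
    blocks = ram.averaged.reshape(m // node_size, node_size, n // node_size, node_size)
    probs = blocks.mean(axis=(1, 3))
    return NodeGrid(images=images, probs=probs, node_size=node_size)


def node_mask_to_pixels(node_mask: np.ndarray, node_size: int = 8) -> np.ndarray:
    """Expand a boolean node-grid mask to a full-resolution pixel mask."""
    return np.kron(node_mask, np.ones((node_size, node_size), dtype=bool))
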