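"""Tiling arithmetic for hard-stride patch splitting and reconstruction.

A large canopy image is split into a grid of overlapping patches ("hard
stride": the stride is much smaller than the patch side, so neighbouring
patches overlap heavily).  Everything downstream — patch classification,
attention-map assembly, node re-splitting — reduces to the three pieces of
arithmetic implemented here:

* the grid size ``k = floor((dim - patch) / stride) + 1`` (no padding, every
  patch fully inside the image);
* the patch→pixel map ``h((r, i), (c, j)) = (i + r*s_x, j + c*s_y)``;
* overlap counting and the inverse projection (sum or overlap-averaged mean)
  from patch space back to the image plane.

Coordinates are 0-based, row-major, origin top-left.  Patch ``(r, c)`` covers
the half-open block ``[r*s_x, r*s_x + p_x) x [c*s_y, c*s_y + p_y)``.  Pixels
past the footprint of the last patch (possible when the stride does not tile
exactly) belong to no patch and carry overlap count 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised when image / patch / stride dimensions are inconsistent."""


def compute_grid(dim: int, patch: int, stride: int) -> int:
    """Number of patch positions along one axis.

    Parameters
    ----------
    dim : int
        Image extent in pixels along the axis.
    patch : int
        Patch extent along the axis; must satisfy ``1 <= patch <= dim``.
    stride : int
        Step between consecutive patch origins; must be >= 1.

    Returns
    -------
    int
        ``floor((dim - patch) / stride) + 1`` — the count of start offsets
        ``0, stride, 2*stride, ...`` whose patch lies fully inside the image.
    """
    if patch < 1 or patch > dim:
        raise GeometryError(f"patch size {patch} not in [1, {dim}]")
    if stride < 1:
        raise GeometryError(f"stride must be >= 1, got {stride}")
    return (dim - patch) // stride + 1


@dataclass(frozen=True)
class SplitSpec:
    """Geometry of one splitting operation.

    Grid counts ``k1`` (rows of patches) and ``k2`` (columns) are derived in
    ``__post_init__`` and must not be passed in.
    """

    image_rows: int
    image_cols: int
    channels: int
    patch_rows: int
    patch_cols: int
    stride_rows: int
    stride_cols: int
    k1: int = field(init=False)
    k2: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "k1", compute_grid(self.image_rows, self.patch_rows, self.stride_rows)
        )
        object.__setattr__(
            self, "k2", compute_grid(self.image_cols, self.patch_cols, self.stride_cols)
        )

    @property
    def n_patches(self) -> int:
        return self.k1 * self.k2

    @property
    def covered_rows(self) -> int:
        """Rows reached by at least one patch (<= image_rows)."""
        return (self.k1 - 1) * self.stride_rows + self.patch_rows

    @property
    def covered_cols(self) -> int:
        return (self.k2 - 1) * self.stride_cols + self.patch_cols


@dataclass
class PatchConfiguration:
    """A ``k1 x k2`` grid of image patches (the "CO" of the pipeline).

    ``patches`` has shape ``(k1, k2, p_x, p_y, d)``; entry ``(r, c)`` is a
    copy of the source block starting at pixel ``(r*s_x, c*s_y)``.
    """

    spec: SplitSpec
    patches: np.ndarray

    def __post_init__(self) -> None:
        expect = (
            self.spec.k1,
            self.spec.k2,
            self.spec.patch_rows,
            self.spec.patch_cols,
            self.spec.channels,
        )
        if self.patches.shape != expect:
            raise GeometryError(
                f"patch grid shape {self.patches.shape} != expected {expect}"
            )


def split_image(image: np.ndarray, spec: SplitSpec) -> PatchConfiguration:
    """Split ``image`` into the overlapping patch grid described by ``spec``."""
    if image.ndim == 2:
        image = image[:, :, None]
    if image.shape != (spec.image_rows, spec.image_cols, spec.channels):
        raise GeometryError(
            f"image shape {image.shape} does not match spec "
            f"({spec.image_rows}, {spec.image_cols}, {spec.channels})"
        )
    windows = np.lib.stride_tricks.sliding_window_view(
        image, (spec.patch_rows, spec.patch_cols), axis=(0, 1)
    )
    # windows: (M-p_x+1, N-p_y+1, d, p_x, p_y); subsample by stride, copy.
    grid = windows[:: spec.stride_rows, :: spec.stride_cols]
    grid = grid[: spec.k1, : spec.k2]
    patches = np.ascontiguousarray(np.moveaxis(grid, 2, -1))
    return PatchConfiguration(spec=spec, patches=patches)


def patch_to_pixel(r: int, c: int, i: int, j: int, spec: SplitSpec) -> tuple[int, int]:
    """Map in-patch pixel ``(i, j)`` of patch ``(r, c)`` to image coordinates."""
    if not (0 <= r < spec.k1 and 0 <= c < spec.k2):
        raise IndexError(f"patch index ({r}, {c}) outside {spec.k1}x{spec.k2} grid")
    if not (0 <= i < spec.patch_rows and 0 <= j < spec.patch_cols):
        raise IndexError(f"in-patch index ({i}, {j}) outside patch")
    return (i + r * spec.stride_rows, j + c * spec.stride_cols)


def accumulate_overlap(spec: SplitSpec) -> np.ndarray:
    """Per-pixel count of covering patches (``A_overlap``), shape ``(M, N)``.

    The total of all counts is ``k1*k2*p_x*p_y`` (each patch contributes one
    hit per pixel of its footprint); trailing uncovered pixels stay 0.
    """
    # Overlap is separable: count(x, y) = count_rows(x) * count_cols(y).
    rows = np.zeros(spec.image_rows, dtype=np.int64)
    for r in range(spec.k1):
        rows[r * spec.stride_rows : r * spec.stride_rows + spec.patch_rows] += 1
    cols = np.zeros(spec.image_cols, dtype=np.int64)
    for c in range(spec.k2):
        cols[c * spec.stride_cols : c * spec.stride_cols + spec.patch_cols] += 1
    return np.outer(rows, cols)


def collapse_to_image(
    values: np.ndarray, spec: SplitSpec, reduce: str = "average"
) -> np.ndarray:
    """Project patch-grid data back onto the image plane.

    Parameters
    ----------
    values : ndarray
        Either a full patch grid ``(k1, k2, p_x, p_y[, d'])`` or a scalar per
        patch ``(k1, k2)`` (each patch then contributes its scalar at every
        footprint pixel — the probability-configuration case).
    reduce : {"sum", "average"}
        ``sum`` accumulates contributions; ``average`` divides by the overlap
        count, leaving never-covered pixels at 0.

    Returns
    -------
    ndarray of shape ``(M, N)`` or ``(M, N, d')``.
    """
    if reduce not in ("sum", "average"):
        raise ValueError(f"reduce must be 'sum' or 'average', got {reduce!r}")
    if values.shape[:2] != (spec.k1, spec.k2):
        raise GeometryError(
            f"values grid {values.shape[:2]} != spec grid ({spec.k1}, {spec.k2})"
        )
    if values.ndim == 2:  # scalar per patch -> broadcast over the footprint
        values = np.broadcast_to(
            values[:, :, None, None], (spec.k1, spec.k2, spec.patch_rows, spec.patch_cols)
        )
    if values.shape[2:4] != (spec.patch_rows, spec.patch_cols):
        raise GeometryError(
            f"patch block shape {values.shape[2:4]} != "
            f"({spec.patch_rows}, {spec.patch_cols})"
        )
    trailing = values.shape[4:]
    out = np.zeros((spec.image_rows, spec.image_cols) + trailing, dtype=np.float64)
    for r in range(spec.k1):
        x0 = r * spec.stride_rows
        for c in range(spec.k2):
            y0 = c * spec.stride_cols
            out[x0 : x0 + spec.patch_rows, y0 : y0 + spec.patch_cols] += values[r, c]
    if reduce == "average":
        counts = accumulate_overlap(spec).astype(np.float64)
        if trailing:
            counts = counts[..., None]
        np.divide(out, counts, out=out, where=counts > 0)
        out[np.broadcast_to(counts == 0, out.shape)] = 0.0
    return out
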