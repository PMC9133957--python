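"""Training-set augmentation for 64x64 RGB patches.

The policy mirrors standard canopy-patch augmentation: random rotation in
[0, 90] degrees, up-down / left-right flips, median-cut colour quantization
to a small palette (default 8 colours), zoom-in (scale and centre-crop),
zoom-out (pad and rescale) and Gaussian blur with sigma drawn from (0.5, 2).
Every transform is applied with parameters drawn from the supplied RNG, so a
fixed seed reproduces the augmented set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import transform as sktransform
from skimage.filters import gaussian


@dataclass(frozen=True)
class AugmentPolicy:
    rotation_max_deg: float = 90.0
    flip_ud: bool = True
    flip_lr: bool = True
    quantize_colors: int = 8
    zoom_in_range: tuple[float, float] = (1.0, 1.5)
    zoom_out_pad_range: tuple[int, int] = (0, 8)  # pixels per side
    blur_sigma_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.quantize_colors < 2:
            raise ValueError("quantize_colors must be >= 2")
        lo, hi = self.blur_sigma_range
        if not (0.5 <= lo <= hi <= 2.0):
            raise ValueError("blur sigma range must lie within [0.5, 2.0]")
        if not 0.0 <= self.rotation_max_deg <= 90.0:
            raise ValueError("rotation range must lie within [0, 90] degrees")


def quantize_colors(patch: np.ndarray, n_colors: int) -> np.ndarray:
    """Median-cut palette quantization; returns float image in [0, 1]."""
    img8 = Image.fromarray(np.clip(patch * 255.0, 0, 255).astype(np.uint8))
    pal = img8.quantize(colors=n_colors, method=Image.Quantize.MEDIANCUT)
    return np.asarray(pal.convert("RGB"), dtype=np.float64) / 255.0


def augment(patch: np.ndarray, policy: AugmentPolicy, rng: np.random.Generator) -> np.ndarray:
    """Apply the full augmentation chain to one float RGB patch in [0, 1].

    Output shape and dtype equal the input's; the chain is rotation →
    flips → quantization → zoom-in → zoom-out → blur.
    """
    out = np.asarray(patch, dtype=np.float64)
    rows, cols = out.shape[:2]

    angle = rng.uniform(0.0, policy.rotation_max_deg)
    out = sktransform.rotate(out, angle, mode="reflect", preserve_range=True)

    if policy.flip_ud and rng.random() < 0.5:
        out = out[::-1]
    if policy.flip_lr and rng.random() < 0.5:
        out = out[:, ::-1]

    out = quantize_colors(out, policy.quantize_colors)

    # Zoom in: upscale then centre-crop back to the original size.
    scale = rng.uniform(*policy.zoom_in_range)
    if scale > 1.0:
        big = sktransform.rescale(
            out, scale, channel_axis=-1, anti_aliasing=True, preserve_range=True
        )
        r0 = (big.shape[0] - rows) // 2
        c0 = (big.shape[1] - cols) // 2
        out = big[r0 : r0 + rows, c0 : c0 + cols]

    # Zoom out: reflect-pad then rescale back down.
    pad = int(rng.integers(policy.zoom_out_pad_range[0], policy.zoom_out_pad_range[1] + 1))
    if pad > 0:
        padded = np.pad(out, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
        out = sktransform.resize(
            padded, (rows, cols), anti_aliasing=True, preserve_range=True
        )

    sigma = rng.uniform(*policy.blur_sigma_range)
    out = gaussian(out, sigma=sigma, channel_axis=-1, preserve_range=True)
    return np.clip(out, 0.0, 1.0)
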