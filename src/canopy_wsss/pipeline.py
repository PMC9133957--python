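"""End-to-end orchestration over the canopy hierarchy.

A plant-factory table image decomposes as table → half-table → tray →
352x576 tile; each tile runs the per-tile chain (overlapping split →
patch classification → attention map → 8x8 node re-split → GCN
refinement), and the tile node masks are placed back at their recorded
offsets to reassemble the full-table segmentation.  Because every split
records its geometry, the inverse reconstruction is exact: composing tile
offsets with in-tile coordinates reproduces table coordinates.

Each connected lesion component in the reassembled mask is attributed to
the tray and cell containing its centroid, giving the per-plant report the
growing hierarchy needs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.measure import label, regionprops

from .attention import build_ram, node_mask_to_pixels, resplit
from .augment import AugmentPolicy
from .classifier import ClassifierConfig, ClassifierContract, classify_configuration
from .graph import GCNConfig, refine
from .patchwork import GeometryError, SplitSpec, split_image
from .synthetic import to_uint8

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CanopyHierarchy:
    """Table tiling geometry; defaults divide a table evenly into tiles.

    The default table is 1408x2304: a 4x4 grid of 352x576 tiles, organized
    as a 2x2 grid of trays, each tray a 4x4 grid of cells (one plant per
    cell).  The real rig's table is larger; all counts are config-driven.
    """

    tile_rows: int = 352
    tile_cols: int = 576
    tiles: tuple[int, int] = (4, 4)          # tile grid over the table
    trays: tuple[int, int] = (2, 2)          # tray grid over the table
    cells_per_tray: tuple[int, int] = (4, 4)

    @property
    def table_shape(self) -> tuple[int, int]:
        return (self.tile_rows * self.tiles[0], self.tile_cols * self.tiles[1])

    def tile_offsets(self) -> list[tuple[int, int]]:
        return [
            (i * self.tile_rows, j * self.tile_cols)
            for i in range(self.tiles[0])
            for j in range(self.tiles[1])
        ]

    def locate(self, row: float, col: float) -> tuple[int, int]:
        """Map a table coordinate to (tray id, cell id), both row-major."""
        m, n = self.table_shape
        tray_r = min(int(row * self.trays[0] / m), self.trays[0] - 1)
        tray_c = min(int(col * self.trays[1] / n), self.trays[1] - 1)
        tray_rows = m / self.trays[0]
        tray_cols = n / self.trays[1]
        cell_r = min(
            int((row - tray_r * tray_rows) * self.cells_per_tray[0] / tray_rows),
            self.cells_per_tray[0] - 1,
        )
        cell_c = min(
            int((col - tray_c * tray_cols) * self.cells_per_tray[1] / tray_cols),
            self.cells_per_tray[1] - 1,
        )
        return (
            tray_r * self.trays[1] + tray_c,
            cell_r * self.cells_per_tray[1] + cell_c,
        )


@dataclass
class PipelineConfig:
    patch_size: int = 64
    stride: int = 8
    tau: float = 0.5
    seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    hierarchy: CanopyHierarchy = field(default_factory=CanopyHierarchy)
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    refine_enabled: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        split = raw.get("split", {})
        cfg = cls(
            patch_size=split.get("patch_size", 64),
            stride=split.get("stride", 8),
            tau=raw.get("eval", {}).get("tau", 0.5),
            seed=raw.get("seed", 0),
            refine_enabled=raw.get("gcn", {}).get("enabled", True),
        )
        if "classifier" in raw:
            cfg.classifier = ClassifierConfig(**raw["classifier"])
        if "augment" in raw:
            aug = dict(raw["augment"])
            for key in ("zoom_in_range", "zoom_out_pad_range", "blur_sigma_range"):
                if key in aug:
                    aug[key] = tuple(aug[key])
            cfg.augment = AugmentPolicy(**aug)
        gcn_keys = {k: v for k, v in raw.get("gcn", {}).items() if k != "enabled"}
        graph_keys = raw.get("graph", {})
        if gcn_keys or graph_keys:
            merged = {**gcn_keys, **graph_keys}
            if "hidden" in merged:
                merged["hidden"] = tuple(merged["hidden"])
            cfg.gcn = GCNConfig(**merged)
        if "hierarchy" in raw:
            h = raw["hierarchy"]
            cfg.hierarchy = CanopyHierarchy(
                tile_rows=h.get("tile_rows", 352),
                tile_cols=h.get("tile_cols", 576),
                tiles=tuple(h.get("tiles", (4, 4))),
                trays=tuple(h.get("trays", (2, 2))),
                cells_per_tray=tuple(h.get("cells_per_tray", (4, 4))),
            )
        return cfg


@dataclass
class RegionRecord:
    tray: int
    cell: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open, 0-based
    area_px: int
    mean_prob: float


@dataclass
class SegmentationResult:
    mask: np.ndarray                 # full-resolution boolean mask
    probability: np.ndarray          # refined node probabilities, pixel-expanded
    regions: list[RegionRecord]

    def report(self) -> dict:
        return {
            "n_regions": len(self.regions),
            "regions": [asdict(r) for r in self.regions],
        }


def segment_tile(
    image: np.ndarray, clf: ClassifierContract, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tile chain; returns (boolean pixel mask, pixel probability map)."""
    spec = SplitSpec(
        image.shape[0], image.shape[1], image.shape[2],
        config.patch_size, config.patch_size, config.stride, config.stride,
    )
    cop = classify_configuration(split_image(image, spec), clf)
    ram = build_ram(cop, spec)
    nodes = resplit(image, ram)
    if config.refine_enabled:
        nodes = refine(nodes, config.gcn)
    node_mask = nodes.probs >= config.tau
    return (
        node_mask_to_pixels(node_mask, nodes.node_size),
        node_mask_to_pixels(node_mask, nodes.node_size) * np.kron(
            nodes.probs, np.ones((nodes.node_size, nodes.node_size))
        ),
    )


def attribute_regions(
    mask: np.ndarray, hierarchy: CanopyHierarchy, probability: np.ndarray | None = None
) -> list[RegionRecord]:
    """Label connected components and map each to its (tray, cell)."""
    records = []
    lab = label(mask)
    for region in regionprops(lab):
        r0, c0, r1, c1 = region.bbox
        tray, cell = hierarchy.locate(*region.centroid)
        if probability is not None:
            mean_prob = float(probability[lab == region.label].mean())
        else:
            mean_prob = 1.0
        records.append(
            RegionRecord(
                tray=tray, cell=cell, bbox=(r0, c0, r1, c1),
                area_px=int(region.area), mean_prob=mean_prob,
            )
        )
    return records


def run_pipeline(
    image: np.ndarray, clf: ClassifierContract, config: PipelineConfig | None = None
) -> SegmentationResult:
    """Segment a table image (or a single tile) and attribute regions.

    ``image`` must either match the hierarchy's table shape (it is then cut
    into tiles, each segmented independently, and reassembled) or be exactly
    one tile.
    """
    config = config or PipelineConfig()
    h = config.hierarchy
    m, n = image.shape[:2]
    full_mask = np.zeros((m, n), dtype=bool)
    full_prob = np.zeros((m, n))
    if (m, n) == (h.tile_rows, h.tile_cols):
        offsets = [(0, 0)]
    elif (m, n) == h.table_shape:
        offsets = h.tile_offsets()
    else:
        raise GeometryError(
            f"image shape {(m, n)} is neither one tile "
            f"{(h.tile_rows, h.tile_cols)} nor the table {h.table_shape}"
        )
    for r0, c0 in offsets:
        t0 = time.perf_counter()
        tile = image[r0 : r0 + h.tile_rows, c0 : c0 + h.tile_cols]
        mask, prob = segment_tile(tile, clf, config)
        full_mask[r0 : r0 + h.tile_rows, c0 : c0 + h.tile_cols] = mask
        full_prob[r0 : r0 + h.tile_rows, c0 : c0 + h.tile_cols] = prob
        logger.info(
            "tile at (%d, %d): %d positive pixels, %.2fs",
            r0, c0, int(mask.sum()), time.perf_counter() - t0,
        )
    regions = attribute_regions(full_mask, h, full_prob)
    return SegmentationResult(mask=full_mask, probability=full_prob, regions=regions)


def write_outputs(result: SegmentationResult, out_dir, config: PipelineConfig) -> None:
    """Persist mask PNG, probability map, and the JSON region report."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "mask.png", to_uint8(result.mask.astype(float)))
    iio.imwrite(
        out / "probability.png",
        np.clip(np.round(result.probability * 65535), 0, 65535).astype(np.uint16),
    )
    (out / "regions.json").write_text(json.dumps(result.report(), indent=2))
    (out / "config.json").write_text(
        json.dumps(asdict(config), indent=2, default=str)
    )
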