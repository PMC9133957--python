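"""Patch-level segmentation metrics and the ablation harness.

Ground-truth masks at pixel level do not exist for the real datasets, so
evaluation happens over the 8x8 node grid ("super-pixels"): the selected
set X is the nodes marked stressed in the ground truth, the predicted set Y
the nodes whose (refined) probability clears 0.5, and

    DSC_patch = 2 |X ∩ Y| / (|X| + |Y|),    IoU = |X ∩ Y| / |X ∪ Y|.

Because nodes are uniform blocks, these equal pixel Dice/IoU computed on
the corresponding block masks.  The ablation harness reruns the same
canopies under four variants: raw attention-map thresholding, a 2-layer
GCN, the default 3-layer GCN, and the 3-layer GCN with the positive
pseudo-label set doubled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .attention import NodeGrid, build_ram, resplit
from .classifier import ClassifierContract, classify_configuration
from .graph import GCNConfig, refine
from .patchwork import SplitSpec, split_image
from .synthetic import CanopySample

NodeSet = frozenset  # of (row, col) grid coordinates

VARIANTS = ("ram-threshold", "gcn-2", "gcn-3", "gcn-3-double-nodes")


def _check_same_grid(selected: Iterable, predicted: Iterable) -> tuple[frozenset, frozenset]:
    return frozenset(selected), frozenset(predicted)


def dsc_patch(selected: Iterable, predicted: Iterable) -> float:
    """Patch-level Dice: 2|X∩Y| / (|X|+|Y|); both empty -> 1."""
    x, y = _check_same_grid(selected, predicted)
    if not x and not y:
        return 1.0
    return 2.0 * len(x & y) / (len(x) + len(y))


def iou_patch(selected: Iterable, predicted: Iterable) -> float:
    """Patch-level intersection over union; both empty -> 1."""
    x, y = _check_same_grid(selected, predicted)
    if not x and not y:
        return 1.0
    return len(x & y) / len(x | y)


def ground_truth_nodes(
    mask: np.ndarray, node_size: int = 8, min_coverage: float = 0.125
) -> frozenset:
    """Node-grid cells counted as ground-truth stressed.

    A node is selected when the lesion covers at least ``min_coverage`` of
    its block (default 1/8, i.e. 8 of 64 pixels) — emulating a human
    selecting visibly stressed super-pixels rather than every block grazed
    by a single lesion pixel.
    """
    m, n = mask.shape
    gr, gc = m // node_size, n // node_size
    frac = (
        mask[: gr * node_size, : gc * node_size]
        .reshape(gr, node_size, gc, node_size)
        .mean(axis=(1, 3))
    )
    rs, cs = np.nonzero(frac >= min_coverage)
    return frozenset(zip(rs.tolist(), cs.tolist()))


def predicted_nodes(nodes: NodeGrid, threshold: float = 0.5) -> frozenset:
    rs, cs = np.nonzero(nodes.probs >= threshold)
    return frozenset(zip(rs.tolist(), cs.tolist()))


@dataclass
class AblationRow:
    variant: str
    dsc: float
    iou: float


def evaluate_variants(
    sample: CanopySample,
    clf: ClassifierContract,
    variants: Iterable[str] = VARIANTS,
    patch_size: int = 64,
    stride: int = 8,
    gcn_config: GCNConfig | None = None,
    tau: float = 0.5,
    ram_tau: float | None = None,
    min_coverage: float = 0.125,
) -> dict[str, tuple[float, float]]:
    """Run the shared pipeline front end once, then score each variant.

    ``tau`` cuts the refined (GCN) probabilities; the attention-map baseline
    is cut at ``ram_tau``, which defaults to the pseudo-label threshold so
    the baseline and the labels the GCN trains on coincide.
    """
    out: dict[str, tuple[float, float]] = {}
    for variant, (truth_set, pred) in predict_variants(
        sample, clf, variants, patch_size, stride, gcn_config, tau, ram_tau, min_coverage
    ).items():
        out[variant] = (dsc_patch(truth_set, pred), iou_patch(truth_set, pred))
    return out


def predict_variants(
    sample: CanopySample,
    clf: ClassifierContract,
    variants: Iterable[str] = VARIANTS,
    patch_size: int = 64,
    stride: int = 8,
    gcn_config: GCNConfig | None = None,
    tau: float = 0.5,
    ram_tau: float | None = None,
    min_coverage: float = 0.125,
) -> dict[str, tuple[frozenset, frozenset]]:
    """Per variant, the (ground-truth, predicted) node sets for one canopy."""
    gcn_config = gcn_config or GCNConfig()
    if ram_tau is None:
        ram_tau = gcn_config.label_threshold
    img = sample.image
    spec = SplitSpec(img.shape[0], img.shape[1], 3, patch_size, patch_size, stride, stride)
    cop = classify_configuration(split_image(img, spec), clf)
    ram = build_ram(cop, spec)
    nodes = resplit(img, ram)
    truth = ground_truth_nodes(sample.mask, nodes.node_size, min_coverage)

    out: dict[str, tuple[frozenset, frozenset]] = {}
    for variant in variants:
        if variant == "ram-threshold":
            out[variant] = (truth, predicted_nodes(nodes, ram_tau))
            continue
        if variant == "gcn-2":
            cfg = replace(gcn_config, hidden=gcn_config.hidden[:1])
            refined = refine(nodes, cfg)
        elif variant == "gcn-3":
            refined = refine(nodes, gcn_config)
        elif variant == "gcn-3-double-nodes":
            refined = refine(nodes, gcn_config, double_positives=True)
        else:
            raise ValueError(f"unknown variant {variant!r}")
        out[variant] = (truth, predicted_nodes(refined, tau))
    return out


def run_ablation(
    samples: Iterable[CanopySample],
    clf: ClassifierContract,
    variants: Iterable[str] = VARIANTS,
    **kwargs,
) -> list[AblationRow]:
    """Pooled DSC/IoU per variant over a set of synthetic canopies.

    Node sets are pooled across canopies before the metrics are computed
    (the canopies act as disjoint parts of one large test image, matching
    an evaluation over a whole table rather than a mean of per-tile
    scores, which a canopy with one or two ground-truth nodes would
    dominate).
    """
    variants = tuple(variants)
    inter = {v: 0 for v in variants}
    size_x = {v: 0 for v in variants}
    size_y = {v: 0 for v in variants}
    union = {v: 0 for v in variants}
    for sample in samples:
        for v, (truth, pred) in predict_variants(sample, clf, variants, **kwargs).items():
            inter[v] += len(truth & pred)
            union[v] += len(truth | pred)
            size_x[v] += len(truth)
            size_y[v] += len(pred)
    rows = []
    for v in variants:
        dsc = 1.0 if size_x[v] + size_y[v] == 0 else 2 * inter[v] / (size_x[v] + size_y[v])
        iou = 1.0 if union[v] == 0 else inter[v] / union[v]
        rows.append(AblationRow(variant=v, dsc=dsc, iou=iou))
    return rows


def format_table(rows: list[AblationRow]) -> str:
    lines = [f"{'variant':24s} {'DSC':>8s} {'IoU':>8s}"]
    lines += [f"{r.variant:24s} {r.dsc:8.4f} {r.iou:8.4f}" for r in rows]
    return "\n".join(lines)


def to_csv(rows: list[AblationRow]) -> str:
    return "variant,dsc,iou\n" + "\n".join(
        f"{r.variant},{r.dsc:.6f},{r.iou:.6f}" for r in rows
    )
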