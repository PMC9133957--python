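"""Patch classification behind a pluggable contract.

The pipeline only requires an object satisfying :class:`ClassifierContract`:
it accepts a batch of patches, resizes each to its input side ``l`` with
anti-aliased interpolation, and returns one probability vector per patch
(non-negative, summing to 1).  In production this is a fine-tuned pretrained
backbone; for desk-scale runs and the test suite it is
:class:`SmallPatchCNN`, a small convolutional softmax network trained here
from scratch on synthetic patches.  The training loop uses categorical
cross-entropy with Adam, early stopping (patience 4, min-delta 0.001) and
plateau learning-rate reduction (factor 0.2, floor 0.001); the initial
learning rate defaults to 0.01 — the production fine-tuning recipe's 0.1 is
tuned to a pretrained backbone and diverges on a from-scratch desk net.

The contract leans on the *principle of decomposition*: a crop of a canopy
looks like a canopy, so one classifier serves the full image and its resized
sub-patches alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from skimage.transform import resize

from ._nnet import Adam, cross_entropy, glorot, relu, softmax_rows
from .patchwork import PatchConfiguration

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """Raised for unusable training configurations (e.g. single-class data)."""


@runtime_checkable
class ClassifierContract(Protocol):
    """What the pipeline requires from any patch classifier."""

    input_size: int
    n_classes: int

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """(n, h, w, 3) float patches in [0, 1] -> (n, n_classes) probabilities."""
        ...


def resize_patches(patches: np.ndarray, side: int) -> np.ndarray:
    """Anti-aliased resize of a patch batch to ``(n, side, side, 3)``."""
    patches = np.asarray(patches, dtype=np.float64)
    if patches.shape[1:3] == (side, side):
        return patches
    out = np.empty((patches.shape[0], side, side, patches.shape[3]))
    for i, p in enumerate(patches):
        out[i] = resize(p, (side, side), anti_aliasing=True, preserve_range=True)
    return out


@dataclass
class StubClassifier:
    """Deterministic stand-in driven by a callable on the *original* patch.

    Used in tests and as the "perfect classifier" oracle: ``fn`` maps one
    patch to the positive-class probability.
    """

    fn: Callable[[np.ndarray], float]
    input_size: int = 16
    n_classes: int = 2

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        p = np.array([float(self.fn(np.asarray(x))) for x in patches])
        probs = np.stack([1.0 - p, p], axis=1)
        return probs


def constant_classifier(prob: float, input_size: int = 16) -> StubClassifier:
    return StubClassifier(fn=lambda _x: prob, input_size=input_size)


@dataclass
class ClassifierConfig:
    input_size: int = 64
    kernel: int = 8            # shared conv kernel side
    kernel_stride: int = 4
    conv_channels: int = 32
    hidden: int = 32           # dense head width
    lr_init: float = 0.01
    plateau_factor: float = 0.2
    min_lr: float = 0.001
    patience: int = 4          # shared by early stopping and LR plateau
    min_delta: float = 0.001
    max_epochs: int = 60
    batch_size: int = 32
    seed: int = 0


@dataclass
class SmallPatchCNN:
    """Desk-scale trainable patch classifier.

    A minimal convolutional network: one shared 8x8 (stride 4) kernel bank
    over the resized patch, ReLU, global max pooling over positions, then a
    dense ReLU layer and a softmax head.  The global max pool gives the
    position invariance a lesion detector needs — "does any sub-window look
    discoloured" — which a dense net on raw pixels lacks; it is the smallest
    architecture that respects the decomposition principle.
    """

    config: ClassifierConfig
    n_classes: int = 2
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    @property
    def input_size(self) -> int:
        return self.config.input_size

    def __post_init__(self) -> None:
        if not self.weights:
            cfg = self.config
            rng = np.random.default_rng(cfg.seed)
            k_in = cfg.kernel**2 * 3
            dims = [(k_in, cfg.conv_channels), (cfg.conv_channels, cfg.hidden),
                    (cfg.hidden, self.n_classes)]
            for fan_in, fan_out in dims:
                self.weights.append(glorot(rng, fan_in, fan_out))
                self.biases.append(np.zeros(fan_out))

    # -- inference ---------------------------------------------------------
    def _blocks(self, patches: np.ndarray) -> np.ndarray:
        """im2col: (n, l, l, 3) -> (n, n_windows, kernel*kernel*3)."""
        cfg = self.config
        x = resize_patches(patches, cfg.input_size)
        win = np.lib.stride_tricks.sliding_window_view(
            x, (cfg.kernel, cfg.kernel), axis=(1, 2)
        )[:, :: cfg.kernel_stride, :: cfg.kernel_stride]
        n, gr, gc = win.shape[:3]
        return np.moveaxis(win, 3, -1).reshape(n, gr * gc, -1)

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        return self._forward(self._blocks(patches))["probs"]

    def _forward(self, blocks: np.ndarray) -> dict:
        w1, w2, w3 = self.weights
        b1, b2, b3 = self.biases
        s1 = blocks @ w1 + b1                    # (n, B, C)
        h1 = relu(s1)
        arg = h1.argmax(axis=1)                  # (n, C) winning window per channel
        pooled = np.take_along_axis(h1, arg[:, None, :], axis=1)[:, 0, :]
        s2 = pooled @ w2 + b2
        h2 = relu(s2)
        probs = softmax_rows(h2 @ w3 + b3)
        return {"blocks": blocks, "s1": s1, "arg": arg, "pooled": pooled,
                "s2": s2, "h2": h2, "probs": probs}

    # -- training ----------------------------------------------------------
    def _grads(self, blocks: np.ndarray, onehot: np.ndarray):
        f = self._forward(blocks)
        n = blocks.shape[0]
        delta3 = (f["probs"] - onehot) / n                       # (n, c)
        gw3 = f["h2"].T @ delta3
        gb3 = delta3.sum(axis=0)
        delta2 = (delta3 @ self.weights[2].T) * (f["s2"] > 0)    # (n, hidden)
        gw2 = f["pooled"].T @ delta2
        gb2 = delta2.sum(axis=0)
        dpool = delta2 @ self.weights[1].T                       # (n, C)
        dh1 = np.zeros_like(f["s1"])                             # route to argmax window
        np.put_along_axis(dh1, f["arg"][:, None, :], dpool[:, None, :], axis=1)
        delta1 = dh1 * (f["s1"] > 0)
        gw1 = blocks.reshape(-1, blocks.shape[-1]).T @ delta1.reshape(-1, delta1.shape[-1])
        gb1 = delta1.sum(axis=(0, 1))
        loss = cross_entropy(f["probs"], onehot)
        return loss, [gw1, gw2, gw3], [gb1, gb2, gb3]

    def fit(self, x_train, y_train, x_val, y_val) -> "SmallPatchCNN":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        xt = self._blocks(x_train)
        xv = self._blocks(x_val)
        eye = np.eye(self.n_classes)
        yt1h = eye[y_train]
        yv1h = eye[y_val]

        params = [*self.weights, *self.biases]
        opt = Adam(params, lr=cfg.lr_init)
        best_loss = np.inf
        best = [p.copy() for p in params]
        stale = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(xt))
            for start in range(0, len(xt), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                _, gw, gb = self._grads(xt[sel], yt1h[sel])
                opt.step([*gw, *gb])
            val_probs = self._forward(xv)["probs"]
            val_loss = cross_entropy(val_probs, yv1h)
            val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val))
            self.history.append(
                {"epoch": epoch, "val_loss": val_loss, "val_acc": val_acc, "lr": opt.lr}
            )
            logger.info("epoch %d: val_loss=%.4f val_acc=%.4f lr=%.4g",
                        epoch, val_loss, val_acc, opt.lr)
            if val_loss < best_loss - cfg.min_delta:
                best_loss = val_loss
                best = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    opt.lr = max(opt.lr * cfg.plateau_factor, cfg.min_lr)
                    break  # early stopping fires at the same patience
        for p, b in zip(params, best):
            p[...] = b
        return self


def train_classifier(
    train_patches: np.ndarray,
    train_labels: np.ndarray,
    val_patches: np.ndarray,
    val_labels: np.ndarray,
    config: ClassifierConfig | None = None,
    n_classes: int | None = None,
) -> SmallPatchCNN:
    """Train the desk-scale patch classifier on labelled patch sets.

    Labels are integer class ids; class 1 (or the configured class of
    interest) is treated downstream as the lesion class.
    """
    config = config or ClassifierConfig()
    if len(np.unique(train_labels)) < 2 or len(np.unique(val_labels)) < 2:
        raise ConfigurationError("training and validation sets must contain >= 2 classes")
    if n_classes is None:
        n_classes = int(max(train_labels.max(), val_labels.max())) + 1
    clf = SmallPatchCNN(config=config, n_classes=n_classes)
    if config.max_epochs > 0:
        clf.fit(train_patches, train_labels, val_patches, val_labels)
    return clf


def classify_configuration(
    co: PatchConfiguration, clf: ClassifierContract, positive_class: int = 1
) -> np.ndarray:
    """Per-patch positive-class probabilities on the split grid (the "CoP").

    Returns a ``(k1, k2)`` float array; entry ``(r, c)`` is the probability
    that resized patch ``(r, c)`` belongs to the class of interest.
    Prediction order is row-major over the grid.
    """
    spec = co.spec
    flat = co.patches.reshape(
        spec.n_patches, spec.patch_rows, spec.patch_cols, spec.channels
    )
    # chunked to bound the im2col working set for large grids
    probs = np.concatenate(
        [np.asarray(clf.predict_proba(flat[i : i + 512])) for i in range(0, len(flat), 512)]
    )
    if probs.ndim != 2 or probs.shape[0] != spec.n_patches:
        raise ValueError("classifier returned malformed probability batch")
    sums = probs.sum(axis=1)
    if np.any(probs < -1e-5) or np.any(np.abs(sums - 1.0) > 1e-5):
        raise ValueError("classifier probabilities must be >= 0 and sum to 1")
    return probs[:, positive_class].reshape(spec.k1, spec.k2)


def save_classifier(clf: SmallPatchCNN, path) -> None:
    arrays = {f"w{i}": w for i, w in enumerate(clf.weights)}
    arrays |= {f"b{i}": b for i, b in enumerate(clf.biases)}
    meta = np.array(
        [clf.config.input_size, clf.config.kernel, clf.config.kernel_stride,
         clf.config.conv_channels, clf.config.hidden, clf.n_classes,
         clf.config.seed],
        dtype=np.int64,
    )
    np.savez(path, meta=meta, **arrays)


def load_classifier(path) -> SmallPatchCNN:
    data = np.load(path)
    meta = data["meta"]
    cfg = ClassifierConfig(
        input_size=int(meta[0]), kernel=int(meta[1]), kernel_stride=int(meta[2]),
        conv_channels=int(meta[3]), hidden=int(meta[4]), seed=int(meta[6]),
    )
    clf = SmallPatchCNN(config=cfg, n_classes=int(meta[5]))
    clf.weights = [data[f"w{i}"] for i in range(3)]
    clf.biases = [data[f"b{i}"] for i in range(3)]
    return clf
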