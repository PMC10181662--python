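"""Seed-level classification with a compact 3-D convolutional network.

Each seed is a fixed-size masked sub-cube; the spectral axis is mapped to
the convolution depth so the kernels mix spatial and spectral context.  The
topology is two [valid conv3d -> ReLU -> max-pool] blocks, flatten, a
fully-connected layer, and a softmax output trained with categorical
cross-entropy under Adam.  Training is deterministic for a fixed seed and
thread count: one master seed drives the split, augmentation order, batch
shuffling, and weight initialisation.

The dataset protocol mirrors the acquisition study: an 80/10/10
train/validation/test split stratified per class, and spatial-only
augmentation (flips, 180-degree rotation, small shifts) of the training
split up to a fixed per-class total (40 by default).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._nn import (
    Adam,
    Conv3dLayer,
    DenseLayer,
    FlattenLayer,
    MaxPool3dLayer,
    ReluLayer,
    Sequential,
    conv3d_batch,
    cross_entropy_and_grad,
    softmax,
)
from .segmentation import SeedCube

__all__ = [
    "LabeledSeedSet",
    "Cnn3dConfig",
    "Cnn3dModel",
    "conv3d_forward",
    "maxpool3d",
    "split_dataset",
    "augment",
    "train_cnn3d",
    "predict_cnn3d",
]

SPLITS = ("train", "val", "test")


@dataclass
class LabeledSeedSet:
    """Seed cubes with class labels and an optional split assignment."""

    cubes: list[SeedCube]
    labels: list[str]
    split: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cubes) != len(self.labels):
            raise ValueError("cubes and labels length mismatch")
        if not self.split:
            self.split = [None] * len(self.cubes)
        if len(self.split) != len(self.cubes):
            raise ValueError("split and cubes length mismatch")

    def subset(self, which: str) -> "LabeledSeedSet":
        idx = [i for i, s in enumerate(self.split) if s == which]
        return LabeledSeedSet(
            cubes=[self.cubes[i] for i in idx],
            labels=[self.labels[i] for i in idx],
            split=[which] * len(idx),
        )

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))


@dataclass
class Cnn3dConfig:
    """Architecture and training hyper-parameters.

    ``conv_blocks`` entries are ``(out_channels, kernel (D',H',W'), pool)``
    with the band axis as depth D.
    """

    conv_blocks: list[tuple[int, tuple[int, int, int], tuple[int, int, int]]] = field(
        default_factory=lambda: [(8, (7, 3, 3), (2, 2, 2)), (16, (5, 3, 3), (2, 2, 2))]
    )
    fc_width: int = 64
    n_classes: int = 2
    lr: float = 1e-3
    epochs: int = 50
    batch_size: int = 8
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# Bare operations (single sample), exposed for direct use and verification.

def conv3d_forward(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid 3-D convolution of one sample.

    x: (C, D, H, W); kernel: (C', C, D', H', W'); bias: (C',).
    ``O[c',i,j,k] = sum_{c,d,h,w} x[c, i+d, j+h, k+w] * K[c',c,d,h,w] + b[c']``.
    """
    x = np.asarray(x, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if x.ndim != 4 or kernel.ndim != 5:
        raise ValueError("expect 4-D input and 5-D kernel")
    if kernel.shape[1] != x.shape[0]:
        raise ValueError(f"kernel input channels {kernel.shape[1]} != input channels {x.shape[0]}")
    return conv3d_batch(x[None], kernel, bias)[0]


def maxpool3d(x: np.ndarray, pool: tuple[int, int, int]) -> np.ndarray:
    """Max pooling of one sample (C, D, H, W), stride = window.

    Non-divisible dimensions are edge-padded by replication.
    """
    layer = MaxPool3dLayer(pool)
    return layer.forward(np.asarray(x, dtype=np.float64)[None])[0]


# ---------------------------------------------------------------------------
# Dataset protocol

def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    left = n - sum(base)
    rema = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in rema[:left]:
        base[i] += 1
    return base


def split_dataset(
    dataset: LabeledSeedSet,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
) -> LabeledSeedSet:
    """Stratified train/val/test assignment, largest-remainder rounding.

    Deterministic given ``rng_seed``.  Raises when a class would leave any
    split empty.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(rng_seed)
    split: list[str | None] = [None] * len(dataset.cubes)
    for cls in dataset.classes:
        idx = np.array([i for i, lab in enumerate(dataset.labels) if lab == cls])
        counts = _largest_remainder(len(idx), fractions)
        if min(counts) < 1:
            raise ValueError(
                f"class {cls!r} has {len(idx)} items; too few for fractions {fractions}"
            )
        order = rng.permutation(len(idx))
        shuffled = idx[order]
        pos = 0
        for name, cnt in zip(SPLITS, counts):
            for i in shuffled[pos : pos + cnt]:
                split[i] = name
            pos += cnt
    return LabeledSeedSet(cubes=dataset.cubes, labels=dataset.labels, split=split)


_TRANSFORMS = ("hflip", "vflip", "rot180", "shift+2r", "shift-2r", "shift+2c", "shift-2c")


def _apply_transform(data: np.ndarray, mask: np.ndarray, name: str):
    if name == "hflip":
        return data[:, ::-1].copy(), mask[:, ::-1].copy()
    if name == "vflip":
        return data[::-1].copy(), mask[::-1].copy()
    if name == "rot180":
        return data[::-1, ::-1].copy(), mask[::-1, ::-1].copy()
    if name.startswith("shift"):
        amt = int(name[5:-1])
        axis = 0 if name[-1] == "r" else 1
        d = np.roll(data, amt, axis=axis)
        m = np.roll(mask, amt, axis=axis)
        # zero the wrapped strip so the shift is a translation, not a roll
        sl = [slice(None)] * data.ndim
        if amt > 0:
            sl[axis] = slice(0, amt)
        else:
            sl[axis] = slice(amt, None)
        d[tuple(sl)] = 0.0
        m[tuple(sl[:2])] = False
        return d, m
    raise ValueError(f"unknown transform {name!r}")


def augment(
    dataset: LabeledSeedSet, per_class_total: int, rng_seed: int = 0
) -> LabeledSeedSet:
    """Grow each class's training split to ``per_class_total`` items.

    Originals are preserved untouched; new items are spatial transforms
    (flips, 180-degree rotation, +/-2 px shifts) of randomly chosen
    training originals.  Spectra are never altered.
    """
    rng = np.random.default_rng(rng_seed)
    cubes = list(dataset.cubes)
    labels = list(dataset.labels)
    split = list(dataset.split)
    for cls in dataset.classes:
        idx = [
            i for i, (lab, s) in enumerate(zip(dataset.labels, dataset.split))
            if lab == cls and s in ("train", None)
        ]
        if not idx:
            raise ValueError(f"class {cls!r} has no training items to augment from")
        if per_class_total < len(idx):
            raise ValueError(
                f"per_class_total {per_class_total} < existing {len(idx)} "
                f"training items for class {cls!r}"
            )
        need = per_class_total - len(idx)
        for _ in range(need):
            src = dataset.cubes[int(rng.choice(idx))]
            name = _TRANSFORMS[int(rng.integers(len(_TRANSFORMS)))]
            d, m = _apply_transform(src.data, src.mask, name)
            cubes.append(
                SeedCube(
                    data=d, mask=m, class_label=src.class_label,
                    exposure_label=src.exposure_label,
                    source=f"{src.source}+{name}",
                )
            )
            labels.append(cls)
            split.append("train")
    return LabeledSeedSet(cubes=cubes, labels=labels, split=split)


# ---------------------------------------------------------------------------
# Model

@dataclass
class Cnn3dModel:
    net: Sequential
    config: Cnn3dConfig
    class_map: list[str]
    input_shape: tuple[int, int, int, int]  # (C, D, H, W)

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params)}
        np.savez(os.path.join(outdir, "weights.npz"), **arrays)
        sidecar = {
            "kind": "cnn3d",
            "class_map": self.class_map,
            "input_shape": list(self.input_shape),
            "config": {
                "conv_blocks": [[c, list(k), list(p)] for c, k, p in self.config.conv_blocks],
                "fc_width": self.config.fc_width,
                "n_classes": self.config.n_classes,
                "lr": self.config.lr,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "rng_seed": self.config.rng_seed,
            },
        }
        with open(os.path.join(outdir, "model.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, outdir: str) -> "Cnn3dModel":
        with open(os.path.join(outdir, "model.json")) as fh:
            sidecar = json.load(fh)
        cfgd = sidecar["config"]
        cfg = Cnn3dConfig(
            conv_blocks=[(c, tuple(k), tuple(p)) for c, k, p in cfgd["conv_blocks"]],
            fc_width=cfgd["fc_width"], n_classes=cfgd["n_classes"], lr=cfgd["lr"],
            epochs=cfgd["epochs"], batch_size=cfgd["batch_size"], rng_seed=cfgd["rng_seed"],
        )
        input_shape = tuple(sidecar["input_shape"])
        net = _build_net(cfg, input_shape, np.random.default_rng(0))
        data = np.load(os.path.join(outdir, "weights.npz"))
        for i, p in enumerate(net.params):
            p[...] = data[f"p{i}"]
        return cls(net=net, config=cfg, class_map=sidecar["class_map"],
                   input_shape=input_shape)


def _build_net(cfg: Cnn3dConfig, input_shape: tuple[int, int, int, int],
               rng: np.random.Generator) -> Sequential:
    c, d, h, w = input_shape
    layers: list = []
    for out_ch, kernel, pool in cfg.conv_blocks:
        kd, kh, kw = kernel
        if kd > d or kh > h or kw > w:
            raise ValueError(
                f"kernel {kernel} does not fit feature volume {(d, h, w)}"
            )
        layers.append(Conv3dLayer(c, out_ch, kernel, rng))
        d, h, w = d - kd + 1, h - kh + 1, w - kw + 1
        layers.append(ReluLayer())
        layers.append(MaxPool3dLayer(pool))
        d, h, w = -(-d // pool[0]), -(-h // pool[1]), -(-w // pool[2])
        c = out_ch
    layers.append(FlattenLayer())
    layers.append(DenseLayer(c * d * h * w, cfg.fc_width, rng))
    layers.append(ReluLayer())
    layers.append(DenseLayer(cfg.fc_width, cfg.n_classes, rng))
    return Sequential(layers)


def _to_tensor(cubes: Sequence[SeedCube]) -> np.ndarray:
    """Stack seed cubes as (N, 1, bands, H, W) with the band axis as depth."""
    arr = np.stack([c.data for c in cubes])  # (N, H, W, B)
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2)[:, None], dtype=np.float64)


def train_cnn3d(dataset: LabeledSeedSet, cfg: Cnn3dConfig | None = None) -> tuple[Cnn3dModel, dict]:
    """Train the two-block 3D-CNN on the dataset's training split.

    Returns the model and a history dict with per-epoch train/val loss and
    accuracy.  Raises for a single-class dataset or a diverging (non-finite)
    loss.
    """
    cfg = cfg or Cnn3dConfig()
    classes = dataset.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    cfg.n_classes = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}

    train = dataset.subset("train") if any(dataset.split) else dataset
    val = dataset.subset("val") if any(s == "val" for s in dataset.split) else None
    x_train = _to_tensor(train.cubes)
    y_train = np.array([cls_index[lab] for lab in train.labels])
    input_shape = x_train.shape[1:]

    rng = np.random.default_rng(cfg.rng_seed)
    net = _build_net(cfg, input_shape, rng)
    opt = Adam(net.params, lr=cfg.lr)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    n = len(y_train)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = net.forward(xb, train=True)
            loss, dlogits = cross_entropy_and_grad(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            grads = net.backward(dlogits)
            opt.step(grads)
            losses.append(loss * len(yb))
            correct += int((logits.argmax(axis=1) == yb).sum())
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        if val is not None and val.cubes:
            xv = _to_tensor(val.cubes)
            yv = np.array([cls_index[lab] for lab in val.labels])
            logits = net.forward(xv)
            vloss, _ = cross_entropy_and_grad(logits, yv)
            history["val_loss"].append(vloss)
            history["val_acc"].append(float((logits.argmax(axis=1) == yv).mean()))
    model = Cnn3dModel(net=net, config=cfg, class_map=classes, input_shape=input_shape)
    return model, history


def predict_cnn3d(model: Cnn3dModel, cubes: Sequence[SeedCube]) -> tuple[list[str], np.ndarray]:
    """Class labels and softmax probabilities for seed cubes.

    Ties in the probabilities resolve to the lowest class index.
    """
    x = _to_tensor(cubes)
    if x.shape[1:] != model.input_shape:
        raise ValueError(f"cube shape {x.shape[1:]} != training shape {model.input_shape}")
    probs = softmax(net_forward_in_chunks(model.net, x))
    labels = [model.class_map[i] for i in probs.argmax(axis=1)]
    return labels, probs


def net_forward_in_chunks(net: Sequential, x: np.ndarray, chunk: int = 64) -> np.ndarray:
    """Forward pass in batches to bound peak memory."""
    outs = [net.forward(x[i : i + chunk]) for i in range(0, len(x), chunk)]
    return np.concatenate(outs, axis=0)
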