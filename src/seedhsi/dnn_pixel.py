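"""Pixel-spectrum classification with a deep fully-connected network.

Every masked seed pixel contributes one training row: its full reflectance
spectrum.  The network is an input layer of width n_bands, twelve ReLU
hidden layers (tapering widths by default), and a softmax output, trained
with categorical cross-entropy under Adam.  Per-band standardisation
(mean/std estimated on the training split) is applied before the network
and stored with the model.

The split protocol is per-seed: 70% of each seed's pixels train the model
and the remaining 30% validate it, so every seed is represented on both
sides of the split.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np

from ._nn import Adam, DenseLayer, ReluLayer, Sequential, cross_entropy_and_grad, softmax
from .segmentation import SeedCube

__all__ = [
    "PixelDataset",
    "DnnConfig",
    "DnnModel",
    "build_pixel_dataset",
    "dense_forward",
    "split_pixels",
    "train_dnn",
    "predict_pixels",
]

logger = logging.getLogger(__name__)

DEFAULT_HIDDEN = (256, 256, 128, 128, 128, 64, 64, 64, 32, 32, 32, 16)


@dataclass
class PixelDataset:
    """Pixel-by-band matrix with labels and panel origins."""

    X: np.ndarray                      # (n_pixels, n_bands)
    y: np.ndarray                      # (n_pixels,) integer class codes
    origin: np.ndarray                 # (n_pixels, 3): seed index, row, col
    class_map: list[str] = field(default_factory=list)
    seed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.origin = np.asarray(self.origin, dtype=np.int64)
        if len(self.X) != len(self.y) or len(self.X) != len(self.origin):
            raise ValueError("X, y, origin length mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("pixel matrix contains non-finite entries")

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("X", data=self.X.astype(np.float32))
            fh.create_dataset("y", data=self.y)
            fh.create_dataset("origin", data=self.origin)
            fh.attrs["class_map"] = json.dumps(self.class_map)
            fh.attrs["seed_ids"] = json.dumps(self.seed_ids)

    @classmethod
    def load(cls, path: str) -> "PixelDataset":
        with h5py.File(path, "r") as fh:
            return cls(
                X=np.asarray(fh["X"], dtype=np.float64),
                y=np.asarray(fh["y"]),
                origin=np.asarray(fh["origin"]),
                class_map=json.loads(fh.attrs.get("class_map", "[]")),
                seed_ids=json.loads(fh.attrs.get("seed_ids", "[]")),
            )


@dataclass
class DnnConfig:
    hidden_widths: tuple[int, ...] = DEFAULT_HIDDEN
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 256
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be >= 1")


def build_pixel_dataset(seeds: Sequence[SeedCube]) -> PixelDataset:
    """One row per masked pixel, labelled by its seed's class.

    Row order is deterministic: seeds in input order, pixels in (row, col)
    order within each seed.
    """
    classes = sorted({s.class_label for s in seeds if s.class_label is not None})
    cls_index = {c: i for i, c in enumerate(classes)}
    rows, labels, origins, seed_ids = [], [], [], []
    for si, seed in enumerate(seeds):
        rr, cc = np.nonzero(seed.mask)
        if rr.size == 0:
            continue
        rows.append(seed.data[rr, cc])
        labels.append(np.full(rr.size, cls_index.get(seed.class_label, -1)))
        origins.append(np.column_stack([np.full(rr.size, si), rr, cc]))
        seed_ids.append(seed.source or str(si))
    if not rows:
        raise ValueError("no masked pixels in any seed")
    return PixelDataset(
        X=np.concatenate(rows),
        y=np.concatenate(labels),
        origin=np.concatenate(origins),
        class_map=classes,
        seed_ids=seed_ids,
    )


def dense_forward(
    X: np.ndarray, W: np.ndarray, b: np.ndarray, activation: str = "relu"
) -> np.ndarray:
    """One layer: ``activation(X @ W + b)``.

    ``activation`` is ``"relu"`` for hidden layers, ``"softmax"`` for the
    output layer, or ``"linear"``.
    """
    X, W, b = np.asarray(X, dtype=np.float64), np.asarray(W, dtype=np.float64), np.asarray(b)
    if X.shape[-1] != W.shape[0]:
        raise ValueError(f"shape mismatch: X has {X.shape[-1]} features, W expects {W.shape[0]}")
    z = X @ W + b
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "softmax":
        return softmax(z)
    if activation == "linear":
        return z
    raise ValueError(f"unknown activation {activation!r}")


def split_pixels(
    ds: PixelDataset, train_frac: float = 0.7, rng_seed: int = 0, per_seed: bool = True
) -> tuple[PixelDataset, PixelDataset]:
    """Train/validation pixel split, 70/30 by default.

    With ``per_seed`` (the default) each seed's pixels are split
    independently so every seed appears in both halves; a seed with fewer
    than 2 pixels goes wholly to train (logged).  ``per_seed=False`` splits
    globally over all pixels.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    n = len(ds.y)
    in_train = np.zeros(n, dtype=bool)
    if per_seed:
        for sid in np.unique(ds.origin[:, 0]):
            idx = np.nonzero(ds.origin[:, 0] == sid)[0]
            if len(idx) < 2:
                in_train[idx] = True
                logger.info("seed %d has %d pixel(s); assigned wholly to train", sid, len(idx))
                continue
            k = int(round(len(idx) * train_frac))
            k = min(max(k, 1), len(idx) - 1)
            chosen = rng.permutation(len(idx))[:k]
            in_train[idx[chosen]] = True
    else:
        k = int(round(n * train_frac))
        in_train[rng.permutation(n)[:k]] = True

    def take(sel: np.ndarray) -> PixelDataset:
        return PixelDataset(
            X=ds.X[sel], y=ds.y[sel], origin=ds.origin[sel],
            class_map=ds.class_map, seed_ids=ds.seed_ids,
        )

    return take(in_train), take(~in_train)


@dataclass
class DnnModel:
    net: Sequential
    config: DnnConfig
    class_map: list[str]
    n_bands: int
    band_mean: np.ndarray
    band_std: np.ndarray

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params)}
        arrays["band_mean"] = self.band_mean
        arrays["band_std"] = self.band_std
        np.savez(os.path.join(outdir, "weights.npz"), **arrays)
        sidecar = {
            "kind": "dnn_pixel",
            "class_map": self.class_map,
            "n_bands": self.n_bands,
            "config": {
                "hidden_widths": list(self.config.hidden_widths),
                "lr": self.config.lr,
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "rng_seed": self.config.rng_seed,
            },
        }
        with open(os.path.join(outdir, "model.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, outdir: str) -> "DnnModel":
        with open(os.path.join(outdir, "model.json")) as fh:
            sidecar = json.load(fh)
        cfgd = sidecar["config"]
        cfg = DnnConfig(
            hidden_widths=tuple(cfgd["hidden_widths"]), lr=cfgd["lr"],
            epochs=cfgd["epochs"], batch_size=cfgd["batch_size"], rng_seed=cfgd["rng_seed"],
        )
        net = _build_net(sidecar["n_bands"], cfg, len(sidecar["class_map"]),
                         np.random.default_rng(0))
        data = np.load(os.path.join(outdir, "weights.npz"))
        for i, p in enumerate(net.params):
            p[...] = data[f"p{i}"]
        return cls(net=net, config=cfg, class_map=sidecar["class_map"],
                   n_bands=sidecar["n_bands"], band_mean=data["band_mean"],
                   band_std=data["band_std"])


def _build_net(n_bands: int, cfg: DnnConfig, n_classes: int,
               rng: np.random.Generator) -> Sequential:
    layers: list = []
    fan_in = n_bands
    for width in cfg.hidden_widths:
        layers.append(DenseLayer(fan_in, width, rng))
        layers.append(ReluLayer())
        fan_in = width
    layers.append(DenseLayer(fan_in, n_classes, rng))
    return Sequential(layers)


def train_dnn(
    ds: PixelDataset, cfg: DnnConfig | None = None, val: PixelDataset | None = None
) -> tuple[DnnModel, dict]:
    """Train the pixel classifier on a (training) pixel dataset.

    Returns the model and a per-epoch history of train (and optional
    validation) loss/accuracy.
    """
    cfg = cfg or DnnConfig()
    classes = np.unique(ds.y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    n_classes = int(ds.y.max()) + 1

    mean = ds.X.mean(axis=0)
    std = ds.X.std(axis=0)
    std[std == 0] = 1.0
    Xn = (ds.X - mean) / std
    Xv = (val.X - mean) / std if val is not None else None

    rng = np.random.default_rng(cfg.rng_seed)
    net = _build_net(ds.n_bands, cfg, n_classes, rng)
    opt = Adam(net.params, lr=cfg.lr)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    n = len(ds.y)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            logits = net.forward(Xn[sel], train=True)
            loss, dlogits = cross_entropy_and_grad(logits, ds.y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            grads = net.backward(dlogits)
            opt.step(grads)
            losses.append(loss * len(sel))
            correct += int((logits.argmax(axis=1) == ds.y[sel]).sum())
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(correct / n)
        if Xv is not None:
            logits = net.forward(Xv)
            vloss, _ = cross_entropy_and_grad(logits, val.y)
            history["val_loss"].append(vloss)
            history["val_acc"].append(float((logits.argmax(axis=1) == val.y).mean()))
    model = DnnModel(
        net=net, config=cfg,
        class_map=ds.class_map or [str(c) for c in range(n_classes)],
        n_bands=ds.n_bands, band_mean=mean, band_std=std,
    )
    return model, history


def predict_pixels(model: DnnModel, ds: PixelDataset) -> tuple[np.ndarray, np.ndarray]:
    """Integer class codes and softmax probabilities per pixel.

    Ties resolve to the lowest class index.
    """
    if ds.n_bands != model.n_bands:
        raise ValueError(f"dataset has {ds.n_bands} bands, model expects {model.n_bands}")
    Xn = (ds.X - model.band_mean) / model.band_std
    logits = np.concatenate(
        [model.net.forward(Xn[i : i + 8192]) for i in range(0, len(Xn), 8192)]
    )
    probs = softmax(logits)
    return probs.argmax(axis=1), probs
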