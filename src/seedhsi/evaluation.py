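"""Classifier evaluation, classification-map rendering, and embedding.

Metrics follow the usual one-vs-rest conventions:

* per-class precision = TP/(TP+FP), recall = TP/(TP+FN),
  f1 = 2PR/(P+R), each with macro (unweighted) and weighted
  (support-weighted) averages;
* OA (overall accuracy) = trace/total of the confusion matrix;
* AA (average accuracy) = mean per-class one-vs-rest accuracy
  (TP+TN)/(TP+TN+FP+FN);
* Cohen's kappa = (Po - Pe)/(1 - Pe) with Po = OA and
  Pe = sum_i row_i * col_i / total^2.

Zero-denominator metrics are reported as 0 and flagged undefined rather
than NaN, keeping tabular output stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

__all__ = [
    "EvaluationReport",
    "ClassificationMap",
    "confusion_matrix",
    "binary_metrics",
    "multiclass_report",
    "render_map",
    "pca_tsne_embed",
]

BACKGROUND = -1  # sentinel label for non-seed pixels in a classification map


@dataclass
class EvaluationReport:
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro_avg: dict[str, float]
    weighted_avg: dict[str, float]
    AA: float
    OA: float
    kappa: float
    class_names: list[str] = field(default_factory=list)
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_names": self.class_names,
            "per_class": self.per_class,
            "macro_avg": self.macro_avg,
            "weighted_avg": self.weighted_avg,
            "AA": self.AA,
            "OA": self.OA,
            "kappa": self.kappa,
            "undefined": self.undefined,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class ClassificationMap:
    labels: np.ndarray                  # 2-D int array, BACKGROUND sentinel
    palette: dict[int, tuple[int, int, int]]
    legend: dict[int, str]


def confusion_matrix(truth, pred, k: int) -> np.ndarray:
    """k x k count matrix; rows are truth, columns predictions."""
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size and (truth.min() < 0 or truth.max() >= k or pred.min() < 0 or pred.max() >= k):
        raise ValueError(f"labels outside [0, {k})")
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


def binary_metrics(TP: int, FP: int, TN: int, FN: int) -> dict[str, float | bool]:
    """Precision, recall, f1 and accuracy from a binary tally.

    Undefined ratios (zero denominator) are reported as 0 with the
    ``undefined`` flag set.
    """
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("counts must be nonnegative")
    undefined = False

    def ratio(num, den):
        nonlocal undefined
        if den == 0:
            undefined = True
            return 0.0
        return num / den

    precision = ratio(TP, TP + FP)
    recall = ratio(TP, TP + FN)
    f1 = ratio(2 * precision * recall, precision + recall)
    accuracy = ratio(TP + TN, TP + TN + FP + FN)
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "accuracy": accuracy, "undefined": undefined,
    }


def multiclass_report(
    confusion: np.ndarray, class_names: list[str] | None = None
) -> EvaluationReport:
    """Full report (per-class metrics, averages, AA, OA, kappa) from counts."""
    cm = np.asarray(confusion, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError(f"confusion matrix must be square with k >= 2, got {cm.shape}")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    names = class_names or [str(i) for i in range(k)]
    if len(names) != k:
        raise ValueError("class_names length mismatch")

    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    supports = cm.sum(axis=1)
    ovr_accuracies = []
    for i in range(k):
        TP = int(cm[i, i])
        FN = int(cm[i].sum() - TP)
        FP = int(cm[:, i].sum() - TP)
        TN = total - TP - FN - FP
        m = binary_metrics(TP, FP, TN, FN)
        if m.pop("undefined"):
            undefined.append(names[i])
        ovr_accuracies.append(m["accuracy"])
        m["support"] = int(supports[i])
        per_class[names[i]] = m

    keys = ("precision", "recall", "f1")
    macro = {key: float(np.mean([per_class[n][key] for n in names])) for key in keys}
    weights = supports / total
    weighted = {
        key: float(np.sum([per_class[n][key] * w for n, w in zip(names, weights)]))
        for key in keys
    }
    OA = float(np.trace(cm) / total)
    AA = float(np.mean(ovr_accuracies))
    Pe = float(np.sum(cm.sum(axis=1) * cm.sum(axis=0)) / total**2)
    kappa = 1.0 if Pe == 1.0 else (OA - Pe) / (1.0 - Pe)
    return EvaluationReport(
        confusion=cm, per_class=per_class, macro_avg=macro, weighted_avg=weighted,
        AA=AA, OA=OA, kappa=float(kappa), class_names=names, undefined=undefined,
    )


DEFAULT_PALETTE = [
    (31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40), (148, 103, 189),
    (140, 86, 75), (227, 119, 194), (127, 127, 127), (188, 189, 34), (23, 190, 207),
]


def render_map(
    panel_shape: tuple[int, int],
    predictions: np.ndarray,
    origins: np.ndarray,
    class_names: list[str],
    png_path: str | None = None,
    palette: dict[int, tuple[int, int, int]] | None = None,
) -> ClassificationMap:
    """Paint per-pixel predictions back into the panel frame.

    ``origins`` rows are ``(seed_id, row, col)``; only ``(row, col)`` are
    used.  Background keeps the sentinel and renders black.  When
    ``png_path`` is given the RGB map is written there with a JSON legend
    sidecar next to it.
    """
    rows, cols = panel_shape
    origins = np.asarray(origins)
    rr, cc = origins[:, -2], origins[:, -1]
    if len(rr) != len(predictions):
        raise ValueError("predictions and origins length mismatch")
    if len(rr) and (rr.min() < 0 or rr.max() >= rows or cc.min() < 0 or cc.max() >= cols):
        raise ValueError("origin outside panel frame")
    labels = np.full(panel_shape, BACKGROUND, dtype=np.int64)
    labels[rr, cc] = predictions
    if palette is None:
        palette = {i: DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)] for i in range(len(class_names))}
    missing = set(np.unique(predictions)) - set(palette)
    if missing:
        raise ValueError(f"palette missing classes {sorted(missing)}")
    legend = {i: name for i, name in enumerate(class_names)}
    cmap = ClassificationMap(labels=labels, palette=palette, legend=legend)
    if png_path is not None:
        from PIL import Image

        rgb = np.zeros((rows, cols, 3), dtype=np.uint8)
        for cls, color in palette.items():
            rgb[labels == cls] = color
        Image.fromarray(rgb).save(png_path)
        with open(png_path + ".json", "w") as fh:
            json.dump(
                {"legend": {str(k): v for k, v in legend.items()},
                 "palette": {str(k): list(v) for k, v in palette.items()},
                 "background": BACKGROUND},
                fh, indent=2,
            )
    return cmap


def pca_tsne_embed(
    X: np.ndarray, n_components: int = 50, rng_seed: int = 0, perplexity: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """PCA to ``n_components`` (centered), then 2-D t-SNE.

    Returns the n x 2 coordinates and the PCA explained-variance vector.
    When n <= n_components the PCA rank is reduced with a warning.
    """
    import warnings

    X = np.asarray(X, dtype=np.float64)
    n = len(X)
    max_rank = min(n - 1, X.shape[1])
    if n_components > max_rank:
        warnings.warn(
            f"n_components reduced from {n_components} to {max_rank} for {n} samples",
            stacklevel=2,
        )
        n_components = max_rank
    pca = PCA(n_components=n_components, random_state=rng_seed)
    Z = pca.fit_transform(X)
    perplexity = min(perplexity, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, random_state=rng_seed, perplexity=perplexity, init="pca")
    coords = tsne.fit_transform(Z)
    return coords, pca.explained_variance_
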