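"""Nucleus classification: softmax CNN plus adjacent-set refinement.

Each detected nucleus is classified from its 27x27 patch by a convolutional
softmax network that reuses the detector's trunk with a K-way head.  Because
cells of the same type cluster spatially in tissue, a nucleus's class
probabilities are then refined by averaging them with those of neighbouring
detections within a radius (the "adjacent set"), which suppresses isolated
misclassifications.  Scoring uses one-vs-rest F1 per class and the
macro-averaged one-vs-rest ranking AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .detect import prf1, summarize
from .errors import InvalidParameterError
from .layers import Conv2D, Dense, Flatten, MaxPool2, ReLU
from .targets import NucleusRecord

__all__ = [
    "DEFAULT_CLASS_NAMES",
    "SoftmaxCNN",
    "softmax",
    "adjacent_set_predict",
    "multiclass_auc",
    "classwise_f1",
    "ClassEvalReport",
]

#: Conventional colorectal-histology nucleus categories; configurable, the
#: model itself only sees integer class indices.
DEFAULT_CLASS_NAMES = ("epithelial", "inflammatory", "fibroblast", "miscellaneous")

DEFAULT_NEIGHBOR_RADIUS = 30.0


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SoftmaxCNN:
    """K-way patch classifier on the detector's convolutional trunk.

    Architecture: conv 4x4x1x36 / pool / conv 3x3x36x48 / pool / FC 512 /
    FC 512 / FC K with softmax.  Trained with cross-entropy by mini-batch
    SGD with momentum; deterministic given the seed.
    """

    def __init__(self, n_classes: int = 4, seed: int = 0, input_side: int = 27):
        if n_classes < 2:
            raise InvalidParameterError("need at least two classes")
        self.n_classes = n_classes
        self.input_side = input_side
        rng = np.random.default_rng(seed)
        side = input_side - 3  # conv 4x4
        side //= 2
        side -= 2  # conv 3x3
        side //= 2
        self.layers = [
            Conv2D(4, 4, 1, 36, rng),
            ReLU(),
            MaxPool2(),
            Conv2D(3, 3, 36, 48, rng),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Dense(side * side * 48, 512, rng),
            ReLU(),
            Dense(512, 512, rng),
            ReLU(),
            Dense(512, n_classes, rng),
        ]
        self.trained = False

    def _forward(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, patches: np.ndarray) -> np.ndarray:
        """(N, 27, 27) patches -> (N, K) class-probability rows."""
        if not self.trained:
            raise InvalidParameterError("classifier has not been trained")
        return softmax(self._forward(patches))

    def predict(self, patches: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(patches), axis=1)

    def fit(
        self,
        patches: np.ndarray,
        labels: np.ndarray,
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        seed: int = 0,
    ) -> list[float]:
        """Cross-entropy training; returns the per-epoch mean loss trace."""
        patches = np.asarray(patches, dtype=np.float64)
        labels = np.asarray(labels, dtype=np.int64)
        if len(patches) == 0:
            raise InvalidParameterError("empty training set")
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise InvalidParameterError("label outside the class alphabet")
        rng = np.random.default_rng(seed + 1)
        params = [p for l in self.layers for p in l.params()]
        grads = [g for l in self.layers for g in l.grads()]
        velocity = [np.zeros_like(p) for p in params]
        onehot = np.eye(self.n_classes)[labels]
        trace = []
        n = len(patches)
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                probs = softmax(self._forward(patches[idx]))
                eps = 1e-12
                loss = -np.mean(np.sum(onehot[idx] * np.log(probs + eps), axis=1))
                epoch_loss += loss * len(idx)
                g = (probs - onehot[idx]) / len(idx)
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                for p, gr, v in zip(params, grads, velocity):
                    v *= momentum
                    v -= learning_rate * gr
                    p += v
            trace.append(epoch_loss / n)
        self.trained = True
        return trace

    def save(self, path) -> None:
        """Single-file checkpoint: JSON header + flat weight arrays."""
        import json

        header = json.dumps(
            {
                "version": 1,
                "n_classes": self.n_classes,
                "input_side": self.input_side,
                "trained": self.trained,
            }
        )
        arrays = {
            f"param_{i}": p
            for i, p in enumerate(p for l in self.layers for p in l.params())
        }
        np.savez(path, header=header, **arrays)

    @classmethod
    def load(cls, path) -> "SoftmaxCNN":
        import json

        data = np.load(path, allow_pickle=False)
        header = json.loads(str(data["header"]))
        if header.get("version") != 1:
            raise InvalidParameterError("unsupported classifier checkpoint version")
        model = cls(n_classes=header["n_classes"], input_side=header["input_side"])
        for i, p in enumerate(p for l in model.layers for p in l.params()):
            p[...] = data[f"param_{i}"]
        model.trained = bool(header["trained"])
        return model


def adjacent_set_predict(
    target_index: int,
    detections,
    per_patch_probs: np.ndarray,
    radius: float = DEFAULT_NEIGHBOR_RADIUS,
    neighbor_weight: float = 1.0,
) -> np.ndarray:
    """Refine one nucleus's class probabilities with its adjacent set.

    The target's probability vector (weight 1) is averaged with those of
    every other detection within ``radius`` (weight ``neighbor_weight``
    each) and renormalized.  With no neighbours the solo prediction is
    returned unchanged.
    """
    probs = np.asarray(per_patch_probs, dtype=np.float64)
    if len(detections) != len(probs):
        raise InvalidParameterError("one probability row per detection required")
    if not 0 <= target_index < len(detections):
        raise InvalidParameterError("target index outside the detection list")
    coords = np.array([(r.row, r.col) for r in detections])
    dist = cdist(coords[target_index : target_index + 1], coords)[0]
    neighbor = (dist <= radius) & (np.arange(len(detections)) != target_index)
    total = probs[target_index] + neighbor_weight * probs[neighbor].sum(axis=0)
    weight = 1.0 + neighbor_weight * int(neighbor.sum())
    return total / weight


def multiclass_auc(true_labels, prob_matrix, return_per_class: bool = False):
    """Macro-averaged one-vs-rest ranking AUC with midrank tie handling.

    Each class present in ``true_labels`` contributes the AUC of its
    probability column against the class-membership indicator; classes
    absent from the labels are skipped (their one-vs-rest problem is
    degenerate).  Requires at least two distinct classes.
    """
    y = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(prob_matrix, dtype=np.float64)
    if p.ndim != 2 or len(y) != len(p):
        raise InvalidParameterError("prob_matrix must be (n_samples, n_classes)")
    present = np.unique(y)
    if present.size < 2:
        raise InvalidParameterError("AUC undefined with a single class present")
    per_class = {int(k): float(roc_auc_score(y == k, p[:, k])) for k in present}
    macro = float(np.mean(list(per_class.values())))
    if return_per_class:
        return macro, per_class
    return macro


def classwise_f1(true_labels, predicted_labels, n_classes: int | None = None):
    """One-vs-rest F1 per class plus (max, min, mean, mse) summary.

    Returns ``(per_class_f1, summary)`` where ``per_class_f1`` is an array
    over classes ``0..K-1`` (0 for classes never predicted correctly).
    """
    y = np.asarray(true_labels, dtype=np.int64)
    yhat = np.asarray(predicted_labels, dtype=np.int64)
    if y.shape != yhat.shape:
        raise InvalidParameterError("label arrays differ in length")
    k = n_classes or int(max(y.max(), yhat.max())) + 1
    scores = np.zeros(k)
    for c in range(k):
        tp = int(np.sum((yhat == c) & (y == c)))
        fp = int(np.sum((yhat == c) & (y != c)))
        fn = int(np.sum((yhat != c) & (y == c)))
        scores[c] = prf1(tp, fp, fn)[2]
    return scores, summarize(scores)


@dataclass
class ClassEvalReport:
    """Classification scores in the layout of the standard report tables."""

    per_class_f1: np.ndarray
    f1_summary: tuple[float, float, float, float]
    per_class_auc: dict[int, float]
    auc_summary: tuple[float, float, float, float]
    weighted_f1: float
    macro_auc: float
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    @classmethod
    def from_predictions(cls, true_labels, predicted_labels, prob_matrix,
                         class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES) -> "ClassEvalReport":
        y = np.asarray(true_labels, dtype=np.int64)
        f1s, f1_summary = classwise_f1(y, predicted_labels, n_classes=len(class_names))
        macro, per_auc = multiclass_auc(y, prob_matrix, return_per_class=True)
        support = np.bincount(y, minlength=len(class_names)).astype(float)
        weighted = float(np.sum(f1s * support) / support.sum()) if support.sum() else 0.0
        return cls(
            per_class_f1=f1s,
            f1_summary=f1_summary,
            per_class_auc=per_auc,
            auc_summary=summarize(list(per_auc.values())),
            weighted_f1=weighted,
            macro_auc=macro,
            class_names=tuple(class_names),
        )

    def summary_frame(self) -> pd.DataFrame:
        index = ["max", "min", "mean", "mse"]
        return pd.DataFrame({"f1": self.f1_summary, "auc": self.auc_summary}, index=index)

    def to_csv(self, path) -> None:
        rows = pd.DataFrame(
            {
                "class": self.class_names,
                "f1": self.per_class_f1,
                "auc": [self.per_class_auc.get(i, np.nan) for i in range(len(self.class_names))],
            }
        )
        rows.to_csv(path, index=False)
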