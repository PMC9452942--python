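"""Peak picking on probability maps and detection scoring.

Predicted maps are turned into nucleus coordinates by thresholded local-
maximum extraction with greedy non-maximum suppression, then scored against
ground-truth centers by one-to-one distance matching within a radius.
Per-image precision/recall/F1 lists are summarised by their max, min, mean
and mean squared deviation about the mean (a dispersion statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import InvalidParameterError
from .targets import NucleusRecord

__all__ = [
    "extract_maxima",
    "match_detections",
    "prf1",
    "summarize",
    "EvalReport",
    "evaluate_images",
]

DEFAULT_THRESHOLD = 0.5
DEFAULT_MIN_SEPARATION = 4.0
DEFAULT_MATCH_RADIUS = 6.0


def extract_maxima(
    prob_map: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> list[NucleusRecord]:
    """Local maxima of a probability map above ``threshold``.

    Candidate peaks (8-neighbourhood local maxima) are kept greedily by
    descending value (ties broken row-major); a candidate closer than
    ``min_separation`` to an already-retained peak is suppressed.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError("threshold must lie strictly in (0, 1)")
    if min_separation < 1:
        raise InvalidParameterError("min_separation must be >= 1")
    prob_map = np.asarray(prob_map, dtype=np.float64)
    is_peak = (prob_map >= ndimage.maximum_filter(prob_map, size=3)) & (
        prob_map >= threshold
    )
    rows, cols = np.nonzero(is_peak)
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -prob_map[rows, cols]))
    kept: list[tuple[int, int]] = []
    records: list[NucleusRecord] = []
    min_sep2 = min_separation ** 2
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if any((r - kr) ** 2 + (c - kc) ** 2 < min_sep2 for kr, kc in kept):
            continue
        kept.append((r, c))
        records.append(NucleusRecord(row=r, col=c, height=float(prob_map[r, c])))
    return records


def _coords(records) -> np.ndarray:
    return np.array(
        [(r.row, r.col) if isinstance(r, NucleusRecord) else tuple(r) for r in records],
        dtype=np.float64,
    ).reshape(-1, 2)


def match_detections(
    pred,
    truth,
    radius: float = DEFAULT_MATCH_RADIUS,
    method: str = "greedy",
) -> tuple[int, int, int]:
    """One-to-one matching of predictions to ground truth within ``radius``.

    ``method="greedy"`` pairs by ascending center distance; ``"hungarian"``
    solves the optimal assignment instead.  Returns ``(TP, FP, FN)`` with
    ``TP + FN = len(truth)`` and ``TP + FP = len(pred)``.
    """
    if radius <= 0:
        raise InvalidParameterError("matching radius must be positive")
    p, t = _coords(pred), _coords(truth)
    if len(p) == 0 or len(t) == 0:
        return 0, len(p), len(t)
    dist = cdist(p, t)
    if method == "hungarian":
        big = radius + 1.0
        rows, cols = linear_sum_assignment(np.minimum(dist, big))
        tp = int(np.sum(dist[rows, cols] <= radius))
    elif method == "greedy":
        order = np.argsort(dist, axis=None, kind="stable")
        used_p = np.zeros(len(p), dtype=bool)
        used_t = np.zeros(len(t), dtype=bool)
        tp = 0
        for flat in order:
            i, j = divmod(int(flat), len(t))
            if dist[i, j] > radius:
                break
            if used_p[i] or used_t[j]:
                continue
            used_p[i] = used_t[j] = True
            tp += 1
    else:
        raise InvalidParameterError(f"unknown matching method {method!r}")
    return tp, len(p) - tp, len(t) - tp


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts (0 on zero denominators)."""
    if min(tp, fp, fn) < 0:
        raise InvalidParameterError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def summarize(values) -> tuple[float, float, float, float]:
    """Max, min, mean, and population mean squared deviation from the mean."""
    values = np.asarray(list(values), dtype=np.float64)
    if values.size == 0:
        raise InvalidParameterError("cannot summarize an empty list")
    mean = float(values.mean())
    return float(values.max()), float(values.min()), mean, float(np.mean((values - mean) ** 2))


@dataclass
class EvalReport:
    """Per-image detection scores plus their summary statistics."""

    image_ids: list[str]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    counts: list[tuple[int, int, int]] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Rows max/min/mean/mse, one column per metric."""
        data = {
            name: summarize(vals)
            for name, vals in (("precision", self.precision), ("recall", self.recall), ("f1", self.f1))
        }
        return pd.DataFrame(data, index=["max", "min", "mean", "mse"])

    def per_image(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image": self.image_ids,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
            }
        )

    def pooled(self) -> tuple[float, float, float]:
        """Precision/recall/F1 from counts pooled over all images."""
        tp = sum(c[0] for c in self.counts)
        fp = sum(c[1] for c in self.counts)
        fn = sum(c[2] for c in self.counts)
        return prf1(tp, fp, fn)

    def to_csv(self, per_image_path, summary_path) -> None:
        self.per_image().to_csv(per_image_path, index=False)
        self.summary().to_csv(summary_path)


def evaluate_images(
    predictions: dict,
    truths: dict,
    radius: float = DEFAULT_MATCH_RADIUS,
    method: str = "greedy",
) -> EvalReport:
    """Score per-image detection lists against ground-truth lists.

    Both arguments map image id -> list of `NucleusRecord`; ids must agree.
    """
    if set(predictions) != set(truths):
        raise InvalidParameterError("prediction and truth image ids differ")
    report = EvalReport(image_ids=[], precision=[], recall=[], f1=[])
    for image_id in sorted(predictions):
        tp, fp, fn = match_detections(predictions[image_id], truths[image_id], radius, method)
        p, r, f = prf1(tp, fp, fn)
        report.image_ids.append(str(image_id))
        report.precision.append(p)
        report.recall.append(r)
        report.f1.append(f)
        report.counts.append((tp, fp, fn))
    return report
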