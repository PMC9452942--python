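"""Canonical desk-scale experiments on synthetic scenes.

These reference experiments fix the study conditions under which the
pipeline's behaviour is demonstrated and regression-tested: a detection
experiment (train the spatially constrained detector on ~200 patches,
score held-out tiles) and a classification experiment (solo softmax vs
adjacent-set refinement on class-clustered tiles).  Both are deterministic
given their seed and shared between the test suite and the acceptance
script so the reported numbers always come from the same procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .classify import SoftmaxCNN, adjacent_set_predict, multiclass_auc
from .detect import DEFAULT_MATCH_RADIUS, evaluate_images, extract_maxima
from .network import TrainConfig, train_detector
from .scenes import (
    SceneSpec,
    hematoxylin_channel,
    make_classification_set,
    make_training_set,
    simulate,
)

__all__ = [
    "DETECTION_SCENE",
    "CLASSIFICATION_TRAIN_SCENE",
    "CLASSIFICATION_TEST_SCENE",
    "DetectionResultSummary",
    "ClassificationResultSummary",
    "run_detection_experiment",
    "run_classification_experiment",
]

#: Detection tiles: 71 px so the stride-11 sliding window covers the
#: interior exactly (8 + 5*11 + 8), 8 nuclei per tile.
DETECTION_SCENE = SceneSpec()

#: Classifier training tiles: larger and denser, classes i.i.d. so the
#: training set is class-balanced and the solo classifier unbiased.
CLASSIFICATION_TRAIN_SCENE = SceneSpec(shape=(151, 151), n_nuclei=30, min_separation=14.0)

#: Classifier evaluation tiles: identical photometry but with two spatial
#: class clusters per tile, so neighbourhoods within the 30 px adjacent-set
#: radius are class-pure enough for ensemble refinement to help.
CLASSIFICATION_TEST_SCENE = replace(
    CLASSIFICATION_TRAIN_SCENE, cluster_classes=True, n_clusters=2
)


@dataclass
class DetectionResultSummary:
    precision: float
    recall: float
    f1: float
    n_train_patches: int
    n_test_nuclei: int
    loss_trace: list[float]


@dataclass
class ClassificationResultSummary:
    solo_accuracy: float
    adjacent_accuracy: float
    macro_auc: float
    n_train_patches: int
    n_test_nuclei: int


def run_detection_experiment(
    seed: int,
    n_train_tiles: int = 12,
    n_test_tiles: int = 6,
    epochs: int = 30,
    match_radius: float = DEFAULT_MATCH_RADIUS,
    scene: SceneSpec = DETECTION_SCENE,
) -> DetectionResultSummary:
    """Train the M=1 detector and score pooled P/R/F1 on held-out tiles."""
    patches, targets, _, _ = make_training_set(scene, n_train_tiles, seed=seed)
    model, trace = train_detector(patches, targets, TrainConfig(epochs=epochs), seed=seed)
    preds, truths = {}, {}
    for i in range(n_test_tiles):
        tile = simulate(scene, seed=seed + 777_000 + i)
        prob = model.predict_image(hematoxylin_channel(tile))
        preds[f"tile_{i}"] = extract_maxima(prob)
        truths[f"tile_{i}"] = tile.records
    report = evaluate_images(preds, truths, radius=match_radius)
    p, r, f1 = report.pooled()
    return DetectionResultSummary(
        precision=p,
        recall=r,
        f1=f1,
        n_train_patches=len(patches),
        n_test_nuclei=sum(len(v) for v in truths.values()),
        loss_trace=trace,
    )


def run_classification_experiment(
    seed: int,
    n_train_tiles: int = 10,
    n_test_tiles: int = 6,
    epochs: int = 30,
    neighbor_radius: float = 30.0,
    neighbor_weight: float = 1.0,
) -> ClassificationResultSummary:
    """Solo softmax vs adjacent-set accuracy on class-clustered tiles."""
    train_scenes = [
        simulate(CLASSIFICATION_TRAIN_SCENE, seed=seed + 1000 * (t + 1))
        for t in range(n_train_tiles)
    ]
    x_train, y_train, _ = make_classification_set(train_scenes)
    test_scenes = [
        simulate(CLASSIFICATION_TEST_SCENE, seed=seed + 555_000 + t)
        for t in range(n_test_tiles)
    ]
    x_test, y_test, kept = make_classification_set(test_scenes)
    model = SoftmaxCNN(seed=seed)
    model.fit(x_train, y_train, epochs=epochs, seed=seed)
    probs = model.predict_proba(x_test)
    solo = float(np.mean(np.argmax(probs, axis=1) == y_test))
    correct = []
    start = 0
    for records in kept:
        n = len(records)
        scene_probs = probs[start : start + n]
        for i in range(n):
            refined = adjacent_set_predict(
                i, records, scene_probs, radius=neighbor_radius, neighbor_weight=neighbor_weight
            )
            correct.append(int(np.argmax(refined)) == y_test[start + i])
        start += n
    return ClassificationResultSummary(
        solo_accuracy=solo,
        adjacent_accuracy=float(np.mean(correct)),
        macro_auc=multiclass_auc(y_test, probs),
        n_train_patches=len(x_train),
        n_test_nuclei=len(y_test),
    )
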