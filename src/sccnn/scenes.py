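"""Synthetic H&E-like tiles with known nucleus centers and classes.

Scenes are built through the same Beer-Lambert forward model the stain
module inverts: nuclei are anisotropic Gaussian hematoxylin-density blobs
(truncated at 3 sigma) composited additively in optical-density space over
a uniform eosin background; Gaussian OD noise is added and the result is
converted to RGB and quantized to 8 bit.  Because the ground-truth centers,
classes and per-stain density maps are known exactly, every stage of the
pipeline — stain separation, target construction, detector training,
peak picking, classification — can be exercised end-to-end without any
external dataset.

What this emulates (and what it does not): the generator reproduces the
low-level photometry of H&E tiles — dark blue-purple nuclei of class-
dependent size, shape and chromatin density on a pink background — but not
tissue texture, touching/overlapping nuclei, stain variation between
slides, or scanner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import stains
from .errors import InvalidParameterError, LayoutBudgetError
from .stains import HE_DEFAULT, StainMatrix, normalize_stain_matrix, od_to_rgb, separate_stains
from .targets import DEFAULT_RADIUS, NucleusRecord, build_probability_map

__all__ = [
    "ClassAppearance",
    "DEFAULT_APPEARANCES",
    "SceneSpec",
    "SyntheticScene",
    "sample_layout",
    "render",
    "simulate",
    "make_training_set",
    "make_classification_set",
]


@dataclass(frozen=True)
class ClassAppearance:
    """Morphology of one nucleus class.

    ``sigma`` is the Gaussian scale in pixels (nucleus "radius" is roughly
    2 sigma), ``eccentricity`` stretches the major over the minor axis, and
    ``od_mean``/``od_sd`` set the peak hematoxylin density.
    """

    name: str
    sigma_mean: float
    sigma_sd: float
    eccentricity: float
    od_mean: float
    od_sd: float


#: Loosely modelled on colorectal H&E appearance: large round epithelial
#: nuclei, small dense inflammatory nuclei, elongated pale fibroblasts and
#: an intermediate miscellaneous class.  Density spreads overlap so the
#: classes are separable but not trivially so.
DEFAULT_APPEARANCES = (
    ClassAppearance("epithelial", sigma_mean=2.6, sigma_sd=0.25, eccentricity=0.2, od_mean=0.85, od_sd=0.12),
    ClassAppearance("inflammatory", sigma_mean=1.7, sigma_sd=0.15, eccentricity=0.05, od_mean=1.25, od_sd=0.12),
    ClassAppearance("fibroblast", sigma_mean=2.4, sigma_sd=0.25, eccentricity=0.55, od_mean=0.6, od_sd=0.12),
    ClassAppearance("miscellaneous", sigma_mean=2.2, sigma_sd=0.3, eccentricity=0.3, od_mean=1.0, od_sd=0.15),
)


@dataclass(frozen=True)
class SceneSpec:
    """Everything that determines a synthetic tile (given a seed)."""

    shape: tuple[int, int] = (71, 71)
    n_nuclei: int = 8
    min_separation: float = 16.0
    margin: float = 9.0
    class_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    appearances: tuple[ClassAppearance, ...] = DEFAULT_APPEARANCES
    background_eosin: float = 0.3
    noise_sd: float = 0.02
    cluster_classes: bool = False
    n_clusters: int = 4
    incident: float = 255.0
    quantize: bool = True

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise InvalidParameterError("min_separation must be positive")
        if self.background_eosin < 0 or self.noise_sd < 0:
            raise InvalidParameterError("densities and noise must be >= 0")
        p = np.asarray(self.class_proportions, dtype=float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise InvalidParameterError("class proportions must be a distribution")
        if len(self.class_proportions) != len(self.appearances):
            raise InvalidParameterError("one appearance per class required")


@dataclass
class SyntheticScene:
    """A rendered tile with its complete ground truth."""

    image: np.ndarray  # (H, W, 3) transmitted intensities
    records: list[NucleusRecord]
    hema_density: np.ndarray  # (H, W) true hematoxylin concentration
    eosin_density: np.ndarray
    spec: SceneSpec


def sample_layout(spec: SceneSpec, seed: int = 0, budget: int = 10_000) -> list[NucleusRecord]:
    """Dart-throwing layout honouring the minimum center separation.

    Classes are drawn i.i.d. from the configured proportions, or — with
    ``cluster_classes`` — from the nearest of ``n_clusters`` random
    cluster seeds so that neighbouring nuclei share a class (the spatial
    clustering real tissue exhibits, which adjacent-set prediction exploits).
    """
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    # centers live on the pixel grid, like point annotations on real tiles
    lo = int(np.ceil(spec.margin))
    hi_r, hi_c = h - 1 - lo, w - 1 - lo
    if hi_r <= lo or hi_c <= lo:
        raise InvalidParameterError("margin leaves no room for nuclei")
    placed: list[tuple[float, float]] = []
    attempts = 0
    while len(placed) < spec.n_nuclei:
        if attempts >= budget:
            raise LayoutBudgetError(
                f"placed {len(placed)}/{spec.n_nuclei} nuclei in {budget} attempts; "
                "density infeasible for the requested separation"
            )
        attempts += 1
        cand = (
            float(rng.integers(lo, hi_r + 1)),
            float(rng.integers(lo, hi_c + 1)),
        )
        if all(
            (cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= spec.min_separation ** 2
            for p in placed
        ):
            placed.append(cand)
    k = len(spec.class_proportions)
    if spec.cluster_classes and placed:
        seeds = rng.uniform([0, 0], [h - 1, w - 1], size=(spec.n_clusters, 2))
        seed_classes = rng.choice(k, size=spec.n_clusters, p=spec.class_proportions)
        pts = np.asarray(placed)
        d2 = ((pts[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels = seed_classes[np.argmin(d2, axis=1)]
    else:
        labels = rng.choice(k, size=len(placed), p=spec.class_proportions)
    return [
        NucleusRecord(row=r, col=c, label=int(lab))
        for (r, c), lab in zip(placed, labels)
    ]


def render(
    layout: list[NucleusRecord],
    spec: SceneSpec,
    seed: int = 0,
    stain_matrix: StainMatrix = HE_DEFAULT,
) -> SyntheticScene:
    """Render a layout into an H&E-like tile via the Beer-Lambert model."""
    rng = np.random.default_rng(seed)
    sm = normalize_stain_matrix(stain_matrix)
    if sm.n_stains != 2:
        raise InvalidParameterError("rendering expects a two-stain (H&E) matrix")
    h, w = spec.shape
    hema = np.zeros((h, w))
    rows = np.arange(h, dtype=np.float64)
    cols = np.arange(w, dtype=np.float64)
    for rec in layout:
        app = spec.appearances[int(rec.label)]
        sigma = max(rng.normal(app.sigma_mean, app.sigma_sd), 0.6)
        amp = max(rng.normal(app.od_mean, app.od_sd), 0.05)
        s_major = sigma * (1.0 + app.eccentricity)
        s_minor = sigma / (1.0 + app.eccentricity)
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        dr = rows[:, None] - rec.row
        dc = cols[None, :] - rec.col
        a = (dr * ct + dc * st) / s_major
        b = (-dr * st + dc * ct) / s_minor
        q = a * a + b * b
        blob = np.where(q <= 9.0, amp * np.exp(-q / 2.0), 0.0)  # truncate at 3 sigma
        hema += blob
    eosin = np.full((h, w), spec.background_eosin)
    od = hema[:, :, None] * sm.rows[0] + eosin[:, :, None] * sm.rows[1]
    if spec.noise_sd > 0:
        od = od + rng.normal(0.0, spec.noise_sd, size=od.shape)
    od = np.maximum(od, 0.0)
    image = od_to_rgb(od, spec.incident)
    if spec.quantize:
        image = np.clip(np.rint(image), 0, spec.incident).astype(np.uint8)
    return SyntheticScene(
        image=image, records=list(layout), hema_density=hema, eosin_density=eosin, spec=spec
    )


def simulate(spec: SceneSpec, seed: int = 0, stain_matrix: StainMatrix = HE_DEFAULT) -> SyntheticScene:
    """Layout + render in one call; the seed fixes both."""
    layout = sample_layout(spec, seed=seed)
    return render(layout, spec, seed=seed + 1, stain_matrix=stain_matrix)


def hematoxylin_channel(scene: SyntheticScene, stain_matrix: StainMatrix = HE_DEFAULT) -> np.ndarray:
    """Deconvolved hematoxylin concentration map of a rendered scene —
    the single-channel input every network in the package consumes."""
    return separate_stains(scene.image, stain_matrix, incident=scene.spec.incident)[:, :, 0]


def _clamped_topleft(center: float, side: int, extent: int, jitter: int, rng) -> int:
    tl = int(round(center)) - side // 2 + int(rng.integers(-jitter, jitter + 1))
    return int(np.clip(tl, 0, extent - side))


def make_training_set(
    spec: SceneSpec,
    n_tiles: int,
    seed: int = 0,
    patch_size: int = 27,
    map_size: int = 11,
    d: float = DEFAULT_RADIUS,
    jitter: int = 3,
    negatives_per_tile: int | None = None,
    stain_matrix: StainMatrix = HE_DEFAULT,
):
    """Paired detector inputs and probability-map targets from fresh tiles.

    Positive patches are cut around each nucleus with +-``jitter`` px
    offset (the center always stays inside the output map); negatives are
    sampled where the target region is identically zero.  Targets are the
    corresponding ``map_size`` crops of the full-tile probability map, with
    the symmetric offset ``(patch_size - map_size) // 2`` between patch and
    map frames.

    Returns ``(patches, targets, labels, scenes)`` with labels -1 for
    background patches.
    """
    if (patch_size - map_size) % 2:
        raise InvalidParameterError("patch and map sizes must share parity")
    off = (patch_size - map_size) // 2
    rng = np.random.default_rng(seed)
    n_neg = negatives_per_tile if negatives_per_tile is not None else spec.n_nuclei
    patches, targets, labels, scenes = [], [], [], []
    h, w = spec.shape
    for t in range(n_tiles):
        scene = simulate(spec, seed=seed + 1000 * (t + 1), stain_matrix=stain_matrix)
        scenes.append(scene)
        conc = hematoxylin_channel(scene, stain_matrix)
        full_map = build_probability_map([r.center for r in scene.records], (h, w), d=d)
        for rec in scene.records:
            tr = _clamped_topleft(rec.row, patch_size, h, jitter, rng)
            tc = _clamped_topleft(rec.col, patch_size, w, jitter, rng)
            patches.append(conc[tr : tr + patch_size, tc : tc + patch_size])
            targets.append(full_map[tr + off : tr + off + map_size, tc + off : tc + off + map_size])
            labels.append(int(rec.label))
        added = 0
        guard = 0
        while added < n_neg and guard < 200:
            guard += 1
            tr = int(rng.integers(0, h - patch_size + 1))
            tc = int(rng.integers(0, w - patch_size + 1))
            target = full_map[tr + off : tr + off + map_size, tc + off : tc + off + map_size]
            if target.any():
                continue
            patches.append(conc[tr : tr + patch_size, tc : tc + patch_size])
            targets.append(target)
            labels.append(-1)
            added += 1
    return (
        np.asarray(patches, dtype=np.float64),
        np.asarray(targets, dtype=np.float64),
        np.asarray(labels, dtype=np.int64),
        scenes,
    )


def make_classification_set(
    scenes: list[SyntheticScene],
    patch_size: int = 27,
    stain_matrix: StainMatrix = HE_DEFAULT,
):
    """Center-aligned labelled patches for classifier training/evaluation.

    Returns ``(patches, labels, records_per_scene)``; nuclei too close to a
    border for a full patch are skipped.
    """
    patches, labels, kept = [], [], []
    for scene in scenes:
        conc = hematoxylin_channel(scene, stain_matrix)
        h, w = conc.shape
        half = patch_size // 2
        scene_records = []
        for rec in scene.records:
            tr, tc = int(round(rec.row)) - half, int(round(rec.col)) - half
            if tr < 0 or tc < 0 or tr + patch_size > h or tc + patch_size > w:
                continue
            patches.append(conc[tr : tr + patch_size, tc : tc + patch_size])
            labels.append(int(rec.label))
            scene_records.append(rec)
        kept.append(scene_records)
    return np.asarray(patches, dtype=np.float64), np.asarray(labels, dtype=np.int64), kept
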