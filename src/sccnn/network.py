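"""The spatially constrained nucleus-detection network (SC-CNN).

A conventional convolutional trunk (two conv/pool stages and two
fully-connected layers) does not emit a probability map directly.  Instead a
*parameter-estimation* layer squashes the 512-dim feature vector into M
candidate-nucleus parameters

    u_m = (H' - 1) * sigm(w_u . x + b_u) + 1        (row, 1-based)
    v_m = (W' - 1) * sigm(w_v . x + b_v) + 1        (col, 1-based)
    h_m = sigm(w_h . x + b_h)                       (height in [0, 1])

and an analytic *spatial-constraint* layer renders those candidates into an
H' x W' map with the same kernel shape as the training target,

    yhat_j = h_m* / (1 + ||z_j - zhat_m*||^2 / 2)   within radius d of the
                                                    nearest candidate m*, else 0.

Because the output is forced to be a sum-of-kernels surface, the network can
only move, raise, or switch off candidates (h_m = 0 disables one), which is
what makes the regression spatially constrained.  Training minimizes a
weighted cross-entropy between target and predicted maps, the weight
``y_j + eps`` emphasising the sparse nonzero-probability pixels.

Everything is plain numpy with hand-derived gradients; the custom layers'
backward passes are validated against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import InvalidParameterError, SpecViolationError
from .layers import Conv2D, Dense, Flatten, MaxPool2, ReLU, sigmoid

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "LossConfig",
    "TrainConfig",
    "ParamEstimation",
    "SpatialConstraint",
    "weighted_xent_loss",
    "epsilon_ratio",
    "build_network",
    "SCNNDetector",
    "train_detector",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a `NetworkSpec`.

    ``kind`` is one of ``input``, ``conv``, ``pool``, ``fully_connected``,
    ``sconv_param`` (parameter estimation) or ``sconv_spatial`` (analytic
    output layer).  Only the fields relevant to the kind are set.
    """

    kind: str
    shape: tuple[int, int, int] | None = None  # input only: (H, W, C)
    filter_size: tuple[int, int] | None = None
    c_out: int | None = None
    units: int | None = None
    n_candidates: int | None = None
    map_shape: tuple[int, int] | None = None


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer stack; shapes must chain under valid stride-1
    convolution and 2x2 non-overlapping pooling."""

    layers: tuple[LayerSpec, ...]

    @classmethod
    def default(cls, n_candidates: int = 1) -> "NetworkSpec":
        """The reference architecture: 27x27x1 input, conv 4x4x1x36, 2x2
        pool, conv 3x3x36x48, 2x2 pool, two 512-unit FC layers, a 3-vector
        parameter layer per candidate, and an 11x11 spatial output map."""
        return cls(
            layers=(
                LayerSpec("input", shape=(27, 27, 1)),
                LayerSpec("conv", filter_size=(4, 4), c_out=36),
                LayerSpec("pool"),
                LayerSpec("conv", filter_size=(3, 3), c_out=48),
                LayerSpec("pool"),
                LayerSpec("fully_connected", units=512),
                LayerSpec("fully_connected", units=512),
                LayerSpec("sconv_param", n_candidates=n_candidates),
                LayerSpec("sconv_spatial", map_shape=(11, 11)),
            )
        )

    def shape_chain(self) -> list[tuple]:
        """Validate the stack and return every layer's output shape."""
        if not self.layers or self.layers[0].kind != "input":
            raise SpecViolationError("spec must start with an input layer")
        shapes: list[tuple] = [tuple(self.layers[0].shape)]
        cur: tuple = shapes[0]
        for spec in self.layers[1:]:
            if spec.kind == "conv":
                if len(cur) != 3:
                    raise SpecViolationError(f"conv after non-spatial shape {cur}")
                h, w, c = cur
                kh, kw = spec.filter_size
                if h < kh or w < kw:
                    raise SpecViolationError(f"kernel {spec.filter_size} exceeds input {cur}")
                cur = (h - kh + 1, w - kw + 1, spec.c_out)
            elif spec.kind == "pool":
                h, w, c = cur
                if h % 2 or w % 2:
                    raise SpecViolationError(f"2x2 pool on odd spatial size {cur}")
                cur = (h // 2, w // 2, c)
            elif spec.kind == "fully_connected":
                cur = (spec.units,)
            elif spec.kind == "sconv_param":
                if len(cur) != 1:
                    raise SpecViolationError("parameter layer requires a flat input")
                cur = (spec.n_candidates, 3)
            elif spec.kind == "sconv_spatial":
                if len(cur) != 2 or cur[1] != 3:
                    raise SpecViolationError("spatial layer requires (M, 3) candidates")
                cur = tuple(spec.map_shape)
            else:
                raise SpecViolationError(f"unknown layer kind {spec.kind!r}")
            shapes.append(cur)
        return shapes

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return tuple(self.layers[0].shape)

    @property
    def map_shape(self) -> tuple[int, int]:
        last = self.layers[-1]
        if last.kind != "sconv_spatial":
            raise SpecViolationError("spec does not end in a spatial-constraint layer")
        return tuple(last.map_shape)

    @property
    def n_candidates(self) -> int:
        for spec in self.layers:
            if spec.kind == "sconv_param":
                return spec.n_candidates
        raise SpecViolationError("spec has no parameter-estimation layer")


@dataclass
class LossConfig:
    """Weighted cross-entropy settings.

    ``epsilon`` is either the string ``"auto"`` — the per-batch ratio of
    nonzero- to zero-probability target pixels, floored at ``eps_floor`` —
    or a fixed positive float.
    """

    epsilon: float | str = "auto"
    eps_floor: float = 1e-3
    delta: float = 1e-7  # log clamp

    def __post_init__(self) -> None:
        if isinstance(self.epsilon, str):
            if self.epsilon != "auto":
                raise InvalidParameterError("epsilon must be 'auto' or a positive float")
        elif self.epsilon <= 0:
            raise InvalidParameterError("epsilon must be positive")

    def value_for(self, y: np.ndarray) -> float:
        if self.epsilon == "auto":
            return epsilon_ratio(y, floor=self.eps_floor)
        return float(self.epsilon)


def epsilon_ratio(y: np.ndarray, floor: float = 1e-3) -> float:
    """Ratio of nonzero- to zero-probability pixels in a target batch."""
    nonzero = int(np.count_nonzero(y))
    zero = y.size - nonzero
    return max(nonzero / max(zero, 1), floor)


class ParamEstimation:
    """Dense layer emitting (u, v, h) per candidate, sigmoid-bounded.

    Rows u lie in [1, H'], cols v in [1, W'] (1-based map coordinates) and
    heights h in (0, 1) by construction, so candidate sets are always valid
    regardless of the weights.
    """

    def __init__(self, d_in: int, n_candidates: int, map_shape: tuple[int, int],
                 rng: np.random.Generator):
        self.m = n_candidates
        self.map_shape = tuple(map_shape)
        self.dense = Dense(d_in, 3 * n_candidates, rng)

    def params(self):
        return self.dense.params()

    def grads(self):
        return self.dense.grads()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, D) features -> (N, M, 3) candidates [u, v, h]."""
        hprime, wprime = self.map_shape
        a = self.dense.forward(x).reshape(x.shape[0], self.m, 3)
        s = sigmoid(a)
        self._s = s
        out = np.empty_like(s)
        out[:, :, 0] = (hprime - 1) * s[:, :, 0] + 1.0
        out[:, :, 1] = (wprime - 1) * s[:, :, 1] + 1.0
        out[:, :, 2] = s[:, :, 2]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        hprime, wprime = self.map_shape
        ds = self._s * (1.0 - self._s)
        da = g * ds
        da[:, :, 0] *= hprime - 1
        da[:, :, 1] *= wprime - 1
        return self.dense.backward(da.reshape(g.shape[0], -1))


class SpatialConstraint:
    """Analytic output layer rendering candidates into a probability map.

    Each pixel is assigned its nearest candidate (ties to the lower index)
    and takes value ``h * 1/(1 + r^2/2)`` inside the closed disc of radius
    ``d``, else 0.  Differentiable in (u, v, h) away from the measure-zero
    support/assignment boundaries; the backward pass treats the assignment
    as locally constant.
    """

    def __init__(self, map_shape: tuple[int, int], d: float = 4.0):
        self.map_shape = tuple(map_shape)
        self.d = float(d)
        hprime, wprime = self.map_shape
        rr, cc = np.meshgrid(np.arange(hprime), np.arange(wprime), indexing="ij")
        self._grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64)  # (J, 2)

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, cands: np.ndarray) -> np.ndarray:
        """(N, M, 3) candidates -> (N, H', W') predicted maps in [0, 1]."""
        n, m, _ = cands.shape
        centers = cands[:, :, :2] - 1.0  # to 0-based pixel frame
        heights = cands[:, :, 2]
        diff = self._grid[None, :, None, :] - centers[:, None, :, :]  # (N, J, M, 2)
        dist2 = np.einsum("njmk,njmk->njm", diff, diff)
        nearest = np.argmin(dist2, axis=2)  # (N, J), lowest index on ties
        take = nearest[:, :, None]
        d2 = np.take_along_axis(dist2, take, axis=2)[:, :, 0]
        kernel = 1.0 / (1.0 + d2 / 2.0)
        support = np.sqrt(d2) <= self.d
        h_sel = np.take_along_axis(heights, nearest, axis=1)
        flat = np.where(support, h_sel * kernel, 0.0)
        self._cache = (cands.shape, nearest, support, kernel, h_sel,
                       np.take_along_axis(diff, take[:, :, :, None], axis=2)[:, :, 0, :])
        return flat.reshape(n, *self.map_shape)

    def backward(self, g: np.ndarray) -> np.ndarray:
        (n, m, _), nearest, support, kernel, h_sel, diff_sel = self._cache
        gflat = g.reshape(n, -1) * support  # (N, J)
        dcands = np.zeros((n, m, 3))
        # d yhat / dh = kernel ; d yhat / d center = h * kernel^2 * (z_j - c)
        dh = gflat * kernel
        dcenter = (gflat * h_sel * kernel ** 2)[:, :, None] * diff_sel  # (N, J, 2)
        for i in range(n):
            np.add.at(dcands[i, :, 2], nearest[i], dh[i])
            np.add.at(dcands[i, :, 0], nearest[i], dcenter[i, :, 0])
            np.add.at(dcands[i, :, 1], nearest[i], dcenter[i, :, 1])
        return dcands


def weighted_xent_loss(
    y: np.ndarray,
    yhat: np.ndarray,
    cfg: LossConfig | None = None,
    return_grad: bool = False,
):
    """Weighted cross-entropy ``sum_j (y_j + eps) * H(y_j, yhat_j)``.

    ``H(y, yhat) = -y log yhat - (1-y) log(1-yhat)`` with ``yhat`` clamped
    to ``[delta, 1-delta]`` before the logs.  The weight upweights the few
    nonzero-target pixels so the sparse peaks are not drowned out by the
    flat background.  Returns the scalar loss, plus ``dl/dyhat`` when
    ``return_grad`` is set (zero where the clamp is active).
    """
    cfg = cfg or LossConfig()
    if y.shape != yhat.shape:
        raise InvalidParameterError(f"shape mismatch {y.shape} vs {yhat.shape}")
    eps = cfg.value_for(y)
    yc = np.clip(yhat, cfg.delta, 1.0 - cfg.delta)
    h = -y * np.log(yc) - (1.0 - y) * np.log(1.0 - yc)
    w = y + eps
    loss = float(np.sum(w * h))
    if not return_grad:
        return loss
    interior = (yhat > cfg.delta) & (yhat < 1.0 - cfg.delta)
    grad = np.where(interior, w * (-(y / yc) + (1.0 - y) / (1.0 - yc)), 0.0)
    return loss, grad


class SCNNDetector:
    """Full detector: convolutional trunk + parameter estimation + spatial
    constraint, with mini-batch SGD training and sliding-window inference."""

    def __init__(self, spec: NetworkSpec | None = None, d: float = 4.0, seed: int = 0):
        self.spec = spec or NetworkSpec.default()
        self.d = float(d)
        self.seed = int(seed)
        shapes = self.spec.shape_chain()  # validates
        rng = np.random.default_rng(seed)
        self.trunk = []
        cur = shapes[0]
        for spec_l, out in zip(self.spec.layers[1:], shapes[1:]):
            if spec_l.kind == "conv":
                self.trunk.append(Conv2D(*spec_l.filter_size, cur[2], spec_l.c_out, rng))
                self.trunk.append(ReLU())
            elif spec_l.kind == "pool":
                self.trunk.append(MaxPool2())
            elif spec_l.kind == "fully_connected":
                if len(cur) == 3:
                    self.trunk.append(Flatten())
                    d_in = int(np.prod(cur))
                else:
                    d_in = cur[0]
                self.trunk.append(Dense(d_in, spec_l.units, rng))
                self.trunk.append(ReLU())
            elif spec_l.kind == "sconv_param":
                self.param = ParamEstimation(cur[0], spec_l.n_candidates,
                                             self.spec.map_shape, rng)
            elif spec_l.kind == "sconv_spatial":
                self.spatial = SpatialConstraint(spec_l.map_shape, self.d)
            cur = out

    # -- plumbing ---------------------------------------------------------
    def _all_layers(self):
        return [*self.trunk, self.param, self.spatial]

    def params(self):
        return [p for l in self._all_layers() for p in l.params()]

    def grads(self):
        return [g for l in self._all_layers() for g in l.grads()]

    @staticmethod
    def _as_batch(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[..., None]
        return x

    # -- forward / backward ----------------------------------------------
    def forward(self, patches: np.ndarray):
        """Patches (N, H, W[, 1]) -> (candidates (N, M, 3), maps (N, H', W'))."""
        x = self._as_batch(patches)
        for layer in self.trunk:
            x = layer.forward(x)
        cands = self.param.forward(x)
        return cands, self.spatial.forward(cands)

    def loss_and_backward(self, patches, targets, loss_cfg: LossConfig):
        _, yhat = self.forward(patches)
        n = yhat.shape[0]
        loss, dyhat = weighted_xent_loss(targets, yhat, loss_cfg, return_grad=True)
        g = self.spatial.backward(dyhat / n)
        g = self.param.backward(g)
        for layer in reversed(self.trunk):
            g = layer.backward(g)
        return loss / n

    def predict_map(self, patches: np.ndarray) -> np.ndarray:
        return self.forward(patches)[1]

    def predict_image(self, image: np.ndarray, stride: int | None = None,
                      average: bool = True) -> np.ndarray:
        """Dense sliding-window inference over a single-channel image.

        Windows of the input side (27) are slid with ``stride`` (default:
        the output-map side, which tiles the interior exactly); each
        window's map is placed at the symmetric offset (27-11)//2 = 8 and
        overlaps are averaged.  Pixels within the offset of the border are
        not covered and stay 0.
        """
        image = np.asarray(image, dtype=np.float64)
        ph = self.spec.input_shape[0]
        mh, mw = self.spec.map_shape
        off = (ph - mh) // 2
        stride = stride or mh
        h, w = image.shape
        if h < ph or w < ph:
            raise InvalidParameterError(f"image {image.shape} smaller than window {ph}")
        rows = sorted({*range(0, h - ph + 1, stride), h - ph})
        cols = sorted({*range(0, w - ph + 1, stride), w - ph})
        windows = np.stack([image[r : r + ph, c : c + ph] for r in rows for c in cols])
        maps = self.predict_map(windows)
        canvas = np.zeros((h, w))
        counts = np.zeros((h, w))
        k = 0
        for r in rows:
            for c in cols:
                canvas[r + off : r + off + mh, c + off : c + off + mw] += maps[k]
                counts[r + off : r + off + mh, c + off : c + off + mw] += 1
                k += 1
        if average:
            np.divide(canvas, counts, out=canvas, where=counts > 0)
        return canvas

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: versioned JSON header + flat weight arrays."""
        header = {
            "version": CHECKPOINT_VERSION,
            "d": self.d,
            "seed": self.seed,
            "spec": {"layers": [asdict(l) for l in self.spec.layers]},
        }
        arrays = {f"param_{i}": p for i, p in enumerate(self.params())}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "SCNNDetector":
        data = np.load(path, allow_pickle=False)
        header = json.loads(str(data["header"]))
        if header.get("version") != CHECKPOINT_VERSION:
            raise InvalidParameterError(f"unsupported checkpoint version {header.get('version')}")
        layers = tuple(
            LayerSpec(**{k: tuple(v) if isinstance(v, list) else v for k, v in l.items()})
            for l in header["spec"]["layers"]
        )
        model = cls(NetworkSpec(layers), d=header["d"], seed=header["seed"])
        for i, p in enumerate(model.params()):
            p[...] = data[f"param_{i}"]
        return model


def build_network(spec: NetworkSpec | None = None, d: float = 4.0, seed: int = 0) -> SCNNDetector:
    """Construct a detector from a layer specification (validating shapes)."""
    return SCNNDetector(spec, d=d, seed=seed)


@dataclass
class TrainConfig:
    """Mini-batch SGD-with-momentum hyperparameters."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 0.005
    momentum: float = 0.9
    loss: LossConfig = field(default_factory=LossConfig)


def train_detector(
    patches: np.ndarray,
    target_maps: np.ndarray,
    config: TrainConfig | None = None,
    seed: int = 0,
    spec: NetworkSpec | None = None,
    d: float = 4.0,
):
    """Train a detector on paired patches / target maps.

    Deterministic given ``seed`` (weight init and shuffling both derive
    from it).  Returns ``(model, loss_trace)`` where the trace holds one
    mean per-sample loss per epoch.
    """
    config = config or TrainConfig()
    patches = np.asarray(patches, dtype=np.float64)
    target_maps = np.asarray(target_maps, dtype=np.float64)
    if len(patches) == 0:
        raise InvalidParameterError("empty training set")
    if len(patches) != len(target_maps):
        raise InvalidParameterError("patches and targets differ in length")
    model = build_network(spec, d=d, seed=seed)
    rng = np.random.default_rng(seed + 1)
    velocity = [np.zeros_like(p) for p in model.params()]
    trace: list[float] = []
    n = len(patches)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = model.loss_and_backward(patches[idx], target_maps[idx], config.loss)
            epoch_loss += loss * len(idx)
            for p, g, v in zip(model.params(), model.grads(), velocity):
                v *= config.momentum
                v -= config.learning_rate * g
                p += v
        trace.append(epoch_loss / n)
    return model, trace
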