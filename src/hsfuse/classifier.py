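"""Inception-style tumor/normal patch classifier and probability-map stitching.

The classifier follows the Inception-v4 layout adapted to square histology
patches: a three-convolution stem (each stride 2), 4 Inception-A blocks,
Reduction-A, 7 Inception-B blocks, Reduction-B, 3 Inception-C blocks,
global average pooling, and a 2-neuron sigmoid head trained with
per-neuron binary cross-entropy on one-hot targets.  Every convolution is
he_normal-initialized and followed by ReLU and 20% dropout.  A width
multiplier ``kappa`` scales all channel counts for desk-scale runs; at
``kappa = 1`` the block widths reproduce the production feature sizes
(384 after the A blocks, 1024 after Reduction-A, 1536 after Reduction-B).

Two deliberate simplifications of the original Inception design: the
factorized 1x7/7x1 and 1x3/3x1 convolution pairs are folded into single
3x3 convolutions with the same output widths, and reduction kernels are
5 (Reduction-A) and 3 (Reduction-B), stride 2, valid padding — the sizes
that reproduce the printed 25->11->5 spatial trace.

Whole-slide probability maps average per-patch tumor probabilities over
each pixel's covering patches (up to 4x coverage with a 200-px window at
100-px step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn


@dataclass
class ClassifierConfig:
    input_shape: tuple[int, int, int] = (200, 200, 87)   # (w, w, C)
    dropout: float = 0.2
    learning_rate: float = 1.0
    rho: float = 0.95
    batch_size: int = 16
    epochs: int = 10
    seed: int = 0
    kappa: float = 1.0

    def __post_init__(self):
        w, w2, _ = self.input_shape
        if w != w2:
            raise ValueError("input patches must be square")
        if w % 8:
            raise ValueError(
                "input size must survive three stride-2 stages (divisible by 8)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")

    def width(self, w: int) -> int:
        return max(1, math.ceil(self.kappa * w))


@dataclass
class ProbabilityMap:
    """Per-pixel tumor probability over a slide grid; NaN where uncovered."""

    values: np.ndarray
    coverage: np.ndarray

    def __post_init__(self):
        covered = self.coverage > 0
        vals = self.values[covered]
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _ConvUnit(nn.Layer):
    """conv -> ReLU -> dropout (ReLU skipped for the logits head)."""

    def __init__(self, cin, cout, k, stride, padding, cfg, rng, drop_rng):
        self.conv = nn.Conv2D(cin, cout, k, stride, padding,
                              init=nn.he_normal, rng=rng)
        self.drop = nn.Dropout(cfg.dropout, drop_rng)
        self.cout = cout

    def parameters(self):
        return self.conv.parameters()

    def out_shape(self, in_shape):
        return self.conv.out_shape(in_shape)

    def __call__(self, x, training=False):
        return self.drop(nn.relu(self.conv(x)), training)


class _Branch(nn.Layer):
    """A sequential chain of conv units, optionally after a pooling op."""

    def __init__(self, units, pool=None):
        self.units = units
        self.pool = pool    # None | ('avg_same', k) | MaxPool2D

    def parameters(self):
        return [p for u in self.units for p in u.parameters()]

    def out_channels(self):
        if self.units:
            return self.units[-1].cout
        raise AssertionError("pool-only branch must know its channels")

    def __call__(self, x, training=False):
        if self.pool is not None:
            if isinstance(self.pool, tuple):
                x = nn.avg_pool_same(x, self.pool[1])
            else:
                x = self.pool(x)
        for u in self.units:
            x = u(x, training)
        return x


class _InceptionBlock(nn.Layer):
    """Parallel branches concatenated along the channel axis."""

    def __init__(self, branches, passthrough_channels=0):
        self.branches = branches
        self.passthrough = passthrough_channels

    def parameters(self):
        return [p for b in self.branches for p in b.parameters()]

    def __call__(self, x, training=False):
        return nn.concat_channels([b(x, training) for b in self.branches])


def _inception_a(cin, cfg, rng, drop_rng):
    W = cfg.width
    u = lambda ci, co, k=1, s=1, p="same": _ConvUnit(ci, co, k, s, p, cfg,
                                                     rng, drop_rng)
    return _InceptionBlock([
        _Branch([u(cin, W(96))], pool=("avg_same", 3)),
        _Branch([u(cin, W(96))]),
        _Branch([u(cin, W(64)), u(W(64), W(96), 3)]),
        _Branch([u(cin, W(64)), u(W(64), W(96), 3), u(W(96), W(96), 3)]),
    ])


def _reduction_a(cin, cfg, rng, drop_rng, k=5):
    W = cfg.width
    u = lambda ci, co, k=1, s=1, p="same": _ConvUnit(ci, co, k, s, p, cfg,
                                                     rng, drop_rng)
    branches = [
        _Branch([], pool=nn.MaxPool2D(k, 2)),
        _Branch([u(cin, W(384), k, 2, "valid")]),
        _Branch([u(cin, W(192)), u(W(192), W(224), 3),
                 u(W(224), W(256), k, 2, "valid")]),
    ]
    block = _InceptionBlock(branches)
    block.out_channels = cin + W(384) + W(256)
    return block


def _inception_b(cin, cfg, rng, drop_rng):
    W = cfg.width
    u = lambda ci, co, k=1, s=1, p="same": _ConvUnit(ci, co, k, s, p, cfg,
                                                     rng, drop_rng)
    return _InceptionBlock([
        _Branch([u(cin, W(128))], pool=("avg_same", 3)),
        _Branch([u(cin, W(384))]),
        _Branch([u(cin, W(192)), u(W(192), W(256), 3)]),
        _Branch([u(cin, W(192)), u(W(192), W(224), 3), u(W(224), W(256), 3)]),
    ])


def _reduction_b(cin, cfg, rng, drop_rng, k=3):
    W = cfg.width
    u = lambda ci, co, k=1, s=1, p="same": _ConvUnit(ci, co, k, s, p, cfg,
                                                     rng, drop_rng)
    branches = [
        _Branch([], pool=nn.MaxPool2D(k, 2)),
        _Branch([u(cin, W(192)), u(W(192), W(192), k, 2, "valid")]),
        _Branch([u(cin, W(256)), u(W(256), W(320), 3),
                 u(W(320), W(320), k, 2, "valid")]),
    ]
    block = _InceptionBlock(branches)
    block.out_channels = cin + W(192) + W(320)
    return block


def _inception_c(cin, cfg, rng, drop_rng):
    W = cfg.width
    u = lambda ci, co, k=1, s=1, p="same": _ConvUnit(ci, co, k, s, p, cfg,
                                                     rng, drop_rng)
    return _InceptionBlock([
        _Branch([u(cin, W(256))], pool=("avg_same", 3)),
        _Branch([u(cin, W(256))]),
        _Branch([u(cin, W(384)), u(W(384), W(512), 3)]),
        _Branch([u(cin, W(384)), u(W(384), W(448), 3), u(W(448), W(512), 3)]),
    ])


class InceptionClassifier:
    """The full network; ``predict_logits`` returns the 2-neuron pre-sigmoid."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.drop_rng = np.random.default_rng(config.seed + 1)
        drop = self.drop_rng
        W = config.width
        w, _, cin = config.input_shape
        u = lambda ci, co, k=3, s=2: _ConvUnit(ci, co, k, s, "same",
                                               config, rng, drop)
        self.stem = [u(cin, W(90)), u(W(90), W(94)), u(W(94), W(96))]
        c = W(96)
        sp = w
        for _ in range(3):
            sp = -(-sp // 2)        # spatial size after the stem
        self.blocks_a = [_inception_a(c if i == 0 else 4 * W(96),
                                      config, rng, drop) for i in range(4)]
        c = 4 * W(96)
        ka = min(5, sp)             # reduction kernels capped at feature size
        self.red_a = _reduction_a(c, config, rng, drop, k=ka)
        sp = (sp - ka) // 2 + 1
        c = self.red_a.out_channels
        b_out = W(128) + W(384) + W(256) + W(256)
        self.blocks_b = [_inception_b(c if i == 0 else b_out,
                                      config, rng, drop) for i in range(7)]
        c = b_out
        kb = min(3, sp)
        self.red_b = _reduction_b(c, config, rng, drop, k=kb)
        c = self.red_b.out_channels
        c_out = W(256) + W(256) + W(512) + W(512)
        self.blocks_c = [_inception_c(c if i == 0 else c_out,
                                      config, rng, drop) for i in range(3)]
        self.feature_channels = c_out
        self.dense = nn.Dense(c_out, 2, init=nn.he_normal, rng=rng)
        self._modules = (self.stem + self.blocks_a + [self.red_a]
                         + self.blocks_b + [self.red_b] + self.blocks_c)

    def parameters(self):
        params = []
        for m in self._modules:
            params.extend(m.parameters())
        params.extend(self.dense.parameters())
        return params

    def get_weights(self):
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights, strict=True):
            p.data = w.astype(nn.DTYPE).copy()

    def forward(self, x: nn.Tensor, training: bool = False) -> nn.Tensor:
        for m in self._modules:
            x = m(x, training)
        h = x.data.shape[2]
        x = nn.AvgPool2D(h, h)(x)   # global average pool
        x = nn.flatten(x)
        return self.dense(x)

    def predict_logits(self, images: np.ndarray,
                       batch_size: int = 16) -> np.ndarray:
        """images: (N, w, w, C) -> (N, 2) logits, eval mode."""
        out = []
        x = images.transpose(0, 3, 1, 2).astype(nn.DTYPE)
        for i in range(0, len(x), batch_size):
            out.append(self.forward(nn.Tensor(x[i:i + batch_size])).data)
        return np.concatenate(out, axis=0)

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 16) -> np.ndarray:
        """(N, 2) per-neuron sigmoid probabilities (need not sum to 1)."""
        return 1.0 / (1.0 + np.exp(-self.predict_logits(images, batch_size)))


def build_classifier(config: ClassifierConfig) -> InceptionClassifier:
    return InceptionClassifier(config)


def spatial_trace(config: ClassifierConfig) -> list[tuple[str, int]]:
    """Spatial size after the stem and each reduction stage."""
    w = config.input_shape[0]
    trace = [("input", w)]
    for i in range(3):
        w = -(-w // 2)
        trace.append((f"stem{i + 1}", w))
    k = min(5, w)
    w = (w - k) // 2 + 1
    trace.append(("reduction_a", w))
    k = min(3, w)
    w = (w - k) // 2 + 1
    trace.append(("reduction_b", w))
    trace.append(("avgpool", 1))
    return trace


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class LabeledPatchSet:
    """Images (N, w, w, C), binary labels, and per-patch patient ids."""

    images: np.ndarray
    labels: np.ndarray
    patients: Sequence = field(default_factory=tuple)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or len(self.images) != len(self.labels):
            raise ValueError("images must be (N, w, w, C) matching labels")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")


class PatientOverlapError(ValueError):
    pass


def check_patient_partition(*sets: LabeledPatchSet):
    """Hard guard: no patient id may appear in two splits."""
    seen: dict = {}
    for i, s in enumerate(sets):
        for pid in set(s.patients):
            if pid in seen and seen[pid] != i:
                raise PatientOverlapError(
                    f"patient {pid!r} appears in splits {seen[pid]} and {i}")
            seen[pid] = i


def train_classifier(train: LabeledPatchSet, config: ClassifierConfig,
                     val: LabeledPatchSet | None = None
                     ) -> tuple[InceptionClassifier, dict]:
    """Seeded Adadelta/BCE training; returns best-validation model + history.

    Raises :class:`PatientOverlapError` if a patient id occurs in both
    splits, and ``ValueError`` if the training set lacks a class.
    """
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain both classes")
    if val is not None:
        check_patient_partition(train, val)
    model = InceptionClassifier(config)
    opt = nn.Adadelta(model.parameters(), lr=config.learning_rate,
                      rho=config.rho)
    shuffle_rng = np.random.default_rng(config.seed + 2)
    x = train.images.transpose(0, 3, 1, 2).astype(nn.DTYPE)
    targets = np.eye(2, dtype=np.float64)[train.labels]
    history: dict = {"train_loss": [], "train_accuracy": [],
                     "val_loss": [], "val_accuracy": []}
    best = (np.inf, model.get_weights())
    n, bs = len(x), config.batch_size
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        running = 0.0
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            logits = model.forward(nn.Tensor(x[idx]), training=True)
            loss = nn.bce_with_logits(logits, targets[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError("non-finite classifier loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            running += float(loss.data) * len(idx)
        history["train_loss"].append(running / n)
        history["train_accuracy"].append(
            evaluate_accuracy(model, train, config.batch_size))
        if val is not None:
            vl, va = _eval_loss_acc(model, val, config.batch_size)
            history["val_loss"].append(vl)
            history["val_accuracy"].append(va)
            if vl < best[0]:
                best = (vl, model.get_weights())
    if val is not None:
        model.set_weights(best[1])
    return model, history


def _eval_loss_acc(model, dataset: LabeledPatchSet, bs: int):
    logits = model.predict_logits(dataset.images, bs)
    targets = np.eye(2)[dataset.labels]
    z = logits.astype(np.float64)
    loss = float((np.maximum(z, 0) - z * targets
                  + np.log1p(np.exp(-np.abs(z)))).mean())
    acc = float((logits.argmax(axis=1) == dataset.labels).mean())
    return loss, acc


def evaluate_accuracy(model, dataset: LabeledPatchSet,
                      batch_size: int = 16) -> float:
    logits = model.predict_logits(dataset.images, batch_size)
    return float((logits.argmax(axis=1) == dataset.labels).mean())


# ---------------------------------------------------------------------------
# probability-map stitching
# ---------------------------------------------------------------------------

def stitch_probability_map(probabilities: Sequence[float],
                           origins: Sequence[tuple[int, int]],
                           slide_shape: tuple[int, int],
                           window: int) -> ProbabilityMap:
    """Average per-patch probabilities over each covered slide pixel.

    Overlapping windows contribute equally; pixels outside every patch
    footprint are NaN with coverage 0.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    h, w = slide_shape
    acc = np.zeros((h, w))
    cov = np.zeros((h, w), dtype=np.int64)
    for p, (r, c) in zip(probs, origins, strict=True):
        if not (0 <= r <= h - window and 0 <= c <= w - window):
            raise ValueError(f"origin {(r, c)} outside slide {slide_shape}")
        acc[r:r + window, c:c + window] += p
        cov[r:r + window, c:c + window] += 1
    with np.errstate(invalid="ignore"):
        values = np.where(cov > 0, acc / np.maximum(cov, 1), np.nan)
    return ProbabilityMap(values, cov)
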