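"""Unsupervised RGB-guided super-resolution reconstruction network.

The model fuses a low-resolution hyperspectral patch (LR-HSI) with a
registered high-resolution RGB patch (HR-RGB).  The RGB channels are
duplicated into a B-band "stacked" image (default 35/35/17 copies of
R/G/B for B = 87), the LR-HSI is upsampled with a transposed convolution
(kernel (S+1)x(S+1), stride S), the two stacks are concatenated along
the band axis, and a U-Net style encoder-decoder with two stride-2
stages and skip connections maps the 2B-band stack to a B-band
high-resolution cube.  An SxS average-pool head re-degrades the output
to LR for the spectral loss.

Training is unsupervised: no high-resolution hyperspectral ground truth
is used.  The loss is a convex combination (default 0.5/0.5) of

* spatial loss — MSE between the panchromatic (band-mean) images of the
  stacked RGB input and the generated HR cube, and
* spectral loss — MSE between the generated and input LR-HSI,

optimized with Adam (lr 1e-4) at batch size 2 with early stopping on the
validation loss.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from . import nn
from .cube_io import DEFAULT_CLAMP_MAX, HyperspectralCube, PatchPair, RgbImage

#: fixed stacked-band order: wavelength-ascending blocks blue, green, red
STACK_ORDER = ("B", "G", "R")


@dataclass
class SrrConfig:
    """Hyper-parameters of one super-resolution network."""

    scale: int = 4
    patch_size: int = 200
    n_bands: int = 87
    duplication: tuple[int, int, int] = (35, 35, 17)   # (nR, nG, nB)
    kappa: float = 1.0            # width multiplier on all channel counts
    learning_rate: float = 1e-4
    batch_size: int = 2
    loss_weights: tuple[float, float] = (0.5, 0.5)     # (spatial, spectral)
    max_epochs: int = 13
    patience: int = 2
    seed: int = 0
    clamp_max: float = DEFAULT_CLAMP_MAX

    def __post_init__(self):
        if self.scale < 1:
            raise ValueError("scale must be >= 1")
        if self.patch_size % self.scale:
            raise ValueError("patch size must be divisible by the scale")
        if self.patch_size % 4:
            raise ValueError("patch size must be divisible by 4 "
                             "(two stride-2 encoder stages)")
        if sum(self.duplication) != self.n_bands:
            raise ValueError(
                f"duplication counts {self.duplication} must sum to "
                f"n_bands={self.n_bands}")
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")
        if min(self.loss_weights) < 0 or not math.isclose(
                sum(self.loss_weights), 1.0, abs_tol=1e-9):
            raise ValueError("loss weights must be nonnegative and sum to 1")

    def width(self, w: int) -> int:
        return max(1, math.ceil(self.kappa * w))

    @property
    def lr_size(self) -> int:
        return self.patch_size // self.scale

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SrrConfig":
        d = dict(d)
        for key in ("duplication", "loss_weights"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# band stacking
# ---------------------------------------------------------------------------

def stack_rgb(rgb: RgbImage | np.ndarray,
              counts: tuple[int, int, int] = (35, 35, 17),
              order: tuple[str, str, str] = STACK_ORDER) -> np.ndarray:
    """Duplicate RGB channels into a B-band stack.

    ``counts`` is (nR, nG, nB).  Blocks are contiguous and arranged in
    ``order`` (default blue, green, red — wavelength ascending, matching
    a blue-shortest band grid).  Output is (H, W, nR+nG+nB).
    """
    values = rgb.values if isinstance(rgb, RgbImage) else np.asarray(rgb)
    if values.ndim != 3 or values.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if min(counts) <= 0:
        raise ValueError("duplication counts must be positive")
    n_by_channel = {"R": counts[0], "G": counts[1], "B": counts[2]}
    chan_index = {"R": 0, "G": 1, "B": 2}
    blocks = [np.repeat(values[:, :, chan_index[ch]:chan_index[ch] + 1],
                        n_by_channel[ch], axis=2) for ch in order]
    return np.concatenate(blocks, axis=2)


# ---------------------------------------------------------------------------
# losses (array API; the training loop uses the autodiff twins)
# ---------------------------------------------------------------------------

def spatial_loss(stacked_rgb: np.ndarray, generated_hr: np.ndarray) -> float:
    """MSE between the panchromatic images of the two stacks."""
    g = np.asarray(stacked_rgb, dtype=np.float64).mean(axis=-1)
    ghat = np.asarray(generated_hr, dtype=np.float64).mean(axis=-1)
    if g.shape != ghat.shape:
        raise ValueError("spatial shapes differ")
    return float(((g - ghat) ** 2).mean())


def spectral_loss(generated_lr: np.ndarray, input_lr: np.ndarray) -> float:
    """Voxel-wise MSE between generated and input LR cubes."""
    a = np.asarray(generated_lr, dtype=np.float64)
    b = np.asarray(input_lr, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("LR shapes differ")
    return float(((a - b) ** 2).mean())


def total_loss(spatial: float, spectral: float,
               weights: tuple[float, float] = (0.5, 0.5)) -> float:
    if min(weights) < 0:
        raise ValueError("loss weights must be nonnegative")
    return weights[0] * spatial + weights[1] * spectral


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SrrModel:
    """The parameterized network; forward maps (LR-HSI, stacked RGB) to
    (generated HR-HSI, generated LR-HSI)."""

    def __init__(self, config: SrrConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        B, S = config.n_bands, config.scale
        W = config.width
        mk = lambda cin, cout, k=3, s=1: nn.Conv2D(
            cin, cout, k, stride=s, init=nn.glorot_uniform, rng=rng)
        self.upsample = nn.ConvTranspose2D(B, B, S + 1, S,
                                           init=nn.glorot_uniform, rng=rng)
        c196, c256, c384, c512, c640, c768 = (W(w) for w in
                                              (196, 256, 384, 512, 640, 768))
        self.enc1 = mk(2 * B, c196)
        self.enc2 = mk(c196, c256)          # full-res skip source
        self.enc3 = mk(c256, c384, s=2)
        self.enc4 = mk(c384, c512)          # half-res skip source
        self.enc5 = mk(c512, c640, s=2)
        self.enc6 = mk(c640, c768)
        self.up1 = nn.ConvTranspose2D(c768, c768, 3, 2,
                                      init=nn.glorot_uniform, rng=rng)
        self.dec1 = mk(c768 + c512, c640)
        self.dec2 = mk(c640, c512)
        self.up2 = nn.ConvTranspose2D(c512, c256, 3, 2,
                                      init=nn.glorot_uniform, rng=rng)
        self.dec3 = mk(c256 + c256, c256)
        self.dec4 = mk(c256, W(194))
        self.dec5 = mk(W(194), W(160))
        self.dec6 = mk(W(160), W(128))
        self.dec7 = mk(W(128), W(96))
        self.head = nn.Conv2D(W(96), B, 1, init=nn.glorot_uniform, rng=rng)
        self.pool = nn.AvgPool2D(S, S)
        self._layers = [self.upsample, self.enc1, self.enc2, self.enc3,
                        self.enc4, self.enc5, self.enc6, self.up1, self.dec1,
                        self.dec2, self.up2, self.dec3, self.dec4, self.dec5,
                        self.dec6, self.dec7, self.head]

    def parameters(self) -> list[nn.Tensor]:
        params = []
        for layer in self._layers:
            params.extend(layer.parameters())
        return params

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]):
        for p, w in zip(self.parameters(), weights, strict=True):
            p.data = w.astype(nn.DTYPE).copy()

    # -- forward ------------------------------------------------------------

    def forward(self, lr: nn.Tensor, stacked_rgb: nn.Tensor
                ) -> tuple[nn.Tensor, nn.Tensor]:
        r = nn.relu
        x = r(self.upsample(lr))
        x = nn.concat_channels([x, stacked_rgb])
        e1 = r(self.enc1(x))
        e2 = r(self.enc2(e1))
        e3 = r(self.enc3(e2))
        e4 = r(self.enc4(e3))
        e5 = r(self.enc5(e4))
        e6 = r(self.enc6(e5))
        d = r(self.up1(e6))
        d = nn.concat_channels([d, e4])
        d = r(self.dec1(d))
        d = r(self.dec2(d))
        d = r(self.up2(d))
        d = nn.concat_channels([d, e2])
        d = r(self.dec3(d))
        d = r(self.dec4(d))
        d = r(self.dec5(d))
        d = r(self.dec6(d))
        d = r(self.dec7(d))
        hr = self.head(d)           # linear output
        lr_gen = self.pool(hr)
        return hr, lr_gen

    def __call__(self, lr_batch: np.ndarray, rgb_batch: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
        """Numpy in, numpy out, NCHW batches, no gradient tracking."""
        hr, lr_gen = self.forward(nn.Tensor(lr_batch), nn.Tensor(rgb_batch))
        return hr.data, lr_gen.data

    # -- static shape trace ---------------------------------------------------

    def layer_shapes(self) -> list[tuple[str, tuple[int, int, int]]]:
        """(name, (C, H, W)) after each layer, without running data."""
        cfg = self.config
        B, w = cfg.n_bands, cfg.patch_size
        trace: list[tuple[str, tuple[int, int, int]]] = []
        shape = self.upsample.out_shape((B, cfg.lr_size, cfg.lr_size))
        trace.append(("upsample", shape))
        shape = (shape[0] + B, shape[1], shape[2])
        trace.append(("concat_rgb", shape))
        for name in ("enc1", "enc2", "enc3", "enc4", "enc5", "enc6"):
            shape = getattr(self, name).out_shape(shape)
            trace.append((name, shape))
        shape = self.up1.out_shape(shape)
        trace.append(("up1", shape))
        skip = trace[[n for n, _ in trace].index("enc4")][1]
        shape = (shape[0] + skip[0], shape[1], shape[2])
        trace.append(("concat_skip1", shape))
        for name in ("dec1", "dec2"):
            shape = getattr(self, name).out_shape(shape)
            trace.append((name, shape))
        shape = self.up2.out_shape(shape)
        trace.append(("up2", shape))
        skip = trace[[n for n, _ in trace].index("enc2")][1]
        shape = (shape[0] + skip[0], shape[1], shape[2])
        trace.append(("concat_skip2", shape))
        for name in ("dec3", "dec4", "dec5", "dec6", "dec7", "head"):
            shape = getattr(self, name).out_shape(shape)
            trace.append((name, shape))
        shape = self.pool.out_shape(shape)
        trace.append(("avgpool", shape))
        return trace


def build_srr(config: SrrConfig) -> SrrModel:
    return SrrModel(config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without improvement."""

    def __init__(self, patience: int = 2):
        self.patience = patience
        self.best = math.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record an epoch's validation loss; returns True when to stop."""
        if value < self.best:
            self.best, self.best_epoch, self.stale = value, epoch, 0
        else:
            self.stale += 1
        return self.stale >= self.patience


def _pairs_to_arrays(pairs: list[PatchPair], config: SrrConfig):
    for p in pairs:
        if (p.hr_hsi.shape[0] != config.patch_size
                or p.hr_hsi.n_bands != config.n_bands
                or p.scale != config.scale):
            raise ValueError("patch inconsistent with config (w, B, S)")
    lr = np.stack([p.lr_hsi.values for p in pairs]).transpose(0, 3, 1, 2)
    stacked = np.stack([stack_rgb(p.hr_rgb, config.duplication)
                        for p in pairs]).transpose(0, 3, 1, 2)
    return lr.astype(nn.DTYPE), stacked.astype(nn.DTYPE)


def _batch_losses(model: SrrModel, lr_b: np.ndarray, rgb_b: np.ndarray,
                  track: bool):
    lr_t = nn.Tensor(lr_b)
    rgb_t = nn.Tensor(rgb_b)
    hr, lr_gen = model.forward(lr_t, rgb_t)
    g = nn.channel_mean(rgb_t if track else nn.Tensor(rgb_b))
    ghat = nn.channel_mean(hr)
    diff = nn.sub(g, ghat)
    l_spatial = nn.mean_all(nn.mul(diff, diff))
    sdiff = nn.sub(lr_gen, lr_t)
    l_spectral = nn.mean_all(nn.mul(sdiff, sdiff))
    w_sp, w_sc = model.config.loss_weights
    l_total = nn.add(nn.scale(l_spatial, w_sp), nn.scale(l_spectral, w_sc))
    return l_spatial, l_spectral, l_total


def evaluate_losses(model: SrrModel, pairs: list[PatchPair],
                    batch_size: int | None = None) -> dict:
    """Mean (spatial, spectral, total) losses over a patch set."""
    cfg = model.config
    lr, rgb = _pairs_to_arrays(pairs, cfg)
    bs = batch_size or cfg.batch_size
    sums = np.zeros(3)
    for i in range(0, len(pairs), bs):
        ls, lc, lt = _batch_losses(model, lr[i:i + bs], rgb[i:i + bs],
                                   track=False)
        n = len(lr[i:i + bs])
        sums += n * np.array([float(ls.data), float(lc.data), float(lt.data)])
    sums /= len(pairs)
    return {"spatial": sums[0], "spectral": sums[1], "total": sums[2]}


def train_srr(train_pairs: list[PatchPair], config: SrrConfig,
              val_pairs: list[PatchPair] | None = None
              ) -> tuple[SrrModel, dict]:
    """Train the unsupervised network; returns best-validation model + history.

    Fully deterministic given ``config.seed`` (weight init and batch
    shuffling both derive from it).  Raises on an empty training set and
    aborts with a diagnostic if the loss becomes non-finite.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    model = SrrModel(config)
    lr_arr, rgb_arr = _pairs_to_arrays(train_pairs, config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    stopper = EarlyStopping(config.patience)
    monitor_pairs = val_pairs if val_pairs else train_pairs
    history: dict = {k: [] for k in
                     ("train_spatial", "train_spectral", "train_total",
                      "val_spatial", "val_spectral", "val_total")}
    best_weights = model.get_weights()
    n = len(train_pairs)
    bs = config.batch_size
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(n)
        ep = np.zeros(3)
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            ls, lc, lt = _batch_losses(model, lr_arr[idx], rgb_arr[idx],
                                       track=True)
            if not np.isfinite(lt.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {i // bs}: "
                    f"spatial={float(ls.data)}, spectral={float(lc.data)}")
            opt.zero_grad()
            lt.backward()
            opt.step()
            ep += len(idx) * np.array([float(ls.data), float(lc.data),
                                       float(lt.data)])
        ep /= n
        val = evaluate_losses(model, monitor_pairs)
        history["train_spatial"].append(ep[0])
        history["train_spectral"].append(ep[1])
        history["train_total"].append(ep[2])
        history["val_spatial"].append(val["spatial"])
        history["val_spectral"].append(val["spectral"])
        history["val_total"].append(val["total"])
        improved = val["total"] < stopper.best
        stop = stopper.update(val["total"], epoch)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break
    model.set_weights(best_weights)
    history["best_epoch"] = stopper.best_epoch
    history["stopped_epoch"] = len(history["val_total"]) - 1
    return model, history


def history_to_csv(history: dict, path: str | Path) -> Path:
    path = Path(path)
    keys = ["train_spatial", "train_spectral", "train_total",
            "val_spatial", "val_spectral", "val_total"]
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["epoch"] + keys)
        for i in range(len(history["train_total"])):
            writer.writerow([i] + [history[k][i] for k in keys])
    return path


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def reconstruct(lr: HyperspectralCube, rgb: RgbImage,
                model: SrrModel) -> HyperspectralCube:
    """Generate the HR-HSI for one (LR-HSI, HR-RGB) pair.

    The LR head is discarded; output values are clamped to
    [0, config.clamp_max].
    """
    cfg = model.config
    if lr.shape[:2] != (cfg.lr_size, cfg.lr_size):
        raise ValueError(f"LR spatial shape {lr.shape[:2]} != "
                         f"({cfg.lr_size}, {cfg.lr_size})")
    if rgb.shape[:2] != (cfg.patch_size, cfg.patch_size):
        raise ValueError("RGB spatial shape inconsistent with config")
    if lr.n_bands != cfg.n_bands:
        raise ValueError("band count inconsistent with config")
    stacked = stack_rgb(rgb, cfg.duplication)
    lr_b = lr.values.transpose(2, 0, 1)[None].astype(nn.DTYPE)
    rgb_b = stacked.transpose(2, 0, 1)[None].astype(nn.DTYPE)
    hr, _ = model(lr_b, rgb_b)
    values = np.clip(hr[0].transpose(1, 2, 0).astype(np.float64),
                     0.0, cfg.clamp_max)
    meta = dict(lr.meta)
    meta.update(reconstructed=True, scale=cfg.scale)
    return HyperspectralCube(values, lr.wavelengths.copy(), meta)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: SrrModel, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("config", data=json.dumps(model.config.to_dict()))
        g = f.create_group("params")
        for i, p in enumerate(model.parameters()):
            g.create_dataset(f"p{i:04d}", data=p.data)
    return path


def load_checkpoint(path: str | Path) -> SrrModel:
    with h5py.File(path, "r") as f:
        config = SrrConfig.from_dict(json.loads(f["config"][()]))
        model = SrrModel(config)
        weights = [f["params"][k][()] for k in sorted(f["params"])]
    model.set_weights(weights)
    return model
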