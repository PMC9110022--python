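"""Reconstruction-quality and classification metrics.

Reconstruction quality is reported band-wise (PSNR, MAE averaged across
bands), spectrally (spectral angle mapper, SAM) and spatially (a global,
single-statistic SSIM between panchromatic images).  Classification
quality uses confusion-count rates and the rank-based (Mann–Whitney)
ROC AUC.

The global SSIM here is deliberately the whole-image single-statistic
form — means, standard deviations and covariance taken over the full
image — not the sliding-window SSIM; the two agree only on stationary
images.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("hsfuse")

#: sentinel for a metric whose denominator is empty/zero
UNDEFINED = float("nan")


@dataclass
class ReconstructionReport:
    psnr_db: float
    mae: float
    sam_deg: float
    ssim: float
    psnr_per_band: np.ndarray = field(default_factory=lambda: np.array([]))
    mae_per_band: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        return {"psnr_db": self.psnr_db, "mae": self.mae,
                "mae_percent": self.mae * 100.0,
                "sam_deg": self.sam_deg, "ssim": self.ssim,
                "psnr_per_band": list(map(float, self.psnr_per_band)),
                "mae_per_band": list(map(float, self.mae_per_band))}


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


def _check_shapes(ref: np.ndarray, gen: np.ndarray):
    if ref.shape != gen.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {gen.shape}")


def _cube_values(x) -> np.ndarray:
    return np.asarray(getattr(x, "values", x), dtype=np.float64)


# ---------------------------------------------------------------------------
# PSNR / MAE
# ---------------------------------------------------------------------------

def psnr_hsi(ref, gen, peak: float = 1.0) -> tuple[float, np.ndarray]:
    """Band-wise peak signal-to-noise ratio, mean over bands (dB).

    Per band: 10·log10(peak² / MSE).  A band with zero MSE yields the
    +inf sentinel in the per-band array and is excluded from the mean,
    with a warning.
    """
    ref, gen = _cube_values(ref), _cube_values(gen)
    _check_shapes(ref, gen)
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = ((ref - gen) ** 2).mean(axis=(0, 1))
    per_band = np.where(mse > 0, 10.0 * np.log10(peak ** 2 / np.where(mse > 0, mse, 1.0)),
                        np.inf)
    finite = np.isfinite(per_band)
    if not finite.all():
        warnings.warn(f"{(~finite).sum()} band(s) with zero MSE excluded "
                      "from mean PSNR", RuntimeWarning, stacklevel=2)
    mean = float(per_band[finite].mean()) if finite.any() else np.inf
    return mean, per_band


def mae_hsi(ref, gen) -> tuple[float, np.ndarray]:
    """Band-wise mean absolute error, mean over bands (transmittance units)."""
    ref, gen = _cube_values(ref), _cube_values(gen)
    _check_shapes(ref, gen)
    per_band = np.abs(ref - gen).mean(axis=(0, 1))
    return float(per_band.mean()), per_band


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def sam(ref, gen, mode: str = "per_pixel_mean") -> float:
    """Spectral angle mapper in degrees.

    ``per_pixel_mean`` computes the angle between each pixel's generated
    and reference spectrum and averages; ``pooled`` treats the whole
    patch as one pair of long vectors and returns their single angle.
    All-zero spectra are excluded (per_pixel_mean) or contribute nothing
    to the sums (pooled); their count is logged.
    """
    t, r = _cube_values(gen), _cube_values(ref)
    _check_shapes(r, t)
    t2 = t.reshape(-1, t.shape[-1])
    r2 = r.reshape(-1, r.shape[-1])
    nt = np.linalg.norm(t2, axis=1)
    nr = np.linalg.norm(r2, axis=1)
    valid = (nt > 0) & (nr > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("SAM: %d zero-spectrum pixel(s) excluded", n_dropped)
    if mode == "per_pixel_mean":
        if not valid.any():
            return UNDEFINED
        dots = (t2[valid] * r2[valid]).sum(axis=1)
        cosang = np.clip(dots / (nt[valid] * nr[valid]), -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)).mean())
    if mode == "pooled":
        dot = (t2[valid] * r2[valid]).sum()
        denom = np.sqrt((t2[valid] ** 2).sum()) * np.sqrt((r2[valid] ** 2).sum())
        if denom == 0:
            return UNDEFINED
        return float(np.degrees(np.arccos(np.clip(dot / denom, -1.0, 1.0))))
    raise ValueError("mode must be 'pooled' or 'per_pixel_mean'")


# ---------------------------------------------------------------------------
# global SSIM
# ---------------------------------------------------------------------------

def ssim_constants(L: float = 1.0) -> tuple[float, float]:
    """Stabilization constants c1 = (0.01 L)^2 and c2 = (0.03 L)^2."""
    return (0.01 * L) ** 2, (0.03 * L) ** 2


def ssim_global(g, ghat, L: float = 1.0) -> float:
    """Single-statistic structural similarity between two grayscale images.

    Uses whole-image means, standard deviations and covariance with
    c1 = (0.01·L)², c2 = (0.03·L)².
    """
    g, ghat = _cube_values(g), _cube_values(ghat)
    _check_shapes(g, ghat)
    if L <= 0:
        raise ValueError("dynamic range L must be positive")
    c1, c2 = ssim_constants(L)
    mu_g, mu_h = g.mean(), ghat.mean()
    var_g, var_h = g.var(), ghat.var()
    cov = ((g - mu_g) * (ghat - mu_h)).mean()
    return float(((2 * mu_g * mu_h + c1) * (2 * cov + c2))
                 / ((mu_g ** 2 + mu_h ** 2 + c1) * (var_g + var_h + c2)))


def reconstruction_report(ref, gen, stacked_rgb_pan: np.ndarray | None = None,
                          peak: float = 1.0, sam_mode: str = "per_pixel_mean"
                          ) -> ReconstructionReport:
    """Full metric suite for a generated cube against its reference.

    SSIM is computed between the generated cube's panchromatic image and
    ``stacked_rgb_pan`` when given (the guidance image's panchromatic),
    else against the reference cube's panchromatic image.
    """
    psnr_mean, psnr_band = psnr_hsi(ref, gen, peak)
    mae_mean, mae_band = mae_hsi(ref, gen)
    angle = sam(ref, gen, sam_mode)
    gen_pan = _cube_values(gen).mean(axis=2)
    other = (stacked_rgb_pan if stacked_rgb_pan is not None
             else _cube_values(ref).mean(axis=2))
    s = ssim_global(other, gen_pan, L=peak)
    return ReconstructionReport(psnr_mean, mae_mean, angle, s,
                                psnr_band, mae_band)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------

def classification_metrics(counts: ConfusionCounts
                           ) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); NaN where undefined."""
    total = counts.tp + counts.tn + counts.fp + counts.fn
    acc = (counts.tp + counts.tn) / total if total else UNDEFINED
    pos = counts.tp + counts.fn
    sens = counts.tp / pos if pos else UNDEFINED
    neg = counts.tn + counts.fp
    spec = counts.tn / neg if neg else UNDEFINED
    return acc, sens, spec


def roc_auc(scores_labels) -> float:
    """Area under the ROC curve via rank averaging (Mann–Whitney U).

    ``scores_labels`` is an iterable of (score, label) with label in
    {0, 1}; ties in score receive average ranks, making the result equal
    to the trapezoidal area under the threshold-swept ROC curve.
    """
    pairs = list(scores_labels)
    scores = np.asarray([p[0] for p in pairs], dtype=np.float64)
    labels = np.asarray([p[1] for p in pairs])
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC requires both classes present")
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores), dtype=np.float64)
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
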