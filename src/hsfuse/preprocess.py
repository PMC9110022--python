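"""Registration, patch extraction, tissue filtering, box downsampling.

The preprocessing chain mirrors a transmittance-mode microscopy workflow:
the high-resolution RGB scan is registered onto the hyperspectral frame's
panchromatic (band-average) image with ORB features and a robust affine
fit, both modalities are cropped into overlapping square patches on a
sliding-window grid, near-blank patches are dropped, and low-resolution
hyperspectral patches are produced with an exact block-average (box)
kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform as _SkAffine
from skimage.transform import warp

from .cube_io import HyperspectralCube, RgbImage

logger = logging.getLogger("hsfuse")

#: Rec. 709 luma weights used for the RGB tissue test
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class AffineTransform:
    """2x3 affine mapping moving-image (row, col) to fixed-image (row, col)."""

    matrix: np.ndarray
    n_inliers: int
    mean_residual: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (2, 3) or not np.all(np.isfinite(self.matrix)):
            raise ValueError("affine matrix must be a finite 2x3 array")


@dataclass
class PatchGridSpec:
    """Sliding-window grid: 200-px window at 100-px step by default."""

    window: int = 200
    step: int = 100
    min_tissue_frac: float = 0.5
    tissue_threshold: float = 0.9

    def __post_init__(self):
        if not 0 < self.step <= self.window:
            raise ValueError("require 0 < step <= window")
        if not 0.0 <= self.min_tissue_frac <= 1.0:
            raise ValueError("min_tissue_frac must be in [0, 1]")
        if not 0.0 < self.tissue_threshold < 1.0:
            raise ValueError("tissue threshold must be in (0, 1)")


def stage_overlap_px(fov_um: float = 1113.0, fov_px: int = 2000,
                     step_um: float = 1000.0) -> int:
    """Pixel overlap between adjacent stage tiles.

    A motorized stage advancing ``step_um`` under a field of view of
    ``fov_um`` (imaged at ``fov_px`` pixels) leaves adjacent frames
    overlapping by ``fov_px - round(step_um * fov_px / fov_um)`` pixels
    (203 px for the 1113-um / 2000-px / 1-mm production geometry).
    """
    return fov_px - round(step_um * fov_px / fov_um)


# ---------------------------------------------------------------------------
# panchromatic synthesis
# ---------------------------------------------------------------------------

def panchromatic(cube: HyperspectralCube) -> np.ndarray:
    """Band-average grayscale image of a cube (same spatial shape)."""
    return cube.values.mean(axis=2)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class RegistrationError(RuntimeError):
    pass


def _to_gray(img: np.ndarray | RgbImage) -> np.ndarray:
    if isinstance(img, RgbImage):
        return img.values @ _LUMA
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        return arr @ _LUMA
    return arr


def register_rgb_to_hsi(moving: RgbImage, fixed: np.ndarray,
                        n_keypoints: int = 5000,
                        ratio: float = 0.75,
                        ransac_threshold: float = 3.0,
                        min_inliers: int = 3,
                        seed: int = 0) -> tuple[RgbImage, AffineTransform]:
    """Affine-register an RGB image onto a panchromatic HSI frame.

    ORB keypoints are detected on both grayscale images, matched by
    Hamming distance with a ratio test, and an affine transform is fitted
    by RANSAC.  The moving image is warped (bilinear) onto the fixed
    image's pixel grid.

    Raises :class:`RegistrationError` when fewer than ``min_inliers``
    robust matches survive.
    """
    fixed_gray = _to_gray(fixed)
    moving_gray = _to_gray(moving)
    if min(fixed_gray.shape) < 64 or min(moving_gray.shape[:2]) < 64:
        raise ValueError("registration requires images of at least 64x64")

    def detect(img):
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(img)
        except (RuntimeError, ValueError) as e:
            raise RegistrationError(f"keypoint detection failed: {e}") from e
        return orb.keypoints, orb.descriptors

    kp_m, desc_m = detect(moving_gray)
    kp_f, desc_f = detect(fixed_gray)
    matches = match_descriptors(desc_m, desc_f, metric="hamming",
                                cross_check=True, max_ratio=ratio)
    if len(matches) < min_inliers:
        raise RegistrationError(
            f"only {len(matches)} descriptor matches; need {min_inliers}")

    # skimage transforms act on (x, y) = (col, row) coordinates
    src = kp_m[matches[:, 0]][:, ::-1]
    dst = kp_f[matches[:, 1]][:, ::-1]
    model, inliers = ransac((src, dst), _SkAffine, min_samples=3,
                            residual_threshold=ransac_threshold,
                            max_trials=2000, rng=seed)
    if model is None or inliers is None or inliers.sum() < min_inliers:
        raise RegistrationError("RANSAC failed to find enough inliers")

    resid = np.linalg.norm(model(src[inliers]) - dst[inliers], axis=1)
    warped = np.stack(
        [warp(moving.values[:, :, c], model.inverse,
              output_shape=fixed_gray.shape, order=1, mode="edge")
         for c in range(3)], axis=2)
    xform = AffineTransform(
        matrix=model.params[:2, :],
        n_inliers=int(inliers.sum()),
        mean_residual=float(resid.mean()),
        meta={"n_keypoints": n_keypoints, "ratio": ratio,
              "ransac_threshold": ransac_threshold, "n_matches": len(matches)})
    logger.info("registration: %d/%d inliers, mean residual %.3f px",
                xform.n_inliers, len(matches), xform.mean_residual)
    return RgbImage(np.clip(warped, 0, 1), dict(moving.meta)), xform


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def patch_origins(shape: tuple[int, int], window: int, step: int
                  ) -> list[tuple[int, int]]:
    """Top-left corners of all fully contained sliding windows."""
    h, w = shape[:2]
    if h < window or w < window:
        raise ValueError(f"image {h}x{w} smaller than window {window}")
    rows = range(0, h - window + 1, step)
    cols = range(0, w - window + 1, step)
    return [(r, c) for r in rows for c in cols]


def tissue_fraction(patch: HyperspectralCube | RgbImage | np.ndarray,
                    threshold: float = 0.9) -> float:
    """Fraction of pixels darker than ``threshold``.

    Stained tissue absorbs light, so tissue pixels have panchromatic
    transmittance (HSI) or luminance (RGB) below the threshold while
    blank slide is near 1.
    """
    if isinstance(patch, HyperspectralCube):
        gray = panchromatic(patch)
    else:
        gray = _to_gray(patch)
    return float((gray < threshold).mean())


def extract_patches(hsi: HyperspectralCube, rgb: RgbImage | None,
                    grid: PatchGridSpec,
                    tissue_source: str = "hsi"
                    ) -> list[dict]:
    """Crop aligned images into overlapping patches and drop near-blank ones.

    Returns a list of dicts with keys ``hsi``, ``rgb`` (None if no RGB
    given), ``origin`` and ``tissue_frac``; patches with tissue fraction
    below ``grid.min_tissue_frac`` are removed.
    """
    if rgb is not None and rgb.shape[:2] != hsi.shape[:2]:
        raise ValueError("HSI and RGB spatial shapes differ")
    if tissue_source not in {"hsi", "rgb"}:
        raise ValueError("tissue_source must be 'hsi' or 'rgb'")
    w = grid.window
    out = []
    for r, c in patch_origins(hsi.shape[:2], w, grid.step):
        sub_hsi = HyperspectralCube(hsi.values[r:r + w, c:c + w],
                                    hsi.wavelengths, dict(hsi.meta))
        sub_rgb = (RgbImage(rgb.values[r:r + w, c:c + w], dict(rgb.meta))
                   if rgb is not None else None)
        probe = sub_hsi if (tissue_source == "hsi" or sub_rgb is None) else sub_rgb
        frac = tissue_fraction(probe, grid.tissue_threshold)
        if frac >= grid.min_tissue_frac:
            out.append({"hsi": sub_hsi, "rgb": sub_rgb,
                        "origin": (r, c), "tissue_frac": frac})
    return out


# ---------------------------------------------------------------------------
# box downsampling
# ---------------------------------------------------------------------------

def box_downsample(cube: HyperspectralCube | np.ndarray, scale: int,
                   allow_crop: bool = False):
    """Block-average downsampling by an integer factor, per band.

    Spatial dims must be divisible by ``scale`` unless ``allow_crop`` is
    set, in which case the image is cropped to the largest divisible size
    first.  ``scale == 1`` is the identity.
    """
    is_cube = isinstance(cube, HyperspectralCube)
    values = cube.values if is_cube else np.asarray(cube, dtype=np.float64)
    if scale < 1:
        raise ValueError("scale must be >= 1")
    h, w = values.shape[:2]
    if (h % scale or w % scale):
        if not allow_crop:
            raise ValueError(
                f"spatial dims {h}x{w} not divisible by scale {scale}")
        values = values[:h - h % scale or None, :w - w % scale or None]
        h, w = values.shape[:2]
    squeeze = values.ndim == 2
    if squeeze:
        values = values[:, :, None]
    small = values.reshape(h // scale, scale, w // scale, scale, -1).mean(axis=(1, 3))
    if squeeze:
        small = small[:, :, 0]
    if is_cube:
        meta = dict(cube.meta)
        meta["downsample_scale"] = scale * meta.get("downsample_scale", 1)
        return HyperspectralCube(small, cube.wavelengths.copy(), meta)
    return small
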