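"""Synthetic stained-tissue phantoms for training and evaluation.

A phantom emulates a transmittance-mode H&E histology patch imaged by two
instruments at once: a sharp color camera (HR-RGB) and a noisy, blurred
hyperspectral camera (degraded HR-HSI, then box-downsampled to LR-HSI).
Absorption follows Beer–Lambert: transmittance = exp(−Σ_k c_k·ε_k(λ))
with Gaussian absorptivity curves ε_k for a hematoxylin-like (nuclear)
and an eosin-like (cytoplasmic) chromophore.  Ellipse nuclei sit on a
smooth cytoplasm concentration field; a fraction of the patch is blank
slide (all concentrations zero, transmittance exactly 1).

Degradation applies band-independent Gaussian defocus blur plus
heteroscedastic per-band noise, inflated at the spectral extremes where a
real sensor's sensitivity drops.  The RGB image is rendered from the
*clean* cube so that, as in the real instrument pairing, the color image
carries high-frequency spatial detail the hyperspectral cube lacks.

These phantoms idealize real slides: Gaussian absorptivities instead of
measured stain spectra, no scattering or autofluorescence, and spatially
uncorrelated noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .cube_io import HyperspectralCube, PatchPair, RgbImage, default_wavelengths
from .preprocess import box_downsample


@dataclass(frozen=True)
class Chromophore:
    """Gaussian absorptivity curve: amplitude · exp(−(λ−center)²/(2·width²))."""
    center_nm: float
    width_nm: float
    amplitude: float

    def absorptivity(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((wavelengths - self.center_nm) / self.width_nm) ** 2)


#: hematoxylin-like (nuclear) and eosin-like (cytoplasmic) idealizations
DEFAULT_CHROMOPHORES = (
    Chromophore(center_nm=600.0, width_nm=70.0, amplitude=1.2),
    Chromophore(center_nm=525.0, width_nm=45.0, amplitude=0.8),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic patch family."""

    size: int = 64                       # patch side, pixels
    n_bands: int = 16
    wl_range: tuple[float, float] = (470.0, 720.0)
    chromophores: tuple[Chromophore, ...] = DEFAULT_CHROMOPHORES
    scale: int = 4                       # LR = HR / scale
    nucleus_density: float = 0.01        # nuclei per pixel^2
    nucleus_axes: tuple[float, float] = (2.0, 5.0)   # ellipse semi-axes, px
    nucleus_concentration: float = 1.0
    cytoplasm_concentration: float = 0.5
    cytoplasm_smoothness: float = 6.0    # Gaussian sigma of the field, px
    blank_fraction: float = 0.15
    noise_sd_mid: float = 0.01           # per-band Gaussian sd, middle bands
    noise_edge_factor: float = 4.0       # inflation at first/last band
    blur_sd: float = 1.5                 # defocus blur sigma, px
    class_contrast: float = 0.3          # staining concentration shift, label 1
    lr_source: str = "degraded"          # 'degraded' or 'clean'

    def __post_init__(self):
        if self.size % self.scale:
            raise ValueError("size must be divisible by scale")
        if any(c.amplitude < 0 for c in self.chromophores):
            raise ValueError("absorptivities must be nonnegative")
        if self.noise_sd_mid < 0 or self.blur_sd < 0:
            raise ValueError("noise and blur magnitudes must be nonnegative")
        if not 0.0 <= self.blank_fraction < 1.0:
            raise ValueError("blank_fraction must be in [0, 1)")
        if self.lr_source not in {"degraded", "clean"}:
            raise ValueError("lr_source must be 'degraded' or 'clean'")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.n_bands, self.wl_range)

    def noise_profile(self) -> np.ndarray:
        """Per-band noise sd with inflated spectral extremes."""
        sd = np.full(self.n_bands, self.noise_sd_mid)
        if self.n_bands >= 2:
            sd[0] *= self.noise_edge_factor
            sd[-1] *= self.noise_edge_factor
        return sd


@dataclass
class PhantomSample:
    clean: HyperspectralCube
    degraded: HyperspectralCube
    hr_rgb: RgbImage
    lr_hsi: HyperspectralCube
    label: int
    concentrations: np.ndarray            # (H, W, K)

    def as_pair(self, origin=(0, 0)) -> PatchPair:
        """Training/eval unit: degraded ground truth stays out of the pair."""
        return PatchPair(hr_hsi=self.clean, hr_rgb=self.hr_rgb,
                         lr_hsi=self.lr_hsi, label=self.label, origin=origin)


# ---------------------------------------------------------------------------
# RGB rendering
# ---------------------------------------------------------------------------

def default_responses(wavelengths: np.ndarray,
                      centers=(610.0, 540.0, 480.0),
                      sd: float = 30.0) -> np.ndarray:
    """(3, B) Gaussian camera response curves, renormalized on the grid."""
    resp = np.stack([np.exp(-0.5 * ((wavelengths - c) / sd) ** 2)
                     for c in centers])
    return resp / resp.sum(axis=1, keepdims=True)


def rgb_from_cube(cube: HyperspectralCube,
                  responses: np.ndarray | None = None) -> RgbImage:
    """Response-weighted band averages -> (R, G, B) channels.

    Each response curve must be nonnegative and sum to 1 on the cube's
    band grid, so a spectrally flat cube of value c maps to (c, c, c).
    """
    if responses is None:
        responses = default_responses(cube.wavelengths)
    responses = np.asarray(responses, dtype=np.float64)
    if responses.shape != (3, cube.n_bands):
        raise ValueError("responses must be (3, B)")
    if (responses < 0).any():
        raise ValueError("responses must be nonnegative")
    if not np.allclose(responses.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each response must sum to 1")
    rgb = np.einsum("hwb,cb->hwc", cube.values, responses)
    return RgbImage(np.clip(rgb, 0.0, 1.0), {"rendered_from": "cube"})


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _concentration_maps(spec: PhantomSpec, label: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(H, W, K) concentration maps: nuclei, cytoplasm, then extras at 0."""
    w = spec.size
    k = len(spec.chromophores)
    c = np.zeros((w, w, k))

    # cytoplasm: smooth positive random field around the nominal level
    fld = gaussian_filter(rng.standard_normal((w, w)),
                          spec.cytoplasm_smoothness, mode="reflect")
    sd = fld.std()
    if sd > 0:
        fld = fld / sd
    cyto = np.clip(spec.cytoplasm_concentration * (1.0 + 0.5 * fld), 0.0, None)
    if k > 1:
        c[:, :, 1] = cyto

    # nuclei: hard ellipses, lightly smoothed
    n_nuclei = rng.poisson(spec.nucleus_density * w * w)
    nuc = np.zeros((w, w))
    yy, xx = np.mgrid[0:w, 0:w]
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, w, size=2)
        a, b = rng.uniform(*spec.nucleus_axes, size=2)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        nuc[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = 1.0
    nuc = gaussian_filter(nuc, 0.5, mode="reflect")
    c[:, :, 0] = spec.nucleus_concentration * nuc

    # class contrast: label-1 tissue is more heavily stained overall
    c *= 1.0 + spec.class_contrast * label

    # blank slide region: quantile of a smooth field -> all concentrations 0
    if spec.blank_fraction > 0:
        mask_fld = gaussian_filter(rng.standard_normal((w, w)),
                                   max(spec.cytoplasm_smoothness, 1.0),
                                   mode="reflect")
        thresh = np.quantile(mask_fld, spec.blank_fraction)
        c[mask_fld <= thresh] = 0.0
    return c


def generate_phantom(spec: PhantomSpec, seed: int | np.random.SeedSequence,
                     label: int = 0) -> PhantomSample:
    """Draw one phantom sample; bit-deterministic in (spec, seed, label)."""
    rng = np.random.default_rng(seed)
    wl = spec.wavelengths
    conc = _concentration_maps(spec, label, rng)
    eps = np.stack([ch.absorptivity(wl) for ch in spec.chromophores])  # (K, B)
    absorbance = np.einsum("hwk,kb->hwb", conc, eps)
    clean = np.exp(-absorbance)

    blurred = (gaussian_filter(clean, (spec.blur_sd, spec.blur_sd, 0),
                               mode="reflect")
               if spec.blur_sd > 0 else clean.copy())
    noise = rng.standard_normal(clean.shape) * spec.noise_profile()
    degraded = np.clip(blurred + noise, 0.0, 1.2)

    clean_cube = HyperspectralCube(clean, wl, {"phantom": True, "kind": "clean"})
    degraded_cube = HyperspectralCube(degraded, wl,
                                      {"phantom": True, "kind": "degraded"})
    rgb = rgb_from_cube(clean_cube)
    source = degraded_cube if spec.lr_source == "degraded" else clean_cube
    lr = box_downsample(source, spec.scale)
    return PhantomSample(clean_cube, degraded_cube, rgb, lr, label, conc)


def make_dataset(spec: PhantomSpec, n_train: int, n_val: int, n_test: int,
                 seed: int = 0) -> dict:
    """Disjoint, balanced train/val/test phantom splits.

    Labels alternate 0/1 within each split; every sample gets its own
    child seed spawned from ``seed``, so splits are disjoint by
    construction.  Returns ``{"train": [...], "val": [...], "test": [...],
    "manifest": {...}}``.
    """
    if min(n_train, n_val, n_test) < 0 or n_train == 0:
        raise ValueError("need a nonempty training split")
    root = np.random.SeedSequence(seed)
    splits = {}
    children = iter(root.spawn(n_train + n_val + n_test))
    for name, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        splits[name] = [generate_phantom(spec, next(children), label=i % 2)
                        for i in range(n)]
    splits["manifest"] = {
        "seed": seed, "n_train": n_train, "n_val": n_val, "n_test": n_test,
        "spec": {f: getattr(spec, f) for f in
                 ("size", "n_bands", "scale", "blank_fraction",
                  "noise_sd_mid", "noise_edge_factor", "blur_sd",
                  "class_contrast")}}
    return splits


def separable_spec(spec: PhantomSpec | None = None,
                   contrast: float = 2.0) -> PhantomSpec:
    """A spec variant whose two classes differ strongly in mean spectrum."""
    base = spec or PhantomSpec()
    return replace(base, class_contrast=contrast)
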