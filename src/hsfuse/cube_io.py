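"""Hyperspectral cube data model, radiometric calibration, and I/O.

A cube is an (H, W, B) transmittance array with an ascending wavelength
grid in nanometres.  The default production grid is 87 bands spanning
470–720 nm, but every operation is band-count agnostic so that small test
cubes work identically.

Supported on-disk dialects: ENVI header + raw binary (BSQ/BIL/BIP read,
BSQ write), multi-page TIFF band stacks (wavelengths in the image
description), and HDF5 with datasets ``/values``, ``/wavelengths`` and a
JSON-encoded ``/meta``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

logger = logging.getLogger("hsfuse")

#: production band count and wavelength span of the microscope system
DEFAULT_BANDS = 87
DEFAULT_WL_RANGE = (470.0, 720.0)
#: transmittance values above this are treated as super-unity noise and clamped
DEFAULT_CLAMP_MAX = 1.2


def default_wavelengths(n_bands: int = DEFAULT_BANDS,
                        wl_range: tuple[float, float] = DEFAULT_WL_RANGE) -> np.ndarray:
    """Uniform ascending wavelength grid (nm)."""
    return np.linspace(wl_range[0], wl_range[1], n_bands)


@dataclass
class HyperspectralCube:
    """(H, W, B) transmittance cube with its wavelength grid.

    Axis convention is (row, col, band), 0-based, band axis last,
    wavelengths strictly ascending.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("cube values must be (H, W, B)")
        if self.values.shape[2] != self.wavelengths.shape[0]:
            raise ValueError(
                f"band axis {self.values.shape[2]} != wavelength grid "
                f"length {self.wavelengths.shape[0]}")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class RgbImage:
    """(H, W, 3) color image with values in [0, 1], channel order (R, G, B)."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("RGB image must be (H, W, 3)")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("RGB values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class PatchPair:
    """Aligned training/evaluation unit: HR-HSI, HR-RGB, LR-HSI, label, origin."""

    hr_hsi: HyperspectralCube
    hr_rgb: RgbImage
    lr_hsi: HyperspectralCube
    label: int
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self):
        w = self.hr_hsi.shape[0]
        if self.hr_hsi.shape[:2] != (w, w) or self.hr_rgb.shape[:2] != (w, w):
            raise ValueError("HR members must share a square spatial size")
        lw = self.lr_hsi.shape[0]
        if w % lw != 0:
            raise ValueError("HR size must be divisible by LR size")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def scale(self) -> int:
        return self.hr_hsi.shape[0] // self.lr_hsi.shape[0]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def calibrate_transmittance(raw: HyperspectralCube,
                            white: HyperspectralCube,
                            dark: HyperspectralCube,
                            eps: float = 1e-6,
                            clamp_max: float = DEFAULT_CLAMP_MAX
                            ) -> HyperspectralCube:
    """Flat-field calibration to transmittance.

    T(λ) = (I_raw(λ) − I_dark(λ)) / (I_white(λ) − I_dark(λ)), elementwise.
    Pixels where the denominator falls below ``eps`` are masked to zero and
    counted in ``meta['n_masked']``.  Output clamped to [0, clamp_max].
    """
    if raw.shape != white.shape or raw.shape != dark.shape:
        raise ValueError("raw, white, dark cubes must share a shape")
    denom = white.values - dark.values
    bad = denom < eps
    numer = raw.values - dark.values
    trans = np.where(bad, 0.0, numer / np.where(bad, 1.0, denom))
    trans = np.clip(trans, 0.0, clamp_max)
    n_masked = int(bad.sum())
    if n_masked:
        logger.warning("calibration masked %d pixels with white-dark < eps",
                       n_masked)
    meta = dict(raw.meta)
    meta.update(calibrated=True, eps=eps, clamp_max=clamp_max,
                n_masked=n_masked)
    return HyperspectralCube(trans, raw.wavelengths.copy(), meta)


# ---------------------------------------------------------------------------
# I/O — HDF5
# ---------------------------------------------------------------------------

def write_cube_hdf5(cube: HyperspectralCube, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=cube.values)
        f.create_dataset("wavelengths", data=cube.wavelengths)
        f.create_dataset("meta", data=json.dumps(cube.meta, default=str))
    return path

def read_cube_hdf5(path: str | Path) -> HyperspectralCube:
    with h5py.File(path, "r") as f:
        values = f["values"][()]
        if "wavelengths" not in f:
            raise ValueError(f"{path}: missing /wavelengths dataset")
        wl = f["wavelengths"][()]
        meta = json.loads(f["meta"][()]) if "meta" in f else {}
    return HyperspectralCube(values, wl, meta)


# ---------------------------------------------------------------------------
# I/O — multi-page TIFF (one page per band)
# ---------------------------------------------------------------------------

def write_cube_tiff(cube: HyperspectralCube, path: str | Path) -> Path:
    path = Path(path)
    desc = json.dumps({"wavelengths": cube.wavelengths.tolist(),
                       "meta": cube.meta}, default=str)
    pages = np.moveaxis(cube.values.astype(np.float32), 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack", description=desc)
    return path

def read_cube_tiff(path: str | Path,
                   wavelengths: np.ndarray | None = None) -> HyperspectralCube:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    if pages.ndim == 2:
        pages = pages[None]
    values = np.moveaxis(pages, 0, 2)
    meta: dict = {}
    if wavelengths is None:
        try:
            info = json.loads(desc)
            wavelengths = np.asarray(info["wavelengths"])
            meta = info.get("meta", {})
        except (json.JSONDecodeError, KeyError, TypeError):
            raise ValueError(
                f"{path}: no wavelength metadata; pass an explicit grid")
    return HyperspectralCube(values, wavelengths, meta)


# ---------------------------------------------------------------------------
# I/O — ENVI header + raw binary
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_brace = None, [], False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.lower() == "envi":
            continue
        if not in_brace:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip().lower(), val.strip()
            if val.startswith("{") and not val.endswith("}"):
                in_brace, buf = True, [val.lstrip("{")]
            else:
                fields[key] = val.strip("{} ")
        else:
            if val_end := line.endswith("}"):
                buf.append(line.rstrip("}"))
            else:
                buf.append(line)
            if val_end:
                fields[key] = " ".join(buf)
                in_brace = False
    return fields


def write_cube_envi(cube: HyperspectralCube, path: str | Path) -> Path:
    """Write BSQ-interleaved ENVI (.hdr + .dat)."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    dat = path.with_suffix(".dat")
    values = cube.values.astype(np.float64)
    h, w, b = values.shape
    wl = ", ".join(f"{x:.6g}" for x in cube.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        f"data type = {_ENVI_CODES[values.dtype]}\n"
        "interleave = bsq\nbyte order = 0\n"
        f"wavelength units = nm\nwavelength = {{ {wl} }}\n")
    np.moveaxis(values, 2, 0).tofile(dat)
    return hdr


def read_cube_envi(path: str | Path,
                   wavelengths: np.ndarray | None = None) -> HyperspectralCube:
    """Read an ENVI cube (.hdr path or basename); BSQ/BIL/BIP interleaves."""
    path = Path(path)
    hdr = path if path.suffix == ".hdr" else path.with_suffix(".hdr")
    fields = _parse_envi_header(hdr.read_text())
    h = int(fields["lines"])
    w = int(fields["samples"])
    b = int(fields["bands"])
    dtype = _ENVI_DTYPES[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    dat = hdr.with_suffix(".dat")
    if not dat.exists():
        for ext in (".img", ".bin", ""):
            cand = hdr.with_suffix(ext)
            if cand.exists() and cand != hdr:
                dat = cand
                break
    arr = np.fromfile(dat, dtype=dtype,
                      offset=int(fields.get("header offset", 0)))
    if arr.size != h * w * b:
        raise ValueError(f"{dat}: expected {h * w * b} values, got {arr.size}")
    if interleave == "bsq":
        values = np.moveaxis(arr.reshape(b, h, w), 0, 2)
    elif interleave == "bil":
        values = np.moveaxis(arr.reshape(h, b, w), 1, 2)
    elif interleave == "bip":
        values = arr.reshape(h, w, b)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    if wavelengths is None:
        if "wavelength" not in fields:
            raise ValueError(f"{hdr}: no wavelength field; pass an explicit grid")
        wavelengths = np.asarray(
            [float(x) for x in fields["wavelength"].split(",") if x.strip()])
    return HyperspectralCube(values.astype(np.float64), wavelengths,
                             {"source": str(hdr)})


# ---------------------------------------------------------------------------
# format dispatch
# ---------------------------------------------------------------------------

_FORMATS = {"hdf5", "tiff", "envi"}


def _infer_format(path: Path) -> str:
    s = path.suffix.lower()
    if s in {".h5", ".hdf5"}:
        return "hdf5"
    if s in {".tif", ".tiff"}:
        return "tiff"
    if s in {".hdr", ".dat", ".img"}:
        return "envi"
    raise ValueError(f"cannot infer cube format from {path.name!r}")


def read_cube(path: str | Path, format: str | None = None,
              wavelengths: np.ndarray | None = None) -> HyperspectralCube:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return read_cube_hdf5(path)
    if fmt == "tiff":
        return read_cube_tiff(path, wavelengths)
    if fmt == "envi":
        return read_cube_envi(path, wavelengths)
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_cube(cube: HyperspectralCube, path: str | Path,
               format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return write_cube_hdf5(cube, path)
    if fmt == "tiff":
        return write_cube_tiff(cube, path)
    if fmt == "envi":
        return write_cube_envi(cube, path)
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


# ---------------------------------------------------------------------------
# patch-set persistence (HDF5 groups)
# ---------------------------------------------------------------------------

def write_patch_set(pairs: list[PatchPair], path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, p in enumerate(pairs):
            g = f.create_group(f"patch_{i:05d}")
            g.create_dataset("hr_hsi", data=p.hr_hsi.values)
            g.create_dataset("hr_rgb", data=p.hr_rgb.values)
            g.create_dataset("lr_hsi", data=p.lr_hsi.values)
            g.create_dataset("wavelengths", data=p.hr_hsi.wavelengths)
            g.attrs["label"] = p.label
            g.attrs["origin"] = p.origin
    return path


def read_patch_set(path: str | Path) -> list[PatchPair]:
    pairs = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            wl = g["wavelengths"][()]
            pairs.append(PatchPair(
                hr_hsi=HyperspectralCube(g["hr_hsi"][()], wl),
                hr_rgb=RgbImage(g["hr_rgb"][()]),
                lr_hsi=HyperspectralCube(g["lr_hsi"][()], wl),
                label=int(g.attrs["label"]),
                origin=tuple(int(x) for x in g.attrs["origin"])))
    return pairs
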