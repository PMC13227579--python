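"""Classical vascular-structure extraction used as the self-supervision label.

The pipeline turns an FI or FFA image into a binary vessel map with no
learned components: green channel -> (FFA only: intensity inversion) ->
field-of-view mask -> 5x5 Gaussian smoothing -> global + adaptive histogram
equalization -> homomorphic illumination equalization -> gamma correction
(1.5) -> oriented line-filter response (length 10, width 1) -> masking ->
grayscale stretch -> Otsu binarization. Both modalities are normalized to
the dark-vessel convention before the shared pipeline, so the FFA variant
differs only by the extra inversion step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure
from skimage import transform as sktransform

from .image_io import RasterImage

__all__ = [
    "StructureMap",
    "ExtractionParams",
    "fov_mask",
    "green_channel",
    "equalize_contrast",
    "homomorphic_filter",
    "gamma_correct",
    "line_response",
    "grayscale_stretch",
    "otsu_binarize",
    "extract_structure",
]


@dataclass
class StructureMap:
    """Binary H x W vessel-structure raster plus its source modality."""

    pixels: np.ndarray  # uint8 {0,1}
    source_modality: str = "unknown"

    def __post_init__(self):
        px = np.asarray(self.pixels)
        vals = np.unique(px)
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("StructureMap pixels must be binary {0,1}")
        self.pixels = px.astype(np.uint8)


@dataclass
class ExtractionParams:
    """Tunables of the extraction pipeline (defaults follow the method)."""

    gaussian_kernel: int = 5
    gaussian_sigma: float = 1.1
    clahe_tiles: int = 10
    gamma: float = 1.5
    line_length: int = 10
    line_width: int = 1
    n_orientations: int = 12
    homo_gamma_high: float = 1.5
    homo_gamma_low: float = 0.5
    homo_cutoff: float = 30.0
    fov_threshold: float = 0.05
    fov_erosion: int = 3

    def __post_init__(self):
        if self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if not (self.line_length >= self.line_width >= 1):
            raise ValueError("need line_length >= line_width >= 1")


def green_channel(img: RasterImage | np.ndarray) -> np.ndarray:
    """Return the green channel (RGB index 1) as an H x W float raster."""
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=np.float32)
    if px.ndim == 2:
        warnings.warn("green_channel: single-channel input returned unchanged")
        return px.astype(np.float32)
    if px.shape[2] == 1:
        warnings.warn("green_channel: single-channel input returned unchanged")
        return px[:, :, 0].astype(np.float32)
    return px[:, :, 1].astype(np.float32)


def fov_mask(img: RasterImage | np.ndarray, threshold: float = 0.05, erosion: int = 3) -> np.ndarray:
    """Binary mask of the circular imaged field.

    Pixels brighter than ``threshold`` (max over channels) are candidate
    field pixels; only the largest connected component is kept, holes are
    filled, and the rim is lightly eroded to suppress border artifacts.
    """
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=np.float32)
    inten = px.max(axis=2) if px.ndim == 3 else px
    cand = inten > threshold
    if not cand.any():
        warnings.warn("fov_mask: image is entirely dark; empty mask returned")
        return np.zeros(inten.shape, dtype=bool)
    lab = measure.label(cand)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    mask = lab == counts.argmax()
    mask = ndimage.binary_fill_holes(mask)
    if erosion > 0:
        # border_value=1 so a frame-filling field is not eaten from the array edge
        mask = ndimage.binary_erosion(mask, iterations=erosion, border_value=1)
    return mask


def equalize_contrast(gray: np.ndarray, clahe_tiles: int = 10, apply_clahe: bool = True) -> np.ndarray:
    """Global histogram equalization followed by CLAHE on a tile grid."""
    gray = np.asarray(gray, dtype=np.float32)
    if float(gray.max() - gray.min()) < 1e-8:
        warnings.warn("equalize_contrast: constant image, equalization is a no-op")
        return gray.copy()
    out = exposure.equalize_hist(gray).astype(np.float32)
    if apply_clahe:
        h, w = gray.shape
        kernel = (max(1, h // clahe_tiles), max(1, w // clahe_tiles))
        out = exposure.equalize_adapthist(np.clip(out, 0, 1), kernel_size=kernel).astype(np.float32)
    return np.clip(out, 0.0, 1.0)


def homomorphic_filter(
    gray: np.ndarray,
    gamma_high: float = 1.5,
    gamma_low: float = 0.5,
    cutoff: float = 30.0,
    eps: float = 1e-4,
) -> np.ndarray:
    """Log-domain Gaussian high-emphasis filtering to equalize illumination.

    Transfer function H(u, v) = g_low + (g_high - g_low) *
    (1 - exp(-D^2 / (2 c^2))) applied to the FFT of log(image + eps):
    low frequencies (slow illumination) are attenuated toward ``g_low``
    while reflectance detail is boosted toward ``g_high``. Output is
    min-max rescaled to [0, 1].
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    logim = np.log(gray + eps)
    F = np.fft.fft2(logim)
    u = np.fft.fftfreq(h) * h
    v = np.fft.fftfreq(w) * w
    D2 = u[:, None] ** 2 + v[None, :] ** 2
    H = gamma_low + (gamma_high - gamma_low) * (1.0 - np.exp(-D2 / (2.0 * cutoff**2)))
    out = np.real(np.fft.ifft2(F * H))
    out = np.exp(out) - eps
    return grayscale_stretch(out)


def gamma_correct(gray: np.ndarray, gamma: float = 1.5) -> np.ndarray:
    """Elementwise power-law correction ``out = in ** gamma`` on [0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.power(np.clip(np.asarray(gray, dtype=np.float32), 0.0, 1.0), gamma)


def _line_kernels(length: int, width: int, n_orient: int) -> list[np.ndarray]:
    size = length if length % 2 == 1 else length + 1
    base = np.zeros((size, size), dtype=np.float64)
    r0 = size // 2 - width // 2
    base[r0 : r0 + width, (size - length) // 2 : (size - length) // 2 + length] = 1.0
    kernels = []
    for k in range(n_orient):
        ang = 180.0 * k / n_orient
        rot = sktransform.rotate(base, ang, order=1, preserve_range=True)
        rot = np.clip(rot, 0.0, None)
        kernels.append(rot / rot.sum())
    return kernels


def line_response(
    gray: np.ndarray,
    length: int = 10,
    width: int = 1,
    n_orient: int = 12,
    return_orientation: bool = False,
):
    """Oriented line-detector response for locally dark elongated structures.

    At each pixel the response is the maximum over ``n_orient`` orientations
    of (mean intensity along a length x width line window) minus (mean
    intensity over the surrounding length x length square), both evaluated
    on the negated image so that dark vessels yield positive responses.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if min(gray.shape) <= length:
        raise ValueError("image must be larger than the line kernel")
    v = -gray  # dark structures become bright
    size = length if length % 2 == 1 else length + 1
    neigh = ndimage.uniform_filter(v, size=size, mode="nearest")
    best = np.full(gray.shape, -np.inf)
    best_k = np.zeros(gray.shape, dtype=np.int32)
    for k, ker in enumerate(_line_kernels(length, width, n_orient)):
        resp = ndimage.correlate(v, ker, mode="nearest") - neigh
        upd = resp > best
        best_k[upd] = k
        best = np.maximum(best, resp)
    if return_orientation:
        angles = 180.0 * best_k / n_orient
        return best, angles
    return best


def grayscale_stretch(gray: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to [0, 1]; constant input maps to zeros."""
    gray = np.asarray(gray, dtype=np.float64)
    lo, hi = float(gray.min()), float(gray.max())
    if hi - lo < 1e-12:
        warnings.warn("grayscale_stretch: constant image mapped to zeros")
        return np.zeros_like(gray, dtype=np.float32)
    return ((gray - lo) / (hi - lo)).astype(np.float32)


def otsu_binarize(gray: np.ndarray, mask: np.ndarray | None = None, nbins: int = 256):
    """Otsu threshold over a 256-bin histogram; returns (threshold, binary).

    The threshold maximizes the between-class variance w0*w1*(mu0-mu1)^2;
    binarization is ``gray > threshold``. With ``mask`` given, the histogram
    uses masked pixels only and the output is zero outside the mask.
    Constant input returns an all-zero map with threshold = nan.
    """
    gray = np.asarray(gray, dtype=np.float64)
    sel = gray[mask] if mask is not None else gray.ravel()
    if sel.size == 0 or float(sel.max() - sel.min()) < 1e-12:
        warnings.warn("otsu_binarize: degenerate input, all-zero output")
        return float("nan"), np.zeros(gray.shape, dtype=np.uint8)
    lo, hi = float(sel.min()), float(sel.max())
    hist, edges = np.histogram(sel, bins=nbins, range=(lo, hi))
    p = hist.astype(np.float64) / hist.sum()
    w0 = np.cumsum(p)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sigma_b[~np.isfinite(sigma_b)] = 0.0
    k = int(np.argmax(sigma_b))  # first maximum on ties
    thr = float(edges[k + 1])
    binary = (gray > thr).astype(np.uint8)
    if mask is not None:
        binary[~mask] = 0
    return thr, binary


def extract_structure(
    img: RasterImage,
    modality: str | None = None,
    params: ExtractionParams | None = None,
    mask: np.ndarray | None = None,
) -> StructureMap:
    """Run the full extraction pipeline on an FI or FFA image.

    For FFA the grayscale is inverted right after green-channel extraction
    so both modalities present dark vessels to the shared pipeline.
    ``mask`` overrides the field-of-view detection with a precomputed mask
    (the FOV detector assumes a dark border, so callers feeding pre-inverted
    images should supply the mask of the original). Degenerate inputs
    (constant image, empty field mask) produce an all-zero map with a
    warning rather than an exception.
    """
    params = params or ExtractionParams()
    modality = (modality or img.modality or "FI").upper()
    g = green_channel(img)
    if modality == "FFA":
        g = 1.0 - g
    if mask is None:
        mask = fov_mask(img, threshold=params.fov_threshold, erosion=params.fov_erosion)
    else:
        mask = np.asarray(mask, dtype=bool)
    if not mask.any() or float(g.max() - g.min()) < 1e-8:
        warnings.warn("extract_structure: degenerate input, all-zero structure")
        return StructureMap(np.zeros(g.shape, dtype=np.uint8), source_modality=modality)

    k = _gaussian_kernel2d(params.gaussian_kernel, params.gaussian_sigma)
    g = ndimage.correlate(g.astype(np.float64), k, mode="nearest")
    g = equalize_contrast(g, clahe_tiles=params.clahe_tiles)
    g = homomorphic_filter(g, params.homo_gamma_high, params.homo_gamma_low, params.homo_cutoff)
    g = gamma_correct(g, params.gamma)
    resp = line_response(g, params.line_length, params.line_width, params.n_orientations)
    resp = np.maximum(resp, 0.0)
    resp[~mask] = 0.0
    stretched = grayscale_stretch(resp)
    _, binary = otsu_binarize(stretched, mask=mask)
    return StructureMap(binary, source_modality=modality)


def _gaussian_kernel2d(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()
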