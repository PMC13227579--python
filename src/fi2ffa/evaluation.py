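"""Distribution metrics (FID, KID), Dice overlap and structure preservation.

FID is the Fréchet distance between Gaussian fits of feature embeddings of
the real and generated sets; KID is the unbiased squared maximum mean
discrepancy with the degree-3 polynomial kernel k(a, b) = (a.b / D + 1)^3.
Both are agnostic to the embedding: the built-in ``toyconv`` extractor is a
fixed-seed random convolutional network that runs fully offline, while the
conventional Inception embedding requires externally downloaded weights and
is therefore only registered as an informative stub.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .image_io import RasterImage, resize_image
from .structure import extract_structure

__all__ = [
    "EvalFeatures",
    "frechet_distance",
    "fid",
    "kid",
    "extract_features",
    "dice",
    "structure_preservation_score",
]


@dataclass
class EvalFeatures:
    matrix: np.ndarray  # N x D
    extractor_id: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2:
            raise ValueError("feature matrix must be N x D")
        if not np.isfinite(m).all():
            raise ValueError("feature matrix must be finite")
        self.matrix = m


def _sqrtm_psd(a: np.ndarray) -> np.ndarray:
    # negative eigenvalue noise from round-off is clipped to zero
    w, v = linalg.eigh(a)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def frechet_distance(mu1: np.ndarray, cov1: np.ndarray, mu2: np.ndarray, cov2: np.ndarray,
                     sym_tol: float = 1e-6) -> float:
    """||mu1 - mu2||^2 + tr(C1 + C2 - 2 (C1 C2)^{1/2}) for Gaussian fits.

    The product square-root trace is computed via the eigendecomposition of
    the symmetrized product C1^{1/2} C2 C1^{1/2}; tiny negative eigenvalues
    from round-off are clipped and the result is floored at zero.
    """
    mu1, mu2 = np.atleast_1d(np.asarray(mu1, float)), np.atleast_1d(np.asarray(mu2, float))
    cov1, cov2 = np.atleast_2d(np.asarray(cov1, float)), np.atleast_2d(np.asarray(cov2, float))
    for c in (cov1, cov2):
        if np.abs(c - c.T).max() > sym_tol * max(1.0, np.abs(c).max()):
            raise ValueError("covariance matrix is not symmetric")
    s1 = _sqrtm_psd((cov1 + cov1.T) / 2.0)
    inner = s1 @ ((cov2 + cov2.T) / 2.0) @ s1
    w = linalg.eigvalsh((inner + inner.T) / 2.0)
    tr_sqrt = np.sqrt(np.clip(w, 0.0, None)).sum()
    d = float(((mu1 - mu2) ** 2).sum() + np.trace(cov1) + np.trace(cov2) - 2.0 * tr_sqrt)
    return max(d, 0.0)


def _fit_gaussian(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    cov = np.cov(x, rowvar=False)
    return mu, np.atleast_2d(cov)


def fid(real: EvalFeatures, fake: EvalFeatures) -> float:
    """Fréchet distance between Gaussian fits of two feature sets."""
    if real.extractor_id != fake.extractor_id:
        raise ValueError("FID requires features from the same extractor")
    if min(len(real.matrix), len(fake.matrix)) < 2:
        raise ValueError("FID needs at least 2 samples per set")
    mu1, c1 = _fit_gaussian(real.matrix)
    mu2, c2 = _fit_gaussian(fake.matrix)
    return frechet_distance(mu1, c1, mu2, c2)


def _poly_kernel(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    return (x @ y.T / d + 1.0) ** 3


def kid(real: EvalFeatures, fake: EvalFeatures, subset_size: int | None = None,
        n_subsets: int = 100, seed: int = 0) -> float:
    """Unbiased squared MMD with the degree-3 polynomial kernel.

    Default: a single unbiased estimate over the full sets — the mean of
    off-diagonal within-set kernel entries for each set minus twice the
    cross-set kernel mean; may be slightly negative (unbiased estimator).
    With ``subset_size`` set, returns the mean estimate over ``n_subsets``
    random subsets of that size (the subset-averaged protocol).
    """
    x, y = real.matrix, fake.matrix
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("KID needs at least 2 samples per set")
    if subset_size is not None:
        if subset_size < 2 or subset_size > min(m, n):
            raise ValueError("subset_size must be in [2, min(len(real), len(fake))]")
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_subsets):
            ix = rng.choice(m, size=subset_size, replace=False)
            iy = rng.choice(n, size=subset_size, replace=False)
            vals.append(kid(EvalFeatures(x[ix], real.extractor_id),
                            EvalFeatures(y[iy], fake.extractor_id)))
        return float(np.mean(vals))
    kxx = _poly_kernel(x, x)
    kyy = _poly_kernel(y, y)
    kxy = _poly_kernel(x, y)
    sum_xx = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    sum_yy = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    return float(sum_xx + sum_yy - 2.0 * kxy.mean())


# ------------------------------------------------------------- extractors

_TOYCONV_SEED = 190_441  # fixed so features are reproducible across runs
_TOYCONV_SIZE = 64


def _toyconv_weights() -> list[np.ndarray]:
    rng = np.random.default_rng(_TOYCONV_SEED)
    shapes = [(16, 3, 3, 3), (32, 16, 3, 3), (64, 32, 3, 3)]
    return [rng.normal(0.0, np.sqrt(2.0 / (s[1] * 9)), size=s).astype(np.float32) for s in shapes]


def _toyconv_forward(batch: np.ndarray) -> np.ndarray:
    from .nn.functional import _conv_fwd

    h = batch
    for w in _toyconv_weights():
        h = _conv_fwd(h, w, stride=2, padding=1)
        h = np.maximum(h, 0.0)
    mean = h.mean(axis=(2, 3))
    std = h.std(axis=(2, 3))
    return np.concatenate([mean, std], axis=1)  # N x 128


def extract_features(images, extractor: str = "toyconv") -> EvalFeatures:
    """Embed a list of images into an N x D feature matrix.

    ``toyconv``: a fixed-seed 3-layer random convolutional embedding with
    mean/std global pooling (D = 128); deterministic and fully offline.
    ``inception``: the conventional FID embedding; it needs pretrained
    weights from the network and is refused with an explanation here.
    """
    if not images:
        raise ValueError("extract_features: empty image list")
    if extractor == "inception":
        raise RuntimeError(
            "the Inception embedding requires downloaded pretrained weights; "
            "use extractor='toyconv' for a fully offline embedding"
        )
    if extractor != "toyconv":
        raise ValueError(f"unknown extractor {extractor!r}")
    batch = []
    for im in images:
        px = im.pixels if isinstance(im, RasterImage) else np.asarray(im, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.shape[2] == 1:
            px = np.repeat(px, 3, axis=2)
        px = resize_image(px, _TOYCONV_SIZE)
        batch.append(px.transpose(2, 0, 1))
    feats = _toyconv_forward(np.stack(batch).astype(np.float32))
    return EvalFeatures(feats, extractor_id="toyconv")


# ----------------------------------------------------------------- overlap

def dice(a, b) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); 1.0 when both masks are empty."""
    pa = np.asarray(getattr(a, "pixels", a))
    pb = np.asarray(getattr(b, "pixels", b))
    if pa.shape != pb.shape:
        raise ValueError("dice: shape mismatch")
    for p in (pa, pb):
        if not np.isin(np.unique(p), [0, 1]).all():
            raise ValueError("dice: masks must be binary {0,1}")
    na, nb = int(pa.sum()), int(pb.sum())
    if na + nb == 0:
        return 1.0
    inter = int((pa.astype(bool) & pb.astype(bool)).sum())
    return 2.0 * inter / (na + nb)


def structure_preservation_score(src: RasterImage, out: RasterImage,
                                 src_modality: str, out_modality: str) -> float:
    """Dice between the extracted structures of a source and its translation.

    A faithful translation keeps the vascular skeleton of its input, so the
    classical extraction of the output should overlap the extraction of the
    source; spurious or missing vessels lower the score.
    """
    if src.pixels.shape[:2] != out.pixels.shape[:2]:
        raise ValueError("structure_preservation_score: size mismatch")
    s1 = extract_structure(src, modality=src_modality)
    s2 = extract_structure(out, modality=out_modality)
    return dice(s1, s2)
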