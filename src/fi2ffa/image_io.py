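"""Image and manifest I/O, CLAHE dataset enhancement, paired augmentation.

Images are held as :class:`RasterImage`: float32 pixels in [0, 1], shape
H x W x C with C in {1, 3}, plus a modality tag (``"FI"``, ``"FFA"`` or
``"unknown"``). Files on disk are 8-bit PNG/JPEG; 16-bit PNG is accepted on
read and rescaled by 65535.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage import exposure, transform

MANIFEST_COLUMNS = ["pair_id", "fi_path", "ffa_path", "gt_structure_path", "dx", "dy", "dtheta"]


@dataclass
class RasterImage:
    """A single fundus (FI) or angiography (FFA) raster."""

    pixels: np.ndarray  # H x W x C float32 in [0, 1]
    modality: str = "unknown"  # FI | FFA | unknown
    source_path: str | None = None

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"RasterImage needs HxWxC with C in {{1,3}}, got {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("RasterImage pixels must be finite")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class PairRecord:
    """One pseudo-paired FI/FFA sample in a dataset manifest."""

    pair_id: str
    fi_path: str
    ffa_path: str
    gt_structure_path: str = ""
    misalignment: tuple[float, float, float] = (0.0, 0.0, 0.0)  # dx_px, dy_px, dtheta_deg


def read_image(path: str | Path, modality: str = "unknown") -> RasterImage:
    """Read a PNG/JPEG file into a [0, 1] float raster.

    8-bit images are divided by 255, 16-bit PNGs by 65535.
    """
    path = str(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B"):
                arr = np.asarray(im, dtype=np.float32) / 65535.0
            elif im.mode in ("L", "RGB"):
                arr = np.asarray(im, dtype=np.float32) / 255.0
            elif im.mode in ("LA", "RGBA", "P"):
                im2 = im.convert("RGB")
                arr = np.asarray(im2, dtype=np.float32) / 255.0
            else:
                arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    except (OSError, ValueError) as e:
        raise IOError(f"cannot read image {path}: {e}") from e
    return RasterImage(arr, modality=modality, source_path=path)


def write_image(img: RasterImage | np.ndarray, path: str | Path) -> None:
    """Write as 8-bit PNG/JPEG with round-half-up quantization."""
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, dtype=np.float32)
    if px.ndim == 3 and px.shape[2] == 1:
        px = px[:, :, 0]
    q = np.floor(np.clip(px, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(q).save(str(path))


def clahe_enhance(img: RasterImage, clip_limit: float = 0.01, tile: int = 8) -> RasterImage:
    """Contrast-limited adaptive histogram equalization, per channel.

    Used to derive a contrast-enhanced variant of a training dataset before
    training (not inside the training loop). Defaults follow common CLAHE
    practice: mild clip limit, 8x8 tile grid.
    """
    px = img.pixels
    if float(px.max() - px.min()) < 1e-8:
        return RasterImage(px.copy(), modality=img.modality, source_path=img.source_path)
    kernel = (max(1, px.shape[0] // tile), max(1, px.shape[1] // tile))
    out = np.empty_like(px)
    for c in range(px.shape[2]):
        ch = px[:, :, c]
        if float(ch.max() - ch.min()) < 1e-8:
            out[:, :, c] = ch
        else:
            out[:, :, c] = exposure.equalize_adapthist(ch, kernel_size=kernel, clip_limit=clip_limit)
    return RasterImage(np.clip(out, 0.0, 1.0), modality=img.modality, source_path=img.source_path)


# ---------------------------------------------------------------- manifests

def write_manifest(records: Sequence[PairRecord], path: str | Path) -> None:
    rows = [
        {
            "pair_id": r.pair_id,
            "fi_path": r.fi_path,
            "ffa_path": r.ffa_path,
            "gt_structure_path": r.gt_structure_path,
            "dx": r.misalignment[0],
            "dy": r.misalignment[1],
            "dtheta": r.misalignment[2],
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_manifest(path: str | Path, check_files: bool = True) -> list[PairRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} missing columns: {missing_cols}")
    records = []
    base = Path(path).parent
    bad: list[str] = []
    for _, row in df.iterrows():
        rec = PairRecord(
            pair_id=str(row["pair_id"]),
            fi_path=_resolve(base, row["fi_path"]),
            ffa_path=_resolve(base, row["ffa_path"]),
            gt_structure_path=_resolve(base, row["gt_structure_path"]) if row["gt_structure_path"] else "",
            misalignment=(float(row["dx"]), float(row["dy"]), float(row["dtheta"])),
        )
        if check_files and not (os.path.exists(rec.fi_path) and os.path.exists(rec.ffa_path)):
            bad.append(rec.pair_id)
        records.append(rec)
    if bad:
        raise FileNotFoundError(f"manifest {path}: missing image files for pairs {bad}")
    return records


def _resolve(base: Path, p: str) -> str:
    p = str(p)
    return p if os.path.isabs(p) else str(base / p)


# --------------------------------------------------------------- augmentation

def resize_image(px: np.ndarray, size: int, is_label: bool = False) -> np.ndarray:
    """Bilinear resize for images, nearest-neighbor for binary labels."""
    order = 0 if is_label else 1
    out = transform.resize(
        px, (size, size) + px.shape[2:], order=order,
        anti_aliasing=(not is_label) and px.shape[0] > size, preserve_range=True,
    )
    return out.astype(np.float32)


def paired_augment(
    fi: np.ndarray,
    ffa: np.ndarray,
    label_fi: np.ndarray,
    label_ffa: np.ndarray,
    load_size: int,
    crop_size: int,
    rng: np.random.Generator,
    hflip: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, dict]:
    """Shared resize -> random crop -> optional horizontal flip.

    The same crop offset and flip decision are applied to both images and
    both structure labels so pixel correspondence is preserved. Labels are
    resampled nearest-neighbor and so remain binary. Returns the augmented
    arrays plus the realized transform (for reproducibility checks).
    """
    if crop_size > load_size:
        raise ValueError("crop_size must be <= load_size")
    arrs = [
        resize_image(fi, load_size),
        resize_image(ffa, load_size),
        resize_image(label_fi, load_size, is_label=True),
        resize_image(label_ffa, load_size, is_label=True),
    ]
    max_off = load_size - crop_size
    r0 = int(rng.integers(0, max_off + 1))
    c0 = int(rng.integers(0, max_off + 1))
    flip = bool(hflip and rng.random() < 0.5)
    out = []
    for a in arrs:
        a = a[r0 : r0 + crop_size, c0 : c0 + crop_size]
        if flip:
            a = a[:, ::-1].copy()
        out.append(np.ascontiguousarray(a))
    meta = {"row0": r0, "col0": c0, "flip": flip}
    return out[0], out[1], out[2], out[3], meta
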