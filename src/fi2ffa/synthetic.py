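"""Procedural pseudo-paired fundus / angiography phantom generator.

Real FI/FFA pairs from the same eye are hard to acquire pixel-aligned: the
two acquisitions happen minutes apart and the eye moves, so pairs exhibit a
small rigid displacement. This module emulates that situation end to end:
a procedural retinal vessel tree (:class:`SceneSpec`) is rendered once in
color-fundus appearance (dark vessels, warm background, bright optic disc)
and once in angiographic appearance (bright vessels, dark background,
optional hyperfluorescent leakage blobs), the FFA render is displaced by a
bounded random rigid transform, and the ground-truth vessel mask is kept.

Everything is a pure function of (parameters, seed); the geometry in the
ground-truth mask never depends on rendering noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .image_io import PairRecord, RasterImage, write_image, write_manifest

__all__ = [
    "SceneSpec",
    "PairRecord",
    "generate_vessel_tree",
    "rasterize_structure",
    "render_fi",
    "render_ffa",
    "make_paired_dataset",
]


@dataclass
class SceneSpec:
    """Geometry of one synthetic retinal scene.

    Coordinates are in pixels of a square canvas of side ``2 * field_radius``
    with the circular imaged field centered in it. Segments are straight
    capsules ``(start_xy, end_xy, width_px)``; child widths never exceed the
    parent width (tapering trees).
    """

    seed: int
    field_radius: float
    disc_center: tuple[float, float]
    disc_radius: float
    fovea_center: tuple[float, float]
    segments: list[tuple[tuple[float, float], tuple[float, float], float]] = field(default_factory=list)
    leakage_spots: list[tuple[tuple[float, float], float, float]] = field(default_factory=list)

    @property
    def canvas(self) -> float:
        return 2.0 * self.field_radius

    @property
    def center(self) -> tuple[float, float]:
        return (self.field_radius, self.field_radius)


def _clamp_into_field(p: np.ndarray, center: np.ndarray, rmax: float) -> np.ndarray:
    d = p - center
    n = float(np.hypot(*d))
    if n <= rmax:
        return p
    return center + d * (rmax / n)


def generate_vessel_tree(
    seed: int,
    n_roots: int = 6,
    max_depth: int = 5,
    field_radius: float = 128.0,
    branch_prob: float = 0.75,
) -> SceneSpec:
    """Grow a branching vessel tree emanating from near the optic disc.

    Each segment at depth < ``max_depth`` spawns two children with
    probability ``branch_prob`` (heading split) and otherwise continues as a
    single child (heading jitter), so with ``branch_prob = 1`` the segment
    count is exactly ``n_roots * (2**(max_depth + 1) - 1)``. Child width is
    the parent width times a factor drawn in [0.6, 0.9]; endpoints are
    clamped inside 0.97 of the field radius.
    """
    if field_radius <= 0:
        raise ValueError("field_radius must be positive")
    if n_roots < 1 or max_depth < 0:
        raise ValueError("n_roots >= 1 and max_depth >= 0 required")
    if not 0.0 <= branch_prob <= 1.0:
        raise ValueError("branch_prob must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    R = float(field_radius)
    center = np.array([R, R])
    # optic disc sits temporally off-center; fovea on the opposite side
    disc_center = center + np.array([0.45 * R, 0.0])
    disc_radius = 0.12 * R
    fovea_center = center + np.array([-0.15 * R, 0.0])
    rmax = 0.97 * R

    root_width = max(2.0, R / 40.0)
    base_len = 0.30 * R
    scene = SceneSpec(
        seed=int(seed),
        field_radius=R,
        disc_center=(float(disc_center[0]), float(disc_center[1])),
        disc_radius=float(disc_radius),
        fovea_center=(float(fovea_center[0]), float(fovea_center[1])),
    )

    # roots leave the disc fanned toward the field center (away from the rim)
    stack: list[tuple[np.ndarray, float, float, int]] = []
    for i in range(n_roots):
        ang = np.pi / 2 + i * (2.0 * np.pi / n_roots) + rng.uniform(-0.2, 0.2)
        start = disc_center + disc_radius * 0.6 * np.array([np.cos(ang), np.sin(ang)])
        start = _clamp_into_field(start, center, rmax)
        heading = ang + rng.uniform(-0.3, 0.3)
        stack.append((start, float(heading), root_width, 0))

    # depth-first growth; the stack order is deterministic given the rng
    while stack:
        start, heading, width, depth = stack.pop()
        seg_len = base_len * (0.82**depth) * rng.uniform(0.8, 1.2)
        end = start + seg_len * np.array([np.cos(heading), np.sin(heading)])
        end = _clamp_into_field(end, center, rmax)
        scene.segments.append(((float(start[0]), float(start[1])), (float(end[0]), float(end[1])), float(width)))
        if depth >= max_depth:
            continue
        if rng.random() < branch_prob:
            split = rng.uniform(0.35, 0.65)
            for sign in (1.0, -1.0):
                child_w = max(0.8, width * rng.uniform(0.6, 0.9))
                stack.append((end, heading + sign * split, child_w, depth + 1))
        else:
            child_w = max(0.8, width * rng.uniform(0.85, 0.95))
            stack.append((end, heading + rng.uniform(-0.35, 0.35), child_w, depth + 1))

    # a few candidate leakage sites along the vasculature
    n_leak = int(rng.integers(1, 4))
    for _ in range(n_leak):
        seg = scene.segments[int(rng.integers(0, len(scene.segments)))]
        t = rng.uniform(0.2, 0.8)
        cx = seg[0][0] + t * (seg[1][0] - seg[0][0])
        cy = seg[0][1] + t * (seg[1][1] - seg[0][1])
        scene.leakage_spots.append(((float(cx), float(cy)), float(rng.uniform(0.04, 0.09) * R), float(rng.uniform(0.3, 0.6))))
    return scene


def rasterize_structure(scene: SceneSpec, size: int) -> np.ndarray:
    """Binary H x W vessel mask: 1 within width/2 of any segment centerline."""
    if size < 32:
        raise ValueError("raster size must be >= 32")
    out = np.zeros((size, size), dtype=np.uint8)
    if not scene.segments:
        return out
    s = size / scene.canvas
    yy, xx = np.mgrid[0:size, 0:size]
    px = (xx + 0.5) / s
    py = (yy + 0.5) / s
    for (x0, y0), (x1, y1), w in scene.segments:
        r = w / 2.0
        lo_x = int(max(0, (min(x0, x1) - r - 1) * s))
        hi_x = int(min(size, (max(x0, x1) + r + 1) * s + 1))
        lo_y = int(max(0, (min(y0, y1) - r - 1) * s))
        hi_y = int(min(size, (max(y0, y1) + r + 1) * s + 1))
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        X = px[lo_y:hi_y, lo_x:hi_x]
        Y = py[lo_y:hi_y, lo_x:hi_x]
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        if L2 < 1e-12:
            d2 = (X - x0) ** 2 + (Y - y0) ** 2
        else:
            t = np.clip(((X - x0) * dx + (Y - y0) * dy) / L2, 0.0, 1.0)
            d2 = (X - (x0 + t * dx)) ** 2 + (Y - (y0 + t * dy)) ** 2
        out[lo_y:hi_y, lo_x:hi_x] |= (d2 <= r * r).astype(np.uint8)
    return out


def _field_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = size / 2.0 - 0.5
    return ((xx - c) ** 2 + (yy - c) ** 2) <= r * r


def _soft_vessels(scene: SceneSpec, size: int) -> np.ndarray:
    hard = rasterize_structure(scene, size).astype(np.float32)
    return np.clip(ndimage.gaussian_filter(hard, sigma=0.6), 0.0, 1.0)


def _radial_falloff(scene: SceneSpec, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    rr = np.sqrt((xx - c) ** 2 + (yy - c) ** 2) / (size / 2.0)
    return 1.0 - 0.45 * rr**2


def _blob(size: int, cx: float, cy: float, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))).astype(np.float32)


def render_fi(scene: SceneSpec, size: int, seed: int = 0, noise_sigma: float = 0.02) -> RasterImage:
    """Render the scene in color-fundus appearance.

    Warm-toned background with radial illumination falloff, vessels darker
    than their surround (strongest contrast in the green channel), a bright
    optic disc, a darker fovea, and mild additive Gaussian noise. Pixels
    outside the circular imaged field are exactly zero.
    """
    rng = np.random.default_rng(seed)
    s = size / scene.canvas
    vess = _soft_vessels(scene, size)
    fall = _radial_falloff(scene, size)
    base = np.array([0.82, 0.52, 0.22], dtype=np.float32)  # warm fundus tint
    img = base[None, None, :] * fall[:, :, None]
    # optic disc: bright, slightly yellow
    disc = _blob(size, scene.disc_center[0] * s, scene.disc_center[1] * s, scene.disc_radius * s * 0.8)
    img += 0.35 * disc[:, :, None] * np.array([0.9, 1.0, 0.7])[None, None, :]
    # fovea: local darkening
    fov = _blob(size, scene.fovea_center[0] * s, scene.fovea_center[1] * s, 0.08 * scene.field_radius * s)
    img *= 1.0 - 0.30 * fov[:, :, None]
    # vessels absorb, mostly in green/blue
    img *= 1.0 - vess[:, :, None] * np.array([0.35, 0.62, 0.55])[None, None, :]
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    img[~_field_mask(size)] = 0.0
    return RasterImage(img.astype(np.float32), modality="FI")


def render_ffa(scene: SceneSpec, size: int, seed: int = 0, with_leakage: bool = True,
               noise_sigma: float = 0.02) -> RasterImage:
    """Render the scene in angiographic appearance.

    Grayscale-looking (3 replicated channels): dark background, perfused
    vessels bright with fluorescein, optional diffuse hyperfluorescent
    leakage blobs, mild noise, zero outside the circular field.
    """
    rng = np.random.default_rng(seed)
    s = size / scene.canvas
    vess = _soft_vessels(scene, size)
    fall = _radial_falloff(scene, size)
    g = 0.12 * fall
    disc = _blob(size, scene.disc_center[0] * s, scene.disc_center[1] * s, scene.disc_radius * s * 0.8)
    g += 0.18 * disc
    g += 0.68 * vess
    if with_leakage:
        for (cx, cy), rad, inten in scene.leakage_spots:
            g += inten * _blob(size, cx * s, cy * s, rad * s)
    if noise_sigma > 0:
        g = g + rng.normal(0.0, noise_sigma, size=g.shape)
    g = np.clip(g, 0.0, 1.0)
    g[~_field_mask(size)] = 0.0
    img = np.repeat(g[:, :, None], 3, axis=2).astype(np.float32)
    return RasterImage(img, modality="FFA")


def _rigid_displace(px: np.ndarray, dx: float, dy: float, dtheta_deg: float) -> np.ndarray:
    """Rotate about the image center then translate; zero fill outside."""
    size = px.shape[0]
    c = (size - 1) / 2.0
    tf = (
        sktransform.SimilarityTransform(translation=(-c, -c))
        + sktransform.SimilarityTransform(rotation=np.deg2rad(dtheta_deg))
        + sktransform.SimilarityTransform(translation=(c + dx, c + dy))
    )
    out = sktransform.warp(px, tf.inverse, order=1, mode="constant", cval=0.0, preserve_range=True)
    return out.astype(np.float32)


def make_paired_dataset(
    n_pairs: int,
    size: int = 256,
    seed: int = 0,
    max_misalign_px: float = 3.0,
    out_dir: str | Path = ".",
    n_roots: int = 6,
    max_depth: int = 5,
    branch_prob: float = 0.75,
    with_leakage: bool = True,
) -> list[PairRecord]:
    """Write ``n_pairs`` FI/FFA/ground-truth triplets plus a manifest CSV.

    The FFA render is displaced by a random rigid transform whose
    translation components are each bounded by ``max_misalign_px`` (rotation
    bounded by ``0.25 * max_misalign_px`` degrees), emulating pseudo-paired
    clinical acquisitions. With ``max_misalign_px = 0`` the pair is
    pixel-aligned. Fully deterministic given ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise IOError(f"output directory {out_dir} is not writable: {e}") from e

    master = np.random.default_rng(seed)
    records: list[PairRecord] = []
    for i in range(n_pairs):
        scene_seed = int(master.integers(0, 2**31 - 1))
        fi_seed = int(master.integers(0, 2**31 - 1))
        ffa_seed = int(master.integers(0, 2**31 - 1))
        if max_misalign_px > 0:
            dx = float(master.uniform(-max_misalign_px, max_misalign_px))
            dy = float(master.uniform(-max_misalign_px, max_misalign_px))
            dth = float(master.uniform(-0.25 * max_misalign_px, 0.25 * max_misalign_px))
        else:
            dx = dy = dth = 0.0

        scene = generate_vessel_tree(scene_seed, n_roots=n_roots, max_depth=max_depth,
                                     field_radius=size / 2.0, branch_prob=branch_prob)
        fi = render_fi(scene, size, seed=fi_seed)
        ffa = render_ffa(scene, size, seed=ffa_seed, with_leakage=with_leakage)
        if dx or dy or dth:
            ffa = RasterImage(_rigid_displace(ffa.pixels, dx, dy, dth), modality="FFA")
        gt = rasterize_structure(scene, size).astype(np.float32)

        pid = f"pair_{i:04d}"
        fi_p, ffa_p, gt_p = (f"{pid}_fi.png", f"{pid}_ffa.png", f"{pid}_gt.png")
        write_image(fi, out_dir / fi_p)
        write_image(ffa, out_dir / ffa_p)
        write_image(gt[:, :, None], out_dir / gt_p)
        records.append(PairRecord(pid, fi_p, ffa_p, gt_p, (dx, dy, dth)))

    write_manifest(records, out_dir / "manifest.csv")  # relative paths on disk
    return [
        PairRecord(r.pair_id, str(out_dir / r.fi_path), str(out_dir / r.ffa_path),
                   str(out_dir / r.gt_structure_path), r.misalignment)
        for r in records
    ]
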