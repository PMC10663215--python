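"""Synthetic raw-sugarcane scene generation, augmentation and VOC-style I/O.

The real calibration imagery (conveyor-belt scenes of harvested cane with
tops and leaves) is not publicly deposited, so this module generates
structurally similar scenes: elongated slightly-curved cane ribbons, short
jagged broken-cane fragments, tapered top wedges and thin curved leaf strips
on a dark background, with the standard five-class palette.  Each scene
carries its ground-truth mask, per-class pixel counts and per-class masses
drawn from the Gaussian surface-density model, so the whole
segmentation-to-ratio chain is testable end to end without any download.

All randomness is driven by an explicit per-call seed; no global RNG state.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import draw as skdraw

from .density import (
    DEFAULT_SURFACE_DENSITY,
    MATERIAL_CLASSES,
    MassPixelSample,
    SurfaceDensityModel,
)

__all__ = [
    "CLASS_NAMES",
    "PALETTE",
    "AUGMENTATION_OPS",
    "SyntheticScene",
    "AugmentationSpec",
    "DatasetManifest",
    "generate_scene",
    "augment",
    "random_augmentation_spec",
    "split_dataset",
    "write_voc",
    "read_voc",
    "make_mass_dataset",
]

#: Segmentation classes in canonical index order (0 = background).
CLASS_NAMES: tuple[str, ...] = ("background",) + MATERIAL_CLASSES

#: Class -> RGB color of the VOC-style palette masks.
PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (0, 0, 0),
    "cane": (128, 0, 0),
    "broken_cane": (0, 0, 128),
    "top": (0, 128, 0),
    "leaf": (128, 128, 0),
}

#: Mean RGB appearance of each class in the rendered image (not the palette).
_APPEARANCE: dict[str, tuple[float, float, float]] = {
    "background": (9.0, 9.0, 11.0),
    "cane": (182.0, 148.0, 92.0),
    "broken_cane": (214.0, 196.0, 128.0),
    "top": (96.0, 150.0, 62.0),
    "leaf": (152.0, 162.0, 84.0),
}

AUGMENTATION_OPS = ("rotation", "affine", "fog", "gaussian_noise", "median_filter", "cutout")


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene with mask, ground-truth pixel counts and masses."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 class indices
    pixel_counts: Mapping[str, int]
    true_masses: Mapping[str, float]
    seed: int

    def as_mass_sample(self, sample_id: str | None = None) -> MassPixelSample:
        return MassPixelSample(
            sample_id=sample_id or f"scene_{self.seed}",
            pixels={c: self.pixel_counts[c] for c in MATERIAL_CLASSES},
            masses=dict(self.true_masses),
        )


@dataclass(frozen=True)
class AugmentationSpec:
    """One augmentation operation with parameters and its own seed."""

    op: str
    params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.op not in AUGMENTATION_OPS:
            raise ValueError(f"unknown augmentation {self.op!r}; valid: {AUGMENTATION_OPS}")


@dataclass(frozen=True)
class DatasetManifest:
    """Split bookkeeping: disjoint id lists plus the augmentation factor."""

    splits: Mapping[str, tuple[str, ...]]
    aug_factor: int = 1

    def counts(self) -> dict[str, int]:
        return {name: len(ids) for name, ids in self.splits.items()}

    def augmented_counts(self) -> dict[str, int]:
        """Post-augmentation image counts; originals count toward the factor."""
        return {name: len(ids) * self.aug_factor for name, ids in self.splits.items()}

    def all_ids(self) -> list[str]:
        out: list[str] = []
        for ids in self.splits.values():
            out.extend(ids)
        return out


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _stamp_disks(mask: np.ndarray, value: int, pts: np.ndarray, radius: float) -> None:
    """Set ``mask`` to ``value`` inside disks of ``radius`` centered at pts."""
    h, w = mask.shape
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = (yy * yy + xx * xx) <= radius * radius
    for cy, cx in pts:
        cy, cx = int(round(cy)), int(round(cx))
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        sub = disk[y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)]
        region = mask[y0:y1, x0:x1]
        region[sub] = value

def _bezier_points(rng: np.random.Generator, size: int, length: float,
                   curvature: float, step: float) -> np.ndarray:
    """Sample points along a random quadratic Bezier curve inside the canvas."""
    p0 = rng.uniform(0.1 * size, 0.9 * size, 2)
    angle = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.sin(angle), np.cos(angle)])
    p2 = p0 + direction * length
    normal = np.array([-direction[1], direction[0]])
    p1 = (p0 + p2) / 2 + normal * rng.uniform(-curvature, curvature) * length
    n = max(int(length / step), 4)
    t = np.linspace(0, 1, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    return np.clip(pts, 0, size - 1)


def _draw_cane(mask, rng, size):
    length = rng.uniform(0.55, 0.95) * size
    width = rng.uniform(0.045, 0.075) * size
    pts = _bezier_points(rng, size, length, curvature=0.12, step=width / 3)
    _stamp_disks(mask, CLASS_NAMES.index("cane"), pts, width / 2)


def _draw_leaf(mask, rng, size):
    length = rng.uniform(0.45, 0.85) * size
    width = max(rng.uniform(0.014, 0.024) * size, 3.0)
    pts = _bezier_points(rng, size, length, curvature=0.3, step=width / 2)
    _stamp_disks(mask, CLASS_NAMES.index("leaf"), pts, width / 2)


def _draw_broken(mask, rng, size):
    # short jagged fragment: a star-shaped polygon with noisy radii
    cy, cx = rng.uniform(0.1 * size, 0.9 * size, 2)
    n_vert = rng.integers(6, 10)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    base = rng.uniform(0.035, 0.07) * size
    radii = base * rng.uniform(0.55, 1.4, n_vert)
    # elongate along one axis to look like a stalk section
    stretch = rng.uniform(1.2, 2.2)
    rr = cy + radii * np.sin(angles) * stretch
    cc = cx + radii * np.cos(angles)
    poly_r, poly_c = skdraw.polygon(np.clip(rr, 0, size - 1), np.clip(cc, 0, size - 1),
                                    shape=mask.shape)
    mask[poly_r, poly_c] = CLASS_NAMES.index("broken_cane")


def _draw_top(mask, rng, size):
    # tapered wedge: wide base narrowing to a tip
    base_c = rng.uniform(0.15 * size, 0.85 * size, 2)
    angle = rng.uniform(0, 2 * np.pi)
    direction = np.array([np.sin(angle), np.cos(angle)])
    normal = np.array([-direction[1], direction[0]])
    length = rng.uniform(0.18, 0.34) * size
    half_base = rng.uniform(0.03, 0.05) * size
    tip = base_c + direction * length
    v1 = base_c + normal * half_base
    v2 = base_c - normal * half_base
    tip_w = normal * half_base * 0.15
    rr = np.array([v1[0], v2[0], tip[0] - tip_w[0], tip[0] + tip_w[0]])
    cc = np.array([v1[1], v2[1], tip[1] - tip_w[1], tip[1] + tip_w[1]])
    poly_r, poly_c = skdraw.polygon(np.clip(rr, 0, size - 1), np.clip(cc, 0, size - 1),
                                    shape=mask.shape)
    mask[poly_r, poly_c] = CLASS_NAMES.index("top")


_DRAWERS = {
    "cane": _draw_cane,
    "broken_cane": _draw_broken,
    "top": _draw_top,
    "leaf": _draw_leaf,
}

DEFAULT_OBJECT_COUNTS = {"cane": 3, "broken_cane": 3, "top": 2, "leaf": 3}


def _render_image(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float32)
    for idx, name in enumerate(CLASS_NAMES):
        color = np.array(_APPEARANCE[name], dtype=np.float32)
        sel = mask == idx
        img[sel] = color
    # low-frequency illumination gradient plus per-pixel texture noise
    gy = np.linspace(-1, 1, h)[:, None]
    gx = np.linspace(-1, 1, w)[None, :]
    shade = 1.0 + 0.06 * (rng.uniform(-1, 1) * gy + rng.uniform(-1, 1) * gx)
    img *= shade[:, :, None]
    img += rng.normal(0.0, 7.0, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Normal(mu, sigma) redrawn until positive (degenerate at sigma = 0)."""
    if sigma == 0:
        return mu
    for _ in range(1000):
        v = rng.normal(mu, sigma)
        if v > 0:
            return v
    raise RuntimeError(f"could not draw a positive density from N({mu}, {sigma})")


def generate_scene(
    n_objects: Mapping[str, int] | None = None,
    size: int = 512,
    density: SurfaceDensityModel | None = None,
    seed: int = 0,
    max_retries: int = 20,
) -> SyntheticScene:
    """Render one synthetic scene.

    Objects are drawn in random order; later objects occlude earlier ones,
    and the mask records the topmost class per pixel.  Per-class masses are
    pixel count times a truncated-normal surface-density draw, so a model
    with sigma = 0 yields exactly ``mu * pixel_count``.
    """
    if size < 64:
        raise ValueError(f"scene size must be >= 64, got {size}")
    counts_spec = dict(DEFAULT_OBJECT_COUNTS if n_objects is None else n_objects)
    for cls, n in counts_spec.items():
        if cls not in MATERIAL_CLASSES or n < 0:
            raise ValueError(f"bad object count {cls!r}={n}")
    density = density or SurfaceDensityModel.reference()
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        mask = np.zeros((size, size), dtype=np.uint8)
        order = [cls for cls, n in counts_spec.items() for _ in range(n)]
        rng.shuffle(order)
        for cls in order:
            _DRAWERS[cls](mask, rng, size)
        # occlusion may wipe a requested class out entirely; retry if so
        ok = all(
            (mask == CLASS_NAMES.index(cls)).any()
            for cls, n in counts_spec.items()
            if n > 0
        )
        if ok:
            break
    else:
        raise RuntimeError(f"could not place all requested objects in a {size}x{size} scene")
    image = _render_image(mask, rng)
    pixel_counts = {
        name: int((mask == idx).sum()) for idx, name in enumerate(CLASS_NAMES)
    }
    true_masses = {}
    for cls in MATERIAL_CLASSES:
        cd = density.classes.get(cls)
        if cd is None or pixel_counts[cls] == 0:
            true_masses[cls] = 0.0
        else:
            true_masses[cls] = _truncated_normal(rng, cd.mu, cd.sigma) * pixel_counts[cls]
    return SyntheticScene(image=image, mask=mask, pixel_counts=pixel_counts,
                         true_masses=true_masses, seed=seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def random_augmentation_spec(op: str, seed: int) -> AugmentationSpec:
    """Draw documented-range parameters for ``op`` from ``seed``."""
    rng = np.random.default_rng(seed)
    if op == "rotation":
        params = {"angle": float(rng.uniform(-180, 180))}
    elif op == "affine":
        params = {
            "scale": float(rng.uniform(0.9, 1.1)),
            "shear": float(rng.uniform(-0.12, 0.12)),
            "tx": float(rng.uniform(-0.05, 0.05)),
            "ty": float(rng.uniform(-0.05, 0.05)),
        }
    elif op == "fog":
        params = {"transmission": float(rng.uniform(0.6, 0.95))}
    elif op == "gaussian_noise":
        params = {"sigma": float(rng.uniform(4, 14))}
    elif op == "median_filter":
        params = {"size": 3}
    elif op == "cutout":
        params = {"fraction": float(rng.uniform(0.08, 0.22))}
    else:
        raise ValueError(f"unknown augmentation {op!r}")
    return AugmentationSpec(op=op, params=params, seed=seed)


def augment(image: np.ndarray, mask: np.ndarray,
            spec: AugmentationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Apply one augmentation jointly to (image, mask).

    Geometric operations use bilinear interpolation on the image and nearest
    neighbor on the mask, filling exposed borders with background.
    Photometric operations (fog, noise, median filter) alter the image only.
    Cutout zeroes a rectangular image patch and relabels it background in
    the mask so labels stay consistent with appearance.
    """
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} sizes differ")
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    img = image.astype(np.float32)
    out_mask = mask.copy()
    if spec.op == "rotation":
        angle = p.get("angle", float(rng.uniform(-180, 180)))
        if angle % 360 != 0:
            img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1, cval=0.0)
            out_mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False, order=0, cval=0)
    elif spec.op == "affine":
        h, w = mask.shape
        scale = p.get("scale", 1.0)
        shear = p.get("shear", 0.0)
        ty = p.get("ty", 0.0) * h
        tx = p.get("tx", 0.0) * w
        A = np.array([[scale, shear], [0.0, scale]], dtype=float)
        center = np.array([h / 2, w / 2])
        offset = center - A @ center + np.array([ty, tx])
        img = np.stack(
            [ndimage.affine_transform(img[:, :, ch], A, offset=offset, order=1, cval=0.0)
             for ch in range(img.shape[2])], axis=2)
        out_mask = ndimage.affine_transform(mask, A, offset=offset, order=0, cval=0)
    elif spec.op == "fog":
        t = p.get("transmission", 0.8)
        atmosphere = np.array([235.0, 235.0, 240.0], dtype=np.float32)
        img = t * img + (1.0 - t) * atmosphere
    elif spec.op == "gaussian_noise":
        img = img + rng.normal(0.0, p.get("sigma", 8.0), img.shape)
    elif spec.op == "median_filter":
        size = int(p.get("size", 3))
        img = np.stack(
            [ndimage.median_filter(img[:, :, ch], size=size) for ch in range(img.shape[2])],
            axis=2)
    elif spec.op == "cutout":
        h, w = mask.shape
        k = int(p.get("fraction", 0.15) * min(h, w))
        k = max(k, 1)
        y0 = int(rng.integers(0, h - k + 1))
        x0 = int(rng.integers(0, w - k + 1))
        img[y0 : y0 + k, x0 : x0 + k] = 0.0
        out_mask[y0 : y0 + k, x0 : x0 + k] = 0
    else:  # pragma: no cover - guarded by AugmentationSpec
        raise ValueError(f"unknown augmentation {spec.op!r}")
    return np.clip(img, 0, 255).astype(np.uint8), out_mask


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_dataset(
    n: int,
    ratios: Sequence[int] = (6, 2, 2),
    aug_factor: int = 10,
    seed: int = 0,
    ids: Sequence[str] | None = None,
    split_names: Sequence[str] = ("train", "val", "test"),
) -> DatasetManifest:
    """Random disjoint split with largest-remainder rounding.

    910 ids at 6:2:2 give 546/182/182; with augmentation factor 10 the
    post-augmentation counts are 5460/1820/1820 (the original counts toward
    the factor).
    """
    total = sum(ratios)
    if n < total:
        raise ValueError(f"need at least {total} ids for ratios {tuple(ratios)}, got {n}")
    if ids is None:
        width = len(str(n - 1))
        ids = [f"scene_{i:0{width}d}" for i in range(n)]
    elif len(ids) != n:
        raise ValueError(f"got {len(ids)} ids for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    exact = np.array(ratios, dtype=float) * n / total
    sizes = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    splits: dict[str, tuple[str, ...]] = {}
    start = 0
    for name, size in zip(split_names, sizes):
        splits[name] = tuple(ids[i] for i in perm[start : start + size])
        start += size
    return DatasetManifest(splits=splits, aug_factor=aug_factor)


# ---------------------------------------------------------------------------
# VOC-style on-disk layout
# ---------------------------------------------------------------------------

def _palette_image(mask: np.ndarray) -> Image.Image:
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    flat = [0] * (256 * 3)
    for idx, name in enumerate(CLASS_NAMES):
        flat[3 * idx : 3 * idx + 3] = PALETTE[name]
    im.putpalette(flat)
    return im


def write_voc(scenes: Mapping[str, SyntheticScene], root,
              manifest: DatasetManifest | None = None) -> None:
    """Write ``JPEGImages/*.jpg``, ``SegmentationClass/*.png`` (palette PNG)
    and ``ImageSets/Segmentation/<split>.txt`` under ``root``."""
    root = str(root)
    img_dir = os.path.join(root, "JPEGImages")
    seg_dir = os.path.join(root, "SegmentationClass")
    set_dir = os.path.join(root, "ImageSets", "Segmentation")
    for d in (img_dir, seg_dir, set_dir):
        os.makedirs(d, exist_ok=True)
    for sid, scene in scenes.items():
        Image.fromarray(scene.image).save(os.path.join(img_dir, f"{sid}.jpg"), quality=95)
        _palette_image(scene.mask).save(os.path.join(seg_dir, f"{sid}.png"))
    if manifest is not None:
        for split, ids in manifest.splits.items():
            with open(os.path.join(set_dir, f"{split}.txt"), "w", encoding="utf-8") as fh:
                fh.write("\n".join(ids) + ("\n" if ids else ""))


def read_voc(root) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], DatasetManifest | None]:
    """Read a VOC-layout dataset back: id -> (image, index mask), manifest.

    Raises ``FileNotFoundError``/``ValueError`` naming the offending file on
    missing directories or palette mismatches.  Masks round-trip bit-exactly.
    """
    root = str(root)
    img_dir = os.path.join(root, "JPEGImages")
    seg_dir = os.path.join(root, "SegmentationClass")
    set_dir = os.path.join(root, "ImageSets", "Segmentation")
    for d in (img_dir, seg_dir):
        if not os.path.isdir(d):
            raise FileNotFoundError(f"missing VOC directory: {d}")
    expected = [0] * (256 * 3)
    for idx, name in enumerate(CLASS_NAMES):
        expected[3 * idx : 3 * idx + 3] = PALETTE[name]
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fn in sorted(os.listdir(seg_dir)):
        if not fn.endswith(".png"):
            continue
        sid = fn[:-4]
        mask_path = os.path.join(seg_dir, fn)
        with Image.open(mask_path) as im:
            if im.mode != "P":
                raise ValueError(f"{mask_path}: expected a palette PNG, got mode {im.mode}")
            pal = im.getpalette() or []
            pal = pal + [0] * (768 - len(pal))
            if pal[: 3 * len(CLASS_NAMES)] != expected[: 3 * len(CLASS_NAMES)]:
                raise ValueError(f"{mask_path}: palette does not match the class palette")
            mask = np.asarray(im, dtype=np.uint8)
        img_path = os.path.join(img_dir, f"{sid}.jpg")
        if not os.path.isfile(img_path):
            raise FileNotFoundError(f"missing image for mask {mask_path}: {img_path}")
        with Image.open(img_path) as im:
            image = np.asarray(im.convert("RGB"), dtype=np.uint8)
        data[sid] = (image, mask)
    manifest = None
    if os.path.isdir(set_dir):
        splits = {}
        for fn in sorted(os.listdir(set_dir)):
            if fn.endswith(".txt"):
                with open(os.path.join(set_dir, fn), encoding="utf-8") as fh:
                    splits[fn[:-4]] = tuple(line.strip() for line in fh if line.strip())
        if splits:
            manifest = DatasetManifest(splits=splits)
    return data, manifest


# ---------------------------------------------------------------------------
# calibration-style mass dataset
# ---------------------------------------------------------------------------

DEFAULT_PIXEL_RANGES: dict[str, tuple[int, int]] = {
    "cane": (30_000, 120_000),
    "broken_cane": (10_000, 60_000),
    "top": (5_000, 50_000),
    "leaf": (5_000, 80_000),
}

#: Default per-class surface-density spread (g/pixel).  Relative spread is
#: small for cane and larger for broken cane, top and leaf, mirroring how
#: concentrated each class's density distribution is in practice.
DEFAULT_DENSITY_SIGMA: dict[str, float] = {
    "cane": 1.2e-4,
    "broken_cane": 1.8e-4,
    "top": 2.2e-4,
    "leaf": 0.9e-5,
}


def default_density_model() -> SurfaceDensityModel:
    """Reference means with the default non-zero spreads."""
    return SurfaceDensityModel.from_mu_sigma(DEFAULT_SURFACE_DENSITY, DEFAULT_DENSITY_SIGMA)


def make_mass_dataset(
    n_samples: int,
    density: SurfaceDensityModel | None = None,
    pixel_ranges: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
    class_correlation: float = 1.0,
) -> list[MassPixelSample]:
    """Generate a calibration-style mass/pixel dataset.

    Per sample, class pixel counts are uniform over ``pixel_ranges`` and the
    class surface densities are Gaussian around the model means.  A sample's
    class densities share a common standardized deviation scaled by
    ``class_correlation`` (1.0 by default): densities within one image move
    together, reflecting that packing density and viewing conditions affect
    all material classes of an image alike.  Masses are density x pixels,
    truncated positive.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0.0 <= class_correlation <= 1.0):
        raise ValueError("class_correlation must lie in [0, 1]")
    density = density or default_density_model()
    ranges = dict(DEFAULT_PIXEL_RANGES if pixel_ranges is None else pixel_ranges)
    for cls, (lo, hi) in ranges.items():
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid pixel range for {cls!r}: ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    rho = class_correlation
    samples = []
    for i in range(n_samples):
        pixels, masses = {}, {}
        z_shared = rng.standard_normal()
        for cls in MATERIAL_CLASSES:
            lo, hi = ranges[cls]
            p = int(rng.integers(lo, hi + 1))
            cd = density.classes[cls]
            if cd.sigma == 0:
                d = cd.mu
            else:
                z = rho * z_shared + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
                d = cd.mu + cd.sigma * z
                while d <= 0:
                    d = cd.mu + cd.sigma * rng.standard_normal()
            pixels[cls] = p
            masses[cls] = d * p
        samples.append(MassPixelSample(sample_id=f"mass_{i:04d}", pixels=pixels, masses=masses))
    return samples
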