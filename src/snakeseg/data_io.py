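"""Dataset reading, splitting, normalization and augmentation.

Expected on-disk layouts for :func:`load_dataset`:

* ``directory/images/*.png`` with matching ``directory/masks/*.png``
  (paired by file stem), or
* ``directory/annotations.json`` (COCO-style: ``images`` +
  ``annotations`` with polygon ``segmentation`` lists) next to an
  ``images/`` folder.

Images are grayscale PNG (8- or 16-bit) scaled to [0, 1]; masks are
binarized at value > 0.  Polygon vertices are (x, y) pixel coordinates
with pixel centers at integers; a pixel belongs to the mask when its
center lies inside the polygon (even-odd rule).

Augmentation follows a three-stage protocol: (1) photometric brightness /
contrast jitter on the image only, (2) CLAHE on the image only, (3)
geometric transforms (flips, rotation, affine, blur) applied identically
to image and mask — the mask via nearest-neighbor so it stays binary —
followed by a random crop.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import exposure, transform
from skimage.draw import polygon as _draw_polygon
from skimage.filters import gaussian as _gaussian

from .exceptions import ShapeError

logger = logging.getLogger(__name__)

__all__ = [
    "Sample",
    "AugmentationConfig",
    "load_dataset",
    "split_dataset",
    "augment",
    "clahe",
    "flip_sample",
    "rotate_sample",
    "read_image",
    "write_image",
    "write_mask",
]


@dataclass
class Sample:
    image: np.ndarray  # float32 grayscale in [0, 1]
    mask: np.ndarray   # uint8 binary {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ShapeError(
                f"sample {self.id!r}: image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


@dataclass(frozen=True)
class AugmentationConfig:
    brightness: float = 0.2          # additive jitter range (+-)
    contrast: float = 0.2            # multiplicative jitter range (+-)
    clahe_clip: float = 0.02         # equalize_adapthist clip fraction
    clahe_tiles: tuple[int, int] = (8, 8)
    rotation: float = 15.0           # degrees (+-)
    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    blur_sigma: tuple[float, float] = (0.1, 1.5)
    p_blur: float = 0.5
    affine_scale: tuple[float, float] = (0.9, 1.1)
    shear: float = 8.0               # degrees (+-)
    translate: float = 0.05          # fraction of image size (+-)
    crop_size: int = 256
    with_photometric: bool = True
    with_clahe: bool = True
    with_geometric: bool = True

    def __post_init__(self):
        for p in (self.p_flip_h, self.p_flip_v, self.p_blur):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.crop_size < 1:
            raise ValueError("crop_size must be positive")


# --------------------------------------------------------------------- reading
def read_image(path: Path) -> np.ndarray:
    """Load a grayscale PNG (8- or 16-bit) scaled to float32 [0, 1]."""
    with Image.open(path) as im:
        if im.mode not in ("L", "I;16", "I"):
            im = im.convert("L")
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        return (arr / 255.0).astype(np.float32)
    if arr.dtype.kind in "iu":  # 16-bit grayscale
        return (arr / 65535.0).astype(np.float32)
    return arr.astype(np.float32)


def write_image(path: Path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def write_mask(path: Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


def _rasterize_polygons(polys: list[list[float]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.uint8)
    for flat in polys:
        xs = np.asarray(flat[0::2], dtype=float)
        ys = np.asarray(flat[1::2], dtype=float)
        rr, cc = _draw_polygon(ys, xs, shape=shape)
        mask[rr, cc] ^= 1  # even-odd rule across overlapping rings
    return mask


def _load_coco(directory: Path) -> list[Sample]:
    spec = json.loads((directory / "annotations.json").read_text())
    img_dir = directory / "images" if (directory / "images").is_dir() else directory
    by_image: dict[int, list[list[float]]] = {}
    for ann in spec.get("annotations", []):
        segs = ann.get("segmentation", [])
        by_image.setdefault(ann["image_id"], []).extend(segs)
    samples = []
    for info in spec.get("images", []):
        path = img_dir / info["file_name"]
        if not path.exists():
            logger.warning("image file %s listed in annotations but missing; skipped", path)
            continue
        image = read_image(path)
        mask = _rasterize_polygons(by_image.get(info["id"], []), image.shape)
        samples.append(Sample(image=image, mask=mask, id=Path(info["file_name"]).stem))
    return samples


def load_dataset(directory: str | Path) -> list[Sample]:
    """Load image/mask pairs; see module docstring for layouts."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    if (directory / "annotations.json").exists():
        samples = _load_coco(directory)
    else:
        img_dir = directory / "images"
        mask_dir = directory / "masks"
        if not img_dir.is_dir() or not mask_dir.is_dir():
            raise FileNotFoundError(f"{directory} contains neither annotations.json nor images/ + masks/")
        masks = {p.stem: p for p in sorted(mask_dir.glob("*.png"))}
        samples = []
        for img_path in sorted(img_dir.glob("*.png")):
            mask_path = masks.get(img_path.stem)
            if mask_path is None:
                logger.warning("no mask for image %s; skipped", img_path.name)
                continue
            image = read_image(img_path)
            mask = (np.asarray(Image.open(mask_path)) > 0).astype(np.uint8)
            samples.append(Sample(image=image, mask=mask, id=img_path.stem))
    if not samples:
        raise FileNotFoundError(f"no usable image/mask pairs found under {directory}")
    return samples


# -------------------------------------------------------------------- splitting
def split_dataset(samples: list, ratio: tuple[int, int, int] = (1000, 200, 300), seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible train/val/test split.

    Counts follow ``ratio`` proportionally (largest-remainder rounding)
    when the sample count differs from ``sum(ratio)``.
    """
    n = len(samples)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for i in np.argsort(remainders)[::-1][: n - sum(counts)]:
        counts[int(i)] += 1
    order = np.random.default_rng(seed).permutation(n)
    train = [samples[i] for i in order[: counts[0]]]
    val = [samples[i] for i in order[counts[0] : counts[0] + counts[1]]]
    test = [samples[i] for i in order[counts[0] + counts[1] :]]
    return train, val, test


# ----------------------------------------------------------------- augmentation
def clahe(image: np.ndarray, clip_limit: float = 0.02, tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on [0, 1] images.

    A constant image is a fixed point (there is no contrast to equalize).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.max() == img.min():
        return img.astype(np.float32)
    kernel = (max(img.shape[0] // tile_grid[0], 1), max(img.shape[1] // tile_grid[1], 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = exposure.equalize_adapthist(np.clip(img, 0.0, 1.0), kernel_size=kernel, clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def flip_sample(sample: Sample, axis: int) -> Sample:
    """Exact flip of image and mask along ``axis`` (0 vertical, 1 horizontal)."""
    return replace(
        sample,
        image=np.ascontiguousarray(np.flip(sample.image, axis=axis)),
        mask=np.ascontiguousarray(np.flip(sample.mask, axis=axis)),
    )


def rotate_sample(sample: Sample, angle: float) -> Sample:
    """Rotate image and mask together; multiples of 90 degrees are exact."""
    if angle % 90 == 0:
        k = int(angle // 90) % 4
        return replace(
            sample,
            image=np.ascontiguousarray(np.rot90(sample.image, k)),
            mask=np.ascontiguousarray(np.rot90(sample.mask, k)),
        )
    img = transform.rotate(sample.image, angle, order=1, mode="edge", preserve_range=True)
    msk = transform.rotate(sample.mask.astype(float), angle, order=0, mode="constant", cval=0, preserve_range=True)
    return replace(sample, image=img.astype(np.float32), mask=(msk > 0.5).astype(np.uint8))


def _random_crop(image: np.ndarray, mask: np.ndarray, size: int, rng: np.random.Generator):
    H, W = image.shape
    if size > H or size > W:
        raise ValueError(f"crop_size {size} exceeds image size {H}x{W}")
    r0 = int(rng.integers(0, H - size + 1))
    c0 = int(rng.integers(0, W - size + 1))
    return image[r0 : r0 + size, c0 : c0 + size], mask[r0 : r0 + size, c0 : c0 + size]


def augment(sample: Sample, cfg: AugmentationConfig, rng: np.random.Generator) -> Sample:
    """Apply the three-stage augmentation protocol to one sample."""
    image = sample.image.astype(np.float32)
    mask = (sample.mask > 0).astype(np.uint8)

    # stage 1: photometric (image only)
    if cfg.with_photometric:
        c = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        b = rng.uniform(-cfg.brightness, cfg.brightness)
        image = np.clip(image * c + b, 0.0, 1.0).astype(np.float32)

    # stage 2: CLAHE (image only)
    if cfg.with_clahe:
        image = clahe(image, cfg.clahe_clip, cfg.clahe_tiles)

    # stage 3: geometric (image and mask together) + random crop
    if cfg.with_geometric:
        s = Sample(image=image, mask=mask, id=sample.id)
        if rng.random() < cfg.p_flip_h:
            s = flip_sample(s, axis=1)
        if rng.random() < cfg.p_flip_v:
            s = flip_sample(s, axis=0)
        angle = float(rng.uniform(-cfg.rotation, cfg.rotation))
        if angle != 0.0:
            s = rotate_sample(s, angle)
        image, mask = s.image, s.mask
        # affine: scale / shear / translate about the image center
        scale = float(rng.uniform(*cfg.affine_scale))
        shear = float(np.deg2rad(rng.uniform(-cfg.shear, cfg.shear)))
        H, W = image.shape
        tr = (float(rng.uniform(-cfg.translate, cfg.translate) * W),
              float(rng.uniform(-cfg.translate, cfg.translate) * H))
        center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        aff = (
            transform.AffineTransform(translation=-center)
            + transform.AffineTransform(scale=scale, shear=shear, translation=tr)
            + transform.AffineTransform(translation=center)
        )
        image = transform.warp(image, aff.inverse, order=1, mode="edge", preserve_range=True).astype(np.float32)
        mask = (
            transform.warp(mask.astype(float), aff.inverse, order=0, mode="constant", cval=0, preserve_range=True)
            > 0.5
        ).astype(np.uint8)
        if rng.random() < cfg.p_blur:
            sigma = float(rng.uniform(*cfg.blur_sigma))
            image = _gaussian(image, sigma=sigma, preserve_range=True).astype(np.float32)

    if cfg.crop_size <= min(image.shape):
        image, mask = _random_crop(image, mask, cfg.crop_size, rng)
    return Sample(image=np.ascontiguousarray(image), mask=np.ascontiguousarray(mask), id=sample.id)
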