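"""Training-time augmentation and evaluation-time normalization.

Training pipeline: bicubic resize to ``target_size``, random horizontal flip,
``n_rand_ops`` operations drawn from a rand-augment-style enhancement pool at
a fixed magnitude (``magnitude`` of ``magnitude_bins`` levels), random
erasing of one rectangle covering 2-33% of the image with probability 0.25,
then per-channel standardization with the ImageNet mean/std convention.
Evaluation pipeline: resize + standardization only (deterministic).

The enhancement pool covers automatic contrast, histogram equalization,
rotation, flipping, exposure adjustment (solarize and posterize), colour
balance, contrast, brightness and sharpening — implemented with Pillow's
``ImageOps``/``ImageEnhance`` operators.  All randomness flows through a
caller-supplied ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageEnhance, ImageOps

__all__ = [
    "AugmentConfig",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "preprocess_train",
    "preprocess_eval",
    "ENHANCEMENT_POOL",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class AugmentConfig:
    target_size: int = 224
    n_rand_ops: int = 2
    magnitude: int = 9
    magnitude_bins: int = 10
    erase_prob: float = 0.25
    erase_area: tuple[float, float] = (0.02, 0.33)
    hflip_prob: float = 0.5

    def __post_init__(self):
        if not 0 <= self.magnitude < self.magnitude_bins:
            raise ValueError("need 0 <= magnitude < magnitude_bins")
        lo, hi = self.erase_area
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("need 0 < erase_area min < max < 1")


# -- enhancement pool ---------------------------------------------------------
# Each op maps (PIL image, magnitude fraction in [0,1], rng) -> PIL image.
# Magnitude scaling follows the usual rand-augment ranges; level-free ops
# (autocontrast, equalize, flip) ignore the fraction.

def _signed(frac: float, rng) -> float:
    return frac if rng.random() < 0.5 else -frac


def _op_autocontrast(im, frac, rng):
    return ImageOps.autocontrast(im)


def _op_equalize(im, frac, rng):
    return ImageOps.equalize(im)


def _op_rotate(im, frac, rng):
    return im.rotate(_signed(30.0 * frac, rng), resample=Image.BICUBIC,
                     fillcolor=(128, 128, 128))


def _op_flip(im, frac, rng):
    return ImageOps.mirror(im) if rng.random() < 0.5 else ImageOps.flip(im)


def _op_solarize(im, frac, rng):
    return ImageOps.solarize(im, threshold=int(255 * (1.0 - frac)))


def _op_posterize(im, frac, rng):
    return ImageOps.posterize(im, bits=max(1, 8 - int(4 * frac)))


def _enhance(factory):
    def op(im, frac, rng):
        return factory(im).enhance(1.0 + _signed(0.9 * frac, rng))
    return op


ENHANCEMENT_POOL = {
    "autocontrast": _op_autocontrast,
    "equalize": _op_equalize,
    "rotate": _op_rotate,
    "flip": _op_flip,
    "solarize": _op_solarize,
    "posterize": _op_posterize,
    "color": _enhance(ImageEnhance.Color),
    "contrast": _enhance(ImageEnhance.Contrast),
    "brightness": _enhance(ImageEnhance.Brightness),
    "sharpness": _enhance(ImageEnhance.Sharpness),
}


def _resize(pixels: np.ndarray, size: int) -> Image.Image:
    if min(pixels.shape[:2]) < 8:
        raise ValueError("input image must be at least 8x8")
    im = Image.fromarray(np.asarray(pixels, dtype=np.uint8))
    return im.resize((size, size), resample=Image.BICUBIC)


def _standardize(arr: np.ndarray) -> np.ndarray:
    return (arr / 255.0 - IMAGENET_MEAN) / IMAGENET_STD


def preprocess_train(pixels: np.ndarray, cfg: AugmentConfig,
                     rng: np.random.Generator, return_info: bool = False):
    """Augment one (H, W, 3) uint8 image into a standardized float array.

    Returns the (target_size, target_size, 3) array, or ``(array, info)``
    with ``info`` recording the applied flip/ops/erase when ``return_info``.
    """
    im = _resize(pixels, cfg.target_size)
    info = {"flipped": False, "ops": [], "erased": False, "erase_box": None}

    if rng.random() < cfg.hflip_prob:
        im = ImageOps.mirror(im)
        info["flipped"] = True

    names = list(ENHANCEMENT_POOL)
    frac = cfg.magnitude / cfg.magnitude_bins
    for idx in rng.choice(len(names), size=cfg.n_rand_ops, replace=True):
        name = names[idx]
        im = ENHANCEMENT_POOL[name](im, frac, rng)
        info["ops"].append(name)

    arr = np.asarray(im, dtype=np.float64)

    if rng.random() < cfg.erase_prob:
        h = w = cfg.target_size
        area = h * w * rng.uniform(*cfg.erase_area)
        aspect = np.exp(rng.uniform(np.log(0.3), np.log(1.0 / 0.3)))
        eh = min(h, max(1, int(round(np.sqrt(area * aspect)))))
        # derive width from the height so integer rounding cannot push the
        # erased fraction outside the configured area bounds
        ew = int(round(area / eh))
        ew = int(np.clip(ew, np.ceil(cfg.erase_area[0] * h * w / eh),
                         min(w, np.floor(cfg.erase_area[1] * h * w / eh))))
        top = int(rng.integers(0, h - eh + 1))
        left = int(rng.integers(0, w - ew + 1))
        arr[top:top + eh, left:left + ew] = rng.integers(
            0, 256, size=(eh, ew, 3))
        info["erased"] = True
        info["erase_box"] = (top, left, eh, ew)

    arr = _standardize(arr)
    return (arr, info) if return_info else arr


def preprocess_eval(pixels: np.ndarray, target_size: int = 224) -> np.ndarray:
    """Deterministic evaluation path: bicubic resize + standardization."""
    arr = np.asarray(_resize(pixels, target_size), dtype=np.float64)
    return _standardize(arr)
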