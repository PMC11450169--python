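"""Synthetic single-cell image generator.

Produces labeled RGB images that mimic the gross structure of stained
single-cell micrographs — a pale background, one roughly elliptical cell body
whose hue is class-specific, a darker (possibly multi-lobed) nucleus and
granular cytoplasmic noise — with exact control over per-class counts, so the
whole classification stack can be exercised without any external dataset.
Class distinctions are carried by hue, nucleus lobe count, nucleus size and
granularity; hue separation between classes is validated so a generated
problem is learnable by construction.

The generator makes no attempt at photorealistic stain simulation; see the
methods note for what that does and does not imply for real data.
"""

from __future__ import annotations

import colorsys
import logging
import uuid
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CellClassSpec",
    "ImageRecord",
    "generate_dataset",
    "write_image_folder",
    "read_image_folder",
    "imbalanced_profile",
]

logger = logging.getLogger(__name__)

SPLITS = ("train", "val", "test")
_UUID_NS = uuid.UUID("6ba7b812-9dad-11d1-80b4-00c04fd430c8")  # uuid5 namespace


@dataclass
class CellClassSpec:
    """One synthetic cell class.

    Parameters
    ----------
    name : class/folder name.
    count : number of images to generate.
    hue : cell-body hue in degrees [0, 360).
    nucleus_lobes : number of nuclear lobes (>= 1; segmented-granulocyte-like
        morphology for > 1).
    nucleus_fraction : nucleus area as a fraction of the cell area, in (0, 1).
    granularity : amplitude of additive cytoplasmic noise (>= 0).
    """

    name: str
    count: int
    hue: float
    nucleus_lobes: int = 1
    nucleus_fraction: float = 0.35
    granularity: float = 8.0

    def __post_init__(self):
        if self.count <= 0:
            raise ValueError(f"class {self.name!r}: count must be positive")
        if not 0.0 <= self.hue < 360.0:
            raise ValueError(f"class {self.name!r}: hue must be in [0, 360)")
        if self.nucleus_lobes < 1:
            raise ValueError(f"class {self.name!r}: nucleus_lobes must be >= 1")
        if not 0.0 < self.nucleus_fraction < 1.0:
            raise ValueError(
                f"class {self.name!r}: nucleus_fraction must be in (0, 1)")
        if self.granularity < 0:
            raise ValueError(f"class {self.name!r}: granularity must be >= 0")


@dataclass
class ImageRecord:
    """One image with its class label and split assignment."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: int
    split: str = "train"

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if min(self.pixels.shape[:2]) < 32:
            raise ValueError("images must be at least 32x32")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")


def _hue_to_rgb(hue: float, sat: float, val: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(hue / 360.0, sat, val)) * 255.0


def _min_circular_gap(hues: np.ndarray) -> float:
    gaps = np.abs(hues[:, None] - hues[None, :])
    gaps = np.minimum(gaps, 360.0 - gaps)
    np.fill_diagonal(gaps, np.inf)
    return float(gaps.min())


def _render_cell(spec: CellClassSpec, side: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one cell image: pale background, elliptical body, darker nucleus
    with ``nucleus_lobes`` lobes, granular noise inside the cytoplasm."""
    yy, xx = np.mgrid[0:side, 0:side].astype(np.float64)
    cy = side / 2 + rng.normal(0, side * 0.03)
    cx = side / 2 + rng.normal(0, side * 0.03)

    # cell body: ellipse with random orientation and mild eccentricity
    r_a = side * rng.uniform(0.30, 0.40)
    r_b = r_a * rng.uniform(0.75, 1.0)
    phi = rng.uniform(0, np.pi)
    cphi, sphi = np.cos(phi), np.sin(phi)
    u = (xx - cx) * cphi + (yy - cy) * sphi
    v = -(xx - cx) * sphi + (yy - cy) * cphi
    cell_mask = (u / r_a) ** 2 + (v / r_b) ** 2 <= 1.0

    # background: pale, slightly textured
    img = np.empty((side, side, 3))
    img[:] = np.array([236.0, 228.0, 233.0])
    img += rng.normal(0, 2.0, size=(side, side, 1))

    hue = (spec.hue + rng.normal(0, 4.0)) % 360.0
    cyto = _hue_to_rgb(hue, sat=rng.uniform(0.45, 0.6), val=rng.uniform(0.75, 0.9))
    img[cell_mask] = cyto

    # nucleus: lobes arranged around the cell centre, darker & more saturated
    cell_area = np.pi * r_a * r_b
    lobe_area = spec.nucleus_fraction * cell_area / spec.nucleus_lobes
    lobe_r = np.sqrt(lobe_area / np.pi)
    nuc = _hue_to_rgb(hue, sat=rng.uniform(0.75, 0.9), val=rng.uniform(0.30, 0.45))
    orbit = 0.0 if spec.nucleus_lobes == 1 else 0.45 * min(r_a, r_b)
    theta0 = rng.uniform(0, 2 * np.pi)
    for l in range(spec.nucleus_lobes):
        ang = theta0 + 2 * np.pi * l / spec.nucleus_lobes
        ly = cy + orbit * np.sin(ang) + rng.normal(0, side * 0.01)
        lx = cx + orbit * np.cos(ang) + rng.normal(0, side * 0.01)
        lobe = (xx - lx) ** 2 + (yy - ly) ** 2 <= lobe_r**2
        img[lobe & cell_mask] = nuc

    if spec.granularity > 0:
        noise = rng.normal(0, spec.granularity, size=(side, side, 3))
        img[cell_mask] += noise[cell_mask]

    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(specs: list[CellClassSpec],
                     image_size_range: tuple[int, int] = (64, 256),
                     seed: int = 0,
                     split_fractions: tuple[float, float, float] = (0.8, 0.2, 0.0),
                     min_hue_separation: float = 10.0) -> list[ImageRecord]:
    """Generate a labeled synthetic dataset.

    Per-class counts match ``specs`` exactly; image side lengths are drawn
    uniformly from ``image_size_range`` (so the resize path downstream is
    exercised); splits are assigned per record by a seeded draw with the given
    train/val/test fractions.  Byte-identical output for identical arguments.

    Raises ``ValueError`` for fewer than two classes, non-positive counts or
    classes whose hues are closer than ``min_hue_separation`` degrees.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 classes")
    hues = np.array([s.hue for s in specs], dtype=np.float64)
    if len(specs) > 1 and _min_circular_gap(hues) < min_hue_separation:
        raise ValueError(
            f"class hues closer than {min_hue_separation} degrees; "
            "classes would not be separable")
    lo, hi = image_size_range
    if lo < 32 or hi < lo:
        raise ValueError("image_size_range must satisfy 32 <= min <= max")
    fr = np.asarray(split_fractions, dtype=np.float64)
    if fr.min() < 0 or not np.isclose(fr.sum(), 1.0):
        raise ValueError("split fractions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    for label, spec in enumerate(specs):
        for _ in range(spec.count):
            side = int(rng.integers(lo, hi + 1))
            pixels = _render_cell(spec, side, rng)
            split = SPLITS[rng.choice(3, p=fr)]
            records.append(ImageRecord(pixels=pixels, label=label, split=split))
    return records


def imbalanced_profile(base_counts, scale: float = 1.0) -> list[int]:
    """Scale a class-count profile (e.g. a real dataset's training counts),
    flooring at 1 image per class."""
    return [max(1, round(c * scale)) for c in base_counts]


def write_image_folder(records: list[ImageRecord], root: str | Path,
                       class_names: list[str] | None = None) -> Path:
    """Write records as ``root/<class_name>/<uuid>.png`` plus ``splits.csv``.

    PNG keeps the round trip lossless.  File names are deterministic
    (uuid5 of class/index) so a written tree is stable for a given record
    list.
    """
    if not records:
        raise ValueError("no records to write")
    root = Path(root)
    n_classes = max(r.label for r in records) + 1
    if class_names is None:
        class_names = [f"class{i:02d}" for i in range(n_classes)]
    lines = ["path,label,split"]
    counters = [0] * n_classes
    for rec in records:
        cname = class_names[rec.label]
        cdir = root / cname
        cdir.mkdir(parents=True, exist_ok=True)
        fname = f"{uuid.uuid5(_UUID_NS, f'{cname}/{counters[rec.label]}')}.png"
        counters[rec.label] += 1
        Image.fromarray(rec.pixels).save(cdir / fname)
        lines.append(f"{cname}/{fname},{rec.label},{rec.split}")
    (root / "splits.csv").write_text("\n".join(lines) + "\n")
    return root


def read_image_folder(root: str | Path) -> list[ImageRecord]:
    """Read a ``root/<class>/<image>.png`` tree back into records.

    Class labels follow the sorted order of the class folder names.  Splits
    come from ``splits.csv`` when present (default ``train``).  Empty class
    folders raise a warning and are skipped; unreadable files are skipped with
    a log entry.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    splits: dict[str, str] = {}
    csv_path = root / "splits.csv"
    if csv_path.exists():
        for line in csv_path.read_text().splitlines()[1:]:
            path, _, split = line.rsplit(",", 2)
            splits[path] = split
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    records: list[ImageRecord] = []
    for label, cdir in enumerate(class_dirs):
        files = sorted(cdir.iterdir())
        loaded = 0
        for f in files:
            try:
                with Image.open(f) as im:
                    pixels = np.asarray(im.convert("RGB"))
            except Exception:
                logger.warning("skipping non-image file %s", f)
                continue
            rel = f"{cdir.name}/{f.name}"
            records.append(ImageRecord(
                pixels=pixels, label=label,
                split=splits.get(rel, "train")))
            loaded += 1
        if loaded == 0:
            warnings.warn(f"class folder {cdir} contains no readable images; "
                          "skipping", stacklevel=2)
    return records
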