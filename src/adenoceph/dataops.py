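"""Dataset I/O, resizing and keypoint-aware augmentation.

Augmentation follows the study protocol for growing a landmark-annotated
training set: each image yields the original, eight translations (10 px
along the axes, 20 px along the diagonals) and eight rotations about the
image center (evenly spaced over [-20, 20] degrees, zero excluded), i.e.
17 variants per input — 581 inputs become 9877 images. Landmarks are
transformed with the exact continuous affine map; a guard deterministically
halves the magnitude of any variant that would push a landmark out of the
image, so the 17x count law holds for every input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize as sk_resize, warp

from .geometry import LandmarkSet
from .synth import CephSample

__all__ = [
    "AugmentConfig",
    "DatasetSplit",
    "RoiViolationError",
    "UnsupportedShapeError",
    "ManifestParseError",
    "resize_with_landmarks",
    "rotate_sample",
    "translate_sample",
    "augment_dataset",
    "split_dataset",
    "read_manifest",
    "write_manifest",
    "write_dataset",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = ["id", "path", "Ba_x", "Ba_y", "Ar_x", "Ar_y",
                    "Aprime_x", "Aprime_y", "PNS_x", "PNS_y",
                    "true_ratio", "true_label"]


class RoiViolationError(ValueError):
    """A transform would move a landmark outside the image."""


class UnsupportedShapeError(ValueError):
    """Input image shape not supported (non-square)."""


class ManifestParseError(ValueError):
    """Malformed manifest row; the message names the offending line."""


@dataclass(frozen=True)
class AugmentConfig:
    """Rotation/translation augmentation protocol.

    Defaults reproduce the 17-variants-per-image scheme: ``n_rotations``
    evenly spaced angles in [-rotation_limit, rotation_limit] excluding 0,
    four 10 px axial shifts and four (+-20, +-20) diagonal shifts.
    """

    rotation_limit: float = 20.0
    n_rotations: int = 8
    axial_shift: float = 10.0
    diagonal_shift: float = 20.0
    include_original: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_limit <= 0 or self.n_rotations < 0:
            raise ValueError("rotation_limit must be > 0 and n_rotations >= 0")
        if self.axial_shift < 0 or self.diagonal_shift < 0:
            raise ValueError("shifts must be >= 0")

    @property
    def variants_per_image(self) -> int:
        return int(self.include_original) + 8 + self.n_rotations

    def rotation_angles(self) -> List[float]:
        """Evenly spaced angles over the rotation range, zero excluded."""
        if self.n_rotations == 0:
            return []
        grid = np.linspace(-self.rotation_limit, self.rotation_limit,
                           self.n_rotations + 1)
        grid = np.delete(grid, int(np.argmin(np.abs(grid))))
        return [float(a) for a in grid]

    def shifts(self) -> List[Tuple[float, float]]:
        a, d = self.axial_shift, self.diagonal_shift
        return [(a, 0.0), (-a, 0.0), (0.0, a), (0.0, -a),
                (d, d), (d, -d), (-d, d), (-d, -d)]


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partitions of a sample list."""

    train: List[CephSample]
    validation: List[CephSample]
    test: List[CephSample]


def _check_bounds(coords: np.ndarray, size: int, what: str) -> None:
    if coords.min() < 0 or coords.max() > size - 1:
        raise RoiViolationError(f"{what} moves a landmark outside the image")


def _affine_apply(s: CephSample, tform: AffineTransform, what: str,
                  suffix: str) -> CephSample:
    """Warp image and landmarks by the same forward affine map."""
    new_coords = tform(s.landmarks.as_array())
    _check_bounds(np.asarray(new_coords), s.image.shape[0], what)
    img = warp(s.image.astype(np.float64), tform.inverse, order=1, cval=0.0,
               preserve_range=True).astype(np.float32)
    return replace(s, image=img, landmarks=LandmarkSet.from_array(new_coords),
                   id=s.id + suffix, path="")


def resize_with_landmarks(s: CephSample, target: int) -> CephSample:
    """Bilinearly resize a square sample; landmarks scale by target/source.

    Uniform scaling leaves the A/N ratio unchanged, so ``true_ratio`` is
    preserved as-is.
    """
    H, W = s.image.shape
    if H != W:
        raise UnsupportedShapeError(f"expected a square image, got {H}x{W}")
    if target < 8:
        raise ValueError("target size must be >= 8")
    if target == H:
        return s
    img = sk_resize(s.image.astype(np.float64), (target, target), order=1,
                    anti_aliasing=target < H, preserve_range=True)
    factor = target / H
    lms = s.landmarks.transformed(lambda a: a * factor)
    return replace(s, image=np.clip(img, 0.0, 1.0).astype(np.float32),
                   landmarks=lms, path="")


def rotate_sample(s: CephSample, angle: float) -> CephSample:
    """Rotate image and landmarks by ``angle`` degrees about the image center.

    The landmark transform is the exact continuous rotation matrix about
    ((W-1)/2, (H-1)/2); the image is warped bilinearly with zero fill.
    Raises :class:`RoiViolationError` if a landmark would leave the image.
    """
    if angle == 0.0:
        return replace(s, id=s.id + "_rot+0")
    H, W = s.image.shape
    c = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    theta = math.radians(angle)
    # skimage composes left-to-right: (t1 + t2)(p) = t2(t1(p))
    tform = (AffineTransform(translation=-c)
             + AffineTransform(rotation=theta)
             + AffineTransform(translation=c))
    return _affine_apply(s, tform, f"rotation by {angle} deg", f"_rot{angle:+g}")


def translate_sample(s: CephSample, dx: float, dy: float) -> CephSample:
    """Shift image content and landmarks by (dx, dy); vacated pixels are 0."""
    if dx == 0.0 and dy == 0.0:
        return replace(s, id=s.id + "_shift+0+0")
    tform = AffineTransform(translation=(dx, dy))
    return _affine_apply(s, tform, f"translation by ({dx}, {dy})",
                         f"_shift{dx:+g}{dy:+g}")


def _guarded(fn, magnitude_args: Sequence[float], max_halvings: int = 10):
    """Apply ``fn(*args)``, halving the magnitudes until in-bounds."""
    args = list(magnitude_args)
    for _ in range(max_halvings + 1):
        try:
            return fn(*args)
        except RoiViolationError:
            args = [a / 2.0 for a in args]
    raise RoiViolationError(
        f"transform still out of bounds after {max_halvings} halvings")


def augment_dataset(samples: Sequence[CephSample], cfg: AugmentConfig,
                    guard: bool = True) -> List[CephSample]:
    """Expand every sample into ``cfg.variants_per_image`` variants.

    With the guard active the output count is exactly
    ``len(samples) * (include_original + 8 + n_rotations)``: any rotation or
    shift that would move a landmark out of the image has its magnitude
    deterministically halved (at most 10 times) until it is valid.
    """
    out: List[CephSample] = []
    angles = cfg.rotation_angles()
    shifts = cfg.shifts()
    for s in samples:
        if cfg.include_original:
            out.append(replace(s, id=s.id + "_orig"))
        for dx, dy in shifts:
            if guard:
                out.append(_guarded(lambda a, b: translate_sample(s, a, b), (dx, dy)))
            else:
                out.append(translate_sample(s, dx, dy))
        for ang in angles:
            if guard:
                out.append(_guarded(lambda a: rotate_sample(s, a), (ang,)))
            else:
                out.append(rotate_sample(s, ang))
    return out


def split_dataset(samples: Sequence[CephSample],
                  sizes: Tuple[int, int, int] = (581, 160, 160),
                  seed: int = 0) -> DatasetSplit:
    """Random disjoint split by a seeded uniform permutation."""
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test > len(samples):
        raise ValueError("split sizes exceed the number of samples")
    order = np.random.default_rng(seed).permutation(len(samples))
    pick = lambda lo, hi: [samples[i] for i in order[lo:hi]]
    return DatasetSplit(train=pick(0, n_train),
                        validation=pick(n_train, n_train + n_val),
                        test=pick(n_train + n_val, n_train + n_val + n_test))


# ---------------------------------------------------------------------------
# manifest and image I/O


def write_dataset(samples: Sequence[CephSample], out_dir,
                  image_format: str = "png") -> Path:
    """Write 8-bit grayscale images plus the manifest CSV; returns its path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for s in samples:
        rel = f"images/{s.id}.{image_format}"
        arr = np.round(s.image * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(out / rel)
        s.path = rel
    manifest = out / "manifest.csv"
    write_manifest(samples, manifest)
    return manifest


def write_manifest(samples: Sequence[CephSample], path) -> None:
    """Manifest CSV with pixel coordinates to six decimal places."""
    rows = []
    for s in samples:
        c = s.landmarks.as_array()
        rows.append({
            "id": s.id, "path": s.path,
            "Ba_x": c[0, 0], "Ba_y": c[0, 1], "Ar_x": c[1, 0], "Ar_y": c[1, 1],
            "Aprime_x": c[2, 0], "Aprime_y": c[2, 1],
            "PNS_x": c[3, 0], "PNS_y": c[3, 1],
            "true_ratio": s.true_ratio, "true_label": s.true_label,
        })
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_manifest(path, load_images: bool = True) -> List[CephSample]:
    """Read a manifest CSV (and, optionally, the images it references).

    Raises :class:`ManifestParseError` naming the 1-based file line of any
    malformed row, and ``FileNotFoundError`` for missing image files.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str, "path": str, "true_label": str})
    missing_cols = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ManifestParseError(f"manifest missing columns: {missing_cols}")
    samples: List[CephSample] = []
    coord_cols = MANIFEST_COLUMNS[2:10]
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        vals = row[coord_cols + ["true_ratio"]]
        if vals.isna().any():
            bad = vals.index[vals.isna()][0]
            raise ManifestParseError(f"line {line_no}: missing value for '{bad}'")
        coords = np.asarray(row[coord_cols], dtype=float).reshape(4, 2)
        image = np.zeros((1, 1), dtype=np.float32)
        if load_images:
            img_path = path.parent / str(row["path"])
            if not img_path.exists():
                raise FileNotFoundError(f"line {line_no}: image not found: {img_path}")
            image = np.asarray(Image.open(img_path).convert("L"),
                               dtype=np.float32) / 255.0
        samples.append(CephSample(
            image=image, landmarks=LandmarkSet.from_array(coords),
            true_ratio=float(row["true_ratio"]), true_label=str(row["true_label"]),
            id=str(row["id"]), path=str(row["path"])))
    return samples
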