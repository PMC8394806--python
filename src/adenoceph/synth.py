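"""Synthetic lateral-cephalogram generator with exact landmark ground truth.

Real pediatric cephalograms cannot ship with the package, so this module
renders images that carry the same *geometric* task structure: a bright,
straight skull-base (clivus) ridge whose endpoints are Ba and Ar, a hard
palate wedge whose posterior tip is PNS, and a smooth adenoid soft-tissue
bulge whose point of maximal convexity is A'. The landmark geometry is
constructed first — so the true A/N ratio is exact by construction — and the
image is rendered from it, then degraded with Gaussian blur and noise.

Severity strata mirror a clinical case mix of 651 normal / 197 moderate /
53 severe; normal ratios are drawn from [0.25, 0.58] and hypertrophic ones
from [0.62, 0.95], leaving a gap around the 0.6 decision threshold so labels
stay unambiguous under small landmark noise (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import LandmarkSet, Point2D, classify_ah, compute_an

__all__ = ["SynthConfig", "CephSample", "generate_case", "generate_dataset"]

#: Clinical case-mix counts the default class proportions are taken from.
CLASS_COUNTS = {"normal": 651, "moderate": 197, "severe": 53}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic-cephalogram generator.

    ``margin`` keeps every landmark at least that many pixels from the image
    border, so downstream rotation/translation augmentation can keep the
    region of interest inside the image. Intensity parameters are in [0, 1]
    units; geometric layout parameters are fractions of ``image_size``.
    """

    image_size: int = 256
    ratio_range_normal: Tuple[float, float] = (0.25, 0.58)
    ratio_range_moderate: Tuple[float, float] = (0.62, 0.75)
    ratio_range_severe: Tuple[float, float] = (0.75, 0.95)
    class_mix: Tuple[float, float, float] = (
        CLASS_COUNTS["normal"], CLASS_COUNTS["moderate"], CLASS_COUNTS["severe"])
    noise_sd: float = 0.03
    blur_sigma: float = 1.0
    margin: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.ratio_range_normal, self.ratio_range_moderate,
                       self.ratio_range_severe):
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("ratio ranges must be within (0, 1) and increasing")
        if self.margin >= self.image_size / 2:
            raise ValueError("margin must be smaller than image_size / 2")
        if any(c < 0 for c in self.class_mix) or sum(self.class_mix) <= 0:
            raise ValueError("class_mix must be non-negative with positive sum")

    @property
    def mix_probabilities(self) -> np.ndarray:
        p = np.asarray(self.class_mix, dtype=float)
        return p / p.sum()

    @classmethod
    def scaled(cls, image_size: int, **overrides) -> "SynthConfig":
        """Config with border margin and blur scaled to a smaller canvas."""
        defaults = dict(image_size=image_size, margin=max(4, image_size // 8),
                        blur_sigma=max(0.5, image_size / 256.0))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class CephSample:
    """One image with its landmark ground truth and provenance."""

    image: np.ndarray  # (S, S) float32 in [0, 1]
    landmarks: LandmarkSet
    true_ratio: float
    true_label: str
    id: str
    path: str = ""

    def validate(self, margin: Optional[int] = None) -> None:
        """Re-check the sample invariants; raises AssertionError on failure."""
        s = self.image.shape[0]
        assert self.image.ndim == 2 and self.image.shape[1] == s
        assert float(self.image.min()) >= 0.0 and float(self.image.max()) <= 1.0
        coords = self.landmarks.as_array()
        if margin is not None:
            assert coords.min() >= margin and coords.max() <= s - 1 - margin, \
                f"landmark outside margin box in {self.id}"
        assert self.true_label == classify_ah(self.true_ratio)
        measured = compute_an(self.landmarks).ratio
        assert abs(measured - self.true_ratio) < 0.01, \
            f"ground-truth closure violated: {measured} vs {self.true_ratio}"


def _sample_landmarks(cfg: SynthConfig, target_ratio: float,
                      rng: np.random.Generator) -> LandmarkSet:
    """Draw a landmark configuration whose A/N ratio equals target_ratio."""
    S = cfg.image_size
    lo, hi = cfg.margin, S - 1 - cfg.margin

    def in_box(*pts) -> bool:
        return all(lo <= v <= hi for p in pts for v in p)

    for _ in range(100):
        # clivus chord: Ar superior, Ba inferior-anterior along the slope
        ar = np.array([rng.uniform(0.52, 0.64), rng.uniform(0.26, 0.36)]) * S
        phi = math.radians(rng.uniform(15.0, 35.0))
        length = rng.uniform(0.28, 0.38) * S
        ba = ar + length * np.array([-math.sin(phi), math.cos(phi)])
        d = (ar - ba) / np.linalg.norm(ar - ba)
        n = np.array([d[1], -d[0]])
        if n[0] > 0:  # anterior (towards the face) is smaller x
            n = -n
        # foot of A' on the chord, nasopharyngeal span towards PNS
        foot = ba + rng.uniform(0.35, 0.65) * (ar - ba)
        span = rng.uniform(0.18, 0.30) * S
        beta = math.radians(rng.uniform(-20.0, 20.0))
        pns = foot + span * (math.cos(beta) * n + math.sin(beta) * d)
        aprime = foot + (target_ratio * span) * n
        if in_box(ba, ar, aprime, pns):
            lms = LandmarkSet(
                Ba=Point2D(*map(float, ba)), Ar=Point2D(*map(float, ar)),
                Aprime=Point2D(*map(float, aprime)), PNS=Point2D(*map(float, pns)))
            # closure is exact by construction of A and N from the same foot
            return lms
    raise RuntimeError("could not place landmarks inside the margin box "
                       "after 100 attempts; margin too large for image_size?")


def _segment_distance(px: np.ndarray, py: np.ndarray,
                      a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of every pixel to the segment a-b (vectorized)."""
    d = b - a
    L2 = float(d @ d)
    t = ((px - a[0]) * d[0] + (py - a[1]) * d[1]) / L2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * d[0]), py - (a[1] + t * d[1]))


def _render(cfg: SynthConfig, lms: LandmarkSet, rng: np.random.Generator) -> np.ndarray:
    S = cfg.image_size
    py, px = np.mgrid[0:S, 0:S].astype(np.float32)
    ba, ar = lms.Ba.as_array(), lms.Ar.as_array()
    aprime, pns = lms.Aprime.as_array(), lms.PNS.as_array()
    d = (ar - ba) / np.linalg.norm(ar - ba)
    n = np.array([d[1], -d[0]])
    if n[0] > 0:
        n = -n

    img = np.full((S, S), 0.10, dtype=np.float32)

    # clivus ridge: bright band along the Ba-Ar segment
    ridge_w = 0.020 * S
    img += 0.75 * np.exp(-(_segment_distance(px, py, ba, ar) / ridge_w) ** 2)
    # condyle knob at Ar and a broader, fainter knob at Ba make the two
    # ridge endpoints visually distinct
    img += 0.55 * np.exp(-(np.hypot(px - ar[0], py - ar[1]) / (0.022 * S)) ** 2)
    img += 0.30 * np.exp(-(np.hypot(px - ba[0], py - ba[1]) / (0.034 * S)) ** 2)

    # hard-palate wedge: a tapering bright band whose posterior tip is PNS,
    # extending anteriorly (continuing the foot -> PNS direction)
    foot = compute_an(lms).foot.as_array()
    pdir = pns - foot
    pdir = pdir / np.linalg.norm(pdir)
    t_along = (px - pns[0]) * pdir[0] + (py - pns[1]) * pdir[1]
    perp = np.abs((px - pns[0]) * pdir[1] - (py - pns[1]) * pdir[0])
    t_clip = np.clip(t_along, 0.0, 0.30 * S)
    half_w = 0.006 * S + 0.05 * t_clip
    inside = (t_along > -0.01 * S) & (t_along < 0.30 * S)
    img += np.where(inside, 0.65 * np.exp(-(perp / np.maximum(half_w, 1e-3)) ** 2), 0.0)

    # adenoid bulge: soft elliptical pad rising from the clivus line; its
    # extreme point along the line normal is exactly A'
    A = float(np.linalg.norm(aprime - foot))
    r = max(0.8 * A, 0.02 * S)
    center = aprime - r * n
    u = (px - center[0]) * d[0] + (py - center[1]) * d[1]
    v = (px - center[0]) * n[0] + (py - center[1]) * n[1]
    rho = np.sqrt((u / (1.7 * r)) ** 2 + (v / r) ** 2)
    img += 0.38 * np.exp(-rho ** 4)

    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, cfg.blur_sigma)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_case(cfg: SynthConfig, target_ratio: float,
                  rng: np.random.Generator, sample_id: str = "synth") -> CephSample:
    """Render one synthetic cephalogram with the requested true A/N ratio.

    Deterministic given the generator state; the emitted landmarks reproduce
    ``target_ratio`` exactly under :func:`adenoceph.geometry.compute_an`.
    """
    if not (0.0 < target_ratio < 1.0):
        raise ValueError(f"target_ratio must be in (0, 1), got {target_ratio}")
    lms = _sample_landmarks(cfg, target_ratio, rng)
    img = _render(cfg, lms, rng)
    return CephSample(image=img, landmarks=lms, true_ratio=float(target_ratio),
                      true_label=classify_ah(target_ratio), id=sample_id)


def generate_dataset(cfg: SynthConfig, n: int,
                     out_dir=None, rng: Optional[np.random.Generator] = None,
                     id_prefix: str = "synth"):
    """Generate ``n`` samples with the configured severity mix.

    Class labels are drawn from ``class_mix`` and per-class ratios uniformly
    from that class's range. If ``out_dir`` is given, 8-bit grayscale PNGs
    and a manifest CSV are written there; the manifest path is recorded on
    each sample. Returns the list of samples.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ranges = (cfg.ratio_range_normal, cfg.ratio_range_moderate, cfg.ratio_range_severe)
    probs = cfg.mix_probabilities
    samples: List[CephSample] = []
    for i in range(n):
        stratum = int(rng.choice(3, p=probs))
        lo, hi = ranges[stratum]
        ratio = float(rng.uniform(lo, hi))
        samples.append(generate_case(cfg, ratio, rng,
                                     sample_id=f"{id_prefix}_{i:06d}"))
    if out_dir is not None:
        from .dataops import write_dataset
        write_dataset(samples, out_dir)
    return samples
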