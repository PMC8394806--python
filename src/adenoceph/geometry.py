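"""Fujioka A/N ratio geometry.

The adenoid–nasopharyngeal (A/N) ratio is measured on a lateral cephalogram
from four landmarks:

* ``Ba`` (basion) and ``Ar`` (articulare) define the skull-base chord that
  stands in for the tangent to the occipital slope,
* ``A'`` is the point of maximal convexity of the adenoid shadow,
* ``PNS`` is the posterior nasal spine.

``A`` is the perpendicular distance from ``A'`` to the Ba–Ar line; ``N`` is
the distance from ``PNS`` to the perpendicular foot of ``A'`` on that line.
An A/N ratio strictly above 0.6 is read as suspected adenoid hypertrophy.

Coordinates are continuous pixels, 0-based, origin at the top-left corner,
x rightward, y downward; an integer coordinate addresses a pixel center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Tuple

import numpy as np

__all__ = [
    "AH_THRESHOLD",
    "KEYPOINT_NAMES",
    "Point2D",
    "Line2D",
    "LandmarkSet",
    "ANMeasurement",
    "InvalidGeometryError",
    "UndefinedRatioError",
    "point_line_distance",
    "perpendicular_foot",
    "compute_an",
    "classify_ah",
]

#: Decision threshold on the A/N ratio (strictly greater -> hypertrophic).
AH_THRESHOLD = 0.6

#: Canonical keypoint order used throughout the package.
KEYPOINT_NAMES = ("Ba", "Ar", "Aprime", "PNS")


class InvalidGeometryError(ValueError):
    """A geometric construction is degenerate (e.g. a line through one point)."""


class UndefinedRatioError(ZeroDivisionError):
    """The nasopharyngeal span N is zero, so A/N is undefined."""


@dataclass(frozen=True)
class Point2D:
    """A continuous pixel coordinate (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidGeometryError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def __iter__(self) -> Iterator[float]:
        yield self.x
        yield self.y


@dataclass(frozen=True)
class Line2D:
    """An infinite line through two distinct points."""

    p: Point2D
    q: Point2D

    def __post_init__(self) -> None:
        if self.p.x == self.q.x and self.p.y == self.q.y:
            raise InvalidGeometryError("line defined by two coincident points")

    @property
    def direction(self) -> np.ndarray:
        d = self.q.as_array() - self.p.as_array()
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class LandmarkSet:
    """The four Fujioka landmarks of one cephalogram."""

    Ba: Point2D
    Ar: Point2D
    Aprime: Point2D
    PNS: Point2D

    def __post_init__(self) -> None:
        if self.Ba.x == self.Ar.x and self.Ba.y == self.Ar.y:
            raise InvalidGeometryError("Ba and Ar coincide; skull-base line undefined")

    def as_array(self) -> np.ndarray:
        """(4, 2) array in canonical order Ba, Ar, A', PNS."""
        return np.array(
            [list(self.Ba), list(self.Ar), list(self.Aprime), list(self.PNS)],
            dtype=float,
        )

    @classmethod
    def from_array(cls, a) -> "LandmarkSet":
        a = np.asarray(a, dtype=float)
        if a.shape != (4, 2):
            raise ValueError(f"expected (4, 2) landmark array, got {a.shape}")
        pts = [Point2D(float(x), float(y)) for x, y in a]
        return cls(*pts)

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn: (4,2) array -> (4,2) array`` to all landmarks jointly."""
        return LandmarkSet.from_array(fn(self.as_array()))


@dataclass(frozen=True)
class ANMeasurement:
    """Adenoid depth A, nasopharyngeal span N, their ratio and the AH label."""

    A: float
    N: float
    ratio: float
    label: str  # "normal" | "hypertrophic"
    foot: Point2D  # perpendicular foot of A' on the Ba–Ar line


def point_line_distance(p: Point2D, line: Line2D) -> float:
    """Perpendicular Euclidean distance from ``p`` to the infinite line."""
    a = line.p.as_array()
    d = line.q.as_array() - a
    norm = np.linalg.norm(d)
    # Line2D guarantees norm > 0
    cross = d[0] * (p.y - a[1]) - d[1] * (p.x - a[0])
    return float(abs(cross) / norm)


def perpendicular_foot(p: Point2D, line: Line2D) -> Point2D:
    """Orthogonal projection of ``p`` onto the infinite line."""
    a = line.p.as_array()
    d = line.q.as_array() - a
    t = float(np.dot(p.as_array() - a, d) / np.dot(d, d))
    foot = a + t * d
    return Point2D(float(foot[0]), float(foot[1]))


def classify_ah(ratio: float, threshold: float = AH_THRESHOLD) -> str:
    """Binary AH call from an A/N ratio; strictly greater than the threshold."""
    if ratio < 0:
        raise ValueError(f"A/N ratio must be non-negative, got {ratio}")
    return "hypertrophic" if ratio > threshold else "normal"


def compute_an(lm: LandmarkSet, threshold: float = AH_THRESHOLD) -> ANMeasurement:
    """Compute the Fujioka A/N measurement from the four landmarks.

    ``A`` is the perpendicular distance from A' to the Ba–Ar line, ``N`` the
    Euclidean distance from PNS to the perpendicular foot of A' on that line.
    Both are rigid-motion invariant and scale together, so the ratio is
    invariant under similarity transforms of the landmark set.

    Raises
    ------
    InvalidGeometryError
        If Ba and Ar coincide (enforced by :class:`LandmarkSet`).
    UndefinedRatioError
        If PNS coincides with the foot (N = 0).
    """
    line = Line2D(lm.Ba, lm.Ar)
    A = point_line_distance(lm.Aprime, line)
    foot = perpendicular_foot(lm.Aprime, line)
    N = lm.PNS.distance_to(foot)
    if N == 0.0:
        raise UndefinedRatioError("PNS coincides with the foot of A'; N = 0")
    ratio = A / N
    return ANMeasurement(A=A, N=N, ratio=ratio, label=classify_ah(ratio, threshold), foot=foot)


def landmarks_to_ratio(coords) -> Tuple[float, str]:
    """Convenience: (4,2) array in canonical order -> (ratio, label)."""
    m = compute_an(LandmarkSet.from_array(coords))
    return m.ratio, m.label
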