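"""Exact planar geometry primitives for annulus assignment.

Everything downstream — assigning a cell soma to the concentric ring that
contains the majority of its area, and the area bookkeeping behind density
estimates — reduces to one primitive: the area of the lens formed by two
intersecting disks. That area has a closed form, so all assignments are
analytic and deterministic; a Monte-Carlo pixel-sampling estimator exists
in the test suite purely as an independent oracle.

Coordinates are continuous Cartesian micrometres; distances are Euclidean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "InvalidAnnulusError",
    "Point2D",
    "Disk",
    "circle_circle_intersection_area",
    "disk_fraction_in_annulus",
    "lens_area",
]


class GeometryError(ValueError):
    """Raised for geometrically invalid inputs (non-finite, non-positive radii)."""


class InvalidAnnulusError(GeometryError):
    """Raised when an annulus is specified with inner radius >= outer radius."""


@dataclass(frozen=True)
class Point2D:
    """A point in the tissue plane, in µm from the field's lower-left corner."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"point coordinates must be finite, got ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Disk:
    """A disk (centre + radius, µm): a plaque footprint or a cell soma."""

    centre: Point2D
    radius: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.radius) or self.radius <= 0:
            raise GeometryError(f"disk radius must be finite and > 0, got {self.radius}")

    @property
    def area(self) -> float:
        return math.pi * self.radius**2


def lens_area(big_r, r, d):
    """Intersection area of two disks with radii ``big_r`` and ``r`` at centre distance ``d``.

    Vectorised over numpy arrays (shapes broadcast); ``big_r`` may be 0, in
    which case the intersection is empty. Used both for the scalar public
    API and for batch annulus assignment in the profiler.
    """
    big_r = np.asarray(big_r, dtype=float)
    r = np.asarray(r, dtype=float)
    d = np.asarray(d, dtype=float)

    r_small = np.minimum(big_r, r)
    r_large = np.maximum(big_r, r)

    disjoint = d >= big_r + r
    contained = d <= r_large - r_small

    # Evaluate the partial-overlap branch on (r_small, r_large) so the result
    # is bit-identical under argument swap; guard against division by zero
    # and acos domain excursions from rounding (masked entries overwritten).
    d_safe = np.where(d > 0, d, 1.0)
    r_large_safe = np.where(r_large > 0, r_large, 1.0)
    r_small_safe = np.where(r_small > 0, r_small, 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        cos_l = np.clip((d_safe**2 + r_large**2 - r_small**2) / (2.0 * d_safe * r_large_safe), -1.0, 1.0)
        cos_s = np.clip((d_safe**2 + r_small**2 - r_large**2) / (2.0 * d_safe * r_small_safe), -1.0, 1.0)
        radicand = (-d + r_small + r_large) * (d + r_large - r_small) * (d - r_large + r_small) * (d + r_large + r_small)
        partial = (
            r_large**2 * np.arccos(cos_l)
            + r_small**2 * np.arccos(cos_s)
            - 0.5 * np.sqrt(np.maximum(radicand, 0.0))
        )

    out = np.where(disjoint, 0.0, np.where(contained, math.pi * r_small**2, partial))
    if out.ndim == 0:
        return float(out)
    return out


def circle_circle_intersection_area(d1: Disk, d2: Disk) -> float:
    """Exact lens area (µm²) of the intersection of two disks.

    Symmetric in its arguments; lies in [0, π·min(r1, r2)²]. Non-finite
    centre distances are impossible by construction of :class:`Disk` /
    :class:`Point2D`, which validate their fields.
    """
    d = d1.centre.distance_to(d2.centre)
    return float(lens_area(d1.radius, d2.radius, d))


def disk_fraction_in_annulus(
    cell: Disk, centre: Point2D, inner_r: float, outer_r: float
) -> float:
    """Fraction of a cell disk's area lying inside the annulus [inner_r, outer_r).

    The annulus is concentric about ``centre``; ``inner_r`` may be 0 (a full
    disk). Computed as the difference of two lens areas divided by the cell
    area, so the fractions of any concentric partition covering the cell sum
    to 1 exactly (up to rounding).
    """
    if not (math.isfinite(inner_r) and math.isfinite(outer_r)):
        raise GeometryError("annulus radii must be finite")
    if inner_r < 0 or inner_r >= outer_r:
        raise InvalidAnnulusError(
            f"annulus requires 0 <= inner_r < outer_r, got [{inner_r}, {outer_r})"
        )
    d = cell.centre.distance_to(centre)
    outer = lens_area(outer_r, cell.radius, d)
    inner = lens_area(inner_r, cell.radius, d) if inner_r > 0 else 0.0
    return float((outer - inner) / cell.area)
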