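"""Axis-aligned bounding boxes (AABBs) and their interval arithmetic.

An AABB is the universal geometric currency of this package: every neuritic
region (axonal or dendritic) is one or more AABBs, and every detected
axonal-dendritic contact is the AABB intersection of two region boxes.

Intervals are closed: two boxes whose faces merely touch (equal coordinates)
count as intersecting, with zero overlap volume.  Densely packed neuritic
regions routinely share face coordinates, so the degenerate case is a
first-class citizen rather than an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

Point3 = Tuple[float, float, float]

#: Axis indices used throughout the package.
X, Y, Z = 0, 1, 2
AXIS_NAMES = ("X", "Y", "Z")


def axis_from_name(name: str) -> int:
    """Map an axis label ('X'/'Y'/'Z', case-insensitive) to its index."""
    try:
        return AXIS_NAMES.index(name.upper())
    except ValueError:
        raise ValueError(f"unknown axis name {name!r}; expected one of X, Y, Z") from None


@dataclass(frozen=True, slots=True)
class AABB:
    """An axis-aligned box given by per-dimension closed coordinate intervals.

    Parameters
    ----------
    lo, hi
        Minimum and maximum corner, in micrometres.  ``lo[d] <= hi[d]`` must
        hold in every dimension; zero-thickness faces are allowed.
    """

    lo: Point3
    hi: Point3

    def __post_init__(self) -> None:
        lo = tuple(float(v) for v in self.lo)
        hi = tuple(float(v) for v in self.hi)
        if len(lo) != 3 or len(hi) != 3:
            raise ValueError("AABB corners must be 3D points")
        for d in range(3):
            if not lo[d] <= hi[d]:
                raise ValueError(
                    f"AABB min exceeds max in {AXIS_NAMES[d]}: {lo[d]} > {hi[d]}"
                )
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @classmethod
    def from_bounds(cls, xmin: float, xmax: float, ymin: float, ymax: float,
                    zmin: float, zmax: float) -> "AABB":
        return cls((xmin, ymin, zmin), (xmax, ymax, zmax))

    @property
    def bounds(self) -> Tuple[float, float, float, float, float, float]:
        """(xmin, xmax, ymin, ymax, zmin, zmax), the flat on-disk order."""
        return (self.lo[0], self.hi[0], self.lo[1], self.hi[1], self.lo[2], self.hi[2])

    @property
    def extents(self) -> Point3:
        return tuple(self.hi[d] - self.lo[d] for d in range(3))  # type: ignore[return-value]

    @property
    def volume(self) -> float:
        e = self.extents
        return e[0] * e[1] * e[2]

    def translate(self, offset: Point3) -> "AABB":
        return AABB(
            tuple(self.lo[d] + offset[d] for d in range(3)),  # type: ignore[arg-type]
            tuple(self.hi[d] + offset[d] for d in range(3)),  # type: ignore[arg-type]
        )

    def contains_point(self, p: Point3) -> bool:
        return all(self.lo[d] <= p[d] <= self.hi[d] for d in range(3))

    def contains_box(self, other: "AABB") -> bool:
        return all(
            self.lo[d] <= other.lo[d] and other.hi[d] <= self.hi[d] for d in range(3)
        )


def aabb_intersect(a: AABB, b: AABB) -> Optional[AABB]:
    """Intersection of two boxes, or None when they are disjoint.

    The test rejects early on the first dimension in which one box's minimum
    exceeds the other's maximum; when all three closed-interval tests pass the
    per-dimension intersection is returned.  Face-touching boxes intersect
    with zero volume.
    """
    alo, ahi, blo, bhi = a.lo, a.hi, b.lo, b.hi
    lo0 = alo[0] if alo[0] > blo[0] else blo[0]
    hi0 = ahi[0] if ahi[0] < bhi[0] else bhi[0]
    if lo0 > hi0:
        return None
    lo1 = alo[1] if alo[1] > blo[1] else blo[1]
    hi1 = ahi[1] if ahi[1] < bhi[1] else bhi[1]
    if lo1 > hi1:
        return None
    lo2 = alo[2] if alo[2] > blo[2] else blo[2]
    hi2 = ahi[2] if ahi[2] < bhi[2] else bhi[2]
    if lo2 > hi2:
        return None
    return AABB((lo0, lo1, lo2), (hi0, hi1, hi2))


def bounding_box(boxes: Iterable[AABB]) -> Optional[AABB]:
    """Smallest AABB enclosing all given boxes; None for an empty iterable."""
    boxes = list(boxes)
    if not boxes:
        return None
    lo = tuple(min(b.lo[d] for b in boxes) for d in range(3))
    hi = tuple(max(b.hi[d] for b in boxes) for d in range(3))
    return AABB(lo, hi)  # type: ignore[arg-type]
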