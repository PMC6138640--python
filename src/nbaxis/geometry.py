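"""Exact geometric primitives for division-axis measurement.

All quantities live in physical space (micrometres) after conversion from
voxel indices with the stack's anisotropic spacing; angles computed on raw
voxel indices would be biased by the ~3x z anisotropy of typical confocal
stacks.

Coordinate convention: axis order is (z, y, x) everywhere, 0-based voxel
indices, voxel-centre convention (index i maps to i * spacing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "Point3D",
    "Axis3D",
    "VoxelSpacing",
    "voxel_to_physical",
    "axis_angle",
    "unit_vector",
]


@dataclass(frozen=True)
class Point3D:
    """A point in physical space, micrometres, ordered (z, y, x)."""

    z: float
    y: float
    x: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.z, self.y, self.x)):
            raise ValueError(f"non-finite coordinate in {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.z, self.y, self.x], dtype=float)

    @classmethod
    def from_array(cls, a: Iterable[float]) -> "Point3D":
        z, y, x = (float(v) for v in a)
        return cls(z, y, x)


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical size of one voxel along each axis, micrometres (dz, dy, dx)."""

    dz: float
    dy: float
    dx: float

    def __post_init__(self) -> None:
        if not all(d > 0 and math.isfinite(d) for d in (self.dz, self.dy, self.dx)):
            raise ValueError(f"spacing must be strictly positive and finite, got {self!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.dz, self.dy, self.dx], dtype=float)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return self.dz * self.dy * self.dx


@dataclass(frozen=True)
class Axis3D:
    """An oriented division (or cue) axis: apical pole ``a`` to basal pole ``b``."""

    a: Point3D
    b: Point3D

    def __post_init__(self) -> None:
        if self.magnitude == 0.0:
            raise ValueError("degenerate axis: apical and basal poles coincide")

    @property
    def vector(self) -> np.ndarray:
        """Displacement b - a as a (z, y, x) array in µm."""
        return self.b.as_array() - self.a.as_array()

    @property
    def magnitude(self) -> float:
        """Euclidean length |b - a| in µm."""
        v = self.b.as_array() - self.a.as_array()
        return float(np.sqrt(np.sum(v * v)))

    @classmethod
    def from_arrays(cls, a: Iterable[float], b: Iterable[float]) -> "Axis3D":
        return cls(Point3D.from_array(a), Point3D.from_array(b))


def voxel_to_physical(index: tuple[int, int, int], spacing: VoxelSpacing) -> Point3D:
    """Convert a 0-based voxel index (z, y, x) to its centre in physical µm.

    Raises ``ValueError`` for negative indices.
    """
    iz, iy, ix = index
    if iz < 0 or iy < 0 or ix < 0:
        raise ValueError(f"negative voxel index {index}")
    return Point3D(iz * spacing.dz, iy * spacing.dy, ix * spacing.dx)


def unit_vector(axis: Axis3D) -> Point3D:
    """Unit direction of an axis, (b - a) / |b - a|."""
    v = axis.vector
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("degenerate axis: zero magnitude")
    return Point3D.from_array(v / n)


def axis_angle(axis1: Axis3D, axis2: Axis3D) -> float:
    """Angle between two oriented 3D axes, degrees in [0, 180].

    alpha = arccos( v1 . v2 / (|v1| |v2|) ) with v = b - a.  The cosine is
    clamped to [-1, 1] so rounding can never produce a NaN; the result is
    not folded at 90 deg (the axes are oriented apical -> basal).
    """
    v1 = axis1.vector
    v2 = axis2.vector
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("degenerate axis: zero magnitude")
    c = float(np.dot(v1, v2)) / (n1 * n2)
    c = min(1.0, max(-1.0, c))
    return math.degrees(math.acos(c))
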