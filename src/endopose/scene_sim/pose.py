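"""6D pose and rotation-range types shared by the whole package.

Conventions (fixed once, used everywhere):

* World frame: right-handed, camera at the origin looking down ``-Z``,
  ``+X`` to the right, ``+Y`` up.
* Image frame: ``x`` rightward, ``y`` downward, origin at the top-left,
  pixel centers at integer coordinates.
* Rotations ``rx, ry, rz`` are intrinsic, applied about the model's own
  axes in X -> Y -> Z order, in degrees.
* ``scale`` maps to distance along the optical axis so that projected
  linear size is proportional to ``scale`` (1.0 = the reference distance).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

AXES = ("x", "y", "z")


@dataclass
class Pose6D:
    """Target state: image-plane position (px), scale factor, rotations (deg)."""

    tx: float
    ty: float
    scale: float
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    def with_rotations(self, r) -> "Pose6D":
        rx, ry, rz = (float(v) for v in r)
        return replace(self, rx=rx, ry=ry, rz=rz)

    def as_dict(self) -> dict:
        return {"tx": self.tx, "ty": self.ty, "scale": self.scale,
                "rx": self.rx, "ry": self.ry, "rz": self.rz}


class AxisSpec:
    """Per-axis rotation behaviour: a (lo, hi) range, mask-derived, or irrelevant."""

    RANGE = "range"
    MASK = "mask-derived"
    IRRELEVANT = "irrelevant"

    def __init__(self, kind: str, lo: float | None = None, hi: float | None = None):
        if kind == self.RANGE:
            if lo is None or hi is None or not lo < hi:
                raise ValueError(f"range axis needs lo < hi, got ({lo}, {hi})")
        elif kind not in (self.MASK, self.IRRELEVANT):
            raise ValueError(f"unknown axis kind {kind!r}")
        self.kind = kind
        self.lo = lo
        self.hi = hi

    @classmethod
    def range(cls, lo: float, hi: float) -> "AxisSpec":
        return cls(cls.RANGE, lo, hi)

    @classmethod
    def mask_derived(cls) -> "AxisSpec":
        return cls(cls.MASK)

    @classmethod
    def irrelevant(cls) -> "AxisSpec":
        return cls(cls.IRRELEVANT)

    @property
    def is_range(self) -> bool:
        return self.kind == self.RANGE

    def __repr__(self):
        if self.is_range:
            return f"AxisSpec.range({self.lo}, {self.hi})"
        return f"AxisSpec({self.kind!r})"


@dataclass
class RotationRangeSpec:
    """Which rotations vary (and over what range), per axis.

    Only axes with a numeric range are sampled by the simulator and
    predicted by the rotation classifier; ``mask-derived`` axes come from
    the silhouette ellipse and ``irrelevant`` axes are fixed at zero
    (rotational symmetry).
    """

    x: AxisSpec
    y: AxisSpec
    z: AxisSpec

    def axis(self, name: str) -> AxisSpec:
        return getattr(self, name)

    @property
    def range_axes(self) -> list[str]:
        return [a for a in AXES if self.axis(a).is_range]

    def contains(self, axis: str, value: float) -> bool:
        s = self.axis(axis)
        if not s.is_range:
            return True
        return s.lo <= value <= s.hi

    def clip(self, axis: str, value: float) -> float:
        s = self.axis(axis)
        if not s.is_range:
            return value
        return float(np.clip(value, s.lo, s.hi))


def catheter_ranges() -> RotationRangeSpec:
    """Rigid-instrument profile: X predicted in [-40, 10] deg, Y from the
    mask, Z irrelevant by rotational symmetry."""
    return RotationRangeSpec(
        x=AxisSpec.range(-40.0, 10.0),
        y=AxisSpec.mask_derived(),
        z=AxisSpec.irrelevant(),
    )


def prostate_ranges() -> RotationRangeSpec:
    return RotationRangeSpec(
        x=AxisSpec.range(-15.0, 20.0),
        y=AxisSpec.range(-25.0, 25.0),
        z=AxisSpec.range(-5.0, 15.0),
    )


def kidney_ranges() -> RotationRangeSpec:
    return RotationRangeSpec(
        x=AxisSpec.range(-10.0, 10.0),
        y=AxisSpec.range(-10.0, 10.0),
        z=AxisSpec.range(-10.0, 10.0),
    )


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Intrinsic X -> Y -> Z rotation, angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz
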