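"""Watertight triangle meshes for the simulated targets and instruments."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

ORGAN_ELLIPSOID = "organ-ellipsoid"
INSTRUMENT_CYLINDER = "instrument-cylinder"
CUSTOM = "custom"

# Mounting rotation applied after the pose rotations, per mesh kind.
# The instrument cylinder is built along its model Z axis (so rz is the
# symmetric spin); the mount lays the long axis horizontally in the image
# (model Z -> world X), sends model Y to the optical axis (so ry is the
# in-plane, mask-recoverable tilt) and model X to world Y (so rx tilts the
# tip toward / away from the camera).
_CYLINDER_MOUNT = np.array([[0.0, 0.0, 1.0],
                            [1.0, 0.0, 0.0],
                            [0.0, 1.0, 0.0]])


@dataclass
class MeshModel:
    """Triangulated closed surface in model units, centered at its centroid."""

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray     # (F, 3) int
    kind: str = CUSTOM

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")

    @property
    def mount(self) -> np.ndarray:
        if self.kind == INSTRUMENT_CYLINDER:
            return _CYLINDER_MOUNT
        return np.eye(3)

    @property
    def extents(self) -> np.ndarray:
        return self.vertices.max(axis=0) - self.vertices.min(axis=0)

    @property
    def radius(self) -> float:
        """Max vertex distance from the centroid, in model units."""
        return float(np.linalg.norm(self.vertices, axis=1).max())

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def _center(vertices: np.ndarray) -> np.ndarray:
    return vertices - vertices.mean(axis=0)


def make_mesh(kind: str, params: dict | None = None, seed: int = 0) -> MeshModel:
    """Build a watertight target mesh.

    Parameters
    ----------
    kind:
        ``"organ-ellipsoid"`` (params: ``semi_axes`` triple, ``bumpiness``,
        ``subdivisions``), ``"instrument-cylinder"`` (params: ``radius``,
        ``length``, ``sections``) or ``"custom"`` (params: ``vertices``,
        ``faces``).
    seed:
        Drives the optional random surface perturbation of the ellipsoid.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == ORGAN_ELLIPSOID:
        semi = np.asarray(params.get("semi_axes", (1.0, 0.8, 0.7)), dtype=float)
        if semi.shape != (3,) or np.any(semi <= 0):
            raise ValueError(f"ellipsoid semi-axes must be 3 positive values, got {semi}")
        sub = int(params.get("subdivisions", 3))
        bump = float(params.get("bumpiness", 0.0))
        sphere = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
        v = sphere.vertices * semi
        if bump > 0:
            # low-order smooth radial perturbation, seeded
            dirs = sphere.vertices
            coef = rng.normal(0, bump, 6)
            r = 1.0 + (coef[0] * dirs[:, 0] * dirs[:, 1] + coef[1] * dirs[:, 1] * dirs[:, 2]
                       + coef[2] * dirs[:, 0] * dirs[:, 2] + coef[3] * dirs[:, 0] ** 2
                       + coef[4] * dirs[:, 1] ** 2 + coef[5] * dirs[:, 2] ** 2)
            v = v * np.clip(r, 0.6, 1.4)[:, None]
        return MeshModel(_center(v), sphere.faces.copy(), ORGAN_ELLIPSOID)
    if kind == INSTRUMENT_CYLINDER:
        radius = float(params.get("radius", 0.15))
        length = float(params.get("length", 2.0))
        if radius <= 0 or length <= 0:
            raise ValueError(f"cylinder radius/length must be positive, got r={radius}, L={length}")
        sections = int(params.get("sections", 24))
        cyl = trimesh.creation.cylinder(radius=radius, height=length, sections=sections)
        tip_radius = float(params.get("tip_radius", 0.0))
        if tip_radius > 0:
            # balloon tip at the +Z end (a Foley-style catheter): keeps the
            # spin symmetry about the long axis but makes tilts of the tip
            # toward or away from the camera geometrically unambiguous
            tip = trimesh.creation.icosphere(subdivisions=2, radius=tip_radius)
            tip.apply_translation([0.0, 0.0, length / 2.0])
            cyl = trimesh.util.concatenate([cyl, tip])
        max_edge = float(params.get("max_edge", max(length / 10.0, radius)))
        v, f = trimesh.remesh.subdivide_to_size(cyl.vertices, cyl.faces, max_edge=max_edge)
        return MeshModel(_center(v), f, INSTRUMENT_CYLINDER)
    if kind == CUSTOM:
        if "vertices" not in params or "faces" not in params:
            raise ValueError("custom mesh needs explicit vertices and faces")
        return MeshModel(_center(np.asarray(params["vertices"], dtype=float)),
                         params["faces"], CUSTOM)
    raise ValueError(f"unknown mesh kind {kind!r}")
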