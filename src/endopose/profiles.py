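"""Canonical desk-scale study profiles: target mesh + scene configuration
for the two simulated case-study families.

These freeze the conditions used throughout the tests and the
reproduction script, so every entry point renders the same scenes.
"""
from __future__ import annotations

from . import scene_sim as sim


def organ_mesh(seed: int = 0) -> sim.MeshModel:
    """Kidney-like bumpy ellipsoid, unit-scale semi-axes."""
    return sim.make_mesh(sim.ORGAN_ELLIPSOID,
                         {"semi_axes": (1.0, 0.85, 0.75), "bumpiness": 0.15},
                         seed=seed)


def catheter_mesh(seed: int = 0) -> sim.MeshModel:
    """Foley-style catheter: rod with a balloon tip, spin-symmetric about
    its long axis."""
    return sim.make_mesh(sim.INSTRUMENT_CYLINDER,
                         {"radius": 0.20, "length": 2.2, "tip_radius": 0.38},
                         seed=seed)


def organ_scene(size: int = 96, **overrides) -> sim.SceneConfig:
    """Organ scenes: up to two occluding tools, moderate pose jitter."""
    kw = dict(width=size, height=size, max_tools=2, pos_jitter=0.08,
              scale_range=(0.8, 1.2), texture_freq=2.0)
    kw.update(overrides)
    return sim.SceneConfig(**kw)


def catheter_scene(size: int = 64, **overrides) -> sim.SceneConfig:
    """Rigid-instrument scenes: close-up view (stronger perspective), no
    extra tools, coarser texture suited to the thin target."""
    kw = dict(width=size, height=size, max_tools=0, ref_distance=3.2,
              focal_frac=0.22, texture_freq=1.2)
    kw.update(overrides)
    return sim.SceneConfig(**kw)


def sequence_scene(size: int = 96, **overrides) -> sim.SceneConfig:
    """Tracking sequences: organ framing without pose jitter."""
    kw = dict(width=size, height=size, max_tools=0, texture_freq=2.0)
    kw.update(overrides)
    return sim.SceneConfig(**kw)
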