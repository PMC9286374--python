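"""Shared fixtures: small simulated scenes, meshes and sequences.

Everything is generated programmatically at session scope with fixed
seeds, so the suite needs no stored data.
"""
from __future__ import annotations

import numpy as np
import pytest

from endopose import profiles
from endopose.scene_sim import (Pose6D, SceneConfig, generate_dataset,
                                generate_sequence, kidney_ranges)


@pytest.fixture(scope="session")
def organ_mesh():
    return profiles.organ_mesh(seed=0)


@pytest.fixture(scope="session")
def catheter_mesh():
    return profiles.catheter_mesh(seed=0)


@pytest.fixture(scope="session")
def organ_scene():
    return profiles.organ_scene(size=96)


@pytest.fixture(scope="session")
def clean_scene():
    """Organ framing without tools or pose jitter (easy localization)."""
    return profiles.sequence_scene(size=96)


@pytest.fixture(scope="session")
def center_pose(clean_scene):
    cx, cy = clean_scene.center
    return Pose6D(tx=cx, ty=cy, scale=1.0)


@pytest.fixture(scope="session")
def small_dataset(organ_mesh, organ_scene):
    """120 labeled organ scenes at 96x96 (70/15/15 split)."""
    return generate_dataset(organ_mesh, 120, kidney_ranges(), organ_scene, seed=0)


@pytest.fixture(scope="session")
def z_sequence(organ_mesh, clean_scene, center_pose):
    """12-frame sequence rotating at +0.5 deg/frame about Z."""
    return generate_sequence(organ_mesh, center_pose, (0, 0, 0.5), 12,
                             clean_scene, seed=3)


@pytest.fixture(scope="session")
def static_sequence(organ_mesh, clean_scene, center_pose):
    return generate_sequence(organ_mesh, center_pose, (0, 0, 0), 8,
                             clean_scene, seed=4)
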