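"""Scene simulator: meshes, rendering invariants, datasets, sequences."""
import numpy as np
import pandas as pd
import pytest

from endopose.scene_sim import (INSTRUMENT_CYLINDER, ORGAN_ELLIPSOID, AxisSpec,
                                Pose6D, RotationRangeSpec, SceneConfig,
                                TargetOutOfViewError, catheter_ranges,
                                generate_dataset, generate_sequence, make_mesh,
                                render_scene, rotation_matrix, split_sizes)


class TestMakeMesh:
    def test_ellipsoid_centered_and_valid(self):
        mesh = make_mesh(ORGAN_ELLIPSOID, {"semi_axes": (1, 0.8, 0.7)}, seed=0)
        assert np.allclose(mesh.vertices.mean(axis=0), 0, atol=1e-9)
        assert mesh.faces.max() < len(mesh.vertices)
        tm = mesh.as_trimesh()
        assert tm.is_watertight
        # non-degenerate triangles
        assert tm.area_faces.min() > 0

    def test_cylinder_extents(self):
        mesh = make_mesh(INSTRUMENT_CYLINDER, {"radius": 0.1, "length": 2.0}, seed=0)
        assert np.allclose(mesh.extents, [0.2, 0.2, 2.0], atol=1e-9)

    @pytest.mark.parametrize("kind,params", [
        (ORGAN_ELLIPSOID, {"semi_axes": (1, -1, 1)}),
        (INSTRUMENT_CYLINDER, {"radius": -0.1, "length": 2.0}),
        ("no-such-kind", {}),
    ])
    def test_invalid_inputs_rejected(self, kind, params):
        with pytest.raises(ValueError):
            make_mesh(kind, params, seed=0)


class TestRotationMatrix:
    def test_orthonormal(self):
        R = rotation_matrix(17.0, -42.0, 95.0)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_intrinsic_xyz_order(self):
        # composing single-axis matrices in X->Y->Z order
        R = rotation_matrix(10, 20, 30)
        Rx = rotation_matrix(10, 0, 0)
        Ry = rotation_matrix(0, 20, 0)
        Rz = rotation_matrix(0, 0, 30)
        assert np.allclose(R, Rx @ Ry @ Rz, atol=1e-12)


class TestRenderScene:
    def test_deterministic_under_fixed_seed(self, organ_mesh, organ_scene,
                                            center_pose):
        a = render_scene(organ_mesh, center_pose, organ_scene, seed=7)
        b = render_scene(organ_mesh, center_pose, organ_scene, seed=7)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_scale_quadruples_mask_area(self, organ_mesh, clean_scene, center_pose):
        cx, cy = clean_scene.center
        a1 = (render_scene(organ_mesh, center_pose, clean_scene, seed=2).mask == 2).sum()
        half = Pose6D(tx=cx, ty=cy, scale=0.5)
        a2 = (render_scene(organ_mesh, half, clean_scene, seed=2).mask == 2).sum()
        assert a1 / a2 == pytest.approx(4.0, rel=0.05)

    def test_scale_law_monotone(self, organ_mesh, clean_scene):
        cx, cy = clean_scene.center
        areas = [(render_scene(organ_mesh, Pose6D(cx, cy, s), clean_scene,
                               seed=2).mask == 2).sum()
                 for s in (0.5, 0.75, 1.0, 1.25, 1.5)]
        assert all(a < b for a, b in zip(areas, areas[1:]))

    def test_no_tools_means_no_tool_class(self, organ_mesh, clean_scene, center_pose):
        s = render_scene(organ_mesh, center_pose, clean_scene, seed=5)
        assert set(np.unique(s.mask)) <= {0, 2}

    def test_mask_matches_unoccluded_silhouette(self, organ_mesh, organ_scene,
                                                center_pose):
        # with tools disabled the target mask IS the rasterized silhouette
        import dataclasses
        no_tools = dataclasses.replace(organ_scene, max_tools=0)
        s = render_scene(organ_mesh, center_pose, no_tools, seed=6)
        assert s.meta["silhouette_area"] == (s.mask == 2).sum()

    def test_occlusion_cap_respected(self, organ_mesh, organ_scene, center_pose):
        for seed in range(5):
            s = render_scene(organ_mesh, center_pose, organ_scene, seed=seed)
            assert s.meta["occluded_fraction"] <= organ_scene.occlusion_cap + 1e-9

    def test_target_out_of_view_raises(self, organ_mesh, clean_scene):
        with pytest.raises(TargetOutOfViewError):
            render_scene(organ_mesh, Pose6D(tx=-500, ty=-500, scale=1.0),
                         clean_scene, seed=0)

    def test_minimum_frame_size_enforced(self, organ_mesh, center_pose):
        with pytest.raises(ValueError):
            render_scene(organ_mesh, center_pose,
                         SceneConfig(width=16, height=16), seed=0)


class TestGenerateDataset:
    def test_split_floor_arithmetic(self):
        assert split_sizes(100) == (70, 15, 15)
        assert split_sizes(10) == (7, 1, 2)

    def test_labels_within_ranges_and_split(self, catheter_mesh):
        from endopose import profiles
        cfg = profiles.catheter_scene()
        ds = generate_dataset(catheter_mesh, 40, catheter_ranges(), cfg, seed=0)
        m = ds.manifest
        assert m["split"].value_counts().to_dict() == {"train": 28, "val": 6, "test": 6}
        assert m["rx"].between(-40, 10).all()
        assert (m["ry"] == 0).all() and (m["rz"] == 0).all()

    def test_same_seed_reproduces_manifest(self, catheter_mesh):
        from endopose import profiles
        cfg = profiles.catheter_scene()
        a = generate_dataset(catheter_mesh, 20, catheter_ranges(), cfg, seed=3)
        b = generate_dataset(catheter_mesh, 20, catheter_ranges(), cfg, seed=3)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        assert all(np.array_equal(x.image, y.image)
                   for x, y in zip(a.samples, b.samples))

    def test_too_few_samples_rejected(self, catheter_mesh):
        with pytest.raises(ValueError):
            generate_dataset(catheter_mesh, 5, catheter_ranges(), seed=0)

    def test_roundtrip_through_disk(self, tmp_path, catheter_mesh):
        from endopose import profiles
        from endopose.scene_sim import load_manifest
        cfg = profiles.catheter_scene()
        ds = generate_dataset(catheter_mesh, 12, catheter_ranges(), cfg, seed=1,
                              out_dir=tmp_path)
        back = load_manifest(tmp_path / "manifest.csv")
        assert np.array_equal(back.samples[0].image, ds.samples[0].image)
        assert np.array_equal(back.samples[0].mask, ds.samples[0].mask)


class TestGenerateSequence:
    def test_static_rates_keep_pose(self, static_sequence, center_pose):
        assert np.allclose(static_sequence.trajectory, center_pose.rotations)

    def test_linear_ramp(self, organ_mesh, clean_scene, center_pose):
        seq = generate_sequence(organ_mesh, center_pose, (0.2, 0, 0), 10,
                                clean_scene, seed=0)
        assert np.allclose(np.diff(seq.trajectory[:, 0]), 0.2)
        assert len(seq.trajectory) == len(seq.frames) == 10

    def test_clamps_to_range_with_warning(self, organ_mesh, clean_scene, center_pose):
        ranges = RotationRangeSpec(x=AxisSpec.irrelevant(), y=AxisSpec.irrelevant(),
                                   z=AxisSpec.range(-10, 10))
        with pytest.warns(UserWarning, match="clamped"):
            seq = generate_sequence(organ_mesh, center_pose, (0, 0, 0.5), 60,
                                    clean_scene, seed=0, ranges=ranges)
        assert seq.trajectory[-1, 2] == pytest.approx(10.0)

    def test_single_frame_rejected(self, organ_mesh, clean_scene, center_pose):
        with pytest.raises(ValueError):
            generate_sequence(organ_mesh, center_pose, (0, 0, 0), 1,
                              clean_scene, seed=0)


class TestSceneConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        from endopose import profiles
        cfg = profiles.catheter_scene(64)
        cfg.to_yaml(tmp_path / "scene.yaml")
        back = SceneConfig.from_yaml(tmp_path / "scene.yaml")
        assert back == cfg

    def test_shifted_variant_marks_domain_shift(self):
        cfg = SceneConfig().shifted()
        assert cfg.domain_shift and cfg.specular > 0 and cfg.mask_noise > 0
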