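"""Rotation classifier: binning arithmetic, tolerance accuracy, training."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endopose.rotation_net import (AngleBinning, RotConfig, RotModel,
                                   fine_tune, make_binning, predict_rotation,
                                   predict_rotation_batch, tolerance_accuracy,
                                   train_rotation_net)
from endopose.scene_sim import (AxisSpec, RotationRangeSpec, catheter_ranges,
                                generate_dataset, kidney_ranges)
from endopose.nn import softmax


class TestAngleBinning:
    def test_catheter_range_gives_50_classes(self):
        assert make_binning(-40, 10, 1).n_classes == 50

    def test_symmetric_range_arithmetic(self):
        b = make_binning(-10, 10, 1)
        assert b.n_classes == 20
        assert b.encode(0.0) == 10
        assert b.decode(10) == 0.5

    def test_boundary_cases(self):
        b = make_binning(-40, 10, 1)
        assert b.encode(-40) == 0
        assert b.decode(0) == -39.5

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            make_binning(10, -40, 1)
        with pytest.raises(ValueError):
            make_binning(-40, 10, 0)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(-40, 9.999), st.sampled_from([0.5, 1.0, 2.5]))
    def test_roundtrip_within_half_bin(self, angle, width):
        b = make_binning(-40, 10, width)
        assert abs(float(b.decode(b.encode(angle))) - angle) <= width / 2 + 1e-9


class TestToleranceAccuracy:
    def test_direct_count(self):
        assert tolerance_accuracy([0, 7, -3], [0, 0, 0], 5) == pytest.approx(2 / 3)
        assert tolerance_accuracy([0, 7, -3], [0, 0, 0], 10) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_monotone_in_tolerance(self, errs):
        truth = np.zeros(len(errs))
        assert (tolerance_accuracy(errs, truth, 10)
                >= tolerance_accuracy(errs, truth, 5))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tolerance_accuracy([1, 2], [1], 5)


@pytest.fixture(scope="module")
def catheter_toy():
    from endopose import profiles
    ds = generate_dataset(profiles.catheter_mesh(0), 60, catheter_ranges(),
                          profiles.catheter_scene(), seed=5)
    tr = ds.arrays("train")
    va = ds.arrays("val")
    return (tr[0], tr[2]), (va[0], va[2])


class TestTraining:
    def test_single_axis_config_gives_one_head(self, catheter_toy):
        m = train_rotation_net(*catheter_toy, catheter_ranges(),
                               RotConfig(epochs=1, head_width=32, seed=0))
        assert m.axes == ["x"]
        assert m.binnings["x"].n_classes == 50

    def test_three_axis_config_gives_three_heads(self, small_dataset):
        tr = small_dataset.arrays("train")
        va = small_dataset.arrays("val")
        m = train_rotation_net((tr[0][:12], tr[2][:12]), (va[0][:4], va[2][:4]),
                               kidney_ranges(),
                               RotConfig(epochs=1, head_width=32, seed=0))
        assert sorted(m.axes) == ["x", "y", "z"]

    def test_seeded_determinism(self, catheter_toy):
        cfg = RotConfig(epochs=2, head_width=32, seed=0)
        a = train_rotation_net(*catheter_toy, catheter_ranges(), cfg)
        b = train_rotation_net(*catheter_toy, catheter_ranges(), cfg)
        assert a.log["val_acc_5deg"].iloc[-1] == b.log["val_acc_5deg"].iloc[-1]
        img = catheter_toy[0][0][0]
        assert predict_rotation(a, img).angles == predict_rotation(b, img).angles

    def test_out_of_range_label_rejected(self, catheter_toy):
        (ti, tr), val = catheter_toy
        bad = tr.copy()
        bad[0, 0] = 45.0
        with pytest.raises(ValueError, match="outside"):
            train_rotation_net((ti, bad), val, catheter_ranges(),
                               RotConfig(epochs=1, seed=0))

    def test_prediction_contract(self, catheter_toy):
        m = train_rotation_net(*catheter_toy, catheter_ranges(),
                               RotConfig(epochs=1, head_width=32, seed=0))
        img = catheter_toy[0][0][0]
        pred = predict_rotation(m, img)
        p = pred.probabilities["x"]
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        # decoded angle is the bin center of the argmax class
        assert pred.angles["x"] == m.binnings["x"].decode(int(np.argmax(p)))
        assert predict_rotation(m, img).angles == pred.angles

    def test_argmax_tie_goes_to_lower_class(self):
        logits = np.zeros((1, 5))
        assert int(np.argmax(softmax(logits))) == 0

    def test_checkpoint_roundtrip(self, catheter_toy, tmp_path):
        m = train_rotation_net(*catheter_toy, catheter_ranges(),
                               RotConfig(epochs=1, head_width=32, seed=0))
        m.save(tmp_path / "rot.npz")
        back = RotModel.load(tmp_path / "rot.npz")
        img = catheter_toy[0][0][0]
        assert predict_rotation(m, img).angles == predict_rotation(back, img).angles


class TestFineTune:
    def test_zero_epochs_leaves_model_unchanged(self, catheter_toy):
        m = train_rotation_net(*catheter_toy, catheter_ranges(),
                               RotConfig(epochs=1, head_width=32, seed=0))
        img = catheter_toy[0][0][0]
        before = predict_rotation(m, img).angles
        out = fine_tune(m, catheter_toy[0], RotConfig(epochs=0, seed=0))
        assert predict_rotation(out, img).angles == before

    def test_out_of_range_label_rejected(self, catheter_toy):
        m = train_rotation_net(*catheter_toy, catheter_ranges(),
                               RotConfig(epochs=1, head_width=32, seed=0))
        (ti, tr), _ = catheter_toy
        bad = tr.copy()
        bad[0, 0] = 99.0
        with pytest.raises(ValueError):
            fine_tune(m, (ti, bad), RotConfig(epochs=1, seed=0))


class TestDomainShiftFineTune:
    def test_fine_tuning_improves_shifted_accuracy(self):
        """A model trained on clean scenes degrades on the domain-shift
        variant; fine-tuning on 100 shifted frames must recover accuracy."""
        from endopose import profiles
        from endopose.scene_sim import generate_dataset
        mesh = profiles.catheter_mesh(0)
        clean = profiles.catheter_scene(64)
        shifted = profiles.catheter_scene(64).shifted()
        ds = generate_dataset(mesh, 600, catheter_ranges(), clean, seed=0)
        ft = generate_dataset(mesh, 143, catheter_ranges(), shifted, seed=50)
        te = generate_dataset(mesh, 300, catheter_ranges(), shifted, seed=60)
        tr, va = ds.arrays("train"), ds.arrays("val")
        model = train_rotation_net((tr[0], tr[2]), (va[0], va[2]),
                                   catheter_ranges(),
                                   RotConfig(epochs=10, seed=0))
        te_imgs = np.stack([s.image for s in te.samples])
        te_rx = te.manifest["rx"].to_numpy()

        def acc10(m):
            return tolerance_accuracy(
                predict_rotation_batch(m, te_imgs)["x"], te_rx, 10)

        before = acc10(model)
        ft_tr = ft.arrays("train")
        tuned = fine_tune(model, (ft_tr[0], ft_tr[2]),
                          RotConfig(epochs=5, seed=0))
        assert acc10(tuned) > before
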