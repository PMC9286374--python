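"""Desk-scale benchmark experiments run by the reproduction script.

Two headline quantities are recomputed from scratch on simulated scenes:

* ``segmentation_benchmark`` — mean IoU of the encoder-decoder over the
  three classes on the held-out test split of 500 organ scenes (96x96,
  up to two occluding tools), 70/15/15 split, batch 4, lr 1e-4.
* ``rotation_benchmark`` — +-5 degree tolerance accuracy of the
  single-head rotation classifier on 3000 held-out catheter frames
  (64x64), trained on ~4000 frames with X drawn uniformly in [-40, 10]
  degrees and 1-degree bins.

Both return the intermediate artifacts so callers can inspect or extend
the runs; seeds fix every source of randomness.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import profiles
from .scene_sim import catheter_ranges, generate_dataset, kidney_ranges
from .segmentation import SegConfig, evaluate_segmentation, train_segmenter
from .rotation_net import (RotConfig, predict_rotation_batch,
                           tolerance_accuracy, train_rotation_net)


@dataclass
class SegBenchmarkResult:
    mean_iou: float
    per_class: dict
    n_test: int
    model: object
    log: object


@dataclass
class RotBenchmarkResult:
    acc_5deg: float
    acc_10deg: float
    n_test: int
    model: object
    errors: np.ndarray


def segmentation_benchmark(seed: int = 0, n_scenes: int = 500, size: int = 96,
                           config: SegConfig | None = None) -> SegBenchmarkResult:
    """Train and score the segmenter on simulated organ scenes."""
    mesh = profiles.organ_mesh(seed)
    scene = profiles.organ_scene(size)
    ds = generate_dataset(mesh, n_scenes, kidney_ranges(), scene, seed=seed)
    tr = ds.arrays("train")
    va = ds.arrays("val")
    te = ds.arrays("test")
    config = config or SegConfig(seed=seed)
    model = train_segmenter((tr[0], tr[1]), (va[0], va[1]), config)
    report = evaluate_segmentation(model, te[0], te[1])
    return SegBenchmarkResult(mean_iou=report.mean, per_class=report.per_class,
                              n_test=len(te[0]), model=model, log=model.log)


def rotation_benchmark(seed: int = 0, n_train: int = 4700, n_test: int = 3000,
                       size: int = 64,
                       config: RotConfig | None = None) -> RotBenchmarkResult:
    """Train and score the single-axis rotation classifier on simulated
    catheter frames.

    ``n_train`` scenes are split 70/15/15 and the train+val splits drive
    training (~4000 frames); an independently seeded set of ``n_test``
    frames is the held-out test set.
    """
    mesh = profiles.catheter_mesh(seed)
    scene = profiles.catheter_scene(size)
    ranges = catheter_ranges()
    ds = generate_dataset(mesh, n_train, ranges, scene, seed=seed)
    test = generate_dataset(mesh, max(n_test, 10), ranges, scene,
                            seed=seed + 1000)
    tr = ds.arrays("train")
    va = ds.arrays("val")
    config = config or RotConfig(seed=seed)
    model = train_rotation_net((tr[0], tr[2]), (va[0], va[2]), ranges, config)
    te_imgs = np.stack([s.image for s in test.samples])
    te_rx = test.manifest["rx"].to_numpy()
    preds = predict_rotation_batch(model, te_imgs)["x"]
    errors = np.abs(preds - te_rx)
    return RotBenchmarkResult(
        acc_5deg=tolerance_accuracy(preds, te_rx, 5.0),
        acc_10deg=tolerance_accuracy(preds, te_rx, 10.0),
        n_test=len(te_imgs), model=model, errors=errors)
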