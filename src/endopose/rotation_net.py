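"""Discretized rotation classification with a multi-branch CNN.

Each predicted axis gets its own head (dense -> ReLU -> batch-norm ->
dropout -> dense-N -> softmax) on a shared convolutional backbone; the
rotation range of an axis is discretized into 1-degree-wide classes by
default and a prediction decodes to the center of the argmax bin.
Training minimizes the summed per-axis cross-entropy with Adam.

The full-size profile described by this architecture family uses a
50-layer residual backbone with 4096-unit heads; the default desk-scale
profile here is a three-stage plain convolutional backbone with a narrower
head, which trains on one CPU in minutes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import (Conv2D, ReLU, MaxPool2, Dense, BatchNorm1D, Dropout, Adam,
                 softmax, softmax_cross_entropy)
from .scene_sim.pose import RotationRangeSpec


@dataclass(frozen=True)
class AngleBinning:
    """Half-open 1D binning of an angle range: bin k is
    [lo + k*w, lo + (k+1)*w), decoded at its center."""

    lo: float
    hi: float
    width: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"need lo < hi, got ({self.lo}, {self.hi})")
        if not self.width > 0:
            raise ValueError(f"bin width must be positive, got {self.width}")

    @property
    def n_classes(self) -> int:
        return int(np.ceil((self.hi - self.lo) / self.width - 1e-9))

    def encode(self, angle) -> np.ndarray:
        k = np.floor((np.asarray(angle, dtype=float) - self.lo) / self.width)
        return np.clip(k, 0, self.n_classes - 1).astype(int)

    def decode(self, k) -> np.ndarray:
        return self.lo + (np.asarray(k, dtype=float) + 0.5) * self.width


def make_binning(lo: float, hi: float, width: float = 1.0) -> AngleBinning:
    return AngleBinning(lo=lo, hi=hi, width=width)


@dataclass
class RotConfig:
    """Desk-scale training profile (the full-size profile uses a deep
    residual backbone, 4096-unit heads, lr 1e-5 and batch 32)."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    head_width: int = 256
    dropout: float = 0.5
    bin_width: float = 1.0
    augment: bool = True          # photometric train-time jitter (gain/offset)
    label_sigma: float = 1.0      # deg; Gaussian smoothing of the class target
    seed: int = 0


class _Head:
    """dense -> ReLU -> batch-norm -> dropout -> dense-N (softmax applied
    by the loss / prediction)."""

    def __init__(self, fin: int, width: int, n_classes: int, dropout: float, rng):
        self.fc1 = Dense(fin, width, rng=rng)
        self.relu = ReLU()
        self.bn = BatchNorm1D(width)
        self.drop = Dropout(dropout, rng)
        self.fc2 = Dense(width, n_classes, rng=rng)

    def params(self):
        return (self.fc1.params() + self.bn.params() + self.fc2.params())

    def forward(self, x, train=True):
        h = self.relu.forward(self.fc1.forward(x, train), train)
        h = self.drop.forward(self.bn.forward(h, train), train)
        return self.fc2.forward(h, train)

    def backward(self, dy):
        d = self.bn.backward(self.drop.backward(self.fc2.backward(dy)))
        return self.fc1.backward(self.relu.backward(d))


class RotNet:
    """Shared conv backbone + one classification head per predicted axis."""

    def __init__(self, input_shape: tuple, n_classes: dict[str, int],
                 head_width: int = 256, dropout: float = 0.5, seed: int = 0,
                 widths: tuple = (12, 24, 48)):
        h, w = input_shape
        if h % 8 or w % 8:
            raise ValueError("input H and W must be divisible by 8")
        rng = np.random.default_rng(seed)
        self.input_shape = tuple(input_shape)
        self.head_width = head_width
        self.dropout = dropout
        self.widths = tuple(widths)
        w1, w2, w3 = self.widths
        self.conv1 = Conv2D(3, w1, 3, rng=rng)
        self.conv2 = Conv2D(w1, w2, 3, rng=rng)
        self.conv3 = Conv2D(w2, w3, 3, rng=rng)
        self.relus = [ReLU(), ReLU(), ReLU()]
        self.pools = [MaxPool2(), MaxPool2(), MaxPool2()]
        self.feat_dim = (h // 8) * (w // 8) * w3
        self.heads = {a: _Head(self.feat_dim, head_width, n, dropout, rng)
                      for a, n in n_classes.items()}

    def params(self):
        p = self.conv1.params() + self.conv2.params() + self.conv3.params()
        for head in self.heads.values():
            p += head.params()
        return p

    def forward(self, x, train=True):
        h = x
        for conv, relu, pool in zip((self.conv1, self.conv2, self.conv3),
                                    self.relus, self.pools):
            h = pool.forward(relu.forward(conv.forward(h, train), train), train)
        self._feat_shape = h.shape
        feat = h.reshape(len(x), -1)
        return {a: head.forward(feat, train) for a, head in self.heads.items()}

    def backward(self, dlogits: dict):
        dfeat = 0.0
        for a, head in self.heads.items():
            dfeat = dfeat + head.backward(dlogits[a])
        d = dfeat.reshape(self._feat_shape)
        d = self.pools[2].backward(d)
        d = self.conv3.backward(self.relus[2].backward(d))
        d = self.pools[1].backward(d)
        d = self.conv2.backward(self.relus[1].backward(d))
        d = self.pools[0].backward(d)
        return self.conv1.backward(self.relus[0].backward(d))

    def state(self):
        arrays = [p.value.copy() for p in self.params()]
        for head in self.heads.values():
            arrays += [head.bn.running_mean.copy(), head.bn.running_var.copy()]
        return arrays

    def load_state(self, arrays):
        ps = self.params()
        for p, a in zip(ps, arrays[:len(ps)]):
            p.value[...] = a
        rest = arrays[len(ps):]
        for i, head in enumerate(self.heads.values()):
            head.bn.running_mean[...] = rest[2 * i]
            head.bn.running_var[...] = rest[2 * i + 1]


@dataclass
class RotationPrediction:
    """Decoded angle and class probabilities per predicted axis."""

    angles: dict            # axis -> degrees (bin center of argmax class)
    probabilities: dict     # axis -> (N,) array


@dataclass
class RotModel:
    net: RotNet
    binnings: dict          # axis -> AngleBinning
    config: RotConfig
    log: pd.DataFrame | None = None

    @property
    def axes(self) -> list[str]:
        return list(self.binnings)

    def save(self, path: str | Path) -> None:
        descriptor = {
            "kind": "rotation", "input_shape": list(self.net.input_shape),
            "binnings": {a: [b.lo, b.hi, b.width] for a, b in self.binnings.items()},
            "head_width": self.net.head_width, "dropout": self.net.dropout,
            "widths": list(self.net.widths),
            "config": asdict(self.config),
        }
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state())}
        np.savez(Path(path), descriptor=json.dumps(descriptor), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "RotModel":
        data = np.load(Path(path), allow_pickle=False)
        desc = json.loads(str(data["descriptor"]))
        cfg = RotConfig(**desc["config"])
        binnings = {a: AngleBinning(*v) for a, v in desc["binnings"].items()}
        net = RotNet(tuple(desc["input_shape"]),
                     {a: b.n_classes for a, b in binnings.items()},
                     head_width=desc["head_width"], dropout=desc["dropout"],
                     seed=cfg.seed, widths=tuple(desc.get("widths", (12, 24, 48))))
        n_arrays = len([k for k in data.files if k.startswith("p")])
        net.load_state([data[f"p{i}"] for i in range(n_arrays)])
        return cls(net=net, binnings=binnings, config=cfg)


def _prep(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    return x - 0.5


def predict_rotation(model: RotModel, image: np.ndarray) -> RotationPrediction:
    """Per-axis decoded rotation for one image; ties in the argmax go to
    the lower class index."""
    if image.shape[:2] != model.net.input_shape:
        raise ValueError(f"image resolution {image.shape[:2]} does not match "
                         f"the trained resolution {model.net.input_shape}")
    logits = model.net.forward(_prep(image)[None], train=False)
    angles, probs = {}, {}
    for a, lg in logits.items():
        p = softmax(lg[0])
        k = int(np.argmax(p))
        angles[a] = float(model.binnings[a].decode(k))
        probs[a] = p
    return RotationPrediction(angles=angles, probabilities=probs)


def predict_rotation_batch(model: RotModel, images: np.ndarray,
                           batch: int = 64) -> dict:
    """Decoded angles for many images: axis -> (N,) array of degrees."""
    out = {a: [] for a in model.axes}
    x = _prep(images)
    for s in range(0, len(x), batch):
        logits = model.net.forward(x[s:s + batch], train=False)
        for a, lg in logits.items():
            out[a].append(model.binnings[a].decode(np.argmax(lg, axis=1)))
    return {a: np.concatenate(v) for a, v in out.items()}


def tolerance_accuracy(predicted, truth, tol: float) -> float:
    """Fraction of predictions within +-tol degrees of the truth."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    return float(np.mean(np.abs(predicted - truth) <= tol))


def _check_labels(rotations: np.ndarray, binnings: dict) -> None:
    axis_idx = {"x": 0, "y": 1, "z": 2}
    for a, b in binnings.items():
        vals = rotations[:, axis_idx[a]]
        if vals.min() < b.lo or vals.max() > b.hi:
            raise ValueError(f"rotation label outside the {a} range "
                             f"[{b.lo}, {b.hi}]")


def _axis_labels(rotations: np.ndarray, binnings: dict) -> dict:
    axis_idx = {"x": 0, "y": 1, "z": 2}
    return {a: b.encode(rotations[:, axis_idx[a]]) for a, b in binnings.items()}


def _soft_targets(angles: np.ndarray, binning: AngleBinning,
                  sigma: float) -> np.ndarray:
    """Gaussian soft class targets centered on the true angle.

    Neighbouring bins represent neighbouring angles, so spreading a little
    target mass onto them teaches the ordinal structure the plain one-hot
    encoding ignores; sigma -> 0 recovers one-hot.
    """
    centers = binning.decode(np.arange(binning.n_classes))
    d = angles[:, None] - centers[None, :]
    t = np.exp(-0.5 * (d / max(sigma, 1e-6)) ** 2)
    return (t / t.sum(axis=1, keepdims=True)).astype(np.float32)


def _soft_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean cross-entropy against a soft target distribution."""
    p = softmax(logits)
    n = len(logits)
    loss = float(-(targets * np.log(p + 1e-12)).sum() / n)
    return loss, ((p - targets) / n).astype(np.float32)


def _val_accuracy(model: RotModel, images, rotations, tol: float = 5.0) -> float:
    preds = predict_rotation_batch(model, images)
    axis_idx = {"x": 0, "y": 1, "z": 2}
    accs = [tolerance_accuracy(preds[a], rotations[:, axis_idx[a]], tol)
            for a in model.axes]
    return float(np.mean(accs))


def train_rotation_net(train_set: tuple, val_set: tuple,
                       ranges: RotationRangeSpec,
                       config: RotConfig | None = None,
                       log_path: str | Path | None = None) -> RotModel:
    """Train the multi-branch rotation classifier; the checkpoint with the
    best validation +-5 degree accuracy (mean over heads) is returned.

    ``train_set`` / ``val_set`` are ``(images, rotations)`` with images
    (N, H, W, 3) uint8 and rotations (N, 3) degrees; only axes with a
    numeric range in ``ranges`` get a head and a loss term.
    """
    config = config or RotConfig()
    images, rotations = (np.asarray(a) for a in train_set)
    vimages, vrot = (np.asarray(a) for a in val_set)
    if len(images) == 0 or len(vimages) == 0:
        raise ValueError("empty dataset")
    axes = ranges.range_axes
    if not axes:
        raise ValueError("no range axis to predict")
    binnings = {a: make_binning(ranges.axis(a).lo, ranges.axis(a).hi,
                                config.bin_width) for a in axes}
    _check_labels(rotations, binnings)
    _check_labels(vrot, binnings)

    net = RotNet(images.shape[1:3], {a: b.n_classes for a, b in binnings.items()},
                 head_width=config.head_width, dropout=config.dropout,
                 seed=config.seed)
    model = RotModel(net=net, binnings=binnings, config=config)
    return _fit(model, images, rotations, vimages, vrot,
                lr=config.learning_rate, epochs=config.epochs,
                seed=config.seed, log_path=log_path)


def _fit(model: RotModel, images, rotations, vimages, vrot, *, lr, epochs,
         seed, log_path=None) -> RotModel:
    config = model.config
    net = model.net
    axis_idx = {"x": 0, "y": 1, "z": 2}
    if config.label_sigma > 0:
        labels = {a: _soft_targets(rotations[:, axis_idx[a]], b,
                                   config.label_sigma)
                  for a, b in model.binnings.items()}
        loss_fn = _soft_cross_entropy
    else:
        labels = _axis_labels(rotations, model.binnings)
        loss_fn = softmax_cross_entropy
    opt = Adam(net.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    x_all = _prep(images)
    n = len(images)
    best_acc, best_state = -np.inf, net.state()
    log = []
    for epoch in range(epochs):
        # step decay: x0.2 after 60% and again after 85% of the epochs
        opt.lr = lr * (0.2 if epoch >= 0.6 * epochs else 1.0) * (
            0.2 if epoch >= 0.85 * epochs else 1.0)
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb = x_all[idx]
            if config.augment:
                # per-image photometric jitter: global gain and offset, so
                # the net keys on geometry rather than absolute shading
                gain = rng.uniform(0.85, 1.15, (len(idx), 1, 1, 1)).astype(np.float32)
                off = rng.uniform(-0.06, 0.06, (len(idx), 1, 1, 1)).astype(np.float32)
                xb = xb * gain + off
            logits = net.forward(xb, train=True)
            loss, dlogits = 0.0, {}
            for a, lg in logits.items():
                l, d = loss_fn(lg, labels[a][idx])
                loss += l
                dlogits[a] = d
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        acc = _val_accuracy(model, vimages, vrot)
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "val_acc_5deg": acc})
        if acc > best_acc:
            best_acc = acc
            best_state = net.state()
    net.load_state(best_state)
    prev = model.log
    model.log = pd.DataFrame(log) if prev is None else pd.concat(
        [prev, pd.DataFrame(log)], ignore_index=True)
    if log_path is not None:
        model.log.to_csv(log_path, index=False)
    return model


def fine_tune(model: RotModel, extra_set: tuple, config: RotConfig | None = None,
              lr_factor: float = 0.1, val_set: tuple | None = None) -> RotModel:
    """Continue training from the checkpoint at a reduced learning rate.

    Used to adapt a synthetically trained model to a shifted domain (the
    simulator's domain-shift variant standing in for real intraoperative
    frames).  ``config.epochs`` == 0 leaves the model unchanged.
    """
    config = config or model.config
    images, rotations = (np.asarray(a) for a in extra_set)
    if len(images) == 0:
        raise ValueError("empty fine-tuning set")
    _check_labels(rotations, model.binnings)
    if config.epochs == 0:
        return model
    if val_set is None:
        val_set = (images, rotations)
    vimages, vrot = (np.asarray(a) for a in val_set)
    return _fit(model, images, rotations, vimages, vrot,
                lr=config.learning_rate * lr_factor, epochs=config.epochs,
                seed=config.seed + 101)
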