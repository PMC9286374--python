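"""Three-class semantic segmentation (background / tool / target).

A small encoder-decoder with skip connections and residual encoder blocks,
trained with pixel-wise cross-entropy and Adam.  Capacity (base width) and
input resolution are configurable; the default profile is sized to train
on a CPU in minutes.  Evaluation is Intersection-over-Union, pooled over
a test set (summed intersections / summed unions) with per-image scores
kept alongside; classes absent from both prediction and truth are flagged
as undefined and excluded from means.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import (Conv2D, ReLU, MaxPool2, Upsample2, Adam, softmax_cross_entropy,
                 softmax)

N_CLASSES = 3
CLASS_NAMES = {0: "background", 1: "tool", 2: "target"}


@dataclass
class SegConfig:
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 1e-4
    width: int = 8
    seed: int = 0


class _ResBlock:
    """conv-relu-conv with an (optionally projected) identity shortcut."""

    def __init__(self, cin: int, cout: int, rng):
        self.convA = Conv2D(cin, cout, 3, rng=rng)
        self.reluA = ReLU()
        self.convB = Conv2D(cout, cout, 3, rng=rng)
        self.proj = Conv2D(cin, cout, 1, rng=rng) if cin != cout else None
        self.reluO = ReLU()

    def params(self):
        p = self.convA.params() + self.convB.params()
        if self.proj is not None:
            p += self.proj.params()
        return p

    def forward(self, x, train=True):
        h = self.convB.forward(self.reluA.forward(self.convA.forward(x, train), train), train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        return self.reluO.forward(h + s, train)

    def backward(self, dy):
        d = self.reluO.backward(dy)
        dx = self.convA.backward(self.reluA.backward(self.convB.backward(d)))
        dx = dx + (self.proj.backward(d) if self.proj is not None else d)
        return dx


class SegUNet:
    """Encoder-decoder with two 2x downsamplings and skip connections."""

    def __init__(self, width: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        w = width
        self.width = width
        self.enc1 = _ResBlock(3, w, rng)
        self.pool1 = MaxPool2()
        self.enc2 = _ResBlock(w, 2 * w, rng)
        self.pool2 = MaxPool2()
        self.bott = _ResBlock(2 * w, 4 * w, rng)
        self.up1 = Upsample2()
        self.dec1 = Conv2D(4 * w + 2 * w, 2 * w, 3, rng=rng)
        self.drelu1 = ReLU()
        self.up2 = Upsample2()
        self.dec2 = Conv2D(2 * w + w, w, 3, rng=rng)
        self.drelu2 = ReLU()
        self.head = Conv2D(w, N_CLASSES, 1, rng=rng)

    def params(self):
        p = []
        for m in (self.enc1, self.enc2, self.bott, self.dec1, self.dec2, self.head):
            p += m.params()
        return p

    def forward(self, x, train=True):
        e1 = self.enc1.forward(x, train)
        e2 = self.enc2.forward(self.pool1.forward(e1, train), train)
        b = self.bott.forward(self.pool2.forward(e2, train), train)
        u1 = np.concatenate([self.up1.forward(b, train), e2], axis=-1)
        d1 = self.drelu1.forward(self.dec1.forward(u1, train), train)
        u2 = np.concatenate([self.up2.forward(d1, train), e1], axis=-1)
        d2 = self.drelu2.forward(self.dec2.forward(u2, train), train)
        return self.head.forward(d2, train)

    def backward(self, dy):
        w = self.width
        dd2 = self.drelu2.backward(self.head.backward(dy))
        du2 = self.dec2.backward(dd2)
        dd1_up, de1_skip = du2[..., :2 * w], du2[..., 2 * w:]
        dd1 = self.drelu1.backward(self.up2.backward(dd1_up))
        du1 = self.dec1.backward(dd1)
        db_up, de2_skip = du1[..., :4 * w], du1[..., 4 * w:]
        db = self.up1.backward(db_up)
        de2 = self.pool2.backward(self.bott.backward(db)) + de2_skip
        de1 = self.pool1.backward(self.enc2.backward(de2)) + de1_skip
        return self.enc1.backward(de1)

    # -- parameter (de)serialisation -------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def load_state(self, arrays) -> None:
        for p, a in zip(self.params(), arrays, strict=True):
            p.value[...] = a


@dataclass
class SegModel:
    """Trained segmenter: network, architecture descriptor, training log."""

    net: SegUNet
    input_shape: tuple          # (H, W)
    config: SegConfig
    log: pd.DataFrame | None = None

    def predict(self, image: np.ndarray) -> np.ndarray:
        return predict_mask(self, image)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        descriptor = {"kind": "segmenter", "width": self.net.width,
                      "input_shape": list(self.input_shape),
                      "config": asdict(self.config)}
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state())}
        np.savez(path, descriptor=json.dumps(descriptor), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        data = np.load(Path(path), allow_pickle=False)
        desc = json.loads(str(data["descriptor"]))
        cfg = SegConfig(**desc["config"])
        net = SegUNet(width=desc["width"], seed=cfg.seed)
        net.load_state([data[f"p{i}"] for i in range(len(net.params()))])
        return cls(net=net, input_shape=tuple(desc["input_shape"]), config=cfg)


def _prep(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    return x - 0.5


def predict_mask(model: SegModel, image: np.ndarray) -> np.ndarray:
    """Argmax class-ID mask for one image (deterministic at inference)."""
    if image.shape[:2] != tuple(model.input_shape):
        raise ValueError(f"image resolution {image.shape[:2]} does not match "
                         f"the trained resolution {tuple(model.input_shape)}")
    logits = model.net.forward(_prep(image)[None], train=False)[0]
    return logits.argmax(axis=-1).astype(np.uint8)


def _predict_batch(model: SegModel, images: np.ndarray, batch: int = 8) -> np.ndarray:
    out = []
    for s in range(0, len(images), batch):
        logits = model.net.forward(_prep(images[s:s + batch]), train=False)
        out.append(logits.argmax(axis=-1).astype(np.uint8))
    return np.concatenate(out)


def iou(pred: np.ndarray, truth: np.ndarray, class_id: int) -> float:
    """Intersection-over-union of one class; NaN if the class is absent
    from both masks (undefined, excluded from means)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    if class_id not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_id}")
    p = pred == class_id
    t = truth == class_id
    union = np.logical_or(p, t).sum()
    if union == 0:
        return float("nan")
    return float(np.logical_and(p, t).sum() / union)


@dataclass
class IoUReport:
    """Per-class (pooled) IoU, their mean, and per-image scores."""

    per_class: dict
    mean: float
    per_image: pd.DataFrame
    pooled: bool = True

    def to_csv(self, path: str | Path) -> None:
        rows = [{"class": CLASS_NAMES[c], "iou": v} for c, v in self.per_class.items()]
        rows.append({"class": "mean", "iou": self.mean})
        header = "# IoU pooled over the test set (summed intersections/unions)\n"
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(rows).to_csv(fh, index=False)

    def to_json(self) -> dict:
        return {"per_class": {CLASS_NAMES[c]: v for c, v in self.per_class.items()},
                "mean": self.mean, "pooled": self.pooled}


def _pooled_iou(preds, truths) -> IoUReport:
    inter = np.zeros(N_CLASSES)
    union = np.zeros(N_CLASSES)
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        row = {"image": i}
        for c in range(N_CLASSES):
            pc, tc = p == c, t == c
            inter[c] += np.logical_and(pc, tc).sum()
            union[c] += np.logical_or(pc, tc).sum()
            row[CLASS_NAMES[c]] = iou(p, t, c)
        rows.append(row)
    per_class = {c: (float(inter[c] / union[c]) if union[c] > 0 else float("nan"))
                 for c in range(N_CLASSES)}
    defined = [v for v in per_class.values() if not np.isnan(v)]
    mean = float(np.mean(defined)) if defined else float("nan")
    return IoUReport(per_class=per_class, mean=mean,
                     per_image=pd.DataFrame(rows))


def evaluate_segmentation(model: SegModel, images: np.ndarray,
                          masks: np.ndarray) -> IoUReport:
    """Pooled per-class and mean IoU of the model over a test set."""
    if len(images) == 0:
        raise ValueError("empty test set")
    preds = _predict_batch(model, np.asarray(images))
    return _pooled_iou(preds, np.asarray(masks))


def train_segmenter(train_set: tuple, val_set: tuple,
                    config: SegConfig | None = None,
                    log_path: str | Path | None = None) -> SegModel:
    """Train the encoder-decoder and return the best-validation checkpoint.

    ``train_set`` / ``val_set`` are ``(images, masks)`` pairs of uint8
    arrays, shapes (N, H, W, 3) and (N, H, W).  Checkpoint selection is by
    best validation mean IoU; the per-epoch log (loss, val mean IoU) is
    attached to the model and optionally persisted as CSV.
    """
    config = config or SegConfig()
    images, masks = (np.asarray(a) for a in train_set)
    vimages, vmasks = (np.asarray(a) for a in val_set)
    if len(images) == 0 or len(vimages) == 0:
        raise ValueError("empty dataset")
    if images.shape[:3] != masks.shape[:3]:
        raise ValueError("image/mask size mismatch")
    h, w = images.shape[1:3]
    if h % 4 or w % 4:
        raise ValueError("input H and W must be divisible by 4")

    net = SegUNet(width=config.width, seed=config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    x_all = _prep(images)
    model = SegModel(net=net, input_shape=(h, w), config=config)

    best_val = -np.inf
    best_state = net.state()
    log = []
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            logits = net.forward(x_all[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, masks[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val = evaluate_segmentation(model, vimages, vmasks)
        log.append({"epoch": epoch, "loss": float(np.mean(losses)),
                    "val_mean_iou": val.mean})
        if val.mean > best_val:
            best_val = val.mean
            best_state = net.state()
    net.load_state(best_state)
    model.log = pd.DataFrame(log)
    if log_path is not None:
        model.log.to_csv(log_path, index=False)
    return model
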