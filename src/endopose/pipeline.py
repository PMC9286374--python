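"""End-to-end registration and tracking of the target over a video.

Three modes mirror the clinical case studies:

``rigid-instrument``
    Every frame: X rotation from the rotation classifier, Y from the
    silhouette ellipse, Z fixed at 0 (rotational symmetry of the
    instrument).
``organ-auto``
    The rotation classifier registers the first well-framed frame; all
    later frames are tracked by masked optical flow.
``organ-manual``
    A supplied pose registers the first frame (no GUI: a CLI flag or a
    one-line init file); later frames are tracked by optical flow.

Every frame yields a pose-log record tagging the source of each field
(``network`` / ``mask`` / ``flow`` / ``fixed`` / ``manual-init`` /
``held``), and optionally an alpha-blended overlay of the posed mesh.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .localization import (AxisAmbiguousError, ScaleReference, TargetNotFoundError,
                           YRotationCalibration, estimate_scale, fit_ellipse,
                           largest_target_region, mask_y_rotation)
from .flow_rotation import (FlowCalibration, NoTargetFlowError, _pair_increment,
                            flow_to_rotation)
from .rotation_net import RotModel, predict_rotation
from .scene_sim.config import SceneConfig
from .scene_sim.mesh import MeshModel
from .scene_sim.pose import Pose6D
from .scene_sim.render import (Lighting, TargetOutOfViewError, _rasterize,
                               _target_world_transform, _vertex_normals, TARGET)
from .segmentation import SegModel, evaluate_segmentation, predict_mask, _pooled_iou
from .rotation_net import tolerance_accuracy

MODES = ("rigid-instrument", "organ-auto", "organ-manual")

_OVERLAY_COLOR = np.array([0.35, 0.55, 0.95])


@dataclass
class ModeConfig:
    """Which source fills each pose field, plus the models it needs."""

    mode: str
    segmenter: object                     # SegModel or callable image -> mask
    rot_model: RotModel | None = None
    flow_calib: FlowCalibration | None = None
    y_calib: YRotationCalibration = field(default_factory=YRotationCalibration)
    scale_ref: ScaleReference | None = None
    init_pose: Pose6D | None = None       # organ-manual registration
    scene: SceneConfig = field(default_factory=SceneConfig)
    alpha: float = 0.5

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("rigid-instrument", "organ-auto") and self.rot_model is None:
            raise ValueError(f"mode {self.mode} requires a rotation model")
        if self.mode in ("organ-auto", "organ-manual") and self.flow_calib is None:
            raise ValueError(f"mode {self.mode} requires a flow calibration")
        if self.mode == "organ-manual" and self.init_pose is None:
            raise ValueError("organ-manual requires an initial pose")


@dataclass
class AugmentedFrame:
    image: np.ndarray
    pose: Pose6D | None
    sources: dict
    flags: list = field(default_factory=list)


def _segment(segmenter, image) -> np.ndarray:
    if isinstance(segmenter, SegModel):
        return predict_mask(segmenter, image)
    return segmenter(image)


def overlay(frame: np.ndarray, mesh: MeshModel, pose: Pose6D,
            scene: SceneConfig | None = None, alpha: float = 0.5) -> AugmentedFrame:
    """Alpha-blend the mesh, rasterized at ``pose``, over the frame.

    Deterministic: fixed frontal lighting, no texture.  A pose that puts
    the target fully outside the frame returns the raw frame, flagged.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if not np.all(np.isfinite(list(pose.as_dict().values()))):
        raise ValueError("pose must be finite")
    scene = scene or SceneConfig(width=frame.shape[1], height=frame.shape[0])
    R, center = _target_world_transform(mesh, pose, scene)
    verts = mesh.vertices @ R.T + center
    prim = {"vertices": verts, "faces": mesh.faces, "class_id": TARGET,
            "model_coords": mesh.vertices,
            "normals": _vertex_normals(mesh.vertices, mesh.faces) @ R.T,
            "base_color": _OVERLAY_COLOR, "textured": False}
    lighting = Lighting(direction=np.array([0.2, 0.2, 0.96]), intensity=1.0)
    img, cls, _ = _rasterize([prim], scene, shade=True, lighting=lighting,
                             texture_phase=None)
    sil = cls == TARGET
    if not sil.any():
        return AugmentedFrame(image=frame.copy(), pose=pose, sources={},
                              flags=["target-out-of-view"])
    out = frame.astype(np.float32) / 255.0
    out[sil] = (1 - alpha) * out[sil] + alpha * img[sil]
    return AugmentedFrame(image=(out * 255 + 0.5).astype(np.uint8), pose=pose,
                          sources={})


def _network_rotation(config: ModeConfig, image) -> dict:
    pred = predict_rotation(config.rot_model, image)
    return pred.angles


def run_video(frames, config: ModeConfig, mesh: MeshModel,
              out_dir: str | Path | None = None):
    """Process a frame sequence; returns (augmented frames, pose log).

    The pose log is one record per input frame: pose fields plus a source
    tag per field; frames where the target is not found carry the raw
    frame and a ``target-not-found`` flag.
    """
    if len(frames) == 0:
        raise ValueError("empty input")
    frames = list(frames)
    log: list[dict] = []
    augmented: list[AugmentedFrame] = []
    scale_ref = config.scale_ref
    registered = False
    last = None          # dict of the last good pose fields
    prev = None          # (frame, mask) of the previous good frame
    for i, frame in enumerate(frames):
        mask = _segment(config.segmenter, frame)
        record = {"frame": i}
        flags = []
        try:
            region = largest_target_region(mask)
            fit = fit_ellipse(region)
        except TargetNotFoundError:
            flags.append("target-not-found")
            record.update({"flags": flags})
            log.append(record)
            augmented.append(AugmentedFrame(image=np.asarray(frame).copy(),
                                            pose=None, sources={}, flags=flags))
            prev = None
            continue

        tx, ty = fit.cx, fit.cy
        if scale_ref is None:
            init_scale = config.init_pose.scale if config.init_pose else 1.0
            scale_ref = ScaleReference(area=fit.area / init_scale ** 2, scale=1.0)
        scale = estimate_scale(fit, scale_ref)
        sources = {"tx": "mask", "ty": "mask", "scale": "mask"}

        if config.mode == "rigid-instrument":
            rx = _network_rotation(config, frame).get("x", 0.0)
            sources["rx"] = "network"
            try:
                ry = mask_y_rotation(fit, config.y_calib)
                sources["ry"] = "mask"
            except AxisAmbiguousError:
                ry = last["ry"] if last else 0.0
                sources["ry"] = "held"
                flags.append("axis-ambiguous")
            rz = 0.0
            sources["rz"] = "fixed"
        elif not registered:
            if config.mode == "organ-auto":
                ang = _network_rotation(config, frame)
                rx = ang.get("x", 0.0)
                ry = ang.get("y", 0.0)
                rz = ang.get("z", 0.0)
                sources.update({"rx": "network", "ry": "network", "rz": "network"})
            else:
                rx, ry, rz = (config.init_pose.rx, config.init_pose.ry,
                              config.init_pose.rz)
                sources.update({"rx": "manual-init", "ry": "manual-init",
                                "rz": "manual-init"})
            registered = True
        else:
            rx, ry, rz = last["rx"], last["ry"], last["rz"]
            if prev is not None:
                try:
                    decomp, _ = _pair_increment(prev[0], frame, prev[1], mask)
                    inc = flow_to_rotation(decomp, config.flow_calib)
                    rx, ry, rz = rx + inc[0], ry + inc[1], rz + inc[2]
                except (NoTargetFlowError, ValueError):
                    flags.append("no-target-flow")
            else:
                flags.append("tracking-gap")
            sources.update({"rx": "flow", "ry": "flow", "rz": "flow"})

        pose = Pose6D(tx=tx, ty=ty, scale=scale, rx=rx, ry=ry, rz=rz)
        aug = overlay(frame, mesh, pose, config.scene, config.alpha)
        aug.sources = sources
        aug.flags = flags + aug.flags
        augmented.append(aug)
        record.update(pose.as_dict())
        record["sources"] = sources
        record["flags"] = flags
        log.append(record)
        last = {"rx": rx, "ry": ry, "rz": rz}
        prev = (frame, mask)

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "augmented").mkdir(parents=True, exist_ok=True)
        for i, aug in enumerate(augmented):
            iio.imwrite(out_dir / "augmented" / f"{i:05d}.png", aug.image)
        write_pose_log(log, out_dir / "pose_log.jsonl")
    return augmented, log


def write_pose_log(log: list[dict], path: str | Path) -> None:
    """JSON-lines pose log, one record per frame."""
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")


def read_pose_log(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def evaluate_pipeline(log: list[dict], truth: pd.DataFrame,
                      pred_masks=None, truth_masks=None,
                      tolerances=(5.0, 10.0), sample_step: int = 10) -> dict:
    """Aggregate a run against simulator ground truth.

    ``truth`` is a per-frame table with columns tx, ty, scale, rx, ry, rz.
    Reports position / scale errors, per-axis rotation tolerance
    accuracies for the sources active in the run, trajectory accuracies
    at every ``sample_step``-th frame, and segmentation IoU when mask
    pairs are provided.
    """
    if len(log) != len(truth):
        raise ValueError("frame count mismatch between log and ground truth")
    good = [r for r in log if "tx" in r]
    idx = [r["frame"] for r in good]
    t = truth.iloc[idx]
    report: dict = {"n_frames": len(log), "n_localized": len(good)}
    if good:
        pos_err = np.hypot([r["tx"] for r in good] - t["tx"].to_numpy(),
                           [r["ty"] for r in good] - t["ty"].to_numpy())
        scale_err = np.abs([r["scale"] for r in good] - t["scale"].to_numpy())
        report["position_error_px"] = {"median": float(np.median(pos_err)),
                                       "mean": float(pos_err.mean())}
        report["scale_error"] = {"median": float(np.median(scale_err)),
                                 "mean": float(scale_err.mean())}
        active = sorted({s for r in good for a, s in r["sources"].items()
                         if a in ("rx", "ry", "rz")})
        report["rotation"] = {}
        for k, axis in enumerate(["rx", "ry", "rz"]):
            est = np.array([r[axis] for r in good])
            tru = t[axis].to_numpy()
            entry = {"source": good[0]["sources"].get(axis, "?")}
            for tol in tolerances:
                entry[f"acc_{int(tol)}deg"] = tolerance_accuracy(est, tru, tol)
            sample = [j for j, fi in enumerate(idx) if fi % sample_step == 0]
            for tol in tolerances:
                entry[f"trajectory_acc_{int(tol)}deg"] = tolerance_accuracy(
                    est[sample], tru[sample], tol)
            report["rotation"][axis] = entry
        report["active_sources"] = active
    if pred_masks is not None and truth_masks is not None:
        iou_rep = _pooled_iou(pred_masks, truth_masks)
        report["segmentation"] = iou_rep.to_json()
    return report
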