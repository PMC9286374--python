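"""Rotation tracking from dense optical flow on the target's pixels.

Between consecutive frames, dense optical flow restricted to the target
mask is decomposed by a least-squares affine fit about the silhouette
ellipse center::

    d(p) = A (p - c) + t

whose antisymmetric part gives the in-plane rotation rate (curl,
``rz``), whose trace gives the looming rate (divergence, scale change),
and whose translation, after subtracting the ellipse-center displacement,
leaves the *texture slip* — surface texture sliding across a quasi-static
silhouette — which is the signature of out-of-plane rotation about the
image axes (``rx``, ``ry``).  Slip is converted to degrees with
calibration constants recovered from simulated single-axis sequences.
Per-frame increments are accumulated from a registered initial pose.

This decomposition is one concrete realization of the premise that flow
magnitude indicates rotation angle and flow direction the rotation axis;
it is deterministic, calibratable on synthetic data, and degrades to zero
on static scenes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.registration import optical_flow_ilk

from .localization import EllipseFit, fit_ellipse, largest_target_region, \
    TargetNotFoundError
from .scene_sim.pose import Pose6D
from .scene_sim.render import TARGET

#: median slip (px) below which increments are zeroed (flow-noise floor)
DEAD_BAND = 0.05


class NoTargetFlowError(RuntimeError):
    """No target pixel common to both frames' masks."""


@dataclass
class FlowField:
    """Per-pixel displacement (pixels/frame): du rightward, dv downward."""

    du: np.ndarray
    dv: np.ndarray

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.du, self.dv)

    @property
    def direction(self) -> np.ndarray:
        """Displacement angle in radians, atan2(dv, du)."""
        return np.arctan2(self.dv, self.du)


@dataclass
class MaskedFlow:
    """Flow samples restricted to target pixels present in both masks."""

    x: np.ndarray
    y: np.ndarray
    du: np.ndarray
    dv: np.ndarray

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class MotionDecomposition:
    """Affine decomposition of the masked flow about the ellipse center.

    ``A`` and ``t`` reproduce the least-squares fit exactly;
    ``curl`` (rad/frame) and ``divergence`` (1/frame) are the
    antisymmetric / trace parts of ``A``; ``slip`` is ``t`` minus the
    ellipse-center displacement between the frames.
    """

    A: np.ndarray           # (2, 2)
    t: np.ndarray           # (2,)
    curl: float             # (A21 - A12) / 2, radians/frame
    divergence: float       # (A11 + A22) / 2, 1/frame
    slip: np.ndarray        # (2,) pixels, texture slip after center motion

    def reconstruct(self, x, y, center) -> tuple[np.ndarray, np.ndarray]:
        p = np.stack([x - center[0], y - center[1]])
        d = self.A @ p + self.t[:, None]
        return d[0], d[1]


@dataclass
class FlowCalibration:
    """Degrees of out-of-plane rotation per pixel of texture slip."""

    kx: float               # deg per px of vertical slip   -> rx
    ky: float               # deg per px of horizontal slip -> ry

    def __post_init__(self):
        if self.kx <= 0 or self.ky <= 0:
            raise ValueError("calibration constants must be positive")


@dataclass
class TrajectoryEstimate:
    """Accumulated per-frame rotations with evaluation sample indices."""

    angles: np.ndarray          # (n_frames, 3) degrees
    sample_step: int = 10
    flagged: list = field(default_factory=list)

    @property
    def sample_indices(self) -> np.ndarray:
        return np.arange(0, len(self.angles), self.sample_step)

    def to_frame(self, truth: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=["rx_est", "ry_est", "rz_est"])
        df.insert(0, "frame", np.arange(len(df)))
        if truth is not None:
            for i, a in enumerate(["rx_true", "ry_true", "rz_true"]):
                df[a] = truth[:, i]
        return df


def _gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        return rgb2gray(frame).astype(np.float32)
    return frame.astype(np.float32) / (255.0 if frame.dtype == np.uint8 else 1.0)


def dense_flow(frame_prev: np.ndarray, frame_next: np.ndarray) -> FlowField:
    """Dense displacement field from ``frame_prev`` to ``frame_next``.

    Estimated with iterative Lucas-Kanade; the contract (not the
    algorithm) is normative: a one-pixel rightward shift of a textured
    image yields median du in [0.8, 1.2] over textured pixels.
    """
    if np.asarray(frame_prev).shape != np.asarray(frame_next).shape:
        raise ValueError("frame size mismatch")
    g0 = _gray(frame_prev)
    g1 = _gray(frame_next)
    flow = optical_flow_ilk(g0, g1, radius=5)
    return FlowField(du=flow[1].astype(np.float32), dv=flow[0].astype(np.float32))


def masked_flow(flow: FlowField, mask_prev: np.ndarray,
                mask_next: np.ndarray | None = None,
                class_id: int = TARGET, erode: int = 0) -> MaskedFlow:
    """Restrict the flow to target pixels present in both frames' masks.

    ``erode`` shrinks the selection away from the silhouette boundary,
    where window-based flow mixes static background with target motion;
    the erosion backs off automatically if too few pixels would remain.
    """
    if flow.du.shape != np.asarray(mask_prev).shape:
        raise ValueError("flow/mask shape mismatch")
    sel = np.asarray(mask_prev) == class_id
    if mask_next is not None:
        sel &= np.asarray(mask_next) == class_id
    if not sel.any():
        raise NoTargetFlowError("no-target-flow")
    if erode > 0:
        keep = max(50, int(0.05 * sel.sum()))
        for it in range(erode, 0, -1):
            shrunk = ndimage.binary_erosion(sel, iterations=it)
            if shrunk.sum() >= keep:
                sel = shrunk
                break
    ys, xs = np.nonzero(sel)
    return MaskedFlow(x=xs.astype(float), y=ys.astype(float),
                      du=flow.du[sel], dv=flow.dv[sel])


def decompose_motion(mf: MaskedFlow, fit: EllipseFit,
                     center_displacement: tuple[float, float] = (0.0, 0.0),
                     ) -> MotionDecomposition:
    """Least-squares affine fit of the masked flow about the ellipse center.

    ``center_displacement`` is the ellipse-center motion between the two
    frames; subtracting it from the fitted translation leaves the texture
    slip attributable to out-of-plane rotation.
    """
    if mf.n < 20:
        raise ValueError(f"need at least 20 masked pixels, got {mf.n}")
    x = mf.x - fit.cx
    y = mf.y - fit.cy
    ones = np.ones_like(x)
    G = np.stack([x, y, ones], axis=1)
    # rank check: collinear pixels cannot constrain an affine field
    if np.linalg.matrix_rank(G) < 3:
        raise ValueError("rank-deficient flow support (collinear pixels)")
    coef_u, *_ = np.linalg.lstsq(G, mf.du, rcond=None)
    coef_v, *_ = np.linalg.lstsq(G, mf.dv, rcond=None)
    A = np.array([[coef_u[0], coef_u[1]], [coef_v[0], coef_v[1]]])
    t = np.array([coef_u[2], coef_v[2]])
    curl = (A[1, 0] - A[0, 1]) / 2.0
    div = (A[0, 0] + A[1, 1]) / 2.0
    slip = t - np.asarray(center_displacement, dtype=float)
    return MotionDecomposition(A=A, t=t, curl=float(curl), divergence=float(div),
                               slip=slip)


def flow_to_rotation(decomp: MotionDecomposition, calib: FlowCalibration,
                     dead_band: float = DEAD_BAND) -> np.ndarray:
    """Per-frame rotation increments (degrees) from a motion decomposition.

    In-plane: ``drz = -degrees(curl)`` (image y points down, so a positive
    model Z rotation appears as negative curl).  Out-of-plane: horizontal
    texture slip maps to Y, vertical slip to X.  Components below the
    dead band are zeroed.
    """
    drz = -np.degrees(decomp.curl)
    sx, sy = decomp.slip
    dry = calib.ky * sx
    drx = calib.kx * sy
    out = np.array([drx, dry, drz])
    # curl floor: the slip noise floor seen over a ~25 px silhouette radius
    thresholds = np.array([calib.kx * dead_band, calib.ky * dead_band,
                           np.degrees(dead_band / 25.0)])
    out[np.abs(out) < thresholds] = 0.0
    return out


#: boundary erosion (px) applied before the affine fit: the flow window
#: radius plus margin, so no fitted pixel's window touches the background
EDGE_ERODE = 7


def _pair_increment(frame0, frame1, mask0, mask1) -> tuple[MotionDecomposition, EllipseFit]:
    flow = dense_flow(frame0, frame1)
    mf = masked_flow(flow, mask0, mask1, erode=EDGE_ERODE)
    fit0 = fit_ellipse(largest_target_region(mask0))
    fit1 = fit_ellipse(largest_target_region(mask1))
    dc = (fit1.cx - fit0.cx, fit1.cy - fit0.cy)
    return decompose_motion(mf, fit0, center_displacement=dc), fit0


def calibrate(sequences: dict, true_rates: dict,
              dead_band: float = DEAD_BAND) -> FlowCalibration:
    """Recover slip-to-degrees constants from single-axis sequences.

    ``sequences`` maps axis ("x" or "y") to (frames, masks) of a sequence
    rotating at the constant known rate ``true_rates[axis]`` (deg/frame)
    about that axis only.  k = mean(rate / slip component) over frame
    pairs whose slip exceeds the dead band.
    """
    comps = {"x": 1, "y": 0}   # slip component index per axis (x<-dv, y<-du)
    ks = {}
    for axis, (frames, masks) in sequences.items():
        slips = []
        for i in range(len(frames) - 1):
            decomp, _ = _pair_increment(frames[i], frames[i + 1],
                                        masks[i], masks[i + 1])
            s = decomp.slip[comps[axis]]
            if abs(s) > dead_band:
                slips.append(true_rates[axis] / s)
        if not slips:
            raise ValueError(f"no usable slip on axis {axis}: "
                             "increase motion or lower the dead band")
        ks["k" + axis] = float(np.mean(slips))
    return FlowCalibration(kx=abs(ks.get("kx", 1.0)), ky=abs(ks.get("ky", 1.0)))


def track_sequence(frames, masks, init_pose: Pose6D,
                   calib: FlowCalibration, sample_step: int = 10,
                   dead_band: float = DEAD_BAND) -> TrajectoryEstimate:
    """Accumulate flow-derived rotation increments over a frame sequence.

    Starts from the registered ``init_pose`` rotations; every consecutive
    frame pair contributes one increment (never pairs further apart).  A
    pair without common target pixels holds the last rotation and flags
    the frame.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    if len(frames) != len(masks):
        raise ValueError("frame/mask count mismatch")
    angles = np.zeros((len(frames), 3))
    angles[0] = init_pose.rotations
    flagged = []
    for i in range(1, len(frames)):
        try:
            decomp, _ = _pair_increment(frames[i - 1], frames[i],
                                        masks[i - 1], masks[i])
            inc = flow_to_rotation(decomp, calib, dead_band=dead_band)
        except (NoTargetFlowError, TargetNotFoundError, ValueError):
            inc = np.zeros(3)
            flagged.append(i)
        angles[i] = angles[i - 1] + inc
    return TrajectoryEstimate(angles=angles, sample_step=sample_step,
                              flagged=flagged)


def evaluate_trajectory(est: TrajectoryEstimate, truth: np.ndarray,
                        tolerances=(5.0, 10.0)) -> pd.DataFrame:
    """Per-axis tolerance accuracies at the sample frames (every
    ``sample_step``-th frame), as a tidy (axis, tol, accuracy) table."""
    truth = np.asarray(truth, dtype=float)
    if len(truth) < len(est.angles):
        raise ValueError("truth trajectory shorter than the estimate")
    idx = est.sample_indices
    rows = []
    for k, axis in enumerate(["x", "y", "z"]):
        err = np.abs(est.angles[idx, k] - truth[idx, k])
        for tol in tolerances:
            rows.append({"axis": axis, "tol": tol,
                         "accuracy": float(np.mean(err <= tol))})
    return pd.DataFrame(rows)
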