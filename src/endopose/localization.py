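"""Target localization from a class-ID mask: ellipse fit, position, scale,
and mask-derived in-plane (Y-axis) rotation.

The segmentation mask of the target is summarized by its moment-equivalent
ellipse: center = region centroid, axes = 4 * sqrt(eigenvalues) of the
second-central-moment matrix, orientation from the moment tensor.  The
ellipse center gives the image-plane position, its area gives the scale
factor through a square-root law (projected area scales with the square of
linear size), and for elongated rigid targets its major-axis angle gives
the in-plane rotation after a one-off sign/offset calibration.
"""
from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage

from .scene_sim.render import TARGET


class TargetNotFoundError(RuntimeError):
    """Requested class has no pixel in the mask."""


class AxisAmbiguousError(RuntimeError):
    """Silhouette too close to circular for an in-plane angle."""


@dataclass
class EllipseFit:
    """Moment-equivalent ellipse of a binary region (pixel units).

    ``theta`` is the major-axis angle in degrees in (-90, 90], measured
    from the image x axis toward negative image y (so a region rotated
    counter-clockwise on screen has larger theta).
    """

    cx: float
    cy: float
    major: float
    minor: float
    theta: float

    @property
    def area(self) -> float:
        """Area of the ellipse, pi/4 * major * minor."""
        return np.pi / 4.0 * self.major * self.minor

    @property
    def elongation(self) -> float:
        return self.major / self.minor


@dataclass
class ScaleReference:
    """Ellipse area registered at a known scale (default 1.0)."""

    area: float
    scale: float = 1.0

    def __post_init__(self):
        if not self.area > 0:
            raise ValueError("reference area must be positive")


@dataclass
class YRotationCalibration:
    """Mapping from ellipse angle to the model's Y rotation, fixed once per
    target from a registered frame: ry = sign * theta + offset."""

    sign: float = 1.0
    offset: float = 0.0


def largest_target_region(mask: np.ndarray, class_id: int = TARGET) -> np.ndarray:
    """Largest 8-connected component of the class as a boolean image.

    Ties are broken by the component whose first pixel comes earliest in
    row-major order.
    """
    binary = np.asarray(mask) == class_id
    if not binary.any():
        raise TargetNotFoundError("target-not-found")
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return labels == 1
    counts = np.bincount(labels.reshape(-1))[1:]
    best = np.flatnonzero(counts == counts.max()) + 1
    if len(best) == 1:
        return labels == best[0]
    # tie: earliest first pixel in row-major order (scipy labels components
    # in raster order, so the smallest label wins)
    flat = labels.reshape(-1)
    firsts = [np.argmax(flat == b) for b in best]
    return labels == best[int(np.argmin(firsts))]


def fit_ellipse(region: np.ndarray) -> EllipseFit:
    """Moment-equivalent ellipse of a binary region.

    Degenerate (collinear) regions get their minor axis floored at 1 px
    with a warning; fewer than 5 pixels is an error.
    """
    ys, xs = np.nonzero(np.asarray(region, dtype=bool))
    n = xs.size
    if n < 5:
        raise ValueError(f"need at least 5 pixels to fit an ellipse, got {n}")
    cx = xs.mean()
    cy = ys.mean()
    dx = xs - cx
    dy = ys - cy
    # second central moments in a y-up frame so theta follows the on-screen
    # counter-clockwise convention
    mu20 = (dx * dx).mean()
    mu02 = (dy * dy).mean()
    mu11 = -(dx * dy).mean()
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals = np.linalg.eigvalsh(cov)  # ascending
    major = 4.0 * np.sqrt(max(evals[1], 0.0))
    minor = 4.0 * np.sqrt(max(evals[0], 0.0))
    if minor < 1.0:
        warnings.warn("degenerate region: minor axis floored at 1 px", stacklevel=2)
        minor = 1.0
    if np.isclose(mu20, mu02) and np.isclose(mu11, 0.0):
        theta = 0.0  # isotropic region: angle undefined, report 0 by tie-break
    else:
        theta = float(np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02)))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    return EllipseFit(cx=float(cx), cy=float(cy), major=float(major),
                      minor=float(minor), theta=theta)


def estimate_position(fit: EllipseFit) -> tuple[float, float]:
    """Image-plane target position = ellipse center."""
    return fit.cx, fit.cy


def estimate_scale(fit: EllipseFit, ref: ScaleReference) -> float:
    """Scale factor from the square-root area law:
    scale = ref.scale * sqrt(area / ref.area)."""
    return float(ref.scale * np.sqrt(fit.area / ref.area))


def mask_y_rotation(fit: EllipseFit, calibration: YRotationCalibration | None = None,
                    min_elongation: float = 1.2) -> float:
    """In-plane (Y-axis) rotation of an elongated rigid target from its
    silhouette angle.  Near-circular silhouettes are rejected."""
    if fit.elongation < min_elongation:
        raise AxisAmbiguousError("axis-ambiguous")
    calibration = calibration or YRotationCalibration()
    ry = calibration.sign * fit.theta + calibration.offset
    ry = (ry + 90.0) % 180.0 - 90.0
    if ry == -90.0:
        ry = 90.0
    return float(ry)


def localize(mask: np.ndarray, ref: ScaleReference | None = None,
             class_id: int = TARGET) -> dict:
    """Convenience: region -> ellipse -> position (+ scale if a reference
    is registered).  Returns a dict with fit, tx, ty and optional scale."""
    region = largest_target_region(mask, class_id)
    fit = fit_ellipse(region)
    out = {"fit": fit, "tx": fit.cx, "ty": fit.cy}
    if ref is not None:
        out["scale"] = estimate_scale(fit, ref)
    return out
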