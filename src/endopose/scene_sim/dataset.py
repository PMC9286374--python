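"""Labeled dataset and video-sequence generation with manifests.

Manifests are CSV files with columns
``image,mask,rx,ry,rz,scale,tx,ty,split``; sequences are numbered frame
directories plus a trajectory CSV.  When no output directory is given the
frames are kept in memory and the manifest's path columns are empty.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import SceneConfig
from .mesh import MeshModel
from .pose import Pose6D, RotationRangeSpec, AXES
from .render import (SceneSample, render_scene, propose_tools, _background,
                     _draw_lighting)

MANIFEST_COLUMNS = ["image", "mask", "rx", "ry", "rz", "scale", "tx", "ty", "split"]


@dataclass
class SceneDataset:
    """Rendered samples plus their manifest (paths filled if written to disk)."""

    samples: list[SceneSample]
    manifest: pd.DataFrame
    config: SceneConfig

    def split(self, name: str) -> list[SceneSample]:
        idx = self.manifest.index[self.manifest["split"] == name]
        return [self.samples[i] for i in idx]

    def arrays(self, name: str):
        """(images, masks, rotations) arrays for one split."""
        rows = self.manifest[self.manifest["split"] == name]
        imgs = np.stack([self.samples[i].image for i in rows.index])
        masks = np.stack([self.samples[i].mask for i in rows.index])
        rots = rows[["rx", "ry", "rz"]].to_numpy(dtype=float)
        return imgs, masks, rots


@dataclass
class SceneSequence:
    """Ordered frames of a smoothly moving target with its true trajectory."""

    frames: list[SceneSample]
    trajectory: np.ndarray         # (n_frames, 3) degrees
    fps: float = 30.0

    def __len__(self):
        return len(self.frames)

    @property
    def images(self) -> list[np.ndarray]:
        return [f.image for f in self.frames]

    @property
    def masks(self) -> list[np.ndarray]:
        return [f.mask for f in self.frames]


def split_sizes(n: int) -> tuple[int, int, int]:
    """70/15/15 split with floors; the remainder goes to test."""
    n_train = int(np.floor(0.70 * n))
    n_val = int(np.floor(0.15 * n))
    return n_train, n_val, n - n_train - n_val


def sample_pose(rng: np.random.Generator, ranges: RotationRangeSpec,
                config: SceneConfig) -> Pose6D:
    """Draw one pose: uniform rotations inside each range axis (other axes
    zero), center position with optional jitter, scale within range."""
    rot = {}
    for a in AXES:
        s = ranges.axis(a)
        rot["r" + a] = float(rng.uniform(s.lo, s.hi)) if s.is_range else 0.0
    cx, cy = config.center
    j = config.pos_jitter * config.width
    tx = cx + float(rng.uniform(-j, j))
    ty = cy + float(rng.uniform(-j, j))
    lo, hi = config.scale_range
    scale = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return Pose6D(tx=tx, ty=ty, scale=scale, **rot)


def generate_dataset(mesh: MeshModel, n: int, ranges: RotationRangeSpec,
                     config: SceneConfig | None = None, seed: int = 0,
                     out_dir: str | Path | None = None) -> SceneDataset:
    """Render ``n`` labeled scenes and split them 70/15/15 train/val/test.

    Rotations are drawn uniformly per range axis; the split assignment and
    every scene nuisance are reproducible from ``seed``.
    """
    if n < 10:
        raise ValueError("need at least 10 samples for a 70/15/15 split")
    config = config or SceneConfig()
    rng = np.random.default_rng(seed)
    n_train, n_val, n_test = split_sizes(n)
    splits = np.array(["train"] * n_train + ["val"] * n_val + ["test"] * n_test)
    rng.shuffle(splits)

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    samples, rows = [], []
    for i in range(n):
        pose = sample_pose(rng, ranges, config)
        sample = render_scene(mesh, pose, config, rng=rng, seed=seed)
        samples.append(sample)
        img_path = mask_path = ""
        if out_dir is not None:
            img_path = str(out_dir / "images" / f"{i:05d}.png")
            mask_path = str(out_dir / "masks" / f"{i:05d}.png")
            iio.imwrite(img_path, sample.image)
            iio.imwrite(mask_path, sample.mask)
        rows.append([img_path, mask_path, pose.rx, pose.ry, pose.rz,
                     pose.scale, pose.tx, pose.ty, splits[i]])
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return SceneDataset(samples=samples, manifest=manifest, config=config)


def load_manifest(path: str | Path):
    """Read a manifest CSV and its referenced images/masks into arrays."""
    manifest = pd.read_csv(Path(path))
    samples = []
    for _, row in manifest.iterrows():
        img = iio.imread(row["image"])
        mask = iio.imread(row["mask"])
        pose = Pose6D(tx=row["tx"], ty=row["ty"], scale=row["scale"],
                      rx=row["rx"], ry=row["ry"], rz=row["rz"])
        samples.append(SceneSample(image=img, mask=mask, pose=pose))
    return SceneDataset(samples=samples, manifest=manifest, config=SceneConfig())


def generate_sequence(mesh: MeshModel, start_pose: Pose6D,
                      angular_rates: tuple[float, float, float], n_frames: int,
                      config: SceneConfig | None = None, seed: int = 0,
                      ranges: RotationRangeSpec | None = None,
                      fps: float = 30.0,
                      out_dir: str | Path | None = None) -> SceneSequence:
    """Render a smooth video of the target rotating at fixed rates (deg/frame).

    Texture phase, lighting, backdrop and tool placement are held fixed for
    the whole sequence so consecutive-frame optical flow reflects target
    motion only.  If the trajectory leaves a configured rotation range it is
    clamped there and a warning is recorded.
    """
    if n_frames < 2:
        raise ValueError("a sequence needs at least 2 frames")
    config = config or SceneConfig()
    rng = np.random.default_rng(seed)
    texture_phase = rng.uniform(0, 2 * np.pi, 3)
    lighting = _draw_lighting(rng, config)
    background = _background(config, rng)
    tools = propose_tools(rng, start_pose, config)

    rates = np.asarray(angular_rates, dtype=float)
    start = start_pose.rotations
    traj = start[None, :] + np.arange(n_frames)[:, None] * rates[None, :]
    if ranges is not None:
        clipped = traj.copy()
        for k, a in enumerate(AXES):
            s = ranges.axis(a)
            if s.is_range:
                clipped[:, k] = np.clip(traj[:, k], s.lo, s.hi)
        if not np.allclose(clipped, traj):
            warnings.warn("trajectory leaves the configured rotation range; clamped",
                          stacklevel=2)
        traj = clipped

    frames = []
    for i in range(n_frames):
        pose = start_pose.with_rotations(traj[i])
        frames.append(render_scene(
            mesh, pose, config, rng=rng, seed=seed, texture_phase=texture_phase,
            lighting=lighting, tools=tools, background=background))
    seq = SceneSequence(frames=frames, trajectory=traj, fps=fps)
    if out_dir is not None:
        write_sequence(seq, out_dir)
    return seq


def write_sequence(seq: SceneSequence, out_dir: str | Path) -> Path:
    """Numbered frame directory + trajectory CSV."""
    out_dir = Path(out_dir)
    (out_dir / "frames").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    for i, fr in enumerate(seq.frames):
        iio.imwrite(out_dir / "frames" / f"{i:05d}.png", fr.image)
        iio.imwrite(out_dir / "masks" / f"{i:05d}.png", fr.mask)
    df = pd.DataFrame(seq.trajectory, columns=["rx", "ry", "rz"])
    for col in ("tx", "ty", "scale"):
        df[col] = [getattr(fr.pose, col) for fr in seq.frames]
    df.to_csv(out_dir / "trajectory.csv", index_label="frame")
    return out_dir


def read_sequence(in_dir: str | Path) -> SceneSequence:
    in_dir = Path(in_dir)
    traj = pd.read_csv(in_dir / "trajectory.csv")[["rx", "ry", "rz"]].to_numpy()
    frames = []
    for i in range(len(traj)):
        img = iio.imread(in_dir / "frames" / f"{i:05d}.png")
        mask_file = in_dir / "masks" / f"{i:05d}.png"
        mask = iio.imread(mask_file) if mask_file.exists() else None
        pose = Pose6D(tx=0, ty=0, scale=1.0, rx=traj[i, 0], ry=traj[i, 1],
                      rz=traj[i, 2])
        frames.append(SceneSample(image=img, mask=mask, pose=pose))
    return SceneSequence(frames=frames, trajectory=traj)
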