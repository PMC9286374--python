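"""Scene configuration: camera, lighting, texture, tools, sampling jitter."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml


@dataclass
class SceneConfig:
    """All tunable knobs of the simulated endoscopic scene.

    The camera is a pinhole at the origin looking down ``-Z``; ``focal_frac``
    sets the focal length so that a unit-radius object at ``scale`` 1 projects
    to a radius of ``focal_frac * height`` pixels at the reference distance
    ``ref_distance`` (model units).
    """

    width: int = 96
    height: int = 96
    ref_distance: float = 6.0
    focal_frac: float = 0.30

    # lighting: Lambertian with a seeded jittered direction, plus the
    # endoscope headlight 1/d^2 falloff (normalized at ref_distance)
    ambient: float = 0.35
    diffuse: float = 0.65
    light_jitter: float = 0.15     # fractional jitter of direction / intensity
    headlight: float = 1.0         # 0 disables the inverse-square falloff

    # procedural surface texture of the target
    texture_freq: float = 2.5      # cycles per model unit
    texture_amp: float = 0.35      # fractional albedo modulation

    # rod-shaped instruments that may partially occlude the target
    max_tools: int = 2
    tool_radius: float = 0.10      # model units
    occlusion_cap: float = 0.40    # max occluded fraction of the target silhouette

    # pose sampling jitter used by the dataset generator
    pos_jitter: float = 0.0        # +- fraction of image width on (tx, ty)
    scale_range: tuple = (1.0, 1.0)

    # domain-shift variant emulating real intraoperative frames
    domain_shift: bool = False
    specular: float = 0.0          # specular strength (domain-shift default 0.35)
    mask_noise: float = 0.0        # fraction of boundary label pixels flipped

    background_level: float = 0.30

    @property
    def focal(self) -> float:
        return self.focal_frac * self.height * self.ref_distance

    @property
    def center(self) -> tuple:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)

    def shifted(self) -> "SceneConfig":
        """The domain-shift variant emulating real intraoperative frames:
        much stronger lighting jitter, wet-surface specular highlights,
        flatter ambient illumination and mild mask-boundary noise."""
        return replace(self, domain_shift=True, light_jitter=0.6,
                       specular=0.7, ambient=0.55, diffuse=0.45,
                       headlight=0.5, background_level=0.45,
                       mask_noise=0.03)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "scale_range" in data:
            data["scale_range"] = tuple(data["scale_range"])
        return cls(**data)
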