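"""Software rasterizer for the simulated endoscopic scene.

Pinhole camera at the origin looking down ``-Z`` (world ``+Y`` up), image
``y`` downward.  Triangles are projected, filled by barycentric coverage
with a z-buffer resolve, Gouraud-lit (Lambertian plus optional specular)
and textured per pixel from interpolated model-space coordinates, so the
texture is rigidly attached to the surface and frame-to-frame optical flow
on the target is physically meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import SceneConfig
from .mesh import MeshModel, make_mesh, INSTRUMENT_CYLINDER
from .pose import Pose6D, rotation_matrix

BACKGROUND, TOOL, TARGET = 0, 1, 2

_TARGET_COLOR = np.array([0.80, 0.47, 0.42])
_TOOL_COLOR = np.array([0.55, 0.58, 0.62])
_BG_COLOR = np.array([0.42, 0.20, 0.17])


class TargetOutOfViewError(RuntimeError):
    """The posed target projects entirely outside the frame."""


@dataclass
class ToolSpec:
    """Placement of one rod-shaped instrument, in image/depth terms."""

    tip_u: float
    tip_v: float
    angle: float        # image-plane direction of the rod, radians
    depth_frac: float   # tool depth as a fraction of the target depth
    z_tilt: float = 0.0


@dataclass
class Lighting:
    direction: np.ndarray
    intensity: float = 1.0


@dataclass
class SceneSample:
    """One rendered frame with its ground truth."""

    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) uint8, IDs {0 bg, 1 tool, 2 target}
    pose: Pose6D
    meta: dict = field(default_factory=dict)


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    fn = np.cross(vertices[faces[:, 1]] - vertices[faces[:, 0]],
                  vertices[faces[:, 2]] - vertices[faces[:, 0]])
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def _project(points: np.ndarray, config: SceneConfig):
    """World points -> (u, v) pixels and positive depth along -Z."""
    cx, cy = config.center
    depth = -points[:, 2]
    f = config.focal
    u = cx + f * points[:, 0] / depth
    v = cy - f * points[:, 1] / depth
    return np.stack([u, v], axis=1), depth


def _target_world_transform(mesh: MeshModel, pose: Pose6D, config: SceneConfig):
    """Rotation and translation taking model coords to world coords."""
    R = mesh.mount @ rotation_matrix(pose.rx, pose.ry, pose.rz)
    d = config.ref_distance / pose.scale
    cx, cy = config.center
    f = config.focal
    center = np.array([(pose.tx - cx) * d / f, (cy - pose.ty) * d / f, -d])
    return R, center


def _rasterize(prims: list[dict], config: SceneConfig, shade: bool,
               lighting: Lighting | None, texture_phase: np.ndarray | None):
    """Z-buffer rasterization of world-space triangle primitives.

    Each prim: vertices (world), faces, class_id, model_coords, base_color,
    textured (bool).  Returns (image float HxWx3 or None, class map, depth).
    """
    H, W = config.height, config.width
    img = np.zeros((H, W, 3), dtype=np.float32) if shade else None
    cls = np.zeros((H, W), dtype=np.uint8)
    depth_map = np.full((H, W), np.inf, dtype=np.float32)

    frag_pix, frag_depth, frag_cls, frag_attr = [], [], [], []

    for prim in prims:
        verts = prim["vertices"]
        faces = prim["faces"]
        uv, vdepth = _project(verts, config)
        if shade:
            normals = prim["normals"]
            l = lighting.direction
            lam = config.ambient + config.diffuse * lighting.intensity * np.clip(
                normals @ l, 0.0, None)
            if config.headlight > 0:
                # inverse-square falloff of the scope's own light source
                falloff = np.clip((config.ref_distance / vdepth) ** 2, 0.0, 4.0)
                lam = lam * (1.0 - config.headlight + config.headlight * falloff)
            if config.specular > 0:
                # Blinn-Phong half vector with the view direction (+Z toward camera)
                h = l + np.array([0.0, 0.0, 1.0])
                h = h / np.linalg.norm(h)
                lam = lam + config.specular * np.clip(normals @ h, 0.0, None) ** 16
            # interpolated attributes: model coords (3) + intensity (1)
            attr = np.concatenate([prim["model_coords"], lam[:, None]], axis=1)
        else:
            attr = np.zeros((len(verts), 0))

        tri_uv = uv[faces]          # (T, 3, 2)
        tri_d = vdepth[faces]       # (T, 3)
        tri_a = attr[faces]         # (T, 3, A)

        # cull triangles behind the camera or fully outside the frame
        ok = (tri_d > 0.05).all(axis=1)
        bmin = np.ceil(tri_uv.min(axis=1)).astype(int)
        bmax = np.floor(tri_uv.max(axis=1)).astype(int)
        bmin = np.maximum(bmin, 0)
        bmax = np.minimum(bmax, [W - 1, H - 1])
        ok &= (bmin <= bmax).all(axis=1)
        x0, y0 = tri_uv[:, 0, 0], tri_uv[:, 0, 1]
        x1, y1 = tri_uv[:, 1, 0], tri_uv[:, 1, 1]
        x2, y2 = tri_uv[:, 2, 0], tri_uv[:, 2, 1]
        area = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
        ok &= np.abs(area) > 1e-12
        if not ok.any():
            continue
        tri_uv, tri_d, tri_a = tri_uv[ok], tri_d[ok], tri_a[ok]
        bmin, bmax, area = bmin[ok], bmax[ok], area[ok]

        ext = (bmax - bmin).max(axis=0) + 1
        E_x, E_y = int(ext[0]), int(ext[1])
        # chunk so candidate-fragment arrays stay modest
        max_frag = 4_000_000
        step = max(1, max_frag // max(E_x * E_y, 1))
        for s in range(0, len(tri_uv), step):
            sl = slice(s, s + step)
            _raster_chunk(tri_uv[sl], tri_d[sl], tri_a[sl], area[sl],
                          bmin[sl], bmax[sl], E_x, E_y, prim["class_id"],
                          frag_pix, frag_depth, frag_cls, frag_attr, W)

    if frag_pix:
        pix = np.concatenate(frag_pix)
        dep = np.concatenate(frag_depth)
        cid = np.concatenate(frag_cls)
        att = np.concatenate(frag_attr) if shade else None
        order = np.argsort(-dep, kind="stable")  # nearest written last
        pix, dep, cid = pix[order], dep[order], cid[order]
        depth_map.reshape(-1)[pix] = dep
        cls.reshape(-1)[pix] = cid
        if shade:
            att = att[order]
            _shade_fragments(img, pix, cid, att, config, texture_phase, prims, W)
    return img, cls, depth_map


def _raster_chunk(tri_uv, tri_d, tri_a, area, bmin, bmax, E_x, E_y, class_id,
                  frag_pix, frag_depth, frag_cls, frag_attr, W):
    T = len(tri_uv)
    gx = np.arange(E_x)
    gy = np.arange(E_y)
    px = bmin[:, 0, None, None] + gx[None, None, :]
    py = bmin[:, 1, None, None] + gy[None, :, None]
    valid = (px <= bmax[:, 0, None, None]) & (py <= bmax[:, 1, None, None])

    x0 = tri_uv[:, 0, 0, None, None]
    y0 = tri_uv[:, 0, 1, None, None]
    x1 = tri_uv[:, 1, 0, None, None]
    y1 = tri_uv[:, 1, 1, None, None]
    x2 = tri_uv[:, 2, 0, None, None]
    y2 = tri_uv[:, 2, 1, None, None]
    ar = area[:, None, None]
    w0 = ((x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)) / ar
    w1 = ((x0 - x2) * (py - y2) - (y0 - y2) * (px - x2)) / ar
    w2 = 1.0 - w0 - w1
    eps = -1e-9
    inside = valid & (w0 >= eps) & (w1 >= eps) & (w2 >= eps)
    if not inside.any():
        return
    d = (w0 * tri_d[:, 0, None, None] + w1 * tri_d[:, 1, None, None]
         + w2 * tri_d[:, 2, None, None])
    px = np.broadcast_to(px, inside.shape)
    py = np.broadcast_to(py, inside.shape)
    frag_pix.append((py[inside] * W + px[inside]).astype(np.int64))
    frag_depth.append(d[inside].astype(np.float32))
    frag_cls.append(np.full(inside.sum(), class_id, dtype=np.uint8))
    if tri_a.shape[-1]:
        a = (w0[..., None] * tri_a[:, None, None, 0, :]
             + w1[..., None] * tri_a[:, None, None, 1, :]
             + w2[..., None] * tri_a[:, None, None, 2, :])
        frag_attr.append(a[inside].astype(np.float32))
    else:
        frag_attr.append(np.zeros((int(inside.sum()), 0), dtype=np.float32))


def _texture(model_coords: np.ndarray, freq: float, amp: float,
             phase: np.ndarray) -> np.ndarray:
    p = model_coords
    w = 2 * np.pi * freq
    t = (np.sin(w * p[:, 0] + phase[0]) * np.sin(w * 1.31 * p[:, 1] + phase[1])
         + 0.6 * np.sin(w * 2.17 * p[:, 2] + w * 0.71 * p[:, 0] + phase[2]))
    return np.clip(1.0 + amp * t / 1.6, 0.2, 1.8)


def _shade_fragments(img, pix, cid, att, config, texture_phase, prims, W):
    base = {p["class_id"]: (p["base_color"], p["textured"]) for p in prims}
    flat = img.reshape(-1, 3)
    for class_id, (color, textured) in base.items():
        sel = cid == class_id
        if not sel.any():
            continue
        inten = att[sel, 3]
        c = color[None, :] * inten[:, None]
        if textured and texture_phase is not None:
            tex = _texture(att[sel, :3], config.texture_freq,
                           config.texture_amp, texture_phase)
            c = c * tex[:, None]
        flat[pix[sel]] = c


_UNIT_TOOL_CACHE: dict = {}


def _unit_tool(radius: float) -> MeshModel:
    key = round(radius, 6)
    if key not in _UNIT_TOOL_CACHE:
        _UNIT_TOOL_CACHE[key] = make_mesh(
            INSTRUMENT_CYLINDER, {"radius": radius, "length": 1.0, "max_edge": 0.35})
    return _UNIT_TOOL_CACHE[key]


def _align_z(direction: np.ndarray) -> np.ndarray:
    """Rotation taking +Z to the given unit direction (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    d = direction / np.linalg.norm(direction)
    v = np.cross(z, d)
    c = float(z @ d)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def _tool_world(tool: ToolSpec, target_depth: float, config: SceneConfig):
    """World-space vertices of a rod entering the frame toward its tip."""
    cx, cy = config.center
    f = config.focal
    d_tip = tool.depth_frac * target_depth
    tip = np.array([(tool.tip_u - cx) * d_tip / f,
                    (cy - tool.tip_v) * d_tip / f, -d_tip])
    span = 2.5 * max(config.width, config.height) * d_tip / f
    back_uv = np.array([tool.tip_u - span * np.cos(tool.angle) * f / d_tip,
                        tool.tip_v - span * np.sin(tool.angle) * f / d_tip])
    # keep the back end at a slightly different depth for a 3D look
    d_back = d_tip * (1.0 + tool.z_tilt)
    back = np.array([(back_uv[0] - cx) * d_back / f,
                     (cy - back_uv[1]) * d_back / f, -d_back])
    axis = tip - back
    length = np.linalg.norm(axis)
    # model-unit radius: keep the projected rod width independent of depth
    base = _unit_tool(config.tool_radius)
    verts = base.vertices.copy()
    verts[:, 2] *= length          # unit length -> segment length
    Rz = _align_z(axis / length)
    world = verts @ Rz.T + (tip + back) / 2.0
    return world, base.faces


def _background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth, seeded low-frequency tissue-like backdrop."""
    H, W = config.height, config.width
    coarse = rng.normal(0.0, 1.0, (3, 7, 7))
    img = np.empty((H, W, 3), dtype=np.float32)
    for c in range(3):
        field = ndimage.zoom(coarse[c], (H / 7, W / 7), order=3)[:H, :W]
        img[:, :, c] = _BG_COLOR[c] * config.background_level / 0.30 * (
            1.0 + 0.35 * field)
    return np.clip(img, 0.0, 1.0)


def propose_tools(rng: np.random.Generator, pose: Pose6D, config: SceneConfig,
                  n_tools: int | None = None) -> list[ToolSpec]:
    """Draw instrument placements aimed near (but offset from) the target."""
    if n_tools is None:
        n_tools = int(rng.integers(0, config.max_tools + 1))
    tools = []
    r_proj = config.focal_frac * config.height
    for _ in range(n_tools):
        rho = rng.uniform(0.4, 1.1) * r_proj
        phi = rng.uniform(0, 2 * np.pi)
        tools.append(ToolSpec(
            tip_u=pose.tx + rho * np.cos(phi),
            tip_v=pose.ty + rho * np.sin(phi),
            angle=rng.uniform(0, 2 * np.pi),
            depth_frac=rng.uniform(0.55, 0.8),
            z_tilt=rng.uniform(-0.05, 0.10),
        ))
    return tools


def _draw_lighting(rng: np.random.Generator, config: SceneConfig) -> Lighting:
    base = np.array([0.3, 0.35, 1.0])
    d = base + config.light_jitter * rng.normal(0, 1, 3)
    d = d / np.linalg.norm(d)
    return Lighting(direction=d,
                    intensity=float(1.0 + config.light_jitter * rng.uniform(-1, 1)))


def render_scene(mesh: MeshModel, pose: Pose6D, config: SceneConfig | None = None,
                 *, seed: int = 0, rng: np.random.Generator | None = None,
                 texture_phase: np.ndarray | None = None,
                 lighting: Lighting | None = None,
                 tools: list[ToolSpec] | None = None,
                 background: np.ndarray | None = None) -> SceneSample:
    """Render one labeled frame of the target (plus 0-2 occluding tools).

    All unspecified scene nuisances (lighting, texture phase, tool
    placement, backdrop) are drawn deterministically from ``seed`` /
    ``rng``; pass them explicitly to hold them fixed across a sequence.

    Raises
    ------
    TargetOutOfViewError
        If the posed target has no visible silhouette pixel.
    """
    config = config or SceneConfig()
    if config.width < 32 or config.height < 32:
        raise ValueError("frame size must be at least 32x32")
    if not np.all(np.isfinite([pose.rx, pose.ry, pose.rz, pose.tx, pose.ty, pose.scale])):
        raise ValueError("pose must be finite")
    rng = rng if rng is not None else np.random.default_rng(seed)

    if texture_phase is None:
        texture_phase = rng.uniform(0, 2 * np.pi, 3)
    if lighting is None:
        lighting = _draw_lighting(rng, config)
    if background is None:
        background = _background(config, rng)

    R, center = _target_world_transform(mesh, pose, config)
    tverts = mesh.vertices @ R.T + center
    tnorm = _vertex_normals(mesh.vertices, mesh.faces) @ R.T
    target_prim = {
        "vertices": tverts, "faces": mesh.faces, "class_id": TARGET,
        "model_coords": mesh.vertices, "normals": tnorm,
        "base_color": _TARGET_COLOR, "textured": True,
    }

    # silhouette / depth of the unoccluded target, also the occlusion reference
    _, sil_cls, sil_depth = _rasterize([target_prim], config, shade=False,
                                       lighting=None, texture_phase=None)
    sil = sil_cls == TARGET
    sil_area = int(sil.sum())
    if sil_area == 0:
        raise TargetOutOfViewError("target-out-of-view")

    target_depth = config.ref_distance / pose.scale
    if tools is None:
        tools = propose_tools(rng, pose, config)
    accepted: list[ToolSpec] = []
    occluded = np.zeros_like(sil)
    tool_prims = []
    for tool in tools:
        spec = tool
        for attempt in range(20):
            world, faces = _tool_world(spec, target_depth, config)
            prim = {"vertices": world, "faces": faces, "class_id": TOOL,
                    "model_coords": _unit_tool(config.tool_radius).vertices,
                    "normals": _vertex_normals(world, faces),
                    "base_color": _TOOL_COLOR, "textured": False}
            _, tcls, tdepth = _rasterize([prim], config, shade=False,
                                         lighting=None, texture_phase=None)
            occ = sil & (tcls == TOOL) & (tdepth < sil_depth)
            if (occluded | occ).sum() / sil_area <= config.occlusion_cap:
                occluded |= occ
                accepted.append(spec)
                tool_prims.append(prim)
                break
            spec = propose_tools(rng, pose, config, n_tools=1)[0]

    img, cls, depth = _rasterize([target_prim] + tool_prims, config, shade=True,
                                 lighting=lighting, texture_phase=texture_phase)
    out = background.copy()
    lit = cls > 0
    out[lit] = img[lit]
    # mild seeded sensor noise
    out = np.clip(out + rng.normal(0, 0.008, out.shape).astype(np.float32), 0, 1)
    mask = cls.copy()
    if config.mask_noise > 0:
        mask = _noisy_mask(mask, config.mask_noise, rng)
    return SceneSample(
        image=(out * 255.0 + 0.5).astype(np.uint8),
        mask=mask,
        pose=pose,
        meta={"seed": seed, "texture_phase": texture_phase.tolist(),
              "light_direction": lighting.direction.tolist(),
              "light_intensity": lighting.intensity,
              "tools": len(accepted), "silhouette_area": sil_area,
              "occluded_fraction": float(occluded.sum() / sil_area)},
    )


def _noisy_mask(mask: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Flip a fraction of target-boundary labels (annotation-style noise)."""
    tgt = mask == TARGET
    boundary = tgt ^ ndimage.binary_erosion(tgt)
    outer = ndimage.binary_dilation(tgt) & ~tgt & (mask == BACKGROUND)
    out = mask.copy()
    flip_off = boundary & (rng.random(mask.shape) < frac)
    flip_on = outer & (rng.random(mask.shape) < frac)
    out[flip_off] = BACKGROUND
    out[flip_on] = TARGET
    return out
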