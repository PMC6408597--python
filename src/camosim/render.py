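"""Stereo rendering of scene layouts with ground-truth masks and disparity.

A deliberately simple z-buffer rasterizer: vertices are shaded (Gouraud)
under either a uniform-hemisphere ambient model or a collimated directional
source with cast shadows, projected through an angle-linear pinhole model
(each pixel spans a fixed angular step, so pixel distances divide exactly
by the configured pixels-per-degree), and triangles are filled with
barycentric interpolation against a depth buffer.

Cast shadows are tested by marching each point towards the light through
the layout's occupancy slabs (top / underside height fields), which makes
the shadow of an element raised by ``h`` land ``h / tan(elevation)`` away
from its footprint, opposite the light azimuth.

Conventions
-----------
* Azimuth: degrees clockwise from the +Y (screen-up) axis seen from above;
  350 deg places the source slightly left of up, shadows fall down-right.
* Disparity: degrees, crossed (nearer than the 57 cm image plane) positive.
* Depth: axial distance from the eye plane, cm (image plane = 57).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import SceneLayout, build_leaf_mesh, build_snake_mesh

__all__ = [
    "CameraRig",
    "LightModel",
    "RenderOutput",
    "View",
    "render_view",
    "render_trial",
    "make_anaglyph",
    "disparity_map",
]

GROUND_ID, LEAF_ID, SNAKE_ID = 0, 1, 2


@dataclass(frozen=True)
class CameraRig:
    """Stereo camera pair on the cyclopean axis, 57 cm from the image plane."""

    ipd: float = 6.5
    distance: float = 57.0
    image_size: tuple[int, int] = (1200, 870)  # (width, height) px
    field: tuple[float, float] = (39.64, 28.74)  # (width, height) deg
    mode: str = "stereoscopic"

    def __post_init__(self) -> None:
        if self.ipd <= 0:
            raise ValueError("ipd must be > 0")
        if self.mode not in ("stereoscopic", "monoscopic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def ppd_x(self) -> float:
        return self.image_size[0] / self.field[0]

    @property
    def ppd_y(self) -> float:
        return self.image_size[1] / self.field[1]

    def pixel_angles(self) -> tuple[np.ndarray, np.ndarray]:
        """Azimuth/elevation (deg) of pixel centres; row 0 is the top row."""
        w, h = self.image_size
        u = (np.arange(w) + 0.5) / self.ppd_x - self.field[0] / 2.0
        v = self.field[1] / 2.0 - (np.arange(h) + 0.5) / self.ppd_y
        return u, v


@dataclass(frozen=True)
class LightModel:
    """Uniform-hemisphere ambient light or a collimated directional source."""

    kind: str = "ambient"
    elevation: float = 45.0
    azimuth: float = 350.0
    ambient_floor: float = 0.15  # residual illumination inside shadows

    def __post_init__(self) -> None:
        if self.kind not in ("ambient", "directional"):
            raise ValueError(f"unknown light kind {self.kind!r}")

    @property
    def casts_shadows(self) -> bool:
        return self.kind == "directional"

    def direction(self) -> np.ndarray:
        """Unit vector from the surface towards the light."""
        el = np.deg2rad(self.elevation)
        az = np.deg2rad(self.azimuth)
        return np.array(
            [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)]
        )


@dataclass
class View:
    """Single-eye render: image, axial depth and object-id buffers."""

    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    depth: np.ndarray  # (H, W) cm from the eye plane
    ids: np.ndarray  # (H, W) int object ids

    @property
    def snake_mask(self) -> np.ndarray:
        return (self.ids == SNAKE_ID).astype(np.uint8)


@dataclass
class RenderOutput:
    """Stereo pair plus cyclopean ground truth."""

    left: np.ndarray
    right: np.ndarray
    snake_mask: np.ndarray  # cyclopean
    snake_mask_left: np.ndarray
    snake_mask_right: np.ndarray
    depth: np.ndarray  # cyclopean, cm
    disparity: np.ndarray  # deg, crossed positive
    ids: np.ndarray  # cyclopean object ids
    rig: CameraRig
    light: LightModel


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _shadow_lit(
    points: np.ndarray, layout: SceneLayout, light: LightModel, skip_rise: float
) -> np.ndarray:
    """1.0 where a point sees the directional source, 0.0 where occluded.

    Marches towards the light in half-cell steps, testing the ray height
    against the [underside, top] slab of each crossed cell.  The first
    ``skip_rise`` cm of ray rise are skipped so elements do not shadow
    their own surfaces (curled leaf centres sit below their cell top).
    """
    l = light.direction()
    if l[2] <= 0:
        return np.zeros(len(points))
    top = layout.height_field
    if top.max() <= 0:
        return np.ones(len(points))
    step = layout.cell * 0.5
    z_max = float(top.max())
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    lit = np.ones(len(points), dtype=bool)
    t = max(skip_rise / l[2], step)
    t_stop = (z_max - z.min()) / l[2] + step
    while t < t_stop:
        sx = x + l[0] * t
        sy = y + l[1] * t
        sz = z + l[2] * t
        tops = layout.sample_height(sx, sy)
        w, h = layout.bounds
        ix = np.floor((sx + w / 2.0) / layout.cell).astype(int)
        iy = np.floor((sy + h / 2.0) / layout.cell).astype(int)
        ny, nx = layout.grid_shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        bottoms = np.full(len(points), np.inf)
        bottoms[inside] = layout.underside_field[iy[inside], ix[inside]]
        # half a vertical step of margin so slabs thinner than the step
        # cannot fall between consecutive samples
        margin = 0.5 * step * l[2]
        hit = inside & (sz <= tops + margin) & (sz >= bottoms - margin) & (tops > 0)
        lit &= ~hit
        t += step
    return lit.astype(float)


def _shade(
    normals: np.ndarray,
    albedo: np.ndarray,
    points: np.ndarray,
    layout: SceneLayout,
    light: LightModel,
    skip_rise: float,
) -> np.ndarray:
    """Lambertian vertex shading under the configured illumination model."""
    if light.kind == "ambient":
        # cosine-weighted uniform upper hemisphere, no cast shadows
        inten = 0.5 * (1.0 + np.clip(normals[:, 2], -1.0, 1.0))
    else:
        direct = np.clip(normals @ light.direction(), 0.0, None)
        vis = _shadow_lit(points, layout, light, skip_rise)
        inten = light.ambient_floor + (1.0 - light.ambient_floor) * direct * vis
    return np.clip(albedo * inten[:, None], 0.0, 1.0)


def _project(
    points: np.ndarray, eye_x: float, rig: CameraRig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Off-axis projection through the shared screen plane, plus axial depth.

    Each eye's ray is intersected with the image (ground) plane and the
    intersection is mapped to pixels through the cyclopean angular grid, as
    on a stereo display: points on the 57 cm plane land on identical pixels
    in both eyes (zero disparity), nearer points shift oppositely.
    """
    dz = rig.distance - points[:, 2]
    xs = eye_x + (points[:, 0] - eye_x) * rig.distance / dz
    ys = points[:, 1] * rig.distance / dz
    u = np.degrees(np.arctan2(xs, rig.distance))
    v = np.degrees(np.arctan2(ys, rig.distance))
    px = (u + rig.field[0] / 2.0) * rig.ppd_x - 0.5
    py = (rig.field[1] / 2.0 - v) * rig.ppd_y - 0.5
    return px, py, dz


def _rasterize(
    view: View,
    px: np.ndarray,
    py: np.ndarray,
    dz: np.ndarray,
    colors: np.ndarray,
    faces: np.ndarray,
    obj_id: int,
) -> None:
    """Fill triangles into the view buffers with a z-test."""
    W = view.rgb.shape[1]
    H = view.rgb.shape[0]
    tri_px = px[faces]
    tri_py = py[faces]
    order = np.arange(len(faces))
    for k in order:
        xs, ys = tri_px[k], tri_py[k]
        ix0 = max(int(np.ceil(xs.min())), 0)
        ix1 = min(int(np.floor(xs.max())), W - 1)
        iy0 = max(int(np.ceil(ys.min())), 0)
        iy1 = min(int(np.floor(ys.max())), H - 1)
        if ix0 > ix1 or iy0 > iy1:
            continue
        x0, x1, x2 = xs
        y0, y1, y2 = ys
        denom = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
        if abs(denom) < 1e-12:
            continue
        gx, gy = np.meshgrid(
            np.arange(ix0, ix1 + 1, dtype=float), np.arange(iy0, iy1 + 1, dtype=float)
        )
        l0 = ((y1 - y2) * (gx - x2) + (x2 - x1) * (gy - y2)) / denom
        l1 = ((y2 - y0) * (gx - x2) + (x0 - x2) * (gy - y2)) / denom
        l2 = 1.0 - l0 - l1
        inside = (l0 >= -1e-9) & (l1 >= -1e-9) & (l2 >= -1e-9)
        if not inside.any():
            continue
        i0, i1, i2 = faces[k]
        depth = l0 * dz[i0] + l1 * dz[i1] + l2 * dz[i2]
        ys_idx, xs_idx = np.nonzero(inside)
        rows = ys_idx + iy0
        cols = xs_idx + ix0
        d = depth[ys_idx, xs_idx]
        closer = d < view.depth[rows, cols]
        if not closer.any():
            continue
        rows, cols = rows[closer], cols[closer]
        ys_idx, xs_idx = ys_idx[closer], xs_idx[closer]
        col = (
            l0[ys_idx, xs_idx, None] * colors[i0]
            + l1[ys_idx, xs_idx, None] * colors[i1]
            + l2[ys_idx, xs_idx, None] * colors[i2]
        )
        view.depth[rows, cols] = d[closer]
        view.rgb[rows, cols] = col
        view.ids[rows, cols] = obj_id


def _ground_view(
    layout: SceneLayout, eye_x: float, rig: CameraRig, light: LightModel
) -> View:
    """Initialise buffers with the shaded ground plane at z = 0."""
    u, v = rig.pixel_angles()
    W, H = rig.image_size
    tanu = np.tan(np.deg2rad(u))[None, :]
    tanv = np.tan(np.deg2rad(v))[:, None]
    # the ground plane coincides with the screen plane, so its pixel->world
    # mapping is eye-independent under the off-axis projection
    gx = rig.distance * np.broadcast_to(tanu, (H, W))
    gy = rig.distance * np.broadcast_to(tanv, (H, W))
    albedo = np.asarray(layout.ground_color, dtype=float)
    if light.kind == "ambient":
        inten = np.ones((H, W))
    else:
        l = light.direction()
        pts = np.stack([gx.ravel(), gy.ravel(), np.zeros(H * W)], axis=-1)
        vis = _shadow_lit(pts, layout, light, skip_rise=0.02).reshape(H, W)
        inten = light.ambient_floor + (1.0 - light.ambient_floor) * l[2] * vis
    rgb = np.clip(albedo[None, None, :] * inten[..., None], 0.0, 1.0)
    depth = np.full((H, W), rig.distance, dtype=float)
    ids = np.full((H, W), GROUND_ID, dtype=np.int16)
    return View(rgb=rgb, depth=depth, ids=ids)


def _snake_albedo(mesh, texture) -> np.ndarray:
    """Per-vertex albedo sampled (nearest) from the body-mapped texture."""
    if texture is None:
        return np.full((len(mesh.vertices), 3), 0.5)
    th, tw = texture.rgb.shape[:2]
    cols = np.clip((mesh.uv[:, 0] * (tw - 1)).round().astype(int), 0, tw - 1)
    rows = np.clip((mesh.uv[:, 1] * (th - 1)).round().astype(int), 0, th - 1)
    return texture.rgb[rows, cols]


def render_view(
    layout: SceneLayout, eye_x: float, light: LightModel, rig: CameraRig
) -> View:
    """Render one eye's view of the layout (deterministic)."""
    view = _ground_view(layout, eye_x, rig, light)
    leaf_skip = layout.leaf_params.thickness + layout.leaf_params.curl + 0.01
    if layout.leaves:
        proto = build_leaf_mesh(layout.leaf_params)
        for leaf in layout.leaves:
            R = _rot_z(leaf.angle)
            verts = proto.vertices @ R.T + np.array(
                [leaf.x, leaf.y, leaf.z + layout.leaf_params.thickness]
            )
            normals = proto.normals @ R.T
            albedo = np.broadcast_to(np.asarray(leaf.color), (len(verts), 3))
            colors = _shade(normals, albedo, verts, layout, light, leaf_skip)
            px, py, dz = _project(verts, eye_x, rig)
            _rasterize(view, px, py, dz, colors, proto.faces, LEAF_ID)
    if layout.snake is not None and layout.snake_params is not None:
        mesh = build_snake_mesh(layout.snake_params)
        R = _rot_z(layout.snake.angle)
        verts = mesh.vertices @ R.T + np.array(
            [layout.snake.x, layout.snake.y, layout.snake.z]
        )
        normals = mesh.normals @ R.T
        albedo = _snake_albedo(mesh, layout.snake_texture)
        skip = layout.snake_params.height + 0.01
        colors = _shade(normals, albedo, verts, layout, light, skip)
        px, py, dz = _project(verts, eye_x, rig)
        _rasterize(view, px, py, dz, colors, mesh.faces, SNAKE_ID)
    return view


def disparity_map(depth: np.ndarray, rig: CameraRig) -> np.ndarray:
    """Signed horizontal disparity (deg) from cyclopean depth.

    For each pixel the cyclopean ray is intersected at its axial depth; the
    disparity is the difference of the two eyes' azimuths to that point,
    referenced to the azimuth difference for the image-plane point in the
    same visual direction (so the 57 cm plane carries zero disparity).
    Crossed (near) disparities are positive.
    """
    u, v = rig.pixel_angles()
    tanu = np.tan(np.deg2rad(u))[None, :]
    dz = depth
    x = tanu * dz
    half = rig.ipd / 2.0
    point = np.arctan2(x + half, dz) - np.arctan2(x - half, dz)
    xs = tanu * rig.distance
    ref = np.arctan2(xs + half, rig.distance) - np.arctan2(xs - half, rig.distance)
    return np.degrees(point - ref)


def render_trial(
    layout: SceneLayout, rig: CameraRig, light: LightModel
) -> RenderOutput:
    """Render a full trial: stereo (or duplicated mono) pair + ground truth."""
    cyc = render_view(layout, 0.0, light, rig)
    if rig.mode == "monoscopic":
        left = right = cyc
    else:
        left = render_view(layout, -rig.ipd / 2.0, light, rig)
        right = render_view(layout, +rig.ipd / 2.0, light, rig)
    return RenderOutput(
        left=left.rgb,
        right=right.rgb,
        snake_mask=cyc.snake_mask,
        snake_mask_left=left.snake_mask,
        snake_mask_right=right.snake_mask,
        depth=cyc.depth,
        disparity=disparity_map(cyc.depth, rig),
        ids=cyc.ids,
        rig=rig,
        light=light,
    )


_LUMA = np.array([0.2126, 0.7152, 0.0722])


def make_anaglyph(output: RenderOutput) -> np.ndarray:
    """Red/green anaglyph: left luminance in red, right in green, blue 0."""
    out = np.zeros_like(output.left)
    out[..., 0] = output.left @ _LUMA
    out[..., 1] = output.right @ _LUMA
    return out
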