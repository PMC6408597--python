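"""Metric 3-D scene composition: leaf litter stacked on a ground plane.

The rigid-body drop of the original stimuli is replaced by a deterministic
sequential stacking model: each element rests flat at the running maximum
of a height field sampled under its footprint, capped at ``max_stack``
(default 1.5 cm).  Nominal drop heights are retained as metadata only.
World units are centimetres; X is right, Y is up on the screen, Z is
elevation above the ground plane.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from matplotlib.path import Path as MplPath

from . import geometry
from .palette import ColorPair, ColorSample, Palette
from .texture import SnakeTexture, TextureParams, compose_texture

__all__ = [
    "LeafParams",
    "SnakeParams",
    "LeafMesh",
    "SnakeMesh",
    "LeafPlacement",
    "SnakePlacement",
    "SceneLayout",
    "build_leaf_mesh",
    "build_snake_mesh",
    "drop_leaves",
    "place_snake",
]

DEFAULT_BOUNDS = (
    geometry.deg_to_cm(39.64),
    geometry.deg_to_cm(28.74),
)
DEFAULT_GROUND_COLOR = (0.32, 0.21, 0.11)  # unspecified in the source; a mid brown


@dataclass(frozen=True)
class LeafParams:
    """Leaf element geometry (cm).  Defaults subtend 1.10 x 0.50 x 0.02 deg."""

    major: float = geometry.deg_to_cm(1.10)
    minor: float = geometry.deg_to_cm(0.50)
    thickness: float = geometry.deg_to_cm(0.02)
    curl: float = 0.08  # out-of-plane rise at the leaf rim, cm
    n_profile: int = 13
    n_across: int = 5

    def __post_init__(self) -> None:
        if min(self.major, self.minor, self.thickness) <= 0:
            raise ValueError("leaf extents must be positive")


@dataclass(frozen=True)
class SnakeParams:
    """Snake target geometry (cm).  Defaults subtend 4.00 x 0.40 x 0.02 deg."""

    length: float = geometry.deg_to_cm(4.00)
    width: float = geometry.deg_to_cm(0.40)
    height: float = geometry.deg_to_cm(0.02)
    head_scale: float = 1.15
    head_frac: float = 0.10
    tail_frac: float = 0.25
    tail_min: float = 0.30
    n_seg: int = 80
    n_theta: int = 12

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("snake extents must be positive")


@dataclass
class LeafMesh:
    vertices: np.ndarray  # (N, 3)
    faces: np.ndarray  # (M, 3) int
    normals: np.ndarray  # (N, 3) unit
    outline: np.ndarray  # (K, 2) closed planar footprint polygon
    params: LeafParams
    color: ColorSample | None = None


@dataclass
class SnakeMesh:
    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    uv: np.ndarray  # (N, 2) texture coordinates: u along body, v around
    params: SnakeParams


@dataclass(frozen=True)
class LeafPlacement:
    x: float
    y: float
    angle: float  # Z rotation, radians
    z: float  # resting height of the leaf underside
    color: tuple[float, float, float]


@dataclass(frozen=True)
class SnakePlacement:
    x: float
    y: float
    angle: float
    z: float


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex normals, oriented towards +Z."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    fn = np.cross(v1 - v0, v2 - v0)
    # orient all face normals upward so shading is consistent for sheets
    flip = fn[:, 2] < 0
    fn[flip] *= -1.0
    acc = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(acc, faces[:, i], fn)
    norm = np.linalg.norm(acc, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    out = acc / norm
    out[(norm == 1.0).ravel() & (np.abs(acc).sum(axis=1) == 0)] = (0.0, 0.0, 1.0)
    return out


def _bezier_halfwidth(t: np.ndarray, major: float, minor: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic Bezier leaf profile: x position and half-width along the long axis."""
    a = major / 2.0
    c = minor * 2.0 / 3.0  # peak of 3*c*t*(1-t) at t=.5 equals minor/2
    x0, x1, x2, x3 = -a, -a / 2.0, a / 2.0, a
    x = (
        (1 - t) ** 3 * x0
        + 3 * t * (1 - t) ** 2 * x1
        + 3 * t**2 * (1 - t) * x2
        + t**3 * x3
    )
    w = 3 * c * t * (1 - t)  # quadratic in t; peak minor/2 at t = 0.5
    return x, w


def build_leaf_mesh(
    params: LeafParams | None = None, color: ColorSample | None = None
) -> LeafMesh:
    """Triangulated leaf sheet: Bezier half-outline mirrored about the long
    axis, then curled orthogonally to it (parabolic z displacement)."""
    p = params or LeafParams()
    t = np.linspace(0.0, 1.0, p.n_profile)
    x, w = _bezier_halfwidth(t, p.major, p.minor)
    if not np.all(np.diff(x) > 0):
        raise ValueError("degenerate leaf control points: profile not monotone")
    frac = np.linspace(-1.0, 1.0, p.n_across)
    X = np.repeat(x[:, None], p.n_across, axis=1)
    Y = w[:, None] * frac[None, :]
    Z = p.curl * (Y / (p.minor / 2.0)) ** 2
    vertices = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    faces = []
    na = p.n_across
    for i in range(p.n_profile - 1):
        for j in range(na - 1):
            k = i * na + j
            faces.append((k, k + na, k + 1))
            faces.append((k + 1, k + na, k + na + 1))
    faces = np.asarray(faces, dtype=int)
    outline = np.concatenate(
        [np.stack([x, w], axis=-1), np.stack([x, -w], axis=-1)[::-1]]
    )
    return LeafMesh(
        vertices=vertices,
        faces=faces,
        normals=_vertex_normals(vertices, faces),
        outline=outline,
        params=p,
        color=color,
    )


def _snake_width_factor(s: np.ndarray, p: SnakeParams) -> np.ndarray:
    """Cross-section scale along the body: wider head, tapering tail."""
    f = np.ones_like(s)
    head = s < p.head_frac
    f[head] = 1.0 + (p.head_scale - 1.0) * (1.0 - s[head] / p.head_frac)
    tail = s > 1.0 - p.tail_frac
    u = (s[tail] - (1.0 - p.tail_frac)) / p.tail_frac
    f[tail] = 1.0 - (1.0 - p.tail_min) * u
    return f


def build_snake_mesh(params: SnakeParams | None = None) -> SnakeMesh:
    """Elliptical-cross-section tube along the X axis, resting on z = 0."""
    p = params or SnakeParams()
    s = np.linspace(0.0, 1.0, p.n_seg)
    theta = np.linspace(0.0, 2 * np.pi, p.n_theta, endpoint=False)
    f = _snake_width_factor(s, p)
    X = np.repeat(((s - 0.5) * p.length)[:, None], p.n_theta, axis=1)
    Y = (f[:, None] * p.width / 2.0) * np.cos(theta)[None, :]
    # ring centre scales with the cross-section so the underside stays at z=0
    Z = (f[:, None] * p.height / 2.0) * (1.0 + np.sin(theta)[None, :])
    vertices = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    uv = np.stack(
        [
            np.repeat(s, p.n_theta),
            np.tile(theta / (2 * np.pi), p.n_seg),
        ],
        axis=-1,
    )
    faces = []
    nt = p.n_theta
    for i in range(p.n_seg - 1):
        for j in range(nt):
            j2 = (j + 1) % nt
            a, b = i * nt + j, i * nt + j2
            c, d = (i + 1) * nt + j, (i + 1) * nt + j2
            faces.append((a, c, b))
            faces.append((b, c, d))
    faces = np.asarray(faces, dtype=int)
    # tube normals: outward from the local ring centre (taper slope ignored)
    n = np.stack(
        [
            np.zeros_like(Y.ravel()),
            np.cos(np.tile(theta, p.n_seg)) / (p.width / 2.0),
            np.sin(np.tile(theta, p.n_seg)) / (p.height / 2.0),
        ],
        axis=-1,
    )
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return SnakeMesh(vertices=vertices, faces=faces, normals=n, uv=uv, params=p)


@dataclass
class SceneLayout:
    """Stacked leaf-litter arrangement plus an optional snake pose."""

    bounds: tuple[float, float] = DEFAULT_BOUNDS
    cell: float = 0.1  # height-field raster resolution, cm
    max_stack: float = 1.5
    ground_color: tuple[float, float, float] = DEFAULT_GROUND_COLOR
    leaf_params: LeafParams = field(default_factory=LeafParams)
    leaves: list[LeafPlacement] = field(default_factory=list)
    snake_params: SnakeParams | None = None
    snake: SnakePlacement | None = None
    snake_texture: SnakeTexture | None = None
    height_field: np.ndarray | None = None
    underside_field: np.ndarray | None = None
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.height_field is None:
            self.height_field = np.zeros(self.grid_shape, dtype=float)
        if self.underside_field is None:
            # underside elevation of the topmost element per cell; together
            # with height_field this forms the occluding slab for shadows
            self.underside_field = np.zeros(self.grid_shape, dtype=float)

    @property
    def grid_shape(self) -> tuple[int, int]:
        w, h = self.bounds
        return (max(1, int(round(h / self.cell))), max(1, int(round(w / self.cell))))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid_shape
        w, h = self.bounds
        xs = -w / 2.0 + (np.arange(nx) + 0.5) * self.cell
        ys = -h / 2.0 + (np.arange(ny) + 0.5) * self.cell
        return xs, ys

    def sample_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-cell height-field lookup; zero outside the bounds."""
        w, h = self.bounds
        ny, nx = self.grid_shape
        ix = np.floor((np.asarray(x) + w / 2.0) / self.cell).astype(int)
        iy = np.floor((np.asarray(y) + h / 2.0) / self.cell).astype(int)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(np.broadcast(x, y).shape, dtype=float)
        out[inside] = self.height_field[iy[inside], ix[inside]]
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "bounds": list(self.bounds),
            "cell": self.cell,
            "max_stack": self.max_stack,
            "ground_color": list(self.ground_color),
            "leaf_params": asdict(self.leaf_params),
            "leaves": [asdict(p) for p in self.leaves],
            "seed": self.seed,
            "metadata": self.metadata,
        }
        if self.snake_params is not None:
            d["snake_params"] = asdict(self.snake_params)
        if self.snake is not None:
            d["snake"] = asdict(self.snake)
        if self.snake_texture is not None:
            tx = self.snake_texture
            d["snake_texture"] = {
                "params": {
                    "width": tx.rgb.shape[1],
                    "height": tx.rgb.shape[0],
                    "seed": None,
                },
                "enhanced": tx.enhanced,
                "dark": [tx.colors.dark.r, tx.colors.dark.g, tx.colors.dark.b],
                "light": [tx.colors.light.r, tx.colors.light.g, tx.colors.light.b],
            }
            d["snake_texture"]["texture_params"] = self.metadata.get("texture_params")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneLayout":
        layout = cls(
            bounds=tuple(d["bounds"]),
            cell=d["cell"],
            max_stack=d["max_stack"],
            ground_color=tuple(d["ground_color"]),
            leaf_params=LeafParams(**d["leaf_params"]),
            seed=d.get("seed", 0),
            metadata=d.get("metadata", {}),
        )
        layout.leaves = [
            LeafPlacement(
                x=p["x"], y=p["y"], angle=p["angle"], z=p["z"], color=tuple(p["color"])
            )
            for p in d.get("leaves", [])
        ]
        if "snake_params" in d:
            layout.snake_params = SnakeParams(**d["snake_params"])
        if "snake" in d:
            layout.snake = SnakePlacement(**{k: d["snake"][k] for k in ("x", "y", "angle", "z")})
        tp = d.get("snake_texture")
        if tp is not None and tp.get("texture_params"):
            params = TextureParams(**tp["texture_params"])
            pair = ColorPair(
                dark=ColorSample.from_rgb(*tp["dark"]),
                light=ColorSample.from_rgb(*tp["light"]),
            )
            layout.snake_texture = compose_texture(params, pair, tp["enhanced"])
        _replay_height_field(layout)
        return layout

    @classmethod
    def from_json(cls, path) -> "SceneLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _footprint_cells(
    layout: SceneLayout, outline: np.ndarray, x: float, y: float, angle: float
) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices (iy, ix) of cell centres inside a placed footprint."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    poly = outline @ rot.T + np.array([x, y])
    xs, ys = layout.cell_centers()
    ny, nx = layout.grid_shape
    x0 = np.searchsorted(xs, poly[:, 0].min() - layout.cell)
    x1 = np.searchsorted(xs, poly[:, 0].max() + layout.cell)
    y0 = np.searchsorted(ys, poly[:, 1].min() - layout.cell)
    y1 = np.searchsorted(ys, poly[:, 1].max() + layout.cell)
    x1, y1 = min(x1, nx), min(y1, ny)
    if x0 >= x1 or y0 >= y1:
        return np.array([], dtype=int), np.array([], dtype=int)
    gx, gy = np.meshgrid(xs[x0:x1], ys[y0:y1])
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    inside = MplPath(poly).contains_points(pts)
    iy, ix = np.divmod(np.flatnonzero(inside), x1 - x0)
    iy, ix = iy + y0, ix + x0
    if iy.size == 0:
        # footprint smaller than a cell: fall back to the nearest cell
        ix = np.array([int(np.clip((x + layout.bounds[0] / 2) / layout.cell, 0, nx - 1))])
        iy = np.array([int(np.clip((y + layout.bounds[1] / 2) / layout.cell, 0, ny - 1))])
    return iy, ix


def _settle(
    layout: SceneLayout, outline: np.ndarray, x: float, y: float, angle: float,
    element_height: float,
) -> float:
    """Resting height of an element footprint; updates the height field."""
    iy, ix = _footprint_cells(layout, outline, x, y, angle)
    if iy.size == 0:
        return 0.0
    rest = float(layout.height_field[iy, ix].max())
    rest = min(rest, layout.max_stack - element_height)
    rest = max(rest, 0.0)
    top = rest + element_height
    raised = layout.height_field[iy, ix] < top
    layout.underside_field[iy[raised], ix[raised]] = rest
    layout.height_field[iy, ix] = np.maximum(layout.height_field[iy, ix], top)
    return rest


def _leaf_element_height(p: LeafParams) -> float:
    return p.thickness + p.curl


def drop_leaves(
    n: int,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    leaf_params: LeafParams | None = None,
    palette: Palette | None = None,
    seed: int = 0,
    cell: float = 0.1,
    max_stack: float = 1.5,
) -> SceneLayout:
    """Sequentially stack ``n`` leaves inside ``bounds`` (cm, centred).

    Each leaf samples a uniform XY position, a uniform Z rotation and a
    palette colour, then rests flat at the running height-field maximum
    under its footprint (capped at ``max_stack``).  Deterministic per seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if bounds[0] <= 0 or bounds[1] <= 0:
        raise ValueError("bounds must have positive area")
    lp = leaf_params or LeafParams()
    layout = SceneLayout(
        bounds=bounds, cell=cell, max_stack=max_stack, leaf_params=lp, seed=seed,
        metadata={"nominal_drop_z_cm": [5.0, 7.0], "n_leaves": n},
    )
    proto = build_leaf_mesh(lp)
    rng = np.random.default_rng(seed)
    if palette is None and n > 0:
        palette = generate_default_palette(seed)
    rgbs = palette.rgb_array() if n > 0 else None
    w, h = bounds
    for _ in range(n):
        x = rng.uniform(-w / 2.0, w / 2.0)
        y = rng.uniform(-h / 2.0, h / 2.0)
        ang = rng.uniform(0.0, 2 * np.pi)
        color = tuple(rgbs[rng.integers(len(rgbs))])
        z = _settle(layout, proto.outline, x, y, ang, _leaf_element_height(lp))
        layout.leaves.append(LeafPlacement(x=x, y=y, angle=ang, z=z, color=color))
    return layout


def generate_default_palette(seed: int) -> Palette:
    from .palette import generate_synthetic_palette

    return generate_synthetic_palette(8, 100, seed=seed)


def _snake_outline(p: SnakeParams) -> np.ndarray:
    """Rectangular footprint polygon of the snake (length x max width)."""
    hw = p.width / 2.0 * max(1.0, p.head_scale)
    hl = p.length / 2.0
    return np.array([[-hl, -hw], [hl, -hw], [hl, hw], [-hl, hw]])


QUADRANTS = ("TL", "TR", "BL", "BR")


def place_snake(
    layout: SceneLayout,
    snake_params: SnakeParams | None = None,
    texture: SnakeTexture | None = None,
    seed: int = 0,
    quadrant: str | None = None,
    add_to_height_field: bool = True,
) -> SceneLayout:
    """Rest a snake on the stacked litter at a random XY pose.

    The nominal 12 cm drop is metadata; the rest state is the height-field
    maximum under the body footprint.  When ``quadrant`` is given the snake
    *centroid* is constrained to that quadrant (body parts may cross the
    midlines).
    """
    p = snake_params or SnakeParams()
    w, h = layout.bounds
    if p.length > min(w, h):
        raise ValueError("snake longer than the scene bounds")
    rng = np.random.default_rng(seed)
    if quadrant is None:
        xlo, xhi, ylo, yhi = -w / 2, w / 2, -h / 2, h / 2
    else:
        if quadrant not in QUADRANTS:
            raise ValueError(f"unknown quadrant {quadrant!r}")
        xlo, xhi = (-w / 2, 0.0) if quadrant in ("TL", "BL") else (0.0, w / 2)
        ylo, yhi = (0.0, h / 2) if quadrant in ("TL", "TR") else (-h / 2, 0.0)
    x = rng.uniform(xlo, xhi)
    y = rng.uniform(ylo, yhi)
    ang = rng.uniform(0.0, 2 * np.pi)
    outline = _snake_outline(p)
    iy, ix = _footprint_cells(layout, outline, x, y, ang)
    rest = float(layout.height_field[iy, ix].max()) if iy.size else 0.0
    if add_to_height_field and iy.size:
        raised = layout.height_field[iy, ix] < rest + p.height
        layout.underside_field[iy[raised], ix[raised]] = rest
        layout.height_field[iy, ix] = np.maximum(
            layout.height_field[iy, ix], rest + p.height
        )
    layout.snake_params = p
    layout.snake = SnakePlacement(x=x, y=y, angle=ang, z=rest)
    layout.snake_texture = texture
    layout.metadata["nominal_snake_drop_z_cm"] = 12.0
    return layout


def _replay_height_field(layout: SceneLayout) -> None:
    """Rebuild the height field from recorded placements (for JSON loads)."""
    layout.height_field = np.zeros(layout.grid_shape, dtype=float)
    layout.underside_field = np.zeros(layout.grid_shape, dtype=float)

    def _apply(iy, ix, bottom, top):
        if iy.size:
            raised = layout.height_field[iy, ix] < top
            layout.underside_field[iy[raised], ix[raised]] = bottom
            layout.height_field[iy, ix] = np.maximum(layout.height_field[iy, ix], top)

    proto = build_leaf_mesh(layout.leaf_params)
    eh = _leaf_element_height(layout.leaf_params)
    for leaf in layout.leaves:
        iy, ix = _footprint_cells(layout, proto.outline, leaf.x, leaf.y, leaf.angle)
        _apply(iy, ix, leaf.z, leaf.z + eh)
    if layout.snake is not None and layout.snake_params is not None:
        iy, ix = _footprint_cells(
            layout, _snake_outline(layout.snake_params),
            layout.snake.x, layout.snake.y, layout.snake.angle,
        )
        _apply(iy, ix, layout.snake.z, layout.snake.z + layout.snake_params.height)
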