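"""Procedural snake-texture synthesis, with and without edge enhancement.

Pipeline: i.i.d. uniform noise -> Gaussian smoothing (sigma = 33 px) ->
binarisation at 0.5 -> two-colour composition.  The edge-enhanced variant
adds a signed luminance ramp to the HSV value channel: at each pixel within
``enh_width`` (default 10 px, Euclidean distance) of a region boundary the
value channel is shifted by ``amplitude * (1 - d / width)``, positive on
the lighter-colour side and negative on the darker side, so the light
region gets lighter and the dark region darker towards the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .palette import ColorPair

__all__ = [
    "TextureParams",
    "SnakeTexture",
    "make_binary_pattern",
    "binarize",
    "locate_edges",
    "enhancement_field",
    "compose_texture",
]


@dataclass(frozen=True)
class TextureParams:
    """Parameters of the noise/smoothing/threshold/enhancement pipeline."""

    width: int = 1024
    height: int = 128
    sigma: float = 33.0
    threshold: float = 0.5
    enh_amplitude: float = 0.25
    enh_width: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        if not 0.0 <= self.enh_amplitude <= 0.25:
            raise ValueError("enh_amplitude must lie in [0, 0.25]")
        if self.enh_width < 1:
            raise ValueError("enh_width must be >= 1")
        if self.width < 1 or self.height < 1:
            raise ValueError("texture dimensions must be positive")


@dataclass
class SnakeTexture:
    """A composed snake texture and its constituents."""

    binary_map: np.ndarray  # (H, W) uint8 in {0, 1}
    colors: ColorPair
    enhancement: np.ndarray  # (H, W) signed field, 0 when not enhanced
    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    enhanced: bool

    def value_channel(self) -> np.ndarray:
        """HSV value channel (max RGB channel) of the composed texture."""
        return self.rgb.max(axis=-1)


def binarize(values: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold to {0, 1}; values exactly at the threshold map to 1."""
    return (np.asarray(values, dtype=float) >= threshold).astype(np.uint8)


def make_binary_pattern(params: TextureParams) -> np.ndarray:
    """Uniform noise, Gaussian-smoothed (reflect boundaries), binarised.

    Deterministic for a fixed ``params.seed``.  Emits a warning when the
    raster is smaller than one smoothing scale (pattern degenerates towards
    a constant map).
    """
    if min(params.width, params.height) < params.sigma:
        warnings.warn(
            "texture raster smaller than the smoothing scale; "
            "the binary pattern may be degenerate",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    noise = rng.uniform(0.0, 1.0, size=(params.height, params.width))
    smooth = ndimage.gaussian_filter(noise, sigma=params.sigma, mode="reflect")
    return binarize(smooth, params.threshold)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def locate_edges(binary_map: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels with a 4-neighbour of the opposite label.

    Both sides of every label change are marked, so each region owns its
    own boundary ring.  An all-0 or all-1 map yields an empty set.
    """
    b = np.asarray(binary_map).astype(bool)
    # border values chosen so the image frame itself never counts as an edge
    dil = ndimage.binary_dilation(b, structure=_CROSS, border_value=0)
    ero = ndimage.binary_erosion(b, structure=_CROSS, border_value=1)
    # dilation grows the 1-region into 0-pixels adjacent to it; erosion
    # shrinks it away from 1-pixels adjacent to a 0.  XOR-style union marks
    # both boundary rings.
    return (dil & ~b) | (b & ~ero)


def enhancement_field(
    binary_map: np.ndarray,
    edges: np.ndarray,
    amplitude: float = 0.25,
    width: float = 10.0,
) -> np.ndarray:
    """Signed linear luminance ramp around region boundaries.

    Magnitude ``amplitude * (1 - d / width)`` for Euclidean distance
    ``d <= width`` to the nearest edge pixel (edge pixels attain the full
    amplitude), exactly zero beyond.  Positive on the 1 (light) side of the
    map, negative on the 0 (dark) side.
    """
    b = np.asarray(binary_map).astype(bool)
    edges = np.asarray(edges).astype(bool)
    field = np.zeros(b.shape, dtype=float)
    if not edges.any():
        return field
    d = ndimage.distance_transform_edt(~edges)
    ramp = np.where(d <= width, amplitude * (1.0 - d / width), 0.0)
    sign = np.where(b, 1.0, -1.0)
    return sign * ramp


def compose_texture(
    params: TextureParams, colors: ColorPair, enhanced: bool
) -> SnakeTexture:
    """Colour the binary pattern, optionally adding the enhancement field.

    The (dark, light) pair colours the (0, 1) regions.  When ``enhanced``,
    the signed field is added to the HSV value channel (hue and saturation
    untouched) before conversion back to RGB; the mid-luminance palette
    invariant keeps the result inside [0, 1].
    """
    binary = make_binary_pattern(params)
    b = binary.astype(bool)
    h = np.where(b, colors.light.h, colors.dark.h)
    s = np.where(b, colors.light.s, colors.dark.s)
    v = np.where(b, colors.light.v, colors.dark.v)
    if enhanced:
        edges = locate_edges(binary)
        field = enhancement_field(binary, edges, params.enh_amplitude, params.enh_width)
        v = v + field
    else:
        field = np.zeros(binary.shape, dtype=float)
    if v.min() < 0.0 or v.max() > 1.0:
        raise ValueError("value channel left [0, 1]; base colours violate invariants")
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    return SnakeTexture(
        binary_map=binary, colors=colors, enhancement=field, rgb=rgb, enhanced=enhanced
    )
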