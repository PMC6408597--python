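"""Natural-colour palettes and base-colour selection for snake textures.

A palette is an ordered set of RGB reflectance triplets with their HSV
representation.  The default generator draws from a parametric forest-like
distribution (hue mass in the green/yellow/brown bands, broad value and
saturation spread); real samples can be substituted through a CSV loader.

Base colours for a snake texture are chosen from the palette after a
luminance filter (0.25 < v < 0.75, which guarantees a later +/-0.25 value
enhancement can never clip) and a saturation filter (s > 0.3):  one colour
is drawn from the 10th-45th value-centile band of the filtered set and one
from the 55th-90th band.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

__all__ = [
    "ColorSample",
    "Palette",
    "ColorPair",
    "PaletteError",
    "generate_synthetic_palette",
    "load_palette_csv",
    "select_base_colors",
]

# Luminance (value) exclusion bounds and saturation floor for base colours.
V_LOW = 0.25
V_HIGH = 0.75
S_MIN = 0.3

# Centile bands (inclusive at both ends) from which the two base colours
# are drawn, on the value dimension of the filtered sample set.
DARK_BAND = (10.0, 45.0)
LIGHT_BAND = (55.0, 90.0)


class PaletteError(ValueError):
    """Raised for malformed palette files or over-restrictive palettes."""


@dataclass(frozen=True)
class ColorSample:
    """An RGB reflectance triplet in [0, 1] with its exact HSV conversion."""

    r: float
    g: float
    b: float
    h: float
    s: float
    v: float

    @classmethod
    def from_rgb(cls, r: float, g: float, b: float) -> "ColorSample":
        if not all(0.0 <= c <= 1.0 for c in (r, g, b)):
            raise PaletteError(f"RGB out of range [0, 1]: {(r, g, b)}")
        h, s, v = rgb_to_hsv(np.array([r, g, b], dtype=float))
        return cls(r=float(r), g=float(g), b=float(b), h=float(h), s=float(s), v=float(v))

    @property
    def rgb(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)


@dataclass
class Palette:
    """Ordered collection of colour samples with a provenance tag."""

    samples: list[ColorSample]
    provenance: str = "synthetic"

    def __len__(self) -> int:
        return len(self.samples)

    def rgb_array(self) -> np.ndarray:
        return np.array([[c.r, c.g, c.b] for c in self.samples], dtype=float)

    def hsv_array(self) -> np.ndarray:
        return np.array([[c.h, c.s, c.v] for c in self.samples], dtype=float)


@dataclass(frozen=True)
class ColorPair:
    """A (dark, light) base-colour pair; dark.v < light.v, both mid-luminance."""

    dark: ColorSample
    light: ColorSample

    def __post_init__(self) -> None:
        if not self.dark.v < self.light.v:
            raise PaletteError("ColorPair requires dark.v < light.v")
        for c in (self.dark, self.light):
            if not (V_LOW < c.v < V_HIGH):
                raise PaletteError(f"base colour value {c.v} outside ({V_LOW}, {V_HIGH})")
            if not c.s > S_MIN:
                raise PaletteError(f"base colour saturation {c.s} <= {S_MIN}")


# Hue bands (fraction of the hue circle) roughly covering browns, yellows
# and greens, with mixture weights; chosen so the filtered set downstream
# is never empty for reasonable sample counts.
_HUE_BANDS = np.array([[0.02, 0.10], [0.10, 0.20], [0.20, 0.42]])
_HUE_WEIGHTS = np.array([0.35, 0.25, 0.40])


def generate_synthetic_palette(
    n_groups: int = 8, n_per_group: int = 100, seed: int = 0
) -> Palette:
    """Draw a forest-like colour palette of ``n_groups * n_per_group`` samples.

    Hues concentrate in green/yellow/brown bands; saturation and value are
    Beta(2, 2) distributed so both sides of the s > 0.3 cut and a broad
    value range are populated.  Deterministic for a fixed seed.
    """
    if n_groups < 1 or n_per_group < 1:
        raise ValueError("n_groups and n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    n = n_groups * n_per_group
    band = rng.choice(len(_HUE_BANDS), size=n, p=_HUE_WEIGHTS / _HUE_WEIGHTS.sum())
    lo, hi = _HUE_BANDS[band, 0], _HUE_BANDS[band, 1]
    h = rng.uniform(lo, hi)
    s = rng.beta(2.0, 2.0, size=n)
    v = rng.beta(2.0, 2.0, size=n)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    samples = [ColorSample.from_rgb(*row) for row in rgb]
    return Palette(samples=samples, provenance="synthetic")


def load_palette_csv(path) -> Palette:
    """Load a palette from a CSV of r,g,b rows (header optional).

    Values may be on a [0, 1] or larger (e.g. [0, 255]) scale; if any value
    exceeds 1 the whole table is rescaled by its maximum channel value.
    """
    rows: list[tuple[float, float, float]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                vals = tuple(float(c) for c in row[:3])
            except ValueError:
                if i == 0 and not rows:
                    continue  # header line
                raise PaletteError(f"malformed palette row {i + 1}: {row!r}") from None
            if len(row) < 3:
                raise PaletteError(f"malformed palette row {i + 1}: {row!r}")
            rows.append(vals)
    if not rows:
        raise PaletteError(f"no colour rows found in {path}")
    arr = np.asarray(rows, dtype=float)
    if arr.min() < 0.0:
        raise PaletteError("negative channel values in palette file")
    peak = arr.max()
    if peak > 1.0:
        arr = arr / peak
    samples = [ColorSample.from_rgb(*row) for row in arr]
    return Palette(samples=samples, provenance="file")


def _filtered_indices(palette: Palette) -> np.ndarray:
    hsv = palette.hsv_array()
    keep = (hsv[:, 2] > V_LOW) & (hsv[:, 2] < V_HIGH) & (hsv[:, 1] > S_MIN)
    return np.flatnonzero(keep)


def value_centiles(values: np.ndarray) -> np.ndarray:
    """Mean-rank percentile of each value within its own set (ties averaged)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    less = (values[:, None] > values[None, :]).sum(axis=1)
    equal = (values[:, None] == values[None, :]).sum(axis=1)
    return 100.0 * (less + 0.5 * equal) / n


def select_base_colors(palette: Palette, seed: int = 0) -> ColorPair:
    """Pick the (dark, light) base-colour pair from a palette.

    Filters to 0.25 < v < 0.75 and s > 0.3, computes value centiles over
    the filtered set, then draws one sample uniformly from each centile
    band (10-45 and 55-90, inclusive bounds).  Returns the pair ordered by
    value.  Raises :class:`PaletteError` if either band is empty.
    """
    idx = _filtered_indices(palette)
    if idx.size == 0:
        raise PaletteError(
            "palette too restrictive: no samples with "
            f"{V_LOW} < v < {V_HIGH} and s > {S_MIN}"
        )
    vals = np.array([palette.samples[i].v for i in idx])
    cent = value_centiles(vals)
    dark_pool = idx[(cent >= DARK_BAND[0]) & (cent <= DARK_BAND[1])]
    light_pool = idx[(cent >= LIGHT_BAND[0]) & (cent <= LIGHT_BAND[1])]
    if dark_pool.size == 0 or light_pool.size == 0:
        raise PaletteError("palette too restrictive: empty centile band")
    rng = np.random.default_rng(seed)
    a = palette.samples[int(rng.choice(dark_pool))]
    b = palette.samples[int(rng.choice(light_pool))]
    dark, light = (a, b) if a.v < b.v else (b, a)
    return ColorPair(dark=dark, light=light)
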