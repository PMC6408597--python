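"""Angular/metric conversions for the desk-scale viewing geometry.

All world coordinates are in centimetres.  The observer (cyclopean point)
sits ``VIEW_DISTANCE_CM`` in front of the ground plane, so an object of
physical size ``s`` centred on the line of sight subtends
``2 * atan(s / 2 / D)`` degrees.
"""

from __future__ import annotations

import numpy as np

#: Default viewing distance from the eyes to the image (ground) plane, cm.
VIEW_DISTANCE_CM: float = 57.0

#: Default inter-ocular (camera) separation, cm.
IPD_CM: float = 6.5


def deg_to_cm(theta_deg: float, distance_cm: float = VIEW_DISTANCE_CM) -> float:
    """Physical extent (cm) of a centred object subtending ``theta_deg``."""
    return 2.0 * distance_cm * np.tan(np.deg2rad(theta_deg) / 2.0)


def cm_to_deg(size_cm: float, distance_cm: float = VIEW_DISTANCE_CM) -> float:
    """Angular subtense (deg) of a centred object of extent ``size_cm``."""
    return np.rad2deg(2.0 * np.arctan(size_cm / (2.0 * distance_cm)))
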