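"""Circular (hue-angle) arithmetic helpers.

All angles are in degrees. Absolute angles live in [0, 360); signed
differences are wrapped to (-180, 180].
"""

from __future__ import annotations

import numpy as np


def wrap360(angle):
    """Map an angle (scalar or array) into [0, 360)."""
    return np.mod(angle, 360.0)


def circ_diff(a, b):
    """Signed circular difference a - b wrapped to (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    # mod gives [0, 360); fold the upper half down to (-180, 180]
    return np.where(d > 180.0, d - 360.0, d)


def circ_dist(a, b):
    """Unsigned circular distance in [0, 180]."""
    return np.abs(circ_diff(a, b))


def unwrap_near(reference, other):
    """Shift ``other`` by a multiple of 360 so it lies closest to ``reference``.

    The result may fall outside [0, 360); it is always within 180 of the
    reference. Used to plot/compare peak angles across conditions without
    artificial 360-degree jumps.
    """
    return np.asarray(reference, dtype=float) + circ_diff(other, reference)
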