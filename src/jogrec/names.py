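"""Canonical series and feature naming.

Every feature name starts with its parent series token, e.g.
``AnkleSteps auto-corr t = 1`` or ``delta(HipAxis3) hist [-70, 89)``, so the
parent series and sensor location of any feature can be recovered from its
name alone.  This is what location-restricted feature selection relies on.
"""

from __future__ import annotations

import re
from typing import List

from .io import CHANNELS, LOCATIONS

__all__ = [
    "series_name",
    "all_series",
    "location_of_series",
    "parent_series",
    "location_of_feature",
]

_CHANNEL_TOKEN = {
    "axis1": "Axis1",
    "axis2": "Axis2",
    "axis3": "Axis3",
    "steps": "Steps",
    "inclinometer": "Incl",
    "vector_magnitude": "Mag",
}
_LOCATION_TOKEN = {"hip": "Hip", "ankle": "Ankle"}


def series_name(location: str, channel: str) -> str:
    """E.g. ``series_name('ankle', 'vector_magnitude') == 'AnkleMag'``."""
    return _LOCATION_TOKEN[location] + _CHANNEL_TOKEN[channel]


def all_series() -> List[str]:
    """The 12 original series names, hip channels first."""
    return [series_name(loc, ch) for loc in LOCATIONS for ch in CHANNELS]


def location_of_series(series: str) -> str:
    for loc, token in _LOCATION_TOKEN.items():
        if series.startswith(token):
            return loc
    raise ValueError(f"series {series!r} has no location prefix")


_DERIVED_RE = re.compile(r"^(?:delta|1st_deriv|FFT_amp|FFT_mag|FFT_freq)\(([A-Za-z0-9]+)\)")
_ORIGINAL_RE = re.compile(r"^((?:Hip|Ankle)[A-Za-z0-9]+)")


def parent_series(feature: str) -> str | None:
    """Parent original series of a feature, or None for gender / cross-sensor."""
    m = _DERIVED_RE.match(feature)
    if m:
        return m.group(1)
    m = _ORIGINAL_RE.match(feature)
    if m:
        return m.group(1)
    return None


def location_of_feature(feature: str) -> str | None:
    """Sensor location of a feature, or None for gender / cross-sensor features."""
    series = parent_series(feature)
    if series is None:
        return None
    return location_of_series(series)
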