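"""Shared clock-time conventions.

All sleep metrics attribute a night to a "metric day" running from 15:00
local time the previous calendar day to 15:00 on the metric day itself.
Clock-time statistics (bedtime/waketime medians etc.) are computed on an
*anchored* linear scale — hours elapsed since the most recent 15:00 — so
that times spanning midnight remain contiguous.
"""

from __future__ import annotations

from datetime import timedelta, timezone

import numpy as np

#: Fixed-offset local timezone used by the synthetic study (no DST, so the
#: 1-minute generation grid maps 1:1 onto wall-clock minutes).
STUDY_TZ = timezone(timedelta(hours=-8), name="UTC-08:00")

#: Metric days run 15:00 -> 15:00 local.
DAY_ANCHOR_HOUR = 15


def clock_to_anchor(hours_clock):
    """Map clock time (h, [0, 24)) to hours since the 15:00 anchor."""
    return (np.asarray(hours_clock, dtype=float) - DAY_ANCHOR_HOUR) % 24.0


def anchor_to_clock(hours_anchor):
    """Inverse of :func:`clock_to_anchor` (result in [0, 24))."""
    return (np.asarray(hours_anchor, dtype=float) + DAY_ANCHOR_HOUR) % 24.0
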