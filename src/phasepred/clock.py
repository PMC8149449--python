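"""Linearized clock-time arithmetic.

Evening circadian phase markers (DLMO, bedtime, CBTmin) straddle midnight,
so naive arithmetic on hour-of-day values wraps discontinuously: the mean of
23:00 and 01:00 is 12:00 on a 0-24 axis. All clock quantities in this
package therefore live on a *linearized* axis running from 12.0 (noon) to
36.0 (the following noon). Times between 12:00 and 23:59 map to 12.0-23.98
and times between 0:00 and 11:59 map to 24.0-35.98. Means, regressions and
prediction errors are all computed on this axis.
"""

from __future__ import annotations

import numpy as np

LINEAR_MIN = 12.0
LINEAR_MAX = 36.0


def linearize(hour_of_day: float | np.ndarray) -> float | np.ndarray:
    """Map an hour-of-day in [0, 24) onto the noon-anchored [12, 36) axis."""
    h = np.asarray(hour_of_day, dtype=float) % 24.0
    out = np.where(h < LINEAR_MIN, h + 24.0, h)
    return float(out) if out.ndim == 0 else out


def to_hour_of_day(linearized: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`linearize`: back to an hour-of-day in [0, 24)."""
    out = np.asarray(linearized, dtype=float) % 24.0
    return float(out) if out.ndim == 0 else out


def parse_clock(text: str) -> float:
    """Parse ``"hh:mm"`` into linearized hours.

    >>> parse_clock("22:07")
    22.116666666666667
    >>> parse_clock("0:41")
    24.683333333333334
    """
    parts = text.strip().split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"expected hh:mm clock time, got {text!r}")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"clock time out of range: {text!r}")
    return linearize(h + m / 60.0)


def format_clock(linearized: float) -> str:
    """Render linearized hours as ``"hh:mm"`` (rounded to the minute)."""
    h = to_hour_of_day(linearized)
    total_min = int(round(h * 60.0)) % (24 * 60)
    return f"{total_min // 60}:{total_min % 60:02d}"


def wrap_diff_hours(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Signed difference a - b in hours, wrapped to (-12, 12].

    Both arguments may be on either the 0-24 or the linearized axis; only
    the clock-of-day difference matters.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 24.0
    out = np.where(d > 12.0, d - 24.0, d)
    return float(out) if out.ndim == 0 else out


def circular_mean_clock(linearized: np.ndarray) -> float:
    """Mean of clock times, robust to the 12:00 seam of the linear axis.

    Values already on the linearized axis are averaged directly when their
    spread is well away from the noon seam (the common case for evening
    markers); otherwise a circular mean is used.
    """
    v = np.asarray(linearized, dtype=float)
    if v.size == 0:
        raise ValueError("empty clock-time array")
    if v.max() - v.min() < 12.0:
        return float(v.mean())
    ang = v / 24.0 * 2.0 * np.pi
    mean_ang = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())
    return linearize(mean_ang / (2.0 * np.pi) * 24.0)
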