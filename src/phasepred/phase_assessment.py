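"""Gold-standard circadian phase: DLMO from salivary melatonin profiles,
and the circadian vs. non-circadian classification of delayed sleep-wake
phase disorder.

DLMO is the clock time at which evening salivary melatonin crosses — and
remains above — 2.3 pg/mL, with the crossing located by linear
interpolation between the bracketing hourly samples. A patient is
classified *circadian* when their DLMO falls no more than 30 min before
(or any time after) the desired bedtime, and *non-circadian* otherwise:
in the latter case the sleep complaint cannot be explained by a delayed
clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndeterminedDLMO

DLMO_THRESHOLD = 2.3  # pg/mL

CIRCADIAN = "circadian"
NON_CIRCADIAN = "non_circadian"


@dataclass
class MelatoninProfile:
    """Hourly salivary melatonin samples around habitual bedtime.

    sample_times are linearized clock hours (strictly increasing);
    concentrations are pg/mL (non-negative).
    """

    sample_times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.sample_times.size != self.concentrations.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


def dlmo_from_melatonin(profile: MelatoninProfile,
                        threshold: float = DLMO_THRESHOLD) -> float:
    """DLMO: earliest upward threshold crossing after which melatonin stays
    above threshold, linearly interpolated between the bracketing samples.

    A transient crossing followed by a dip back below the threshold does not
    qualify. Raises :class:`UndeterminedDLMO` when no sample pair brackets a
    qualifying crossing, or when the profile starts already above threshold
    (no onset can be interpolated). A sample exactly at the threshold counts
    as above it, and the crossing time is that sample's time.
    """
    c = profile.concentrations
    t = profile.sample_times
    if c.size < 2:
        raise UndeterminedDLMO("need at least two samples")
    if c[0] >= threshold:
        raise UndeterminedDLMO("first sample already at/above threshold")
    above = c >= threshold
    for i in range(c.size - 1):
        if not above[i] and above[i + 1] and above[i + 1:].all():
            if c[i + 1] == threshold:
                return float(t[i + 1])
            frac = (threshold - c[i]) / (c[i + 1] - c[i])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    raise UndeterminedDLMO("melatonin never crossed and remained above threshold")


def classify_circadian(dlmo: float, desired_bedtime: float,
                       margin_h: float = 0.5) -> str:
    """Circadian iff DLMO >= desired bedtime - 30 min (boundary inclusive).

    Both times are linearized clock hours. Delaying DLMO can never flip a
    circadian classification to non-circadian.
    """
    return CIRCADIAN if dlmo >= desired_bedtime - margin_h else NON_CIRCADIAN
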