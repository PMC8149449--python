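"""Participant recordings: epoch series containers, CSV I/O, and the
diary-vs-actigraphy bed/wake reconciliation rule.

A recording is ~7 days of 1-min wrist actigraphy: white-light illuminance
(lux) and a scored sleep/wake state per epoch, plus diary bed/wake times for
each night and the participant's desired bedtime. Diary times are taken as
the primary sleep timing, but when the diary disagrees with the objective
record by an hour or more the objective transition wins (see
:func:`adjust_bed_wake`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clock import circular_mean_clock, format_clock, linearize, parse_clock
from .errors import FormatError, InsufficientDataError


@dataclass
class EpochSeries:
    """Uniformly spaced samples (lux or binary state) with a missing mask.

    Epochs are half-open intervals ``[t, t + width)``; the timestamp of
    epoch *i* is ``start_time + i * epoch_width`` minutes.
    """

    start_time: pd.Timestamp
    epoch_width: float  # minutes
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != self.missing.shape:
            raise ValueError("values and missing mask must have equal length")
        if self.epoch_width <= 0:
            raise ValueError("epoch_width must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_hours(self) -> float:
        return self.n * self.epoch_width / 60.0

    def hours_from_start(self) -> np.ndarray:
        """Offset of each epoch start from series start, in hours."""
        return np.arange(self.n) * (self.epoch_width / 60.0)

    def clock_hours(self) -> np.ndarray:
        """Hour-of-day in [0, 24) of each epoch start."""
        h0 = self.start_time.hour + self.start_time.minute / 60.0 + self.start_time.second / 3600.0
        return (h0 + self.hours_from_start()) % 24.0

    def copy(self) -> "EpochSeries":
        return EpochSeries(self.start_time, self.epoch_width,
                           self.values.copy(), self.missing.copy())


@dataclass
class Recording:
    """One participant's week of light and sleep/wake data plus diary times.

    Nightly bed/wake times are linearized clock hours (noon-anchored axis);
    night *j* belongs to the j-th noon-to-noon window of the recording.
    ``bedtimes``/``waketimes`` start as copies of the diary values and are
    replaced by objective times by :func:`adjust_bed_wake`.
    """

    participant_id: str
    site: str
    light: EpochSeries
    sleepwake: EpochSeries
    diary_bedtimes: np.ndarray
    diary_waketimes: np.ndarray
    desired_bedtime: float
    bedtimes: np.ndarray = field(default=None)  # type: ignore[assignment]
    waketimes: np.ndarray = field(default=None)  # type: ignore[assignment]
    night_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.diary_bedtimes = np.asarray(self.diary_bedtimes, dtype=float)
        self.diary_waketimes = np.asarray(self.diary_waketimes, dtype=float)
        if self.bedtimes is None:
            self.bedtimes = self.diary_bedtimes.copy()
        if self.waketimes is None:
            self.waketimes = self.diary_waketimes.copy()
        if self.night_valid is None:
            self.night_valid = np.ones(self.n_nights, dtype=bool)
        self.night_valid = np.asarray(self.night_valid, dtype=bool)
        if self.light.n * self.light.epoch_width != self.sleepwake.n * self.sleepwake.epoch_width:
            raise ValueError("light and sleepwake must cover identical spans")

    @property
    def n_nights(self) -> int:
        return self.diary_bedtimes.size

    def anchor_noon(self) -> pd.Timestamp:
        """The noon at or immediately before the recording start."""
        t = self.light.start_time
        noon = t.normalize() + pd.Timedelta(hours=12)
        if t < noon:
            noon -= pd.Timedelta(days=1)
        return noon

    def night_interval_hours(self, j: int) -> tuple[float, float]:
        """Sleep interval of night j as (start, end) hours from series start."""
        off = (self.anchor_noon() - self.light.start_time).total_seconds() / 3600.0
        start = off + 24.0 * j + (self.bedtimes[j] - 12.0)
        end = off + 24.0 * j + (self.waketimes[j] - 12.0)
        return start, end

    def copy(self) -> "Recording":
        return replace(
            self,
            light=self.light.copy(), sleepwake=self.sleepwake.copy(),
            diary_bedtimes=self.diary_bedtimes.copy(),
            diary_waketimes=self.diary_waketimes.copy(),
            bedtimes=self.bedtimes.copy(), waketimes=self.waketimes.copy(),
            night_valid=self.night_valid.copy(),
        )


@dataclass(frozen=True)
class DetectConfig:
    """Thresholds operationalising the "substantial reduction/increase" in
    light and activity used for diary reconciliation: a sustained run of at
    least ``run_min`` minutes of sleep-scored epochs with light below
    ``lux_threshold`` (and the mirror-image condition for wake)."""

    run_min: int = 30
    lux_threshold: float = 10.0
    adjust_threshold_min: int = 60


def parse_recording(epoch_path, diary_path=None, participant_id: str | None = None,
                    site: str = "A") -> Recording:
    """Read an epoch CSV (columns ``timestamp, lux, sleep_state``) and an
    optional diary CSV (columns ``bedtime, waketime, desired_bedtime``).

    Raises :class:`FormatError` for non-uniform epoch spacing and
    ``ValueError`` for negative lux. Blank/absent lux cells are masked
    missing. Without a diary, nightly times default to the scored sleep
    state's main transitions being absent — an empty diary is rejected.
    """
    df = pd.read_csv(epoch_path)
    required = {"timestamp", "lux", "sleep_state"}
    if not required.issubset(df.columns):
        raise FormatError(f"epoch CSV needs columns {sorted(required)}")
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) < 2:
        raise FormatError("epoch CSV must contain at least two rows")
    deltas = ts.diff().dropna().dt.total_seconds().to_numpy()
    if not np.allclose(deltas, deltas[0]):
        raise FormatError("non-uniform epoch spacing in epoch CSV")
    width_min = deltas[0] / 60.0

    lux = pd.to_numeric(df["lux"], errors="coerce").to_numpy(dtype=float)
    missing = ~np.isfinite(lux)
    if np.any(lux[~missing] < 0):
        raise ValueError("negative lux values in epoch CSV")
    lux = np.where(missing, 0.0, lux)

    state = pd.to_numeric(df["sleep_state"], errors="coerce").fillna(0).to_numpy(dtype=float)
    if not np.isin(state, (0.0, 1.0)).all():
        raise FormatError("sleep_state must be 0 (wake) or 1 (sleep)")

    start = pd.Timestamp(ts.iloc[0])
    light = EpochSeries(start, width_min, lux, missing)
    sleep = EpochSeries(start, width_min, state, np.zeros_like(state, dtype=bool))

    if diary_path is None:
        raise FormatError("a diary CSV is required to define nightly bed/wake times")
    diary = pd.read_csv(diary_path)
    for col in ("bedtime", "waketime", "desired_bedtime"):
        if col not in diary.columns:
            raise FormatError(f"diary CSV missing column {col!r}")
    beds = np.array([parse_clock(str(v)) for v in diary["bedtime"]])
    wakes = np.array([parse_clock(str(v)) for v in diary["waketime"]])
    desired = parse_clock(str(diary["desired_bedtime"].iloc[0]))

    pid = participant_id or str(epoch_path)
    return Recording(pid, site, light, sleep, beds, wakes, desired)


def write_recording(rec: Recording, epoch_path, diary_path) -> None:
    """Write a recording back out in the same CSV dialect parse_recording reads."""
    times = rec.light.start_time + pd.to_timedelta(
        np.arange(rec.light.n) * rec.light.epoch_width, unit="m")
    lux = np.where(rec.light.missing, np.nan, rec.light.values)
    pd.DataFrame({
        "timestamp": times.strftime("%Y-%m-%dT%H:%M:%S"),
        "lux": np.round(lux, 3),
        "sleep_state": rec.sleepwake.values.astype(int),
    }).to_csv(epoch_path, index=False)
    pd.DataFrame({
        "night": np.arange(rec.n_nights),
        "bedtime": [format_clock(b) for b in rec.diary_bedtimes],
        "waketime": [format_clock(w) for w in rec.diary_waketimes],
        "desired_bedtime": [format_clock(rec.desired_bedtime)] * rec.n_nights,
    }).to_csv(diary_path, index=False)


def _run_onsets(cond: np.ndarray, run_len: int) -> np.ndarray:
    """Indices where a run of >= run_len consecutive True values begins."""
    if cond.size == 0 or run_len <= 0:
        return np.array([], dtype=int)
    padded = np.concatenate(([False], cond, [False])).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return starts[(ends - starts) >= run_len]


def adjust_bed_wake(rec: Recording, cfg: DetectConfig = DetectConfig()) -> Recording:
    """Reconcile diary bed/wake times against the objective record.

    If the recorded bedtime precedes the onset of the night's sustained
    low-light/sleep run by at least ``adjust_threshold_min`` minutes, the
    bedtime moves to that onset; symmetrically, if the recorded wake time
    disagrees with the start of the sustained wake/light-rise run ending
    the night by at least the threshold (in either direction), the wake
    time moves to that onset.
    Nights with no detectable sleep episode are flagged invalid. The
    operation is idempotent.
    """
    out = rec.copy()
    ew = rec.light.epoch_width
    run_epochs = max(1, int(round(cfg.run_min / ew)))
    thresh_h = cfg.adjust_threshold_min / 60.0
    n_ep = rec.light.n

    low = (rec.light.values < cfg.lux_threshold) | rec.light.missing
    asleep = rec.sleepwake.values >= 0.5
    sleepy = low & asleep
    wakey = ~asleep & ((rec.light.values >= cfg.lux_threshold) | rec.light.missing)

    off = (rec.anchor_noon() - rec.light.start_time).total_seconds() / 3600.0

    def to_idx(hours_from_start: float) -> int:
        return int(np.clip(round(hours_from_start * 60.0 / ew), 0, n_ep))

    for j in range(rec.n_nights):
        bed_h = off + 24.0 * j + (out.bedtimes[j] - 12.0)
        wake_h = off + 24.0 * j + (out.waketimes[j] - 12.0)
        i_bed, i_wake = to_idx(bed_h), to_idx(wake_h)

        # bedtime: first sustained low-light sleep run at/after diary bedtime
        srch_hi = min(n_ep, i_bed + int(16 * 60 / ew))
        onsets = _run_onsets(sleepy[i_bed:srch_hi], run_epochs)
        if onsets.size == 0:
            out.night_valid[j] = False
            continue
        onset_h = (i_bed + onsets[0]) * ew / 60.0
        if onset_h - bed_h >= thresh_h - 1e-9:
            out.bedtimes[j] = 12.0 + (onset_h - off - 24.0 * j)

        # wake: snap to the onset of the sustained wake/light-rise run ending
        # the night whenever it disagrees with the diary by >= the threshold
        # (the diary may run either early or late)
        w_lo = i_bed + int(onsets[0]) + run_epochs
        w_hi = min(n_ep, i_bed + int(20 * 60 / ew))
        wonsets = _run_onsets(wakey[w_lo:w_hi], run_epochs)
        if wonsets.size:
            rise_h = (w_lo + wonsets[0]) * ew / 60.0
            if abs(wake_h - rise_h) >= thresh_h - 1e-9:
                out.waketimes[j] = 12.0 + (rise_h - off - 24.0 * j)

    return out


def summarize_sleep_timing(rec: Recording, min_nights: int = 5) -> tuple[float, float]:
    """Mean objective bed and wake time over valid nights (linearized hours).

    Requires at least ``min_nights`` valid nights, mirroring the 5-7 night
    analysis window.
    """
    valid = rec.night_valid
    if valid.sum() < min_nights:
        raise InsufficientDataError(
            f"{valid.sum()} valid nights < required {min_nights}")
    return (circular_mean_clock(rec.bedtimes[valid]),
            circular_mean_clock(rec.waketimes[valid]))


def sleep_mask_from_nights(rec: Recording) -> np.ndarray:
    """Per-epoch boolean sleep mask reconstructed from nightly bed/wake times."""
    ew = rec.light.epoch_width
    mask = np.zeros(rec.light.n, dtype=bool)
    for j in range(rec.n_nights):
        if not rec.night_valid[j]:
            continue
        s, e = rec.night_interval_hours(j)
        i0 = max(0, int(np.ceil(s * 60.0 / ew - 1e-9)))
        i1 = min(rec.light.n, int(np.ceil(e * 60.0 / ew - 1e-9)))
        mask[i0:i1] = True
    return mask
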