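"""Light-series cleaning, binning, gap filling and contiguous-segment
extraction shared by both DLMO predictors.

Cleaning rules: wake epochs below 1 lux are treated as a covered device and
removed (masked missing, strict ``< 1``); light during scored sleep is set
to 0 lux because closed eyelids block retinal exposure. Cleaned series are
binned (mean or max), short gaps are filled, and the longest gap-free run —
trimmed to whole 24-h days — becomes the model input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .actigraphy_io import EpochSeries
from .errors import ConfigError, InsufficientDataError

BIN_WIDTHS = (1, 2, 5, 10, 15, 30, 60, 120)
BIN_STATS = ("mean", "max")
GAP_POLICIES = ("zero_fill", "mean_prev_2h")
MAX_GAP_HOURS = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class PreprocessConfig:
    """One point of the preprocessing search grid.

    bin_width_min : light bin width in minutes (1-120).
    bin_stat : reduce each bin to its ``mean`` or its ``max``.
    gap_policy : fill missing runs with ``zero_fill`` (0 lux) or
        ``mean_prev_2h`` (average of the preceding 2 h).
    max_gap_h : longest missing run, in hours, that may be filled (1-6).
    wake_lux_floor : wake epochs strictly below this are removed as
        covered-device artifacts.
    """

    bin_width_min: int = 60
    bin_stat: str = "max"
    gap_policy: str = "mean_prev_2h"
    max_gap_h: int = 2
    wake_lux_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width_min not in BIN_WIDTHS:
            raise ConfigError(f"bin_width_min must be one of {BIN_WIDTHS}")
        if self.bin_stat not in BIN_STATS:
            raise ConfigError(f"bin_stat must be one of {BIN_STATS}")
        if self.gap_policy not in GAP_POLICIES:
            raise ConfigError(f"gap_policy must be one of {GAP_POLICIES}")
        if self.max_gap_h not in MAX_GAP_HOURS:
            raise ConfigError(f"max_gap_h must be one of {MAX_GAP_HOURS}")


def clean_light(light: EpochSeries, sleep_mask: np.ndarray,
                wake_lux_floor: float = 1.0) -> EpochSeries:
    """Apply the covered-device and sleep-zeroing rules.

    Wake epochs with lux strictly below ``wake_lux_floor`` become missing;
    every sleep epoch is set to 0 lux regardless of the measured value
    (a measured 1.0 lux during wake is kept — the cut is strict).
    """
    sleep_mask = np.asarray(sleep_mask, dtype=bool)
    if sleep_mask.size != light.n:
        raise ValueError("sleep mask length must match light series")
    out = light.copy()
    covered = ~sleep_mask & ~out.missing & (out.values < wake_lux_floor)
    out.missing = out.missing | covered
    out.values = np.where(out.missing, 0.0, out.values)
    out.values[sleep_mask] = 0.0
    out.missing[sleep_mask] = False
    return out


def _bin_offset_epochs(s: EpochSeries, width_min: int) -> int:
    """Check midnight-anchored alignment; return 0 (we require alignment)."""
    start_min = (s.start_time.hour * 60 + s.start_time.minute)
    if start_min % width_min != 0:
        raise ConfigError(
            f"series start {s.start_time} is not aligned to {width_min}-min "
            "bins anchored at midnight")
    return 0


def bin_series(s: EpochSeries, width_min: int, stat: str = "max") -> EpochSeries:
    """Bin an epoch series to ``width_min`` minutes using mean or max.

    Bins are anchored at clock midnight. Each output value is the statistic
    over the bin's non-missing members; a bin whose members are all missing
    is itself missing.
    """
    if stat not in BIN_STATS:
        raise ConfigError(f"stat must be one of {BIN_STATS}")
    ratio = width_min / s.epoch_width
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ConfigError(
            f"bin width {width_min} min is not a multiple of the epoch width "
            f"{s.epoch_width} min")
    k = int(round(ratio))
    _bin_offset_epochs(s, width_min)
    n_bins = s.n // k
    if n_bins == 0:
        raise InsufficientDataError("series shorter than one bin")
    v = s.values[: n_bins * k].reshape(n_bins, k)
    m = s.missing[: n_bins * k].reshape(n_bins, k)
    any_valid = (~m).any(axis=1)
    vm = np.ma.masked_array(v, mask=m)
    agg = vm.max(axis=1) if stat == "max" else vm.mean(axis=1)
    out_vals = np.where(any_valid, np.ma.filled(agg, 0.0), 0.0)
    return EpochSeries(s.start_time, float(width_min), out_vals, ~any_valid)


def _missing_runs(missing: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal missing runs (half-open)."""
    padded = np.concatenate(([False], missing, [False])).astype(int)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def fill_gaps(s: EpochSeries, cfg: PreprocessConfig) -> EpochSeries:
    """Fill missing runs no longer than ``cfg.max_gap_h``.

    ``zero_fill`` inserts 0 lux; ``mean_prev_2h`` inserts the mean of the
    non-missing values in the 2 h immediately preceding the run (0 lux when
    that window is empty, e.g. a gap at the series start). Longer runs stay
    missing, and non-missing values are never modified.
    """
    out = s.copy()
    max_gap_epochs = int(round(cfg.max_gap_h * 60.0 / s.epoch_width))
    prev_epochs = int(round(120.0 / s.epoch_width))
    for start, stop in _missing_runs(s.missing):
        if stop - start > max_gap_epochs:
            continue
        if cfg.gap_policy == "zero_fill":
            fill = 0.0
        else:
            lo = max(0, start - prev_epochs)
            window_v = s.values[lo:start]
            window_m = s.missing[lo:start]
            valid = window_v[~window_m]
            fill = float(valid.mean()) if valid.size else 0.0
        out.values[start:stop] = fill
        out.missing[start:stop] = False
    return out


def longest_contiguous_days(s: EpochSeries) -> EpochSeries:
    """Longest run with no missing values, trimmed to whole 24-h days.

    The trim is anchored to the run's first epoch, so a repeated-day input
    keeps its clock alignment. Raises :class:`InsufficientDataError` when no
    run covers a full day.
    """
    epochs_per_day = int(round(1440.0 / s.epoch_width))
    best = (0, 0)
    runs = _missing_runs(~s.missing)  # runs of *valid* epochs
    for start, stop in runs:
        if stop - start > best[1] - best[0]:
            best = (start, stop)
    start, stop = best
    n_days = (stop - start) // epochs_per_day
    if n_days < 1:
        raise InsufficientDataError(
            "cannot construct at least 1 day of consecutive valid light data")
    stop = start + n_days * epochs_per_day
    new_start = s.start_time + pd.Timedelta(minutes=start * s.epoch_width)
    return EpochSeries(new_start, s.epoch_width,
                       s.values[start:stop].copy(), s.missing[start:stop].copy())


def preprocess_recording(rec, cfg: PreprocessConfig,
                         sleep_mask: np.ndarray | None = None
                         ) -> tuple[EpochSeries, np.ndarray]:
    """Full chain clean -> bin -> fill -> longest whole-day segment.

    Returns the light segment plus the binary sleep forcing resampled onto
    the same bins (a bin counts as sleep when at least half its epochs are
    sleep-scored).
    """
    if sleep_mask is None:
        sleep_mask = rec.sleepwake.values >= 0.5
    cleaned = clean_light(rec.light, sleep_mask, cfg.wake_lux_floor)
    binned = bin_series(cleaned, cfg.bin_width_min, cfg.bin_stat)
    filled = fill_gaps(binned, cfg)
    segment = longest_contiguous_days(filled)

    sleep_series = EpochSeries(rec.sleepwake.start_time, rec.sleepwake.epoch_width,
                               np.asarray(sleep_mask, dtype=float),
                               np.zeros(rec.sleepwake.n, dtype=bool))
    sleep_binned = bin_series(sleep_series, cfg.bin_width_min, "mean")
    i0 = int(round((segment.start_time - sleep_binned.start_time)
                   .total_seconds() / 60.0 / cfg.bin_width_min))
    sleep_seg = sleep_binned.values[i0:i0 + segment.n] >= 0.5
    return segment, sleep_seg.astype(float)
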