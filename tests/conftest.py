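import numpy as np
import pandas as pd
import pytest

from phasepred.actigraphy_io import EpochSeries, Recording

NOON_START = pd.Timestamp("2021-03-01 12:00:00")


def make_series(values, missing=None, start=NOON_START, width=1.0):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(values.size, dtype=bool)
    return EpochSeries(start, width, values, np.asarray(missing, dtype=bool))


def make_recording(bed=24.0, wake=32.0, n_nights=7, wake_lux=100.0,
                   diary_bed=None, diary_wake=None, desired=24.0,
                   pid="T000", site="A"):
    """Deterministic noon-anchored recording with constant wake lux and a
    clean nightly sleep episode from ``bed`` to ``wake`` (linearized hours)."""
    bed = np.full(n_nights, bed) if np.isscalar(bed) else np.asarray(bed, float)
    wake = np.full(n_nights, wake) if np.isscalar(wake) else np.asarray(wake, float)
    lux_days, sleep_days = [], []
    for j in range(n_nights):
        t = 12.0 + np.arange(1440) / 60.0
        asleep = (t >= bed[j] - 1e-9) & (t < wake[j] - 1e-9)
        lux = np.where(asleep, 0.0, wake_lux)
        lux_days.append(lux)
        sleep_days.append(asleep.astype(float))
    lux = np.concatenate(lux_days)
    sleep = np.concatenate(sleep_days)
    light = make_series(lux)
    sw = make_series(sleep)
    db = np.full(n_nights, diary_bed) if diary_bed is not None else bed.copy()
    dw = np.full(n_nights, diary_wake) if diary_wake is not None else wake.copy()
    return Recording(pid, site, light, sw, db, dw, desired)


@pytest.fixture
def noon_start():
    return NOON_START
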