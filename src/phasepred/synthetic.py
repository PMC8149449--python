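"""Seeded generator of delayed-phase (DSWPD-like) synthetic cohorts.

Each synthetic participant carries a 7-day, 1-min actigraphy recording
(white-light lux and scored sleep/wake), a sleep diary, demographics, a
melatonin profile, and a ground-truth DLMO — everything the prediction
pipeline consumes, with the cohort-level statistics of the clinical sample
it emulates: DLMO 22:07 +/- 1:26, bedtime 0:41 +/- 1:19, wake 8:46 +/-
1:21, desired-bedtime-to-DLMO phase angle -0:19 +/- 1:17, age 30.1 +/-
10.7 (16-64), 54.5% female, 85.1% definite evening chronotype.

Two ground-truth modes exist. *phenomenological* (default) draws DLMO from
the phase-angle distribution anchored to sleep timing and is model
agnostic. *model_consistent* forward-simulates the dynamic pacemaker model
with a reference parameter set on the artifact-free light schedule and uses
its prediction as the truth, which makes parameter-recovery experiments
well posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actigraphy_io import EpochSeries, Recording
from .clock import linearize
from .phase_assessment import MelatoninProfile

EPOCH_MIN = 1.0
N_NIGHTS = 7


@dataclass(frozen=True)
class SynthConfig:
    """Cohort generator settings; defaults reproduce the target cohort
    moments (times are linearized clock hours, SDs in hours)."""

    n: int = 154
    seed: int = 0
    mode: str = "phenomenological"  # or "model_consistent"

    bedtime_mean: float = 24.0 + 41.0 / 60.0      # 0:41
    bedtime_sd: float = 1.0 + 19.0 / 60.0          # 1:19
    dlmo_bed_gap_mean: float = 2.0 + 34.0 / 60.0   # bedtime - DLMO = 2:34
    dlmo_bed_gap_sd: float = 0.565                  # so that DLMO SD = 1:26
    sleep_duration_mean: float = 8.0 + 5.0 / 60.0  # wake 8:46 on average
    sleep_duration_sd: float = 0.5
    phase_angle_mean: float = -(19.0 / 60.0)       # DBT - DLMO = -0:19
    phase_angle_sd: float = 1.0 + 17.0 / 60.0      # 1:17
    night_jitter_sd: float = 0.4                    # night-to-night timing SD
    diary_noise_sd: float = 10.0 / 60.0             # diary reporting noise

    age_mean: float = 30.1
    age_sd: float = 10.7
    age_range: tuple[float, float] = (16.0, 64.0)
    p_female: float = 0.545
    p_definite_evening: float = 0.851
    site_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    indoor_lux_median: float = 150.0
    indoor_lux_log_sd: float = 0.7
    daylight_bursts_per_day: float = 2.0
    burst_lux_median: float = 5000.0
    burst_duration_mean_min: float = 30.0
    evening_dim_factor: float = 0.2
    evening_dim_hours: float = 2.0
    sleep_lux: float = 0.0
    wake_lux_min: float = 1.5

    covered_episodes_per_day: float = 0.5
    covered_duration_mean_min: float = 30.0
    gaps_per_day: float = 0.3
    gap_duration_mean_min: float = 60.0

    melatonin_noise_sd: float = 0.0
    melatonin_rise_slope: float = 2.0  # pg/mL per hour through onset
    melatonin_floor: float = 0.25      # daytime baseline pg/mL

    reference_params: object = None  # DynamicParams for model_consistent mode


@dataclass
class SyntheticParticipant:
    """A recording plus everything measured about the synthetic patient."""

    recording: Recording
    age: float
    sex_female: int
    cmeq_score: int
    true_dlmo: float
    melatonin: MelatoninProfile
    mean_bedtime: float
    mean_waketime: float


def _participant_rng(seed: int, participant_id: str) -> np.random.Generator:
    """Stable per-participant substream keyed on the participant id."""
    digest = np.uint32(2166136261)
    for ch in participant_id.encode():
        digest = np.uint32((int(digest) ^ ch) * 16777619 & 0xFFFFFFFF)
    return np.random.default_rng([seed, int(digest)])


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def generate_light_day(bed_lin: float, wake_lin: float, cfg: SynthConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """One noon-to-noon day of 1-min measured lux for the given schedule.

    Sleep minutes read a dim constant (the device sees essentially no
    light); wake minutes draw log-normal indoor illuminance with optional
    outdoor daylight bursts, dimmed in the final hours before bedtime.
    """
    n = int(round(1440 / EPOCH_MIN))
    t = 12.0 + np.arange(n) * (EPOCH_MIN / 60.0)  # linearized hours
    asleep = (t >= bed_lin - 1e-9) & (t < wake_lin - 1e-9)

    lux = np.exp(rng.normal(np.log(cfg.indoor_lux_median),
                            cfg.indoor_lux_log_sd, size=n))
    # daylight bursts within daylight clock hours (8:00-18:00)
    clock = t % 24.0
    daylight = (clock >= 8.0) & (clock < 18.0)
    n_bursts = rng.poisson(cfg.daylight_bursts_per_day)
    day_idx = np.flatnonzero(daylight & ~asleep)
    for _ in range(n_bursts):
        if day_idx.size == 0:
            break
        start = rng.choice(day_idx)
        dur = max(1, int(rng.exponential(cfg.burst_duration_mean_min)))
        lvl = np.exp(rng.normal(np.log(cfg.burst_lux_median), 0.5))
        lux[start:start + dur] = np.maximum(lux[start:start + dur], lvl)
    # dim pre-bed evening light
    pre_bed = (t >= bed_lin - cfg.evening_dim_hours) & (t < bed_lin)
    lux[pre_bed] *= cfg.evening_dim_factor
    lux = np.maximum(lux, cfg.wake_lux_min)
    lux[asleep] = cfg.sleep_lux
    return lux


def inject_missingness(rec: Recording, cfg: SynthConfig,
                       rng: np.random.Generator) -> Recording:
    """Insert covered-device episodes (wake lux < 1, removed later by
    cleaning) and true recording gaps. Ground truth is unchanged."""
    out = rec.copy()
    n = out.light.n
    days = n * out.light.epoch_width / 1440.0
    awake = out.sleepwake.values < 0.5

    for _ in range(rng.poisson(cfg.covered_episodes_per_day * days)):
        start = int(rng.integers(0, n))
        dur = max(1, int(rng.exponential(cfg.covered_duration_mean_min)))
        sel = slice(start, min(n, start + dur))
        vals = out.light.values[sel]
        out.light.values[sel] = np.where(awake[sel], rng.uniform(0.0, 0.9), vals)
    for _ in range(rng.poisson(cfg.gaps_per_day * days)):
        start = int(rng.integers(0, n))
        dur = max(1, int(rng.exponential(cfg.gap_duration_mean_min)))
        out.light.missing[start:min(n, start + dur)] = True
    return out


def generate_melatonin_profile(true_dlmo: float, habitual_bedtime: float,
                               cfg: SynthConfig, rng: np.random.Generator
                               ) -> MelatoninProfile:
    """Hourly samples from 5 h before to 2 h after habitual bedtime.

    The noise-free profile rises linearly through (true DLMO, 2.3 pg/mL)
    at ``melatonin_rise_slope``, floored at a daytime baseline. The floor
    sits low enough that the two samples bracketing the onset always lie on
    the rising line, so linear interpolation recovers the true DLMO
    exactly in the noise-free case. A DLMO outside the sampling window
    yields a profile whose onset is undetermined downstream, mirroring
    failed laboratory assessments.
    """
    t0 = habitual_bedtime - 5.0
    t = t0 + np.arange(8, dtype=float)  # hourly through bedtime + 2 h
    conc = 2.3 + cfg.melatonin_rise_slope * (t - true_dlmo)
    conc = np.maximum(conc, cfg.melatonin_floor)
    if cfg.melatonin_noise_sd > 0:
        conc = conc * np.exp(rng.normal(0.0, cfg.melatonin_noise_sd, size=t.size))
    return MelatoninProfile(t, np.maximum(conc, 0.0))


def _schedule(cfg: SynthConfig, rng: np.random.Generator):
    mean_bed = _truncnorm(rng, cfg.bedtime_mean, cfg.bedtime_sd, 20.0, 30.0)
    gap = _truncnorm(rng, cfg.dlmo_bed_gap_mean, cfg.dlmo_bed_gap_sd, 0.75, 6.0)
    dur = _truncnorm(rng, cfg.sleep_duration_mean, cfg.sleep_duration_sd, 5.0, 11.0)
    mean_wake = mean_bed + dur
    beds = mean_bed + rng.normal(0.0, cfg.night_jitter_sd, N_NIGHTS)
    wakes = mean_wake + rng.normal(0.0, cfg.night_jitter_sd, N_NIGHTS)
    wakes = np.maximum(wakes, beds + 3.0)
    wakes = np.minimum(wakes, 35.9)
    return mean_bed, mean_wake, gap, beds, wakes


def _build_recording(pid, site, beds, wakes, desired, cfg, rng,
                     start: pd.Timestamp) -> Recording:
    lux_days, sleep_days = [], []
    for j in range(N_NIGHTS):
        lux_days.append(generate_light_day(beds[j], wakes[j], cfg, rng))
        n = lux_days[-1].size
        t = 12.0 + np.arange(n) * (EPOCH_MIN / 60.0)
        sleep_days.append(((t >= beds[j] - 1e-9)
                           & (t < wakes[j] - 1e-9)).astype(float))
    lux = np.concatenate(lux_days)
    sleep = np.concatenate(sleep_days)
    light = EpochSeries(start, EPOCH_MIN, lux, np.zeros(lux.size, dtype=bool))
    sw = EpochSeries(start, EPOCH_MIN, sleep, np.zeros(sleep.size, dtype=bool))
    diary_beds = beds + rng.normal(0.0, cfg.diary_noise_sd, N_NIGHTS)
    diary_wakes = wakes + rng.normal(0.0, cfg.diary_noise_sd, N_NIGHTS)
    return Recording(pid, site, light, sw, diary_beds, diary_wakes, desired)


def generate_participant(cfg: SynthConfig, index: int,
                         start: pd.Timestamp | None = None
                         ) -> SyntheticParticipant:
    """Generate one synthetic participant (deterministic given cfg.seed)."""
    pid = f"S{index:03d}"
    rng = _participant_rng(cfg.seed, pid)
    site = ("A", "B", "C")[rng.choice(3, p=cfg.site_probs)]
    mean_bed, mean_wake, gap, beds, wakes = _schedule(cfg, rng)

    age = _truncnorm(rng, cfg.age_mean, cfg.age_sd, *cfg.age_range)
    sex_female = int(rng.random() < cfg.p_female)
    definite = rng.random() < cfg.p_definite_evening
    cmeq = int(rng.integers(16, 31)) if definite else int(rng.integers(31, 42))

    true_dlmo = mean_bed - gap
    pa = rng.normal(cfg.phase_angle_mean, cfg.phase_angle_sd)
    desired = linearize(true_dlmo + pa)

    if start is None:
        start = pd.Timestamp("2021-03-01 12:00:00")
    rec = _build_recording(pid, site, beds, wakes, desired, cfg, rng, start)

    if cfg.mode == "model_consistent":
        from .light_preprocess import PreprocessConfig
        from .pacemaker import DynamicParams, predict_dlmo_dynamic
        params = cfg.reference_params or DynamicParams()
        true_dlmo = predict_dlmo_dynamic(rec, params, PreprocessConfig())
    elif cfg.mode != "phenomenological":
        raise ValueError(f"unknown mode {cfg.mode!r}")

    rec = inject_missingness(rec, cfg, rng)
    mel = generate_melatonin_profile(true_dlmo, mean_bed, cfg, rng)
    return SyntheticParticipant(rec, age, sex_female, cmeq, float(true_dlmo),
                                mel, mean_bed, mean_wake)


def generate_cohort(cfg: SynthConfig) -> list[SyntheticParticipant]:
    """Generate a full cohort; byte-identical across runs with one seed."""
    if cfg.n < 1:
        raise ValueError("cohort size must be at least 1")
    return [generate_participant(cfg, i) for i in range(cfg.n)]


def sample_feature_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw regression design rows (delay light, advance light, age, sex,
    bedtime, waketime, chronotype) from the cohort covariate distributions,
    for Monte-Carlo experiments on the regression machinery alone."""
    cfg = SynthConfig()
    bed = rng.normal(cfg.bedtime_mean, cfg.bedtime_sd, n)
    wake = bed + rng.normal(cfg.sleep_duration_mean, cfg.sleep_duration_sd, n)
    return np.column_stack([
        rng.normal(0.5, 0.6, n),            # mean log10 delay-zone lux
        rng.normal(1.8, 0.5, n),            # mean log10 advance-zone lux
        np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 16, 64),
        (rng.random(n) < cfg.p_female).astype(float),
        bed,
        wake,
        (rng.random(n) < cfg.p_definite_evening).astype(float),
    ])
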