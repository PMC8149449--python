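"""PRC-zone light features and the multiple linear regression DLMO
predictor.

Light has opposite circadian effects before and after the core body
temperature minimum (CBTmin): exposure in the 6 h before CBTmin delays the
clock and exposure in the 6 h after advances it. CBTmin is anchored for the
whole sample at the group-mean DLMO + 7 h, the zones are fixed around it,
and each participant's mean log10 light in the delay and advance zones —
together with age, sex, actigraphic bed/wake times and chronotype category
— enters an ordinary least-squares regression with DLMO (linearized hours)
as the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .actigraphy_io import Recording, summarize_sleep_timing
from .clock import linearize
from .errors import InsufficientDataError
from .light_preprocess import clean_light

#: Zero lux is floored to this value before the log10 transform.
LOG_LUX_FLOOR = 0.001

#: Default CBTmin anchor: sample-mean DLMO of 22:10 plus the 7-h phase angle.
DEFAULT_MEAN_DLMO = 22.0 + 10.0 / 60.0

FEATURE_NAMES = ("delay_light", "advance_light", "age", "sex_female",
                 "bedtime", "waketime", "cmeq_definite_evening")


@dataclass(frozen=True)
class PRCZones:
    """Delay/advance light windows around the anchored CBTmin.

    The delay zone is [cbtmin - 6 h, cbtmin) and the advance zone is
    (cbtmin, cbtmin + 6 h], all in linearized clock hours; together they
    partition the 12 h around CBTmin.
    """

    cbtmin: float

    @property
    def delay_window(self) -> tuple[float, float]:
        return (self.cbtmin - 6.0, self.cbtmin)

    @property
    def advance_window(self) -> tuple[float, float]:
        return (self.cbtmin, self.cbtmin + 6.0)


@dataclass
class FeatureVector:
    """Regression predictors for one participant."""

    delay_light: float
    advance_light: float
    age: float
    sex_female: int
    bedtime: float
    waketime: float
    cmeq_definite_evening: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES],
                        dtype=float)


@dataclass
class RegressionFit:
    """Fitted OLS model: coefficients, their standard errors, and fit
    summaries. Predictions reproduce fitted values on the training data."""

    intercept: float
    coef: dict[str, float]
    se: dict[str, float]
    intercept_se: float
    r_squared: float
    resid_sd: float
    n: int


def estimate_group_cbtmin(group_mean_dlmo: float) -> PRCZones:
    """Anchor CBTmin at the sample-mean DLMO + 7 h.

    A mean DLMO of 22:10 gives CBTmin 5:10, delay zone 23:10-5:10 and
    advance zone 5:10-11:10.
    """
    return PRCZones(cbtmin=group_mean_dlmo + 7.0)


def cmeq_definite_evening(score: float) -> int:
    """1 for definite evening type (cMEQ 16-30), 0 for moderate (31-41)."""
    return 1 if score <= 30 else 0


def _zone_day_means(light, zones: PRCZones, min_coverage: float
                    ) -> list[tuple[float, float]]:
    """Per noon-anchored day, mean log10 lux in each zone, or None entries
    when a zone's non-missing coverage falls below ``min_coverage``."""
    clock = linearize(light.clock_hours())
    hours = light.hours_from_start()
    start_clock = clock[0]
    day_idx = np.floor((hours + (start_clock - 12.0)) / 24.0).astype(int)

    loglux = np.log10(np.maximum(light.values, LOG_LUX_FLOOR))
    out = []
    for d in range(day_idx.min(), day_idx.max() + 1):
        in_day = day_idx == d
        feats = []
        for lo, hi, closed_hi in (
                (*zones.delay_window, False), (*zones.advance_window, True)):
            eps = 1e-6  # tolerate float jitter on minute-grid boundaries
            if closed_hi:
                in_zone = in_day & (clock > lo + eps) & (clock <= hi + eps)
            else:
                in_zone = in_day & (clock >= lo - eps) & (clock < hi - eps)
            n_zone = int(in_zone.sum())
            expected = int(round(6.0 * 60.0 / light.epoch_width))
            valid = in_zone & ~light.missing
            if n_zone < expected or valid.sum() < min_coverage * n_zone:
                feats.append(None)
            else:
                feats.append(float(loglux[valid].mean()))
        out.append(tuple(feats))
    return out


def extract_features(rec: Recording, zones: PRCZones, age: float,
                     sex_female: int, cmeq_score: float,
                     min_days: int = 5, min_coverage: float = 0.75
                     ) -> FeatureVector:
    """Per-participant delay/advance light features plus covariates.

    The light series is cleaned (sleep zeroed, < 1 lux wake removed), then
    for each recorded day the mean of log10(max(lux, 0.001)) is taken within
    each zone; days where a zone has under ``min_coverage`` non-missing
    epochs are dropped, and at least ``min_days`` valid days are required.
    The day-level means are averaged into one delay and one advance value.
    """
    sleep_mask = rec.sleepwake.values >= 0.5
    cleaned = clean_light(rec.light, sleep_mask)
    day_means = _zone_day_means(cleaned, zones, min_coverage)
    delay = [d for d, a in day_means if d is not None and a is not None]
    advance = [a for d, a in day_means if d is not None and a is not None]
    if len(delay) < min_days:
        raise InsufficientDataError(
            f"only {len(delay)} valid zone-days < required {min_days}")
    bed, wake = summarize_sleep_timing(rec, min_nights=min_days)
    return FeatureVector(
        delay_light=float(np.mean(delay)),
        advance_light=float(np.mean(advance)),
        age=age, sex_female=int(sex_female),
        bedtime=bed, waketime=wake,
        cmeq_definite_evening=cmeq_definite_evening(cmeq_score),
    )


def split_train_test(cohort: list, sites: list[str], seed: int
                     ) -> tuple[list[int], list[int]]:
    """Seeded 50/50 split of cohort indices, stratified by study site.

    Odd-sized sites contribute their extra member to whichever half is
    currently smaller (seeded coin flip on ties), so overall halves differ
    by at most one.
    """
    rng = np.random.default_rng(seed)
    by_site: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_site.setdefault(s, []).append(i)
    train: list[int] = []
    test: list[int] = []
    for s in sorted(by_site):
        idx = np.array(by_site[s])
        rng.shuffle(idx)
        n_tr = len(idx) // 2
        if len(idx) % 2 == 1:
            if len(train) < len(test):
                n_tr += 1
            elif len(train) == len(test) and rng.random() < 0.5:
                n_tr += 1
        train.extend(idx[:n_tr].tolist())
        test.extend(idx[n_tr:].tolist())
    return sorted(train), sorted(test)


def fit_ols(features: list[FeatureVector], dlmo: np.ndarray) -> RegressionFit:
    """Ordinary least squares of DLMO (linearized hours) on the predictors."""
    X = np.vstack([fv.as_array() for fv in features])
    y = np.asarray(dlmo, dtype=float)
    if y.size <= X.shape[1] + 1:
        raise InsufficientDataError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        sds = X.std(axis=0)
        flat = [FEATURE_NAMES[j] for j in range(len(FEATURE_NAMES)) if sds[j] == 0]
        raise ValueError(
            "rank-deficient design matrix; constant or collinear columns: "
            f"{flat or 'correlated predictors'}")
    res = sm.OLS(y, Xc).fit()
    dof = max(1, res.df_resid)
    return RegressionFit(
        intercept=float(res.params[0]),
        coef={name: float(v) for name, v in zip(FEATURE_NAMES, res.params[1:])},
        se={name: float(v) for name, v in zip(FEATURE_NAMES, res.bse[1:])},
        intercept_se=float(res.bse[0]),
        r_squared=float(res.rsquared),
        resid_sd=float(np.sqrt(np.sum(res.resid ** 2) / dof)),
        n=int(y.size),
    )


def predict_dlmo_statistical(fit: RegressionFit, fv: FeatureVector) -> float:
    """Predicted DLMO (linearized hours) for one feature vector."""
    x = fv.as_array()
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains non-finite covariates")
    return float(fit.intercept
                 + sum(fit.coef[n] * xi for n, xi in zip(FEATURE_NAMES, x)))
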