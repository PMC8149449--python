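import numpy as np
import pytest

from phasepred.clock import parse_clock
from phasepred.errors import InsufficientDataError
from phasepred.statistical_model import (FEATURE_NAMES, FeatureVector,
                                         RegressionFit, cmeq_definite_evening,
                                         estimate_group_cbtmin,
                                         extract_features, fit_ols,
                                         predict_dlmo_statistical,
                                         split_train_test)

from conftest import make_recording


def _random_features(rng, n):
    from phasepred.synthetic import sample_feature_matrix
    X = sample_feature_matrix(n, rng)
    return [FeatureVector(*row) for row in X], X


class TestZones:
    def test_group_anchor_2210_gives_cbtmin_0510(self):
        zones = estimate_group_cbtmin(parse_clock("22:10"))
        assert zones.cbtmin == pytest.approx(parse_clock("5:10"))
        assert zones.delay_window == pytest.approx(
            (parse_clock("23:10"), parse_clock("5:10")))
        assert zones.advance_window == pytest.approx(
            (parse_clock("5:10"), parse_clock("11:10")))

    def test_2200_and_midnight_wrap(self):
        assert estimate_group_cbtmin(parse_clock("22:00")).cbtmin == \
            pytest.approx(parse_clock("5:00"))
        z = estimate_group_cbtmin(parse_clock("23:30"))
        assert z.cbtmin == pytest.approx(parse_clock("6:30"))
        assert z.delay_window[0] == pytest.approx(parse_clock("0:30"))

    def test_windows_partition_12h(self):
        z = estimate_group_cbtmin(22.5)
        assert z.delay_window[1] == z.advance_window[0]
        assert z.advance_window[1] - z.delay_window[0] == pytest.approx(12.0)


class TestExtractFeatures:
    def test_dark_delay_zone_and_bright_advance_zone(self):
        # asleep throughout the delay zone (light zeroed -> log10 0.001 = -3),
        # awake at 100 lux throughout the advance zone -> log10 = 2
        zones = estimate_group_cbtmin(parse_clock("22:10"))
        rec = make_recording(bed=parse_clock("23:10"), wake=parse_clock("5:10"),
                             wake_lux=100.0)
        fv = extract_features(rec, zones, age=30.0, sex_female=1,
                              cmeq_score=25)
        assert fv.delay_light == pytest.approx(-3.0)
        assert fv.advance_light == pytest.approx(2.0)
        assert fv.bedtime == pytest.approx(parse_clock("23:10"))
        assert fv.cmeq_definite_evening == 1

    def test_sleep_lux_does_not_leak_into_features(self):
        zones = estimate_group_cbtmin(parse_clock("22:10"))
        rec1 = make_recording(bed=parse_clock("23:10"), wake=parse_clock("5:10"))
        rec2 = make_recording(bed=parse_clock("23:10"), wake=parse_clock("5:10"))
        sleeping = rec2.sleepwake.values >= 0.5
        rec2.light.values[sleeping] = 300.0  # device saw light during sleep
        f1 = extract_features(rec1, zones, 30.0, 0, 20)
        f2 = extract_features(rec2, zones, 30.0, 0, 20)
        assert f1.delay_light == pytest.approx(f2.delay_light)
        assert f1.advance_light == pytest.approx(f2.advance_light)

    def test_insufficient_valid_days(self):
        zones = estimate_group_cbtmin(parse_clock("22:10"))
        rec = make_recording(bed=parse_clock("23:10"), wake=parse_clock("5:10"))
        rec.light.missing[: 5 * 1440] = True  # kill five days of light
        with pytest.raises(InsufficientDataError):
            extract_features(rec, zones, 30.0, 0, 20)

    def test_cmeq_category_boundaries(self):
        assert cmeq_definite_evening(16) == 1
        assert cmeq_definite_evening(30) == 1
        assert cmeq_definite_evening(31) == 0
        assert cmeq_definite_evening(41) == 0


class TestSplit:
    def test_even_sites_split_in_half(self):
        sites = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        train, test = split_train_test(list(range(30)), sites, seed=3)
        assert len(train) == len(test) == 15
        for s in "ABC":
            idx = [i for i, x in enumerate(sites) if x == s]
            assert sum(i in train for i in idx) == 5

    def test_same_seed_reproduces_split(self):
        sites = (["A"] * 7 + ["B"] * 7 + ["C"] * 8)
        s1 = split_train_test(list(range(22)), sites, seed=9)
        s2 = split_train_test(list(range(22)), sites, seed=9)
        assert s1 == s2

    def test_odd_sites_balance_overall(self):
        sites = (["A"] * 7 + ["B"] * 7 + ["C"] * 8)
        train, test = split_train_test(list(range(22)), sites, seed=9)
        assert {len(train), len(test)} == {11}


class TestOLS:
    def test_exact_recovery_without_noise(self):
        rng = np.random.default_rng(11)
        feats, X = _random_features(rng, 60)
        beta = np.array([0.35, -0.2, 0.01, 0.3, 0.5, 0.1, -0.4])
        y = 5.0 + X @ beta
        fit = fit_ols(feats, y)
        assert fit.intercept == pytest.approx(5.0, abs=1e-8)
        for name, b in zip(FEATURE_NAMES, beta):
            assert fit.coef[name] == pytest.approx(b, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_training_observation_reproduced_under_zero_residual_fit(self):
        rng = np.random.default_rng(2)
        feats, X = _random_features(rng, 40)
        y = 20.0 + X @ np.linspace(-0.3, 0.3, 7)
        fit = fit_ols(feats, y)
        pred = predict_dlmo_statistical(fit, feats[0])
        assert pred == pytest.approx(y[0], abs=1e-8)

    def test_constant_column_raises_naming_rank_deficiency(self):
        rng = np.random.default_rng(4)
        feats, X = _random_features(rng, 40)
        for fv in feats:
            fv.sex_female = 1  # no variance left
        with pytest.raises(ValueError, match="sex_female"):
            fit_ols(feats, np.arange(40, dtype=float))

    def test_affine_equivariance_under_time_shift(self):
        rng = np.random.default_rng(8)
        feats, X = _random_features(rng, 80)
        y = 3.0 + X @ np.array([0.3, -0.1, 0.0, 0.2, 0.6, 0.05, -0.2]) \
            + rng.normal(0, 0.5, 80)
        fit = fit_ols(feats, y)
        delta = 1.5
        shifted = []
        for fv in feats:
            s = FeatureVector(fv.delay_light, fv.advance_light, fv.age,
                              fv.sex_female, fv.bedtime + delta,
                              fv.waketime + delta, fv.cmeq_definite_evening)
            shifted.append(s)
        fit2 = fit_ols(shifted, y + delta)
        for fv, sv in zip(feats, shifted):
            p1 = predict_dlmo_statistical(fit, fv)
            p2 = predict_dlmo_statistical(fit2, sv)
            assert p2 == pytest.approx(p1 + delta, abs=1e-6)

    def test_hand_computed_dot_product(self):
        fit = RegressionFit(
            intercept=10.0,
            coef={n: c for n, c in zip(FEATURE_NAMES,
                                       [2.0, -1.0, 0.0, 0.0, 0.5, 0.0, 0.0])},
            se={n: 0.0 for n in FEATURE_NAMES}, intercept_se=0.0,
            r_squared=1.0, resid_sd=0.0, n=10)
        fv = FeatureVector(delay_light=1.0, advance_light=2.0, age=30,
                           sex_female=0, bedtime=24.0, waketime=32.0,
                           cmeq_definite_evening=1)
        # 10 + 2*1 - 1*2 + 0.5*24 = 22
        assert predict_dlmo_statistical(fit, fv) == pytest.approx(22.0)

    def test_all_zero_features_give_intercept(self):
        fit = RegressionFit(10.5, {n: 1.0 for n in FEATURE_NAMES},
                            {n: 0.0 for n in FEATURE_NAMES}, 0.0, 1.0, 0.0, 9)
        fv = FeatureVector(0, 0, 0, 0, 0, 0, 0)
        assert predict_dlmo_statistical(fit, fv) == pytest.approx(10.5)
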