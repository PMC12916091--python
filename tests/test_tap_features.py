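import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tapcog import tap_features as tf
from tapcog.tap_features import InvalidTrialError, ZeroVarianceError

import oracles
from conftest import make_trial, random_trial

# Hand-derived values for the worked trial: taps at 0/200/450/650/950 ms,
# buttons L,R,L,R,L -> all-button ITIs [200, 250, 200, 300].
WORKED_EXPECTED = {
    "n_taps": 5.0,
    "mean_iti": 237.5,
    "sd_iti": math.sqrt(6875.0 / 3.0),          # 47.871...
    "cv_iti": math.sqrt(6875.0 / 3.0) / 237.5,  # 0.2016...
    "skewness_iti": 35156.25 / 1718.75**1.5,    # 0.4934...
    "kurtosis_iti": 4809570.3125 / 1718.75**2 - 3.0,  # -1.3719...
    "alternating_tap_ratio": 1.0,
    "mean_left_iti": 475.0,                      # left taps 0/450/950
    "sd_left_iti": 50.0 / math.sqrt(2.0),        # 35.355...
    "mean_right_iti": 450.0,                     # right taps 200/650
    "sd_right_iti": math.nan,                    # single right interval
    "iti_range": 100.0,
    "iti_slope": 25.0,
    "last_to_first_iti": 1.5,
    "microfluctuation_index": math.sqrt(35000.0 / 3.0 / 2.0),  # 76.376...
}


def assert_feature_equal(actual, expected, tol=1e-9):
    for name in tf.FEATURE_NAMES:
        a, e = actual[name], expected[name]
        if math.isnan(e):
            assert math.isnan(a), f"{name}: expected missing, got {a}"
        else:
            assert a == pytest.approx(e, abs=tol), name


class TestComputeIti:
    def test_all_buttons(self, worked_trial):
        assert list(tf.compute_iti(worked_trial)) == [200, 250, 200, 300]

    def test_left_button_scope(self, worked_trial):
        assert list(tf.compute_iti(worked_trial, "left_button")) == [450, 500]

    def test_single_tap_empty(self):
        assert tf.compute_iti(make_trial([100], "L")).size == 0

    def test_unknown_scope(self, worked_trial):
        with pytest.raises(ValueError, match="scope"):
            tf.compute_iti(worked_trial, "both")

    def test_length_is_taps_minus_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            trial = random_trial(rng)
            if trial.n_taps >= 2:
                assert tf.compute_iti(trial).size == trial.n_taps - 1


class TestIndividualOperations:
    def test_basic_temporal_worked(self, worked_trial):
        n, mean, sd, cv = tf.basic_temporal_features(worked_trial)
        assert n == 5
        assert mean == pytest.approx(237.5)
        assert sd == pytest.approx(47.87135, abs=1e-4)
        assert cv == pytest.approx(0.201564, abs=1e-5)

    def test_constant_itis(self):
        trial = make_trial([0, 250, 500, 750], "LRLR")
        _, mean, sd, cv = tf.basic_temporal_features(trial)
        assert (mean, sd, cv) == (250.0, 0.0, 0.0)

    def test_single_tap_missing(self):
        n, mean, sd, cv = tf.basic_temporal_features(make_trial([10], "L"))
        assert n == 1
        assert all(math.isnan(v) for v in (mean, sd, cv))

    def test_distribution_worked(self):
        g1, g2 = tf.distribution_features(np.array([200.0, 250, 200, 300]))
        assert g1 == pytest.approx(0.49338, abs=1e-4)
        assert g2 == pytest.approx(-1.37190, abs=1e-4)

    def test_symmetric_series_zero_skew(self):
        g1, _ = tf.distribution_features(np.array([200.0, 300, 200, 300]))
        assert g1 == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_missing_moments(self):
        g1, g2 = tf.distribution_features(np.array([250.0, 250, 250, 250]))
        assert math.isnan(g1) and math.isnan(g2)

    @pytest.mark.parametrize(
        "buttons,expected",
        [("LRLRL", 1.0), ("LLL", 0.0), ("LRRL", 2.0 / 3.0)],
    )
    def test_alternating_ratio(self, buttons, expected):
        t = np.arange(len(buttons)) * 100
        assert tf.alternating_tap_ratio(make_trial(t, buttons)) == pytest.approx(expected)

    def test_alternating_ratio_single_tap_missing(self):
        assert math.isnan(tf.alternating_tap_ratio(make_trial([0], "L")))

    def test_per_button_worked(self, worked_trial):
        ml, sl, mr, sr = tf.per_button_features(worked_trial)
        assert ml == pytest.approx(475.0)
        assert sl == pytest.approx(35.35534, abs=1e-4)
        assert mr == pytest.approx(450.0)
        assert math.isnan(sr)

    def test_one_button_only(self):
        ml, sl, mr, sr = tf.per_button_features(make_trial([0, 100, 250], "LLL"))
        assert not math.isnan(ml) and not math.isnan(sl)
        assert math.isnan(mr) and math.isnan(sr)

    def test_perfect_alternation_constant_iti(self):
        # constant interval c=100 under strict alternation: per-button means 2c
        trial = make_trial(np.arange(8) * 100, "LRLRLRLR")
        ml, sl, mr, sr = tf.per_button_features(trial)
        assert (ml, mr) == (200.0, 200.0)
        assert (sl, sr) == (0.0, 0.0)

    def test_consistency_drift_worked(self):
        rng_, slope, ratio, mfi = tf.consistency_drift_features(
            np.array([200.0, 250, 200, 300])
        )
        assert rng_ == 100.0
        assert slope == pytest.approx(25.0)
        assert ratio == pytest.approx(1.5)
        assert mfi == pytest.approx(76.37626, abs=1e-4)

    def test_arithmetic_progression(self):
        rng_, slope, ratio, mfi = tf.consistency_drift_features(
            np.array([200.0, 225, 250, 275])
        )
        assert mfi == 0.0
        assert slope == pytest.approx(25.0)
        assert rng_ == 75.0

    def test_constant_series(self):
        rng_, slope, ratio, mfi = tf.consistency_drift_features(np.full(5, 250.0))
        assert (rng_, slope, ratio, mfi) == (0.0, 0.0, 1.0, 0.0)

    def test_zero_first_interval_ratio_missing(self):
        *_, ratio, _ = tf.consistency_drift_features(np.array([0.0, 100, 200]))
        assert math.isnan(ratio)


class TestExtractTrialFeatures:
    def test_worked_trial_all_fields(self, worked_trial):
        feats = tf.extract_trial_features(worked_trial)
        assert set(feats) == set(tf.FEATURE_NAMES)
        assert_feature_equal(feats, WORKED_EXPECTED)

    def test_single_tap_trial(self):
        feats = tf.extract_trial_features(make_trial([4000], "L"))
        assert feats["n_taps"] == 1
        assert sum(math.isnan(v) for v in feats.values()) == 14

    def test_invalid_trial_rejected_with_reason(self):
        with pytest.raises(InvalidTrialError, match="out-of-window"):
            tf.extract_trial_features(make_trial([0, 12_000], "LR"))

    def test_matches_composition_of_operations(self, worked_trial):
        feats = tf.extract_trial_features(worked_trial)
        n, mean, sd, cv = tf.basic_temporal_features(worked_trial)
        assert (feats["n_taps"], feats["mean_iti"]) == (n, mean)
        assert feats["sd_iti"] == pytest.approx(sd, rel=1e-12)
        assert feats["cv_iti"] == pytest.approx(cv, rel=1e-12)
        iti = tf.compute_iti(worked_trial)
        assert (feats["skewness_iti"], feats["kurtosis_iti"]) == pytest.approx(
            tf.distribution_features(iti), rel=1e-12
        )
        assert feats["alternating_tap_ratio"] == tf.alternating_tap_ratio(worked_trial)
        assert tuple(
            feats[k] for k in ("iti_range", "iti_slope", "last_to_first_iti",
                               "microfluctuation_index")
        ) == pytest.approx(tf.consistency_drift_features(iti))


class TestInvariances:
    @given(st.integers(0, 5000))
    def test_time_shift_leaves_features_unchanged(self, shift):
        t = np.array([0, 200, 450, 650, 950]) + shift
        feats = tf._feature_vector(t.astype(float), np.array([0, 1, 0, 1, 0], bool))
        base = tf._feature_vector(
            np.array([0.0, 200, 450, 650, 950]), np.array([0, 1, 0, 1, 0], bool)
        )
        np.testing.assert_allclose(feats, base, rtol=1e-12, equal_nan=True)

    @given(st.floats(0.1, 5.0))
    def test_time_scaling(self, c):
        t = np.array([0.0, 200, 450, 650, 950])
        b = np.array([0, 1, 0, 1, 0], bool)
        base = tf._feature_vector(t, b)
        scaled = tf._feature_vector(t * c, b)
        names = list(tf.FEATURE_NAMES)
        ms_scale = [names.index(k) for k in
                    ("mean_iti", "sd_iti", "mean_left_iti", "sd_left_iti",
                     "mean_right_iti", "iti_range", "iti_slope",
                     "microfluctuation_index")]
        unchanged = [names.index(k) for k in
                     ("n_taps", "cv_iti", "skewness_iti", "kurtosis_iti",
                      "alternating_tap_ratio", "last_to_first_iti")]
        np.testing.assert_allclose(scaled[ms_scale], base[ms_scale] * c,
                                   rtol=1e-9, equal_nan=True)
        np.testing.assert_allclose(scaled[unchanged], base[unchanged],
                                   rtol=1e-9, equal_nan=True)

    def test_random_trials_match_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            trial = random_trial(rng)
            got = tf._feature_vector(
                np.asarray(trial.t_ms, float), trial.buttons == "R"
            )
            want = oracles.feature_dict(trial.t_ms.tolist(), list(trial.buttons))
            for name, g in zip(tf.FEATURE_NAMES, got):
                w = want[name]
                if math.isnan(w):
                    assert math.isnan(g), name
                else:
                    assert abs(g - w) <= 1e-10 + 1e-10 * abs(w), name


def _trial_feature_frame():
    rows = [
        ("P1", 1, "L", [0, 200, 400], "LRL"),
        ("P1", 1, "R", [0, 300, 600], "LRL"),
        ("P1", 2, "L", [0, 400, 800], "LRL"),
        ("P2", 1, "R", [0, 100, 250], "LRL"),
    ]
    trials = [make_trial(t, b, pid=p, session=s, hand=h) for p, s, h, t, b in rows]
    return tf.features_table(trials)


class TestAggregation:
    def test_single_trial_passthrough(self):
        feats = _trial_feature_frame()
        agg = tf.aggregate_participant(feats[feats.participant_id == "P2"], "all")
        assert agg.loc["P2", "mean_iti"] == pytest.approx(125.0)

    def test_mean_of_two_trials(self):
        feats = _trial_feature_frame()
        agg = tf.aggregate_participant(feats, "left")
        # P1 left-hand trials have mean ITIs 200 and 400
        assert agg.loc["P1", "mean_iti"] == pytest.approx(300.0)

    def test_no_in_stratum_trials_gives_missing_row(self):
        feats = _trial_feature_frame()
        agg = tf.aggregate_participant(feats, "left")
        assert agg.loc["P2"].isna().all()

    def test_dominance_mapping_and_exclusions(self):
        feats = _trial_feature_frame()
        handedness = pd.Series(
            {"P1": "right", "P2": "ambidextrous"}, name="handedness"
        )
        dom = tf.aggregate_participant(feats, "dominant", handedness=handedness)
        assert list(dom.index) == ["P1"]  # ambidextrous excluded
        # P1 is right-handed: dominant = the right-hand trial (mean ITI 300)
        assert dom.loc["P1", "mean_iti"] == pytest.approx(300.0)
        nondom = tf.aggregate_participant(feats, "nondominant", handedness=handedness)
        assert nondom.loc["P1", "mean_iti"] == pytest.approx(300.0)  # L trials: 200, 400

    def test_unknown_stratum(self):
        with pytest.raises(ValueError, match="stratum"):
            tf.aggregate_participant(_trial_feature_frame(), "upper")


class TestStandardize:
    def test_simple_column(self):
        z = tf.standardize_columns(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        np.testing.assert_allclose(z["a"], [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(5, 2, size=(40, 3)), columns=list("abc"))
        df.iloc[2, 0] = np.nan
        z = tf.standardize_columns(df)
        assert abs(z["a"].mean()) < 1e-10 and abs(z["a"].std(ddof=1) - 1) < 1e-10
        assert np.isnan(z.iloc[2, 0])

    def test_constant_column_error_names_column(self):
        with pytest.raises(ZeroVarianceError, match="flat"):
            tf.standardize_columns(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            tf.standardize_columns(pd.DataFrame({"a": [1.0, np.nan]}))
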