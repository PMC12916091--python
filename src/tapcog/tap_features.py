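"""The 15 per-trial inter-tap-interval (ITI) features and their aggregation.

Feature conventions
-------------------
* SD-type features (``sd_iti``, per-button SDs, the Microfluctuation Index)
  use the n-1 (sample) denominator.
* Skewness and excess kurtosis use population moments,
  ``g1 = m3 / m2**1.5`` and ``g2 = m4 / m2**2 - 3``, with no small-sample
  bias correction; a zero-variance series leaves them missing (0/0).
* Per-button "ITI" means intervals between successive taps **on the same
  button** (the within-finger tapping period).  Under perfect alternation
  at constant interval ``c`` both per-button means are ``2c``.
* ``iti_slope`` is the ordinary-least-squares slope of ITI against the
  0-based interval index (not wall-clock time), so pauses do not stretch
  the regressor; a time-based slope is available via ``slope_on_time``.
* ``last_to_first_iti`` is missing when the first interval is 0 ms.
* Insufficient data makes the individual feature missing (NaN), never the
  whole record; a valid 1-tap trial yields ``n_taps = 1`` and 14 NaNs.

Participant aggregation averages each feature over the participant's valid
in-stratum trials, pairwise over non-missing values, then z-standardizes
columns with the n-1 SD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tap_io import Trial, TrialValidity, validate_trial

#: Stable column order of the 15 features.
FEATURE_NAMES = (
    "n_taps",
    "mean_iti",
    "sd_iti",
    "cv_iti",
    "skewness_iti",
    "kurtosis_iti",
    "alternating_tap_ratio",
    "mean_left_iti",
    "sd_left_iti",
    "mean_right_iti",
    "sd_right_iti",
    "iti_range",
    "iti_slope",
    "last_to_first_iti",
    "microfluctuation_index",
)

SCOPES = ("all_buttons", "left_button", "right_button")
STRATA = ("all", "left", "right", "dominant", "nondominant")

TRIAL_KEY_COLUMNS = ("participant_id", "session_index", "hand")


class InvalidTrialError(ValueError):
    """Raised when feature extraction is asked for an invalid trial."""


class ZeroVarianceError(ValueError):
    """Raised when a column to be z-standardized has zero variance."""


def compute_iti(trial: Trial, scope: str = "all_buttons") -> np.ndarray:
    """Successive differences of the time-sorted in-scope tap timestamps.

    ``scope`` restricts the taps to one on-screen button
    (``left_button`` / ``right_button``) or uses all taps
    (``all_buttons``).  Fewer than two in-scope taps give an empty series.
    Zero differences (duplicate timestamps) are retained.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope '{scope}'; expected one of {SCOPES}")
    t = trial.t_ms
    if scope == "left_button":
        t = t[trial.buttons == "L"]
    elif scope == "right_button":
        t = t[trial.buttons == "R"]
    return np.diff(np.asarray(t, dtype=float))


def _sample_sd(x: np.ndarray) -> float:
    return float(np.sqrt(np.sum((x - x.mean()) ** 2) / (x.size - 1)))


def basic_temporal_features(trial: Trial) -> tuple[int, float, float, float]:
    """(n_taps, mean ITI, n-1 SD of ITI, CV = SD/mean) over all buttons."""
    iti = compute_iti(trial, "all_buttons")
    n_taps = trial.n_taps
    mean = float(iti.mean()) if iti.size >= 1 else np.nan
    sd = _sample_sd(iti) if iti.size >= 2 else np.nan
    cv = sd / mean if np.isfinite(sd) and mean != 0 else np.nan
    return n_taps, mean, sd, cv


def distribution_features(series: np.ndarray) -> tuple[float, float]:
    """Population-moment skewness g1 and excess kurtosis g2 of an ITI series.

    Missing when the series has fewer than 3 (skewness) / 4 (kurtosis)
    intervals or zero variance.
    """
    series = np.asarray(series, dtype=float)
    skew = kurt = np.nan
    if series.size >= 3:
        d = series - series.mean()
        m2 = float(np.mean(d**2))
        if m2 > 0:
            skew = float(np.mean(d**3)) / m2**1.5
            if series.size >= 4:
                kurt = float(np.mean(d**4)) / m2**2 - 3.0
    return skew, kurt


def alternating_tap_ratio(trial: Trial) -> float:
    """Fraction of consecutive tap pairs landing on different buttons."""
    b = trial.buttons
    if b.size < 2:
        return np.nan
    return float(np.mean(b[1:] != b[:-1]))


def per_button_features(trial: Trial) -> tuple[float, float, float, float]:
    """(mean_left, sd_left, mean_right, sd_right) of the within-button ITIs.

    The mean needs >= 2 same-button taps (1 interval); the SD needs >= 3
    (2 intervals, n-1 denominator).
    """
    out = []
    for scope in ("left_button", "right_button"):
        iti = compute_iti(trial, scope)
        out.append(float(iti.mean()) if iti.size >= 1 else np.nan)
        out.append(_sample_sd(iti) if iti.size >= 2 else np.nan)
    return tuple(out)  # type: ignore[return-value]


def _ols_slope(y: np.ndarray, x: np.ndarray) -> float:
    xd = x - x.mean()
    denom = float(np.sum(xd**2))
    if denom == 0:
        return np.nan
    return float(np.sum(xd * (y - y.mean())) / denom)


def consistency_drift_features(
    series: np.ndarray,
) -> tuple[float, float, float, float]:
    """(range, slope vs interval index, last/first ratio, Microfluctuation Index).

    * range = max - min (>= 1 interval)
    * slope = OLS slope of ITI on the 0-based interval index (>= 2 intervals)
    * last_to_first = last / first, missing when the first interval is 0
    * MFI = n-1 SD of first differences of the series (>= 3 intervals)
    """
    series = np.asarray(series, dtype=float)
    rng = slope = ratio = mfi = np.nan
    if series.size >= 1:
        rng = float(series.max() - series.min())
        if series[0] > 0:
            ratio = float(series[-1] / series[0])
    if series.size >= 2:
        slope = _ols_slope(series, np.arange(series.size, dtype=float))
    if series.size >= 3:
        mfi = _sample_sd(np.diff(series))
    return rng, slope, ratio, mfi


def slope_on_time(trial: Trial) -> float:
    """Alternative drift: OLS slope of ITI against the wall-clock time of the
    interval's closing tap (ms of ITI per ms of elapsed time)."""
    iti = compute_iti(trial, "all_buttons")
    if iti.size < 2:
        return np.nan
    return _ols_slope(iti, np.asarray(trial.t_ms[1:], dtype=float))


def extract_trial_features(trial: Trial) -> dict[str, float]:
    """All 15 features of one valid trial, in :data:`FEATURE_NAMES` order.

    Raises :class:`InvalidTrialError` (carrying the validity reason) for
    invalid trials — they produce no feature record.
    """
    validity: TrialValidity = validate_trial(trial)
    if not validity.valid:
        raise InvalidTrialError(f"invalid trial {trial.key}: {validity.reason}")
    vec = _feature_vector(np.asarray(trial.t_ms, dtype=float), trial.buttons == "R")
    return dict(zip(FEATURE_NAMES, vec))


def _feature_vector(t: np.ndarray, is_right: np.ndarray) -> np.ndarray:
    """Fast path: the 15-vector from sorted timestamps + right-button mask.

    Mathematically identical to composing the public per-feature
    operations; kept inline because repeated-simulation calibration runs
    it millions of times.
    """
    # Plain-Python accumulation: the trials are ~30 taps long, where
    # per-call numpy overhead dominates actual arithmetic.
    tl = t.tolist() if isinstance(t, np.ndarray) else list(t)
    bl = is_right.tolist() if isinstance(is_right, np.ndarray) else list(is_right)
    out = [np.nan] * len(FEATURE_NAMES)
    n = len(tl)
    out[0] = float(n)
    if n < 2:
        return np.asarray(out)
    iti = [tl[i + 1] - tl[i] for i in range(n - 1)]
    k = n - 1
    m = sum(iti) / k
    out[1] = m
    ss = s3 = s4 = sjd = sd_sum = 0.0
    mn = mx = iti[0]
    for j, v in enumerate(iti):
        d = v - m
        d2 = d * d
        ss += d2
        s3 += d2 * d
        s4 += d2 * d2
        sd_sum += d
        sjd += j * d
        if v < mn:
            mn = v
        elif v > mx:
            mx = v
    if k >= 2:
        sd = (ss / (k - 1)) ** 0.5
        out[2] = sd
        if m != 0:
            out[3] = sd / m
        if k >= 3 and ss > 0:
            m2 = ss / k
            out[4] = (s3 / k) / m2**1.5
            if k >= 4:
                out[5] = (s4 / k) / m2**2 - 3.0
    alt = 0
    for i in range(1, n):
        if bl[i] != bl[i - 1]:
            alt += 1
    out[6] = alt / (n - 1)
    for slot, side in ((7, False), (9, True)):
        prev = None
        ivals = []
        for ti, bi in zip(tl, bl):
            if bi == side:
                if prev is not None:
                    ivals.append(ti - prev)
                prev = ti
        kb = len(ivals)
        if kb >= 1:
            mb = sum(ivals) / kb
            out[slot] = mb
            if kb >= 2:
                ssb = 0.0
                for v in ivals:
                    db = v - mb
                    ssb += db * db
                out[slot + 1] = (ssb / (kb - 1)) ** 0.5
    out[11] = float(mx - mn)
    if k >= 2:
        xbar = (k - 1) / 2.0
        sxx = k * (k * k - 1) / 12.0  # sum of (j - xbar)^2, j = 0..k-1
        out[12] = (sjd - xbar * sd_sum) / sxx
    if iti[0] > 0:
        out[13] = iti[-1] / iti[0]
    if k >= 3:
        dmean = (iti[-1] - iti[0]) / (k - 1)  # mean of successive differences
        ssd = 0.0
        for i in range(1, k):
            dd = (iti[i] - iti[i - 1]) - dmean
            ssd += dd * dd
        out[14] = (ssd / (k - 2)) ** 0.5
    return np.asarray(out)


def features_table(trials: list[Trial]) -> pd.DataFrame:
    """One feature row per *valid* trial; invalid trials are silently skipped
    (use :func:`tapcog.tap_io.validate_trial` to enumerate reasons)."""
    rows = []
    keys = []
    for trial in trials:
        if not validate_trial(trial).valid:
            continue
        keys.append(trial.key)
        rows.append(_feature_vector(np.asarray(trial.t_ms, dtype=float), trial.buttons == "R"))
    if not rows:
        return pd.DataFrame(columns=list(TRIAL_KEY_COLUMNS) + list(FEATURE_NAMES))
    key_df = pd.DataFrame(keys, columns=list(TRIAL_KEY_COLUMNS))
    feat_df = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))
    return pd.concat([key_df, feat_df], axis=1)


def dominant_hand(handedness: pd.Series) -> pd.Series:
    """Map self-reported handedness to the dominant tapping hand.

    Right-handers -> ``R``, left-handers -> ``L``; ambidextrous and
    unknown handedness have no defined dominant hand (NaN) and are
    excluded from dominance strata.
    """
    return handedness.map({"right": "R", "left": "L"})


def aggregate_participant(
    features: pd.DataFrame,
    stratum: str = "all",
    handedness: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-participant mean of each feature over the in-stratum trials.

    Missing feature values are excluded pairwise; a participant with no
    in-stratum trial (or no non-missing value for a feature) gets NaN for
    it but keeps their row.  Dominance strata need a ``handedness``
    Series indexed by participant id.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum '{stratum}'; expected one of {STRATA}")
    participants = pd.Index(features["participant_id"].unique(), name="participant_id")

    sub = features
    if stratum == "left":
        sub = features[features["hand"] == "L"]
    elif stratum == "right":
        sub = features[features["hand"] == "R"]
    elif stratum in ("dominant", "nondominant"):
        if handedness is None:
            raise ValueError(f"stratum '{stratum}' requires a handedness series")
        dom = dominant_hand(handedness)
        trial_dom = features["participant_id"].map(dom)
        match = features["hand"] == trial_dom
        sub = features[match if stratum == "dominant" else (~match & trial_dom.notna())]
        # ambidextrous / unknown handedness: trial_dom is NaN -> excluded
        participants = pd.Index(
            dom.dropna().index.intersection(participants), name="participant_id"
        )

    agg = (
        sub.groupby("participant_id")[list(FEATURE_NAMES)]
        .mean()
        .reindex(participants)
        .sort_index()
    )
    agg.attrs["stratum"] = stratum
    return agg


def standardize_columns(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scores over non-missing rows (n-1 SD); NaNs stay NaN.

    Raises :class:`ZeroVarianceError` naming the first constant column and
    ``ValueError`` if a column has fewer than 2 non-missing values.
    """
    z = matrix.copy().astype(float)
    for col in z.columns:
        x = z[col]
        n_obs = int(x.notna().sum())
        if n_obs < 2:
            raise ValueError(f"column '{col}' has fewer than 2 non-missing values")
        sd = x.std(ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise ZeroVarianceError(f"column '{col}' has zero variance")
        z[col] = (x - x.mean()) / sd
    return z
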