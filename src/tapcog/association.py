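"""Covariate-adjusted tapping-cognition association battery.

Each model regresses a cognitive outcome (one of four domain scores or the
global score) on one z-standardized tapping feature, adjusting for the
fixed covariate set: age at tapping, sex, education (categorical,
reference = college and higher), cohort, handedness (categorical,
reference = right) and the neuropsych-to-tapping time interval in years.
Fits are ordinary least squares on complete cases; the reported ``beta``
is the feature coefficient in outcome z-units per 1 SD of the feature,
with a t-based 95% CI and two-sided p-value.

The main battery runs 15 features x 5 outcomes = 75 models and reports
both multiplicity controls side by side: a Bonferroni flag at
``alpha / 15`` within each outcome and a Benjamini-Hochberg FDR flag
across all 75 tests.

Sensitivity filters (applied to trials before participant aggregation)
mirror the study's variants: dropping trials with alternating tap ratio
below 0.80 (strict less-than), keeping only each participant's first k
sessions, and restricting to one hand or to dominant/nondominant trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .tap_features import FEATURE_NAMES, dominant_hand

OUTCOMES = ("memory", "executive", "language", "visuospatial", "global")

EDUCATION_REFERENCE = "college_plus"
HANDEDNESS_REFERENCE = "right"


class CollinearityError(ValueError):
    """Raised for a rank-deficient design; names the collinear columns."""


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    outcome: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int


@dataclass(frozen=True)
class InteractionResult:
    feature: str
    outcome: str
    beta_interaction: float
    se: float
    p: float
    n: int


def build_design(covariates: pd.DataFrame, drop_unknown_handedness: bool = False) -> pd.DataFrame:
    """Numeric covariate design (no intercept column).

    Education enters as two dummies against 'college_plus', handedness as
    three dummies against 'right' ('unknown' is its own dummy level by
    default; with ``drop_unknown_handedness`` those rows become NaN and
    fall out of complete-case fits), sex and cohort as binary indicators.
    """
    design = pd.DataFrame(index=covariates.index)
    design["age"] = covariates["age"].astype(float)
    design["sex_female"] = (covariates["sex"] == "F").astype(float)
    design["cohort_omni"] = (covariates["cohort"] == "omni").astype(float)
    for level in ("high_school", "some_college"):
        design[f"education_{level}"] = (covariates["education"] == level).astype(float)
    for level in ("left", "ambidextrous", "unknown"):
        design[f"handedness_{level}"] = (covariates["handedness"] == level).astype(float)
    design["time_interval_years"] = covariates["time_interval_years"].astype(float)
    if drop_unknown_handedness:
        design.loc[covariates["handedness"] == "unknown", :] = np.nan
        design = design.drop(columns=["handedness_unknown"])
    return design


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in np.where(diag <= tol)[0]]
        raise CollinearityError(f"design is rank deficient; collinear columns: {bad}")


def _complete_rows(*arrays) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        mask &= np.isfinite(a) if a.ndim == 1 else np.isfinite(a).all(axis=1)
    return mask


def fit_association(
    outcome, feature, covariates: pd.DataFrame | None = None,
    feature_name: str = "feature", outcome_name: str = "outcome",
) -> AssociationResult:
    """OLS of one outcome on one standardized feature plus covariates.

    ``covariates`` must already be numeric (see :func:`build_design`).
    Complete cases only; requires at least (design columns + 2) rows.
    Covariate columns constant on the complete cases (typically dummies
    of a factor level absent from this subsample) are dropped, as a
    factor fit would drop the unused level; any remaining rank
    deficiency raises :class:`CollinearityError`.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(feature, dtype=float)
    if covariates is not None:
        C = covariates.to_numpy(dtype=float)
        names = ["const", feature_name] + list(covariates.columns)
    else:
        C = np.empty((len(y), 0))
        names = ["const", feature_name]
    mask = _complete_rows(y, x, C) if C.size else _complete_rows(y, x)
    n = int(mask.sum())
    Cm = C[mask]
    if Cm.size:
        keep = Cm.std(axis=0) > 0
        Cm = Cm[:, keep]
        names = names[:2] + [nm for nm, k in zip(names[2:], keep) if k]
    X = np.column_stack([np.ones(n), x[mask], Cm])
    if n < X.shape[1] + 2:
        raise ValueError(f"too few complete rows ({n}) for {X.shape[1]} design columns")
    _check_rank(X, names)
    res = sm.OLS(y[mask], X).fit()
    ci = res.conf_int(alpha=0.05)[1]
    return AssociationResult(
        feature=feature_name,
        outcome=outcome_name,
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p=float(res.pvalues[1]),
        n=n,
    )


def fit_interaction(
    outcome, feature, cohort_indicator, covariates: pd.DataFrame,
    feature_name: str = "feature", outcome_name: str = "outcome",
) -> InteractionResult:
    """Association model plus a feature x cohort product term.

    ``covariates`` should already contain the cohort main effect
    (``cohort_omni`` from :func:`build_design`); only the product term is
    added.  Raises on single-cohort data.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(feature, dtype=float)
    coh = np.asarray(cohort_indicator, dtype=float)
    C = covariates.to_numpy(dtype=float)
    mask = _complete_rows(y, x, coh, C)
    if len(np.unique(coh[mask])) < 2:
        raise ValueError("interaction model needs data from both cohorts")
    n = int(mask.sum())
    Cm = C[mask]
    keep = Cm.std(axis=0) > 0
    Cm = Cm[:, keep]
    names = (
        ["const", feature_name]
        + [nm for nm, k in zip(covariates.columns, keep) if k]
        + ["interaction"]
    )
    X = np.column_stack([np.ones(n), x[mask], Cm, x[mask] * coh[mask]])
    if n < X.shape[1] + 2:
        raise ValueError(f"too few complete rows ({n}) for {X.shape[1]} design columns")
    _check_rank(X, names)
    res = sm.OLS(y[mask], X).fit()
    return InteractionResult(
        feature=feature_name,
        outcome=outcome_name,
        beta_interaction=float(res.params[-1]),
        se=float(res.bse[-1]),
        p=float(res.pvalues[-1]),
        n=n,
    )


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def apply_filters(
    trial_features: pd.DataFrame,
    min_alt_ratio: float | None = None,
    first_k_sessions: int | None = None,
    hand: str | None = None,
    dominance: str | None = None,
    handedness: pd.Series | None = None,
) -> pd.DataFrame:
    """Compose the sensitivity filters on a per-trial feature table.

    * ``min_alt_ratio``: drop trials with alternating tap ratio strictly
      below the threshold (trials whose ratio is undefined are kept — the
      inclusion rule never imposes performance thresholds).
    * ``first_k_sessions``: keep sessions 1..k (k >= 1).
    * ``hand``: keep trials of one hand ('L' / 'R').
    * ``dominance``: 'dominant' or 'nondominant'; needs ``handedness``
      indexed by participant id; ambidextrous/unknown are excluded.
    """
    out = trial_features
    if min_alt_ratio is not None:
        ratio = out["alternating_tap_ratio"]
        out = out[~(ratio < min_alt_ratio)]
    if first_k_sessions is not None:
        if first_k_sessions <= 0:
            raise ValueError("first_k_sessions must be >= 1")
        out = out[out["session_index"] <= first_k_sessions]
    if hand is not None:
        if hand not in ("L", "R"):
            raise ValueError("hand must be 'L' or 'R'")
        out = out[out["hand"] == hand]
    if dominance is not None:
        if dominance not in ("dominant", "nondominant"):
            raise ValueError("dominance must be 'dominant' or 'nondominant'")
        if handedness is None:
            raise ValueError("dominance filter requires a handedness series")
        dom = dominant_hand(handedness)
        trial_dom = out["participant_id"].map(dom)
        match = out["hand"] == trial_dom
        out = out[match if dominance == "dominant" else (~match & trial_dom.notna())]
    return out.copy()


def run_battery(
    feature_z: pd.DataFrame,
    domain_scores: pd.DataFrame,
    covariate_design: pd.DataFrame,
    alpha: float = 0.05,
    stratum: str = "all",
) -> pd.DataFrame:
    """Every (feature, outcome) model of one stratum, with both
    multiplicity flags.

    Inputs are aligned on their participant index.  Returns one row per
    feature x outcome with columns ``stratum, outcome, feature, beta, se,
    ci_low, ci_high, p, q, n, bonferroni_sig, fdr_sig``; the Bonferroni
    flag uses ``alpha / n_features`` within each outcome and the BH flag
    controls the FDR across the full battery.
    """
    idx = feature_z.index.intersection(domain_scores.index).intersection(
        covariate_design.index
    )
    fz, ds, cv = feature_z.loc[idx], domain_scores.loc[idx], covariate_design.loc[idx]
    rows = []
    for outcome in OUTCOMES:
        for feature in FEATURE_NAMES:
            res = fit_association(
                ds[outcome], fz[feature], cv, feature_name=feature, outcome_name=outcome
            )
            rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out.insert(0, "stratum", stratum)
    out["q"] = bh_fdr(out["p"].to_numpy())
    threshold = bonferroni_threshold(alpha, len(FEATURE_NAMES))
    out["bonferroni_sig"] = out["p"] < threshold
    out["fdr_sig"] = out["q"] < alpha
    return out[
        [
            "stratum", "outcome", "feature", "beta", "se", "ci_low", "ci_high",
            "p", "q", "n", "bonferroni_sig", "fdr_sig",
        ]
    ]
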