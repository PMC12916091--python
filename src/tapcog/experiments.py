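"""End-to-end pipeline runs and Monte-Carlo calibration experiments.

These functions wire the modules together the way the analysis is meant to
be run — simulate a cohort, extract and aggregate tapping features, build
domain scores, fit the association battery, derive the composite — and
provide the repeated-simulation checks used to calibrate the statistics:
type-I error of the battery under the null generator, confidence-interval
coverage of the association model, and the out-of-fold composite under
independence.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import association, cognition_scores, composite_score, synthetic_data, tap_features, tap_io


def _subseeds(seed: int, n: int, stream: int = 0) -> np.ndarray:
    """n reproducible sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence((int(seed), 997, int(stream)))
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64) % (2**31)


def run_cohort_analysis(
    config: synthetic_data.SimulationConfig,
    stratum: str = "all",
    min_alt_ratio: float | None = None,
    first_k_sessions: int | None = None,
    m_imputations: int = 5,
) -> dict:
    """Simulate one cohort and run the full association battery on it.

    Returns a dict with the cohort, truth, per-trial features, the
    z-standardized participant feature matrix, domain scores, covariate
    design and the battery result table.
    """
    cohort, truth = synthetic_data.generate_cohort(config)
    events = synthetic_data.simulate_events(cohort, truth)
    trials = tap_io.segment_trials(events)
    trial_feats = tap_features.features_table(trials)

    handedness = cohort.set_index("participant_id")["handedness"]
    trial_feats = association.apply_filters(
        trial_feats,
        min_alt_ratio=min_alt_ratio,
        first_k_sessions=first_k_sessions,
    )
    matrix = tap_features.aggregate_participant(trial_feats, stratum, handedness=handedness)
    feature_z = tap_features.standardize_columns(matrix)

    neuro = synthetic_data.generate_neuro_battery(cohort, truth, config)
    scores = cognition_scores.score_battery(neuro, m=m_imputations, seed=config.seed)

    cov = cohort.set_index("participant_id")
    design = association.build_design(cov)
    battery = association.run_battery(feature_z, scores, design, stratum=stratum)
    return {
        "cohort": cohort,
        "truth": truth,
        "trial_features": trial_feats,
        "feature_z": feature_z,
        "domain_scores": scores,
        "covariate_design": design,
        "battery": battery,
    }


def null_battery_pvalues(
    n_reps: int, seed: int = 0, n_participants: int = 300
) -> np.ndarray:
    """p-values of the full battery under the null generator.

    Every tapping-cognition coupling is zero, so tapping features are
    independent of the latent cognition and every one of the 75 tests per
    repetition is a true null.  Returns an (n_reps, 75) array.
    """
    base = synthetic_data.SimulationConfig(n_participants=n_participants).null()
    seeds = _subseeds(seed, n_reps, stream=1)
    out = np.empty((n_reps, len(tap_features.FEATURE_NAMES) * len(association.OUTCOMES)))
    for r in range(n_reps):
        config = dataclasses.replace(base, seed=int(seeds[r]))
        battery = run_cohort_analysis(config)["battery"]
        out[r] = battery["p"].to_numpy()
    return out


def ci_coverage(
    n_reps: int = 200,
    n: int = 300,
    beta_true: float = -0.25,
    seed: int = 0,
) -> float:
    """Coverage of the association model's 95% CI for a known coupling.

    The outcome is built directly on the standardized feature pathway,
    ``y = beta_true * x + age and sex effects + noise``, where the
    standardized truth is exactly defined, and the full covariate-adjusted
    model is refit each repetition.
    """
    covered = 0
    demo_cfg = synthetic_data.SimulationConfig(n_participants=n, seed=int(_subseeds(seed, 1, 2)[0]))
    cohort, _ = synthetic_data.generate_cohort(demo_cfg)
    design = association.build_design(cohort.set_index("participant_id"))
    age_z = (design["age"] - design["age"].mean()) / design["age"].std(ddof=1)
    seeds = _subseeds(seed, n_reps, stream=3)
    for r in range(n_reps):
        rng = np.random.default_rng(int(seeds[r]))
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (
            beta_true * x
            - 0.10 * age_z.to_numpy()
            + 0.10 * design["sex_female"].to_numpy()
            + 0.90 * rng.standard_normal(n)
        )
        res = association.fit_association(y, x, design)
        if res.ci_low <= beta_true <= res.ci_high:
            covered += 1
    return covered / n_reps


def null_composite_correlations(
    n_reps: int = 200, n: int = 300, p: int = 15, seed: int = 0
) -> np.ndarray:
    """Out-of-fold composite vs outcome correlation when they are independent.

    Features are correlated Gaussians (AR(1), rho = 0.3), the outcome an
    independent standard normal.  A degenerate composite (the LASSO
    all-zero model in every fold makes it piecewise constant) counts as
    correlation 0.  Returns one r per repetition.
    """
    rho = 0.3
    cov = rho ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    chol = np.linalg.cholesky(cov)
    seeds = _subseeds(seed, n_reps, stream=4)
    rs = np.empty(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(int(seeds[r]))
        X = rng.standard_normal((n, p)) @ chol.T
        y = rng.standard_normal(n)
        result = composite_score.nested_cv_composite(X, y, seed=int(seeds[r]))
        comp = result.composite
        if np.var(comp) <= 1e-12:
            rs[r] = 0.0
        else:
            rs[r] = float(np.corrcoef(comp, y)[0, 1])
    return rs


def composite_analysis(
    analysis: dict, outcome: str = "global", seed: int = 0
) -> dict:
    """Composite score + partial correlation for one outcome of a cohort
    analysis produced by :func:`run_cohort_analysis`."""
    cohort = analysis["cohort"].set_index("participant_id")
    return composite_score.composite_with_validation(
        analysis["feature_z"],
        analysis["domain_scores"][outcome],
        cohort[["age", "sex", "education"]],
        seed=seed,
    )
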