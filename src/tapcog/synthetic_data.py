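"""Synthetic cohort, tap-stream and neuropsychological-battery generator.

The generator emulates a community-based older-adult smartphone sub-study:
~300 participants, up to 7 bimonthly sessions, each session consisting of a
10-second left-hand and a 10-second right-hand alternating two-button
tapping trial, plus a 21-test neuropsychological battery loading on four
correlated cognitive domains.

Generative model
----------------
Each participant carries a latent global cognition ``g ~ N(0, 1)``.

* Tapping: inter-tap intervals within a segment are gamma distributed with

  ``mean  = base_mean_iti_ms * exp(coupling_mean_iti * (-g))``
  ``CV    = base_cv_iti      * exp(coupling_sd_iti  * (-g))``

  plus a within-trial linear drift of ``coupling_slope * (-g)`` ms per
  interval index.  Lower cognition (negative ``g``) therefore taps slower,
  more variably and with a stronger slowdown over the trial, and all
  couplings at zero make tapping independent of cognition (the null
  configuration used for calibration).  Button labels alternate L/R with
  an independent flip probability ``alternation_error_prob``.

* Cognition: domain latents ``d_k = L*g + sqrt(1-L^2)*eps_k`` with
  ``L = domain_loading``; each test in domain ``k`` scores ``d_k`` plus
  ``N(0, test_noise_sd^2)`` noise, mapped onto a plausible raw scale
  (timed tests are emitted in positive seconds with lower = better).
  Missingness is injected MCAR at ``missing_rate`` (optionally MAR, with
  probability increasing in age rank).

Determinism: one master seed; every stream draws from a
``numpy.random.SeedSequence`` keyed by a counter scheme —
``(seed, 0)`` for the cohort draw, ``(seed, 1, participant_index,
session_index)`` for one tapping session (left segment drawn first, then
right), ``(seed, 2)`` for the test battery and ``(seed, 3)`` for the
missingness mask — so any sub-stream is reproducible independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cognition_scores as _cs

EDUCATION_LEVELS = ("high_school", "some_college", "college_plus")
HANDEDNESS_LEVELS = ("right", "left", "ambidextrous", "unknown")

TRIAL_WINDOW_MS = 10_000


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _check_probs(name: str, probs, length: int) -> None:
    probs = np.asarray(probs, dtype=float)
    if probs.size != length or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
        raise ConfigError(f"{name} must be {length} nonnegative values summing to 1")


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Demographic defaults mirror the target population: mean age 74.7
    (SD 6.3) years, 56% female, 13.2% Omni cohort, education split
    9.9/26.5/63.6%, handedness 81.8/11.9/5/1.3% right/left/ambidextrous/
    unknown, about 7 tapping sessions per participant, and a mean 1.7
    (SD 1.2) year gap between the neuropsychological and tapping
    assessments.  Coupling defaults (0.25 SD on log mean ITI, 0.20 SD on
    log ITI dispersion, 2 ms/interval of drift per SD of cognition) give
    tapping-cognition effects on the order the association battery is
    designed to detect; set them to 0 for the null configuration.
    """

    n_participants: int = 302
    seed: int = 0
    age_mean: float = 74.7
    age_sd: float = 6.3
    frac_female: float = 0.56
    frac_omni: float = 0.132
    education_probs: tuple[float, float, float] = (0.099, 0.265, 0.636)
    handedness_probs: tuple[float, float, float, float] = (0.818, 0.119, 0.050, 0.013)
    sessions_mean: float = 7.0
    max_sessions: int = 7
    time_interval_mean: float = 1.7
    time_interval_sd: float = 1.2
    base_mean_iti_ms: float = 300.0
    base_cv_iti: float = 0.25
    min_iti_ms: int = 50
    coupling_mean_iti: float = 0.25
    coupling_sd_iti: float = 0.20
    coupling_slope: float = 2.0
    alternation_error_prob: float = 0.05
    domain_loading: float = 0.7
    test_noise_sd: float = 0.6
    missing_rate: float = 0.05
    missing_mechanism: str = "mcar"

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.sessions_mean < 1:
            raise ConfigError("sessions_mean must be >= 1")
        _check_probs("education_probs", self.education_probs, 3)
        _check_probs("handedness_probs", self.handedness_probs, 4)
        for name in ("frac_female", "frac_omni", "alternation_error_prob", "missing_rate"):
            _check_unit(name, getattr(self, name))
        if not -1.0 <= self.domain_loading <= 1.0:
            raise ConfigError("domain_loading must lie in [-1, 1]")
        if self.base_mean_iti_ms <= 0 or self.base_cv_iti < 0:
            raise ConfigError("base ITI mean must be > 0 and base CV >= 0")
        if self.min_iti_ms < 1:
            raise ConfigError("min_iti_ms must be >= 1")
        if self.missing_mechanism not in ("mcar", "mar"):
            raise ConfigError("missing_mechanism must be 'mcar' or 'mar'")

    def null(self) -> "SimulationConfig":
        """Copy of this config with every tapping-cognition coupling zeroed."""
        import dataclasses

        return dataclasses.replace(
            self, coupling_mean_iti=0.0, coupling_sd_iti=0.0, coupling_slope=0.0
        )


@dataclass
class SimulationTruth:
    """Ground truth recorded for recovery tests: the latent cognition of
    every participant, the domain latents, and the couplings actually used."""

    table: pd.DataFrame  # participant_id, participant_index, g, d_<domain>...
    couplings: dict[str, float]
    config: SimulationConfig = field(repr=False, default=None)

    def g_of(self, participant_id: str) -> float:
        return float(self.table.set_index("participant_id").loc[participant_id, "g"])


def _rng(*key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in key)))


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw the participant table and its ground truth.

    Returns one record per participant (id, age, sex, education, cohort,
    handedness, neuropsych-to-tap time interval in years, number of
    sessions >= 1) and a :class:`SimulationTruth` with the latent global
    cognition ``g`` and the four domain latents.  Deterministic in
    ``config.seed``.
    """
    n = config.n_participants
    rng = _rng(config.seed, 0)
    ids = [f"P{i:04d}" for i in range(n)]
    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = np.where(rng.random(n) < config.frac_female, "F", "M")
    cohort = np.where(rng.random(n) < config.frac_omni, "omni", "offspring")
    education = rng.choice(EDUCATION_LEVELS, size=n, p=config.education_probs)
    handedness = rng.choice(HANDEDNESS_LEVELS, size=n, p=config.handedness_probs)
    time_interval = np.abs(rng.normal(config.time_interval_mean, config.time_interval_sd, n))
    n_sessions = 1 + rng.poisson(config.sessions_mean - 1.0, n)
    n_sessions = np.minimum(n_sessions, config.max_sessions)
    g = rng.standard_normal(n)

    load = config.domain_loading
    resid = math.sqrt(max(0.0, 1.0 - load**2))
    truth_cols = {"participant_id": ids, "participant_index": np.arange(n), "g": g}
    for domain in _cs.DOMAINS:
        truth_cols[f"d_{domain}"] = load * g + resid * rng.standard_normal(n)

    cohort_df = pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "sex": sex,
            "education": education,
            "cohort": cohort,
            "handedness": handedness,
            "time_interval_years": time_interval,
            "n_sessions": n_sessions.astype(np.int64),
        }
    )
    truth = SimulationTruth(
        table=pd.DataFrame(truth_cols),
        couplings={
            "coupling_mean_iti": config.coupling_mean_iti,
            "coupling_sd_iti": config.coupling_sd_iti,
            "coupling_slope": config.coupling_slope,
        },
        config=config,
    )
    return cohort_df, truth


def _simulate_segment(
    rng: np.random.Generator, config: SimulationConfig, neg_g: float
) -> tuple[np.ndarray, np.ndarray]:
    """One 10-s segment: (timestamps ms, button codes 0=L/1=R)."""
    mean = config.base_mean_iti_ms * math.exp(config.coupling_mean_iti * neg_g)
    cv = config.base_cv_iti * math.exp(config.coupling_sd_iti * neg_g)
    drift = config.coupling_slope * neg_g

    # Enough intervals to cover the window even if every draw clamps to
    # the minimum tapping period.
    m0 = TRIAL_WINDOW_MS // config.min_iti_ms + 2
    if cv > 0:
        raw = rng.gamma(1.0 / cv**2, mean * cv**2, m0)
    else:
        raw = np.full(m0, mean)
    raw = raw + drift * np.arange(m0)
    iti = np.maximum(np.rint(raw).astype(np.int64), config.min_iti_ms)
    t = np.cumsum(iti)
    t = t[t <= TRIAL_WINDOW_MS]
    n_taps = t.size

    start = int(rng.integers(0, 2))
    flips = rng.random(max(n_taps, 1)) < config.alternation_error_prob
    steps = (~flips[1:n_taps]).astype(np.int64)
    codes = (start + np.concatenate([[0], np.cumsum(steps)])) % 2
    return t, codes[:n_taps]


def _participant_index(participant_record, truth: SimulationTruth) -> int:
    if "participant_index" in participant_record:
        return int(participant_record["participant_index"])
    pid = str(participant_record["participant_id"])
    return int(truth.table.set_index("participant_id").loc[pid, "participant_index"])


def generate_tap_stream(
    participant_record, session_index: int, truth: SimulationTruth, seed: int
) -> pd.DataFrame:
    """Tap events of one session: a left-hand then a right-hand 10-s segment.

    Timestamps are integer milliseconds from segment start, strictly
    increasing within a segment and <= 10000 ms.  Interval draws are
    rounded to the millisecond and floored at ``config.min_iti_ms`` (a
    physiological minimum tapping period that also keeps the drift term
    from collapsing intervals to zero), which breaks any tie.
    """
    config = truth.config
    pid = str(participant_record["participant_id"])
    pidx = _participant_index(participant_record, truth)
    g = truth.g_of(pid) if "g" not in participant_record else float(participant_record["g"])

    frames = []
    rng = _rng(seed, 1, pidx, session_index)
    for hand in ("L", "R"):
        t, codes = _simulate_segment(rng, config, -g)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "session_index": int(session_index),
                    "hand": hand,
                    "button": np.where(codes == 0, "L", "R"),
                    "t_ms": t,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trials(cohort: pd.DataFrame, truth: SimulationTruth) -> list:
    """All trials of a cohort as :class:`tapcog.tap_io.Trial` objects.

    Equivalent to segmenting :func:`simulate_events` (same streams, same
    sub-seeds) without the event-table round trip.
    """
    from .tap_io import Trial

    config = truth.config
    seed = config.seed
    trials = []
    merged = cohort.merge(
        truth.table[["participant_id", "participant_index", "g"]], on="participant_id"
    )
    lr = np.array(["L", "R"])
    for pid, pidx, g, n_sessions in zip(
        merged["participant_id"], merged["participant_index"], merged["g"], merged["n_sessions"]
    ):
        for session in range(1, int(n_sessions) + 1):
            rng = _rng(seed, 1, pidx, session)
            for hand in ("L", "R"):
                t, codes = _simulate_segment(rng, config, -float(g))
                trials.append(
                    Trial(
                        participant_id=str(pid),
                        session_index=session,
                        hand=hand,
                        t_ms=t,
                        buttons=lr[codes],
                    )
                )
    return trials


def simulate_events(cohort: pd.DataFrame, truth: SimulationTruth) -> pd.DataFrame:
    """All tap events of a cohort (every participant, every session)."""
    trials = simulate_trials(cohort, truth)
    if not trials:
        return pd.DataFrame(
            columns=["participant_id", "session_index", "hand", "button", "t_ms"]
        )
    counts = [tr.n_taps for tr in trials]
    return pd.DataFrame(
        {
            "participant_id": np.repeat([tr.participant_id for tr in trials], counts),
            "session_index": np.repeat([tr.session_index for tr in trials], counts).astype(np.int64),
            "hand": np.repeat([tr.hand for tr in trials], counts),
            "button": np.concatenate([tr.buttons for tr in trials]),
            "t_ms": np.concatenate([tr.t_ms for tr in trials]).astype(np.int64),
        }
    )


def generate_neuro_battery(
    cohort: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig | None = None,
    specs=None,
) -> pd.DataFrame:
    """The 21-test battery plus covariate columns for a generated cohort.

    Test ``t`` in domain ``k`` scores ``d_k + N(0, test_noise_sd^2)``
    mapped to the test's raw scale; the three timed tests come out in
    positive seconds with lower = better, the Hooper on a positive scale
    with higher = better.  Missing cells are NaN.
    """
    if config is None:
        config = truth.config
    if len(cohort) == 0:
        raise ConfigError("cohort is empty")
    _check_unit("missing_rate", config.missing_rate)
    if specs is None:
        specs = _cs.default_test_specs()

    rng = _rng(config.seed, 2)
    n = len(cohort)
    latents = truth.table.set_index("participant_id").loc[cohort["participant_id"]]
    table = pd.DataFrame({"participant_id": cohort["participant_id"].to_numpy()})
    for spec in specs:
        latent = latents[f"d_{spec.domain}"].to_numpy() + config.test_noise_sd * rng.standard_normal(n)
        if spec.log_transform and not spec.higher_is_better:
            raw = np.exp(math.log(40.0) - 0.25 * latent)  # timed, seconds
        elif spec.log_transform:
            raw = np.exp(math.log(25.0) + 0.10 * latent)  # positive scale, higher better
        else:
            raw = 50.0 + 10.0 * latent
        table[spec.name] = raw

    mrng = _rng(config.seed, 3)
    if config.missing_rate > 0:
        if config.missing_mechanism == "mar":
            ranks = cohort["age"].rank(method="first").to_numpy()
            p = np.clip(config.missing_rate * 2.0 * ranks / (n + 1), 0.0, 1.0)
        else:
            p = np.full(n, config.missing_rate)
        for spec in specs:
            mask = mrng.random(n) < p
            table.loc[mask, spec.name] = np.nan

    covs = cohort[
        ["participant_id", "age", "sex", "education", "cohort", "handedness", "time_interval_years"]
    ]
    return table.merge(covs, on="participant_id")


def write_dataset(outdir, config: SimulationConfig) -> dict[str, Path]:
    """Generate a full dataset and write cohort/events/neuro/truth CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort, truth = generate_cohort(config)
    events = simulate_events(cohort, truth)
    paths = {
        "cohort": outdir / "cohort.csv",
        "events": outdir / "events.csv",
        "truth": outdir / "truth.csv",
    }
    cohort.to_csv(paths["cohort"], index=False)
    events.to_csv(paths["events"], index=False)
    truth.table.to_csv(paths["truth"], index=False)
    if len(cohort):
        neuro = generate_neuro_battery(cohort, truth, config)
        paths["neuro"] = outdir / "neuro.csv"
        neuro.to_csv(paths["neuro"], index=False)
    return paths
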