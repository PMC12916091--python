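"""Reading, segmenting and validating raw tap-event logs.

A tap-event log is a comma-separated UTF-8 file with a mandatory header::

    participant_id,session_index,hand,button,t_ms

``hand`` is the hand performing the 10-second segment and ``button`` the
on-screen button that was hit, both coded ``L``/``R``.  ``t_ms`` is the
integer millisecond timestamp relative to the start of the segment, so a
well-formed trial lives inside the closed window ``[0, 10000]`` ms.

A *trial* is one 10-second single-hand segment, keyed by
``(participant_id, session_index, hand)``.  A trial is valid when it
contains at least one tap event and all timestamps fall inside the
10-second window; no performance-based thresholds (minimum tap counts,
alternation quality, ...) are applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("participant_id", "session_index", "hand", "button", "t_ms")

#: Duration of one single-hand trial; timestamps must lie in [0, TRIAL_WINDOW_MS].
TRIAL_WINDOW_MS = 10_000

_HANDS = frozenset({"L", "R"})


@dataclass
class ParseReport:
    """Per-file ingest report: one issue line per dropped row."""

    n_rows: int = 0
    n_dropped: int = 0
    issues: list[str] = field(default_factory=list)

    def add(self, row: int, message: str) -> None:
        self.n_dropped += 1
        self.issues.append(f"row {row}: {message}")


@dataclass
class Trial:
    """One 10-second single-hand tapping segment.

    ``t_ms`` is sorted ascending (ties keep input order) and ``buttons``
    is aligned with it.
    """

    participant_id: str
    session_index: int
    hand: str
    t_ms: np.ndarray
    buttons: np.ndarray

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, self.session_index, self.hand)

    @property
    def n_taps(self) -> int:
        return int(self.t_ms.size)


@dataclass(frozen=True)
class TrialValidity:
    valid: bool
    reason: str | None = None


def read_tap_events(path) -> tuple[pd.DataFrame, ParseReport]:
    """Parse a tap-event CSV.

    Rows with unparseable fields (non-integer ``session_index``/``t_ms``,
    hand or button outside ``{L, R}``) are dropped and counted in the
    returned :class:`ParseReport`.  Out-of-window timestamps are *not* a
    parse error; they parse fine and later invalidate their trial.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If a required column is missing (the message names the column).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise ValueError(f"tap-event file is missing required column '{col}'")

    report = ParseReport(n_rows=len(raw))
    if len(raw) == 0:
        empty = pd.DataFrame(
            {
                "participant_id": pd.Series(dtype=str),
                "session_index": pd.Series(dtype=np.int64),
                "hand": pd.Series(dtype=str),
                "button": pd.Series(dtype=str),
                "t_ms": pd.Series(dtype=np.int64),
            }
        )
        return empty, report

    session = pd.to_numeric(raw["session_index"], errors="coerce")
    t_ms = pd.to_numeric(raw["t_ms"], errors="coerce")

    ok = np.ones(len(raw), dtype=bool)
    for i in range(len(raw)):
        if not np.isfinite(session.iloc[i]) or session.iloc[i] != int(session.iloc[i]):
            report.add(i, f"session_index '{raw['session_index'].iloc[i]}' is not an integer")
            ok[i] = False
        elif session.iloc[i] < 1:
            report.add(i, f"session_index {int(session.iloc[i])} is not >= 1")
            ok[i] = False
        elif not np.isfinite(t_ms.iloc[i]) or t_ms.iloc[i] != int(t_ms.iloc[i]):
            report.add(i, f"t_ms '{raw['t_ms'].iloc[i]}' is not an integer")
            ok[i] = False
        elif raw["hand"].iloc[i] not in _HANDS:
            report.add(i, f"hand '{raw['hand'].iloc[i]}' is not L or R")
            ok[i] = False
        elif raw["button"].iloc[i] not in _HANDS:
            report.add(i, f"button '{raw['button'].iloc[i]}' is not L or R")
            ok[i] = False

    events = pd.DataFrame(
        {
            "participant_id": raw.loc[ok, "participant_id"].astype(str),
            "session_index": session[ok].astype(np.int64),
            "hand": raw.loc[ok, "hand"],
            "button": raw.loc[ok, "button"],
            "t_ms": t_ms[ok].astype(np.int64),
        }
    ).reset_index(drop=True)
    return events, report


def write_tap_events(events: pd.DataFrame, path) -> None:
    """Write an event table in the tap-event CSV dialect (lossless round trip)."""
    events.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, index=False)


def segment_trials(events: pd.DataFrame) -> list[Trial]:
    """Split an event table into trials, one per (participant, session, hand).

    Events are sorted by timestamp within a trial with ties kept in input
    order (stable sort).  Every input event lands in exactly one trial; a
    session may contribute 0, 1 or 2 trials depending on which hands appear.
    Duplicate rows (including duplicate timestamps) are retained; their
    zero inter-tap intervals are handled downstream.
    """
    trials: list[Trial] = []
    if len(events) == 0:
        return trials
    for (pid, session, hand), grp in events.groupby(
        ["participant_id", "session_index", "hand"], sort=True
    ):
        order = np.argsort(grp["t_ms"].to_numpy(), kind="stable")
        trials.append(
            Trial(
                participant_id=str(pid),
                session_index=int(session),
                hand=str(hand),
                t_ms=grp["t_ms"].to_numpy()[order],
                buttons=grp["button"].to_numpy()[order],
            )
        )
    return trials


def validate_trial(trial: Trial) -> TrialValidity:
    """Apply the inclusion rule: >= 1 tap event, all timestamps in-window.

    Out-of-window timestamps invalidate the whole trial (they are never
    clamped): a tap outside [0, 10000] ms indicates a logging fault.
    """
    if trial.n_taps == 0:
        return TrialValidity(False, "empty")
    if (trial.t_ms < 0).any() or (trial.t_ms > TRIAL_WINDOW_MS).any():
        return TrialValidity(False, "out-of-window")
    return TrialValidity(True, None)
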