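import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tapcog.tap_io import Trial

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_trial(t_ms, buttons, pid="P0001", session=1, hand="L") -> Trial:
    return Trial(
        participant_id=pid,
        session_index=session,
        hand=hand,
        t_ms=np.asarray(t_ms, dtype=np.int64),
        buttons=np.asarray(list(buttons), dtype=object),
    )


@pytest.fixture
def worked_trial() -> Trial:
    """Taps at 0/200/450/650/950 ms, buttons L,R,L,R,L."""
    return make_trial([0, 200, 450, 650, 950], "LRLRL")


def random_trial(rng: np.random.Generator) -> Trial:
    """A random valid trial covering the awkward cases: 1-tap trials,
    duplicate timestamps, single-button trials, zero first intervals."""
    n = int(rng.integers(1, 60))
    t = np.sort(rng.integers(0, 10_001, size=n))
    if n > 2 and rng.random() < 0.3:  # force duplicate timestamps
        t[1] = t[0]
    if rng.random() < 0.15:
        buttons = np.full(n, rng.choice(["L", "R"]), dtype=object)
    else:
        buttons = rng.choice(["L", "R"], size=n).astype(object)
    return make_trial(t, buttons)
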