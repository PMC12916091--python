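"""Independently coded brute-force oracles used by the test suite.

Everything here is written directly from the feature definitions using
plain Python loops and ``math``/``statistics`` primitives, deliberately
avoiding the package's implementation and numpy vector paths.
"""

from __future__ import annotations

import math


def _mean(xs):
    return math.fsum(xs) / len(xs)


def _sample_sd(xs):
    if len(xs) < 2:
        return math.nan
    m = _mean(xs)
    return math.sqrt(math.fsum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def iti_series(times, buttons=None, button=None):
    """Successive differences of the taps on ``button`` (or all taps)."""
    if button is not None:
        times = [t for t, b in zip(times, buttons) if b == button]
    return [times[i + 1] - times[i] for i in range(len(times) - 1)]


def feature_dict(times, buttons):
    """All 15 features of one trial, from the definitions, by brute force."""
    times = list(times)
    buttons = list(buttons)
    n = len(times)
    out = {name: math.nan for name in (
        "n_taps", "mean_iti", "sd_iti", "cv_iti", "skewness_iti", "kurtosis_iti",
        "alternating_tap_ratio", "mean_left_iti", "sd_left_iti", "mean_right_iti",
        "sd_right_iti", "iti_range", "iti_slope", "last_to_first_iti",
        "microfluctuation_index",
    )}
    out["n_taps"] = float(n)
    if n < 2:
        return out
    iti = iti_series(times)
    k = len(iti)

    out["mean_iti"] = _mean(iti)
    if k >= 2:
        out["sd_iti"] = _sample_sd(iti)
        if out["mean_iti"] != 0:
            out["cv_iti"] = out["sd_iti"] / out["mean_iti"]
        m = _mean(iti)
        m2 = math.fsum((x - m) ** 2 for x in iti) / k
        if k >= 3 and m2 > 0:
            m3 = math.fsum((x - m) ** 3 for x in iti) / k
            out["skewness_iti"] = m3 / m2 ** 1.5
            if k >= 4:
                m4 = math.fsum((x - m) ** 4 for x in iti) / k
                out["kurtosis_iti"] = m4 / m2 ** 2 - 3.0

    out["alternating_tap_ratio"] = (
        sum(1 for i in range(1, n) if buttons[i] != buttons[i - 1]) / (n - 1)
    )

    for side, prefix in (("L", "left"), ("R", "right")):
        seq = iti_series(times, buttons, side)
        if len(seq) >= 1:
            out[f"mean_{prefix}_iti"] = _mean(seq)
        if len(seq) >= 2:
            out[f"sd_{prefix}_iti"] = _sample_sd(seq)

    out["iti_range"] = float(max(iti) - min(iti))
    if k >= 2:
        xs = list(range(k))
        xbar = _mean(xs)
        ybar = _mean(iti)
        num = math.fsum((x - xbar) * (y - ybar) for x, y in zip(xs, iti))
        den = math.fsum((x - xbar) ** 2 for x in xs)
        out["iti_slope"] = num / den
    if iti[0] > 0:
        out["last_to_first_iti"] = iti[-1] / iti[0]
    if k >= 3:
        diffs = [iti[i + 1] - iti[i] for i in range(k - 1)]
        out["microfluctuation_index"] = _sample_sd(diffs)
    return out


def ols_normal_equations(X, y):
    """(X'X)^-1 X'y via explicit Gaussian elimination on small designs."""
    import numpy as np

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def bh_stepup(pvalues):
    """BH q-values by literal step-up enumeration: q_i is the smallest
    value of p_(j) * m / j over the sorted positions j at or after i."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    for rank_pos in range(m):
        q_sorted[rank_pos] = min(
            min(pvalues[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0
        )
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        q[idx] = q_sorted[rank_pos]
    return q


def residualize_then_correlate(x, y, covariates):
    """Partial correlation oracle: residualize both on [1, C], correlate."""
    import numpy as np

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = np.asarray(covariates, float)
    if C.ndim == 1:
        C = C[:, None]
    A = np.column_stack([np.ones(len(x)), C])
    bx = ols_normal_equations(A, x)
    by = ols_normal_equations(A, y)
    rx = x - A @ bx
    ry = y - A @ by
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def soft_threshold(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0
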