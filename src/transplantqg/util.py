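"""Small shared helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd


def elevation_order(values) -> list[str]:
    """Unique elevation labels, sorted numerically when possible.

    Elevation labels like ``"500"``/``"1000"`` sort lexicographically in the
    wrong order; this sorts by numeric value and falls back to string order
    for non-numeric labels.
    """
    uniq = pd.unique(pd.Series(values).astype(str))
    try:
        return sorted(uniq, key=float)
    except ValueError:
        return sorted(uniq)


def posterior_summary(draws: np.ndarray, level: float = 0.95):
    """(mean, lower, upper) equal-tailed interval along axis 0."""
    draws = np.asarray(draws, float)
    a = (1.0 - level) / 2.0
    return (
        draws.mean(axis=0),
        np.quantile(draws, a, axis=0),
        np.quantile(draws, 1.0 - a, axis=0),
    )


def tail_prob_two_sided(draws: np.ndarray) -> float:
    """Two-sided posterior tail probability that a contrast differs from 0.

    Doubled one-sided empirical tail with plus-one smoothing so the result
    is never exactly 0; capped at 1.
    """
    draws = np.asarray(draws, float)
    s = draws.size
    p_low = (1 + np.sum(draws <= 0)) / (s + 1)
    p_high = (1 + np.sum(draws >= 0)) / (s + 1)
    return float(min(1.0, 2.0 * min(p_low, p_high)))
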