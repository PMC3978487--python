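"""Independent brute-force oracles for survival statistics.

Deliberately naive: plain Python loops over sorted event times, written
directly from the textbook definitions, sharing no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def km_oracle(times, events) -> list[tuple[float, float]]:
    """Product-limit estimate by direct enumeration: [(event_time, S(t))]."""
    times = [float(t) for t in times]
    events = [int(e) for e in events]
    out = []
    s = 1.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        n_at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oracle(times, events, is_high) -> tuple[float, float]:
    """Two-group log-rank by direct O/E/V tabulation at each event time."""
    from scipy.stats import chi2 as chi2_dist

    times = [float(t) for t in times]
    events = [int(e) for e in events]
    is_high = [bool(h) for h in is_high]
    o_minus_e = 0.0
    v = 0.0
    for t in sorted({t for t, e in zip(times, events) if e == 1}):
        risk = [i for i, ti in enumerate(times) if ti >= t]
        n = len(risk)
        n1 = sum(1 for i in risk if is_high[i])
        dead = [i for i, (ti, ei) in enumerate(zip(times, events)) if ti == t and ei == 1]
        d = len(dead)
        o1 = sum(1 for i in dead if is_high[i])
        o_minus_e += o1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / v
    return chi2, float(chi2_dist.sf(chi2, 1))


def random_small_cohort(rng: np.random.Generator, n_max: int = 12) -> pd.DataFrame:
    """Random two-group cohort with ties, both groups non-empty, >= 1 event."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        time = rng.integers(1, 7, size=n).astype(float)  # integer times force ties
        event = (rng.random(n) < 0.7).astype(float)
        high = rng.random(n) < 0.5
        if event.sum() >= 1 and high.any() and (~high).any():
            return pd.DataFrame(
                {
                    "time": time,
                    "event": event,
                    "group": np.where(high, "high", "low"),
                    "dataset_id": "d1",
                }
            )
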