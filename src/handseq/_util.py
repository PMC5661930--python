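"""Deterministic numeric helpers shared across modules.

Rounding here is display rounding: analysis code keeps unrounded floats and
rounds only where a value is printed or exported.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Sequence


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed clinical tables).

    Python's builtin ``round`` uses banker's rounding, which would turn
    e.g. 54.45 into 54.4.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(part: float, whole: float, ndigits: int = 1) -> float | None:
    """Percentage of ``part`` in ``whole`` rounded half-up; None when whole == 0."""
    if whole == 0:
        return None
    return round_half_up(100.0 * part / whole, ndigits)


def apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of an integer ``total`` across ``weights``.

    Deterministic: remainder ties are broken by position. The result sums to
    ``total`` exactly and every part is >= 0.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    w = [float(x) for x in weights]
    if any(x < 0 for x in w):
        raise ValueError("weights must be >= 0")
    s = sum(w)
    if s == 0:
        out = [0] * len(w)
        for i in range(total):
            out[i % len(w)] += 1
        return out
    quotas = [total * x / s for x in w]
    out = [int(q) for q in quotas]
    short = total - sum(out)
    order = sorted(range(len(w)), key=lambda i: (-(quotas[i] - out[i]), i))
    for i in order[:short]:
        out[i] += 1
    return out


def proportional_schedule(counts: dict[Hashable, int]) -> list:
    """Interleave labels proportionally to their counts (Bresenham scheduling).

    Emits each label exactly ``counts[label]`` times, spread as evenly as the
    integer counts allow, deterministically. Used to lay out categorical
    quotas (surface types, glove flags, durations) over an event sequence
    without random draws.
    """
    labels = [k for k, v in counts.items() if v > 0]
    total = sum(counts[k] for k in labels)
    if total == 0:
        return []
    acc = {k: 0.0 for k in labels}
    left = dict((k, counts[k]) for k in labels)
    out = []
    for _ in range(total):
        for k in labels:
            acc[k] += counts[k] / total
        k_best = max(labels, key=lambda k: (acc[k] if left[k] > 0 else float("-inf"),))
        out.append(k_best)
        acc[k_best] -= 1.0
        left[k_best] -= 1
    return out
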