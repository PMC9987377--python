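"""Independent brute-force oracles for the daily-measure operations.

Deliberately naive: explicit Python loops and sorts, no shared code with the
package implementations they check.
"""

from __future__ import annotations

import math


def oracle_sum(values) -> float:
    total = 0.0
    for v in values:
        total += v
    return total


def oracle_total_log(values) -> float:
    total = 0.0
    for v in values:
        total += math.log(v + 1.0)
    return total


def oracle_active_sedentary(values, threshold) -> tuple[int, int]:
    active = 0
    for v in values:
        if v > threshold:
            active += 1
    return active, len(values) - active


def oracle_transitions(labels) -> tuple[float, float]:
    """labels: iterable of booleans (True = active). Returns (ASTP, SATP)."""
    labels = list(labels)
    a_to_s = s_to_a = n_active = n_sed = 0
    for i in range(len(labels) - 1):
        if labels[i]:
            n_active += 1
            if not labels[i + 1]:
                a_to_s += 1
        else:
            n_sed += 1
            if labels[i + 1]:
                s_to_a += 1
    astp = a_to_s / n_active if n_active else float("nan")
    satp = s_to_a / n_sed if n_sed else float("nan")
    return astp, satp


def oracle_max_window_mean(values, window) -> float:
    best = -math.inf
    for start in range(len(values) - window + 1):
        total = 0.0
        for v in values[start : start + window]:
            total += v
        best = max(best, total / window)
    return best


def oracle_top_k_mean(values, k) -> float:
    return sum(sorted(values, reverse=True)[:k]) / k


def oracle_band_percent(values, in_band_flags, lo, hi) -> float:
    """Percent of flagged minutes whose value is in [lo, hi] (hi None = inf)."""
    denom = num = 0
    for v, flag in zip(values, in_band_flags):
        if not flag:
            continue
        denom += 1
        if v >= lo and (hi is None or v <= hi):
            num += 1
    return 100.0 * num / denom if denom else float("nan")


def oracle_percentile_linear(values, q) -> float:
    """q-th percentile with linear interpolation between order statistics."""
    xs = sorted(values)
    if not xs:
        return float("nan")
    pos = (len(xs) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return xs[lo]
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def oracle_valid_hours_actigraph(wear, missing) -> int:
    count = 0
    for h in range(24):
        ok = True
        for m in range(60 * h, 60 * h + 60):
            if missing[m] or not wear[m]:
                ok = False
                break
        if ok:
            count += 1
    return count


def oracle_valid_hours_modus(steps) -> int:
    count = 0
    for h in range(24):
        if sum(steps[60 * h : 60 * h + 60]) >= 1:
            count += 1
    return count
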