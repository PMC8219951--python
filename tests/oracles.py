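"""Independent naive reference implementations used as test oracles.

Everything here is written as plain loops straight from the definitions, on
purpose: the package's vectorized/structured implementations are checked
against these, so they must stay independent of the package internals.
"""
from __future__ import annotations

import numpy as np


def naive_local_maxima(v):
    """Interior samples strictly above the left neighbour, >= the right one."""
    out = []
    for i in range(1, len(v) - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            out.append(i)
    return out


def naive_prominence(v, i):
    """Topographic prominence: drop to the higher of the two key saddles."""
    n = len(v)
    left_min = v[i]
    j = i - 1
    while j >= 0 and v[j] <= v[i]:
        left_min = min(left_min, v[j])
        j -= 1
    right_min = v[i]
    j = i + 1
    while j < n and v[j] <= v[i]:
        right_min = min(right_min, v[j])
        j += 1
    return v[i] - max(left_min, right_min)


def naive_half_prominence_width(v, i, dt):
    """Interpolated width at half prominence, bounded by the peak's base."""
    level = v[i] - 0.5 * naive_prominence(v, i)
    # left crossing
    j = i
    while j - 1 >= 0 and v[j - 1] >= level and v[j - 1] <= v[i]:
        j -= 1
    if j - 1 >= 0 and v[j - 1] < level:
        tl = (j - 1) + (level - v[j - 1]) / (v[j] - v[j - 1])
    else:
        tl = float(j)
    # right crossing
    j = i
    n = len(v)
    while j + 1 < n and v[j + 1] >= level and v[j + 1] <= v[i]:
        j += 1
    if j + 1 < n and v[j + 1] < level:
        tr = j + (v[j] - level) / (v[j] - v[j + 1])
    else:
        tr = float(j)
    return (tr - tl) * dt


def naive_median_step(v, i, half_window):
    lo = max(0, i - half_window)
    hi = min(len(v) - 1, i + half_window)
    steps = [abs(v[k + 1] - v[k]) for k in range(lo, hi)]
    return float(np.median(steps)) if steps else 0.0


def naive_detect_peak(v, dt, min_peak=100.0, min_width_ms=0.4,
                      max_neighbor_jump=0.3, neighborhood_ms=1.0, strict=False):
    """Exhaustive rule-by-rule screening; returns (index or None, fates).

    fates maps candidate index -> True (accepted) / False (rejected by any
    of the three rules, combined by OR).
    """
    half_window = max(1, int(round(neighborhood_ms * 1e-3 / dt / 2.0)))
    fates = {}
    for i in naive_local_maxima(v):
        ok = True
        if v[i] < min_peak:
            ok = False
        if naive_half_prominence_width(v, i, dt) * 1e3 < min_width_ms:
            ok = False
        jump = max(abs(v[i] - v[i - 1]), abs(v[i] - v[i + 1]))
        if not strict:
            jump -= naive_median_step(v, i, half_window)
        if jump > max_neighbor_jump:
            ok = False
        fates[i] = ok
    survivors = [i for i, ok in fates.items() if ok]
    if not survivors:
        return None, fates
    best = survivors[0]
    for i in survivors[1:]:
        if v[i] > v[best]:
            best = i
    return best, fates


def students_t_two_sided_p(t, df):
    """Two-sided p from the regularized incomplete beta, independent of
    scipy.stats.t."""
    from scipy.special import betainc

    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))
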