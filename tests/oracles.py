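"""Independent naive reimplementations of the index formulas.

Deliberately slow and direct (Python loops, textbook formulas, no shared
machinery with the package) so they can serve as oracles for the vectorised
index engine.
"""

import math

import numpy as np


def naive_mean_icp(series):
    vals = [v for v, ok in zip(series.icp, series.valid) if ok]
    return sum(vals) / len(vals) if vals else None


def naive_cpp(series):
    vals = [m - i for i, m, ok in zip(series.icp, series.map, series.valid) if ok]
    return sum(vals) / len(vals) if vals else None


def _pearson(xs, ys):
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx <= n * (1e-9 * (1 + abs(mx))) ** 2 or syy <= n * (1e-9 * (1 + abs(my))) ** 2:
        return None
    return sxy / math.sqrt(sxx * syy)


def naive_windowed_corr(x, y, valid, window_samples, step_samples, min_valid=0.75):
    rs = []
    for start in range(0, len(x) - window_samples + 1, step_samples):
        sl = slice(start, start + window_samples)
        xs = [xv for xv, ok in zip(x[sl], valid[sl]) if ok]
        ys = [yv for yv, ok in zip(y[sl], valid[sl]) if ok]
        if len(xs) < max(min_valid * window_samples, 3):
            continue
        r = _pearson(xs, ys)
        if r is not None:
            rs.append(max(-1.0, min(1.0, r)))
    return rs


def naive_prx(series, window_s=300.0, step_s=60.0):
    w = int(round(window_s / series.sample_interval_s))
    s = int(round(step_s / series.sample_interval_s))
    rs = naive_windowed_corr(series.map, series.icp, series.valid, w, s)
    return sum(rs) / len(rs) if rs else None


def naive_rap(series, window_s=240.0, step_s=60.0):
    w = int(round(window_s / series.sample_interval_s))
    s = int(round(step_s / series.sample_interval_s))
    rs = naive_windowed_corr(series.amp, series.icp, series.valid, w, s)
    return sum(rs) / len(rs) if rs else None


def naive_dicp_rectangle(series, threshold=20.0):
    """Rectangle-rule dose: each valid sample contributes dt x its excess."""
    total = 0.0
    for v, ok in zip(series.icp, series.valid):
        if ok and v > threshold:
            total += (v - threshold) * series.sample_interval_s
    return total / 3600.0


def pair_count_auc(scores, labels):
    """O(n^2) AUC: fraction of (positive, negative) pairs correctly ordered,
    ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_u(sample1, sample2):
    """Pairs with sample1 > sample2 (ties half) by direct enumeration."""
    u = 0.0
    for a in sample1:
        for b in sample2:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u
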