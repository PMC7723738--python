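"""Independent brute-force oracles used by the test suite.

Everything here is written as plain loops over Python floats, sharing
no code path with the package, so agreement between the two routes is
evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import math


def brute_median(values) -> float:
    """Sort-and-pick median; even sizes average the two central order stats."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        raise ValueError("median of empty list")
    if n % 2 == 1:
        return v[n // 2]
    return (v[n // 2 - 1] + v[n // 2]) / 2.0


def brute_baseline(samples, pre_count, sample_rate=5.0, fallback_seconds=2.0) -> float:
    if pre_count >= 1:
        return brute_median(samples[:pre_count])
    n = max(1, round(sample_rate * fallback_seconds))
    return min(float(x) for x in samples[:n])


def brute_co_estimate(samples, pre_count, mode="corrected", sample_rate=5.0):
    """Enumeration re-implementation of the 3-step CO estimator."""
    b = brute_baseline(samples, pre_count, sample_rate)
    if mode == "corrected":
        c = [float(x) - b for x in samples]
        m = max(c)
        window = [i for i, v in enumerate(c) if v >= 0.5 * m]
        value = brute_median([c[i] for i in window])
    else:
        m = max(float(x) for x in samples)
        window = [i for i, v in enumerate(samples) if float(v) >= 0.5 * m]
        value = brute_median([float(samples[i]) for i in window]) - b
    return max(0.0, value), b, window


def brute_superposition(events, t, boost, half_life) -> float:
    total = 0.0
    for when, n in events:
        if when <= t:
            total += n * boost * math.pow(2.0, -(t - when) / half_life)
    return total


def brute_awards(history, base=1, increment=1, cap=None, reset=True):
    """Run-decomposition award oracle: split the history into maximal runs
    of negatives and pay the arithmetic escalation within each run."""
    awards = []
    run = 0
    for status in history:
        if status == "negative":
            run += 1
            amount = base + (run - 1) * increment
            if cap is not None:
                amount = min(amount, cap)
            awards.append(amount)
        else:
            awards.append(0)
            if reset:
                run = 0
    return awards


def brute_total_by_runs(history, base=1, increment=1, cap=None):
    """Total tokens = sum over maximal negative runs of the capped series."""
    total = 0
    run = 0
    for status in list(history) + ["positive"]:
        if status == "negative":
            run += 1
        else:
            for k in range(1, run + 1):
                amount = base + (k - 1) * increment
                total += min(amount, cap) if cap is not None else amount
            run = 0
    return total


def brute_sens_spec(index, reference):
    """Cell-count sensitivity/specificity from paired binary sequences."""
    tp = sum(1 for i, r in zip(index, reference) if i == 1 and r == 1)
    fn = sum(1 for i, r in zip(index, reference) if i == 0 and r == 1)
    tn = sum(1 for i, r in zip(index, reference) if i == 0 and r == 0)
    fp = sum(1 for i, r in zip(index, reference) if i == 1 and r == 0)
    return tp / (tp + fn), tn / (tn + fp)


def brute_auc(scores, labels) -> float:
    """Mann-Whitney pair enumeration; ties count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_rm_corr(clusters, xs, ys):
    """ANCOVA repeated-measures correlation by explicit sums of squares."""
    groups = {}
    for c, x, y in zip(clusters, xs, ys):
        groups.setdefault(c, []).append((float(x), float(y)))
    sxx = sxy = syy = 0.0
    n = 0
    for pairs in groups.values():
        mx = sum(p[0] for p in pairs) / len(pairs)
        my = sum(p[1] for p in pairs) / len(pairs)
        for x, y in pairs:
            sxx += (x - mx) ** 2
            sxy += (x - mx) * (y - my)
            syy += (y - my) ** 2
            n += 1
    ss_reg = sxy**2 / sxx
    r = math.copysign(math.sqrt(ss_reg / syy), sxy)
    dof = n - len(groups) - 1
    ss_err = syy - ss_reg
    return r, ss_reg, ss_err, dof
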