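"""Independent brute-force oracles used to validate the pipeline.

These deliberately re-derive results from first principles (exhaustive
enumeration) and share no code with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def stable_intervals_bruteforce(times, values, band, min_span=90.0):
    """All maximal stable intervals via exhaustive pair scanning.

    Tests every index pair (i < j) for "both endpoints in band, span >=
    min_span, every reading between also in band", then merges overlapping
    qualifying pairs into maximal (start, end) intervals.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    lo, hi = band
    inb = (values >= lo) & (values <= hi)
    qual = []
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            if (inb[i] and inb[j] and times[j] - times[i] >= min_span
                    and all(inb[k] for k in range(i + 1, j))):
                qual.append((times[i], times[j]))
    qual.sort()
    merged = []
    for s, e in qual:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def status_bruteforce(times, values, min_span=90.0):
    """Case/control/excluded status re-derived from the pairwise oracle."""
    times = np.asarray(times, float)
    if len(times) < 4:
        return "excluded", None
    early = stable_intervals_bruteforce(times, values, (30.0, 89.0), min_span)
    if not early:
        return "excluded", None
    late = stable_intervals_bruteforce(times, values, (0.0, 29.0), min_span)
    if not late:
        return "control", None
    for t in times[:2]:
        if any(s <= t <= e for s, e in late):
            return "excluded", None
    return "case", late[0][0]


def average_precision_bruteforce(labels, scores):
    """AP by explicit threshold enumeration: sum of precision * recall-step."""
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = scores >= thr
        tp = int(labels[sel].sum())
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def pairwise_auroc_bruteforce(labels, scores):
    """Case-control pair concordance with ties counted one half."""
    labels = np.asarray(labels, int)
    scores = np.asarray(scores, float)
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for k in ctrls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(ctrls))


def max_matching_bruteforce(case_ids, control_ids, eligible, ratio):
    """Maximum total matches by enumerating all control-to-case maps.

    ``eligible[(case, control)]`` marks allowed pairs.  Each control maps to
    one case or none; each case takes at most ``ratio`` controls.  Only
    feasible for small pools.
    """
    best = 0
    options = []
    for ctl in control_ids:
        opts = [None] + [c for c in case_ids if eligible.get((c, ctl), False)]
        options.append(opts)
    for combo in itertools.product(*options):
        counts: dict = {}
        ok = True
        total = 0
        for c in combo:
            if c is None:
                continue
            counts[c] = counts.get(c, 0) + 1
            if counts[c] > ratio:
                ok = False
                break
            total += 1
        if ok and total > best:
            best = total
    return best


def random_egfr_series(rng, max_len=20):
    """Random series for oracle comparisons: values U(5,95), span U(0,400)."""
    n = int(rng.integers(1, max_len + 1))
    times = np.sort(rng.uniform(0.0, 400.0, size=n))
    while len(np.unique(times)) < n:
        times = np.sort(rng.uniform(0.0, 400.0, size=n))
    values = rng.uniform(5.0, 95.0, size=n)
    return times, values
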