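"""Brute-force reference implementations, independent of the package.

Every metric is recomputed here by direct enumeration of records (and, for
the C-statistic, of record pairs) so that the vectorised library code can
be checked against an implementation with no shared logic.
"""

from __future__ import annotations

import math

import numpy as np


def joint_counts(eol, cso, alerts):
    """The 8-cell (alert, eol, cso) joint table, one record at a time."""
    counts = {}
    for a, e, c in zip(alerts, eol, cso):
        key = (int(a), int(e), int(c))
        counts[key] = counts.get(key, 0) + 1
    return counts


def _effective(a, e, c, tree, strategy):
    if strategy == "usual_care":
        return c
    if strategy == "alerts_for_all":
        act = 1
    elif strategy == "alerts_for_none":
        act = 0
    else:
        act = a
    if tree == "tree2":
        act = act or c
    return act


def outcomes(eol, cso, alerts, tree, strategy):
    """(p_tp, p_fp, p_fn, p_tn) by per-record enumeration."""
    n = len(eol)
    tp = fp = fn = tn = 0
    for a, e, c in zip(alerts, eol, cso):
        act = _effective(int(a), int(e), int(c), tree, strategy)
        if act and e:
            tp += 1
        elif act and not e:
            fp += 1
        elif not act and e:
            fn += 1
        else:
            tn += 1
    return tp / n, fp / n, fn / n, tn / n


def erd(eol, cso, alerts):
    n_eol = sum(int(e) for e in eol)
    num = sum(1 for a, e, c in zip(alerts, eol, cso) if a and e and not c)
    return num / n_eol


def nnb(eol, cso, alerts):
    n_alert = sum(int(a) for a in alerts)
    newly = sum(1 for a, e, c in zip(alerts, eol, cso) if a and e and not c)
    return n_alert / newly if newly else math.nan


def observed_rate(eol, cso):
    tp = sum(1 for e, c in zip(eol, cso) if c and e)
    fp = sum(1 for e, c in zip(eol, cso) if c and not e)
    return tp / fp


def net_benefit(eol, cso, alerts, tree, strategy, rate):
    p_tp, p_fp, _, _ = outcomes(eol, cso, alerts, tree, strategy)
    return p_tp - p_fp * rate


def confusion(eol, alerts):
    """ppv, npv, sensitivity, specificity by enumeration (NaN on empty)."""
    tp = sum(1 for a, e in zip(alerts, eol) if a and e)
    fp = sum(1 for a, e in zip(alerts, eol) if a and not e)
    fn = sum(1 for a, e in zip(alerts, eol) if not a and e)
    tn = sum(1 for a, e in zip(alerts, eol) if not a and not e)

    def div(x, y):
        return x / y if y else math.nan

    return (div(tp, tp + fp), div(tn, tn + fn),
            div(tp, tp + fn), div(tn, tn + fp))


def c_pairwise(risks, eol):
    """C-statistic by all-pairs comparison (ties credited 1/2)."""
    risks = np.asarray(risks, dtype=float)
    eol = np.asarray(eol).astype(bool)
    pos = risks[eol]
    neg = risks[~eol]
    if pos.size == 0 or neg.size == 0:
        return math.nan
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
                 / (pos.size * neg.size))


def brier(risks, eol):
    return sum((float(r) - float(e)) ** 2 for r, e in zip(risks, eol)) / len(eol)


def err(eol, cso, alerts):
    n_eol = sum(int(e) for e in eol)
    aoc = sum(1 for a, e, c in zip(alerts, eol, cso) if e and (a or c))
    ce = sum(1 for e, c in zip(eol, cso) if e and c)
    if n_eol == 0 or ce == 0:
        return math.nan
    return (aoc / n_eol) / (ce / n_eol)
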