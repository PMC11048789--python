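"""Independent brute-force oracles.

Deliberately naive re-implementations (loops, exhaustive enumeration) used
to cross-check the vectorized package code.  They share no code with the
implementation.
"""

import math


def oracle_differences(rr):
    return [rr[i + 1] - rr[i] for i in range(len(rr) - 1)]


def oracle_prrx_ms(rr, x):
    deltas = oracle_differences(rr)
    hits = 0
    for d in deltas:
        if abs(d) >= x:
            hits += 1
    return 100.0 * hits / len(deltas)


def oracle_prrx_rel(rr, x):
    deltas = oracle_differences(rr)
    hits = 0
    for i, d in enumerate(deltas):
        if abs(d) >= (x / 100.0) * rr[i]:
            hits += 1
    return 100.0 * hits / len(deltas)


def oracle_symbols(deltas):
    return ["+" if d > 0 else "-" if d < 0 else "0" for d in deltas]


def oracle_runs(symbols):
    """One-pass scan splitting on symbol change; (type, length) pairs."""
    names = {"+": "DR", "-": "AR", "0": "NR"}
    runs = []
    cur, length = symbols[0], 1
    for s in symbols[1:]:
        if s == cur:
            length += 1
        else:
            runs.append((names[cur], length))
            cur, length = s, 1
    runs.append((names[cur], length))
    return runs


def oracle_run_probs(symbols):
    """p_{i,k} recomputed by counting memberships difference-by-difference."""
    runs = oracle_runs(symbols)
    membership = []  # (type, run length) of every single difference
    for k, ln in runs:
        membership.extend([(k, ln)] * ln)
    n = len(membership)
    probs = {}
    for cell in set(membership):
        probs[cell] = membership.count(cell) / n
    return probs


def oracle_entropies(symbols):
    probs = oracle_run_probs(symbols)
    out = {"H": 0.0, "AR": 0.0, "DR": 0.0, "NR": 0.0}
    for (k, _), p in probs.items():
        term = -p * math.log(p)
        out["H"] += term
        out[k] += term
    return {"H": out["H"], "HAR": out["AR"], "HDR": out["DR"], "HNR": out["NR"]}


def oracle_auc_pairwise(scores_af, scores_sr):
    """P(score_AF > score_SR) + 0.5 P(tie) over all pairs."""
    total = 0.0
    for a in scores_af:
        for s in scores_sr:
            if a > s:
                total += 1.0
            elif a == s:
                total += 0.5
    return total / (len(scores_af) * len(scores_sr))


def oracle_youden_scan(scores, is_af):
    """Best J over midpoints between adjacent distinct values plus +/-inf.

    Predicts AF when score >= threshold (AF-high orientation assumed by the
    caller).  Returns (best_j, best_sensitivity, best_threshold), ties broken
    by higher sensitivity then smaller threshold.
    """
    distinct = sorted(set(scores))
    thresholds = [float("-inf")]
    thresholds += [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    thresholds += [float("inf")]
    n_af = sum(is_af)
    n_sr = len(is_af) - n_af
    best = None
    for t in thresholds:
        tp = sum(1 for s, y in zip(scores, is_af) if y and s >= t)
        tn = sum(1 for s, y in zip(scores, is_af) if not y and s < t)
        sens, spec = tp / n_af, tn / n_sr
        key = (sens + spec - 1.0, sens, -t)
        if best is None or key > best[0]:
            best = (key, t)
    (j, sens, _), t = best
    return j, sens, t


def oracle_confusion(pred, truth):
    tp = sum(1 for p, y in zip(pred, truth) if p == "AF" and y == "AF")
    fp = sum(1 for p, y in zip(pred, truth) if p == "AF" and y == "SR")
    tn = sum(1 for p, y in zip(pred, truth) if p == "SR" and y == "SR")
    fn = sum(1 for p, y in zip(pred, truth) if p == "SR" and y == "AF")
    return tp, fp, tn, fn
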