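"""Independent reference implementations used only by the tests.

Everything here is coded directly from the defining formulas, separately
from the package's implementation, so that agreement between the two routes
is a meaningful check. Nothing in this module imports from hairpinmi.
"""

from __future__ import annotations

import math


# --- mutual-information features, direct from the definitions --------------


def direct_feature_vector(sequence: str, dotbracket: str, mfe: float,
                          epsilon: float = 1e-8) -> list[float]:
    """55-value feature vector computed straight from the formulas:
    unordered window counts, smoothed frequencies, pointwise pair MI,
    conditional MI via the two conditional entropies, 3-tuple MI as their
    difference, plus raw symbol frequencies, base-pair count and MFE."""
    return (
        _mi_block(sequence, "ACGU", epsilon)
        + _mi_block(dotbracket, "(.)", epsilon)
        + [float(dotbracket.count("("))]
        + [mfe]
    )


def _sorted_tuple(chars, order):
    return tuple(sorted(chars, key=order.index))


def _mi_block(s: str, order: str, eps: float) -> list[float]:
    L = len(s)
    n1: dict[str, int] = {c: 0 for c in order}
    n2: dict[tuple, int] = {}
    n3: dict[tuple, int] = {}
    for c in s:
        n1[c] += 1
    for i in range(L - 1):
        k = _sorted_tuple(s[i : i + 2], order)
        n2[k] = n2.get(k, 0) + 1
    for i in range(L - 2):
        k = _sorted_tuple(s[i : i + 3], order)
        n3[k] = n3.get(k, 0) + 1

    def p1(x):
        return (n1[x] + eps) / L

    def p2(x, y):
        return (n2.get(_sorted_tuple((x, y), order), 0) + eps) / (L - 1)

    def p3(x, y, z):
        return (n3.get(_sorted_tuple((x, y, z), order), 0) + eps) / (L - 2)

    def seen2(x, y):
        return n2.get(_sorted_tuple((x, y), order), 0) > 0

    def seen3(x, y, z):
        return n3.get(_sorted_tuple((x, y, z), order), 0) > 0

    # 0 log 0 = 0 convention: unobserved joint n-grams contribute nothing
    def mi2(x, y):
        if not seen2(x, y):
            return 0.0
        return p2(x, y) * math.log2(p2(x, y) / (p1(x) * p1(y)))

    def mi3(x, y, z):
        # MI(x,y,z) = MI(x,y) - [H(x|z) - H(x|y,z)]
        if seen2(x, z):
            r = p2(x, z) / p1(z)
            h_xz = -r * math.log2(r)
        else:
            h_xz = 0.0
        if seen3(x, y, z):
            r = p3(x, y, z) / p2(y, z)
            h_xyz = -r * math.log2(r)
        else:
            h_xyz = 0.0
        return mi2(x, y) - (h_xz - h_xyz)

    k = len(order)
    triples = [
        (order[a], order[b], order[c])
        for a in range(k)
        for b in range(a, k)
        for c in range(b, k)
    ]
    pairs = [(order[a], order[b]) for a in range(k) for b in range(a, k)]
    vals = [mi3(*t) for t in triples]
    vals += [mi2(*p) for p in pairs]
    vals += [n1[c] / L for c in order]
    return vals


# --- folding: exhaustive enumeration of nested structures ------------------

_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def max_pair_weight_exhaustive(s: str, min_loop: int = 3) -> int:
    """Maximum total pair weight over every valid nested structure, found by
    explicit enumeration of all non-crossing pair sets (feasible for short
    sequences)."""
    best = 0
    for pairing in enumerate_structures(s, 0, len(s) - 1, min_loop):
        w = sum(_WEIGHTS[(s[i], s[j])] for i, j in pairing)
        best = max(best, w)
    return best


def enumerate_structures(s, i, j, min_loop):
    """Yield every set of non-crossing complementary pairs on s[i..j]."""
    if j - i < min_loop + 1:
        yield []
        return
    # case: i unpaired
    yield from enumerate_structures(s, i + 1, j, min_loop)
    # case: i paired with some k
    for k in range(i + min_loop + 1, j + 1):
        if (s[i], s[k]) not in _WEIGHTS:
            continue
        for inner in enumerate_structures(s, i + 1, k - 1, min_loop):
            for outer in enumerate_structures(s, k + 1, j, min_loop):
                yield [(i, k)] + inner + outer


# --- evaluation metrics, direct formula evaluation --------------------------


def metrics_direct(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    n = tp + tn + fp + fn
    se = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    pr = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * se * pr / (se + pr) if se + pr else 0.0
    acc = (tp + tn) / n
    den = math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return {"SE": se, "SP": sp, "PR": pr, "F1": f1, "ACC": acc, "MCC": mcc}


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalised Mann-Whitney U: fraction of (positive,
    negative) pairs ranked correctly, ties counting one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))


def aupr_all_thresholds(scores, labels) -> float:
    """Area under the precision-recall curve by explicit enumeration of
    every distinct score threshold, integrated as sum (R_k - R_{k-1}) P_k."""
    n_pos = sum(labels)
    pts = []  # (recall, precision), descending threshold
    for t in sorted(set(scores), reverse=True):
        pred = [s >= t for s in scores]
        tp = sum(1 for p, l in zip(pred, labels) if p and l == 1)
        fp = sum(1 for p, l in zip(pred, labels) if p and l == 0)
        pts.append((tp / n_pos, tp / (tp + fp) if tp + fp else 1.0))
    area = 0.0
    prev_r = 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return area
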