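"""Independent brute-force reference implementations used as test oracles.

Everything here is written from the textbook definitions with plain loops,
deliberately sharing no code with the package under test.
"""

from __future__ import annotations

import math

import numpy as np


def balanced_accuracy_bruteforce(y_true, y_pred) -> float:
    """Average per-class recall, classes taken from the true labels only."""
    classes = sorted(set(int(c) for c in y_true))
    recalls = []
    for c in classes:
        idx = [i for i, t in enumerate(y_true) if t == c]
        hits = sum(1 for i in idx if y_pred[i] == c)
        recalls.append(hits / len(idx))
    return sum(recalls) / len(recalls)


def ece_bruteforce(probs, y_true, n_bins: int = 10) -> float:
    """Right-closed equal-width confidence binning, empty bins skipped."""
    probs = np.asarray(probs, dtype=float)
    n = len(y_true)
    conf = [max(row) for row in probs]
    pred = [int(np.argmax(row)) for row in probs]
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        members = [
            i
            for i in range(n)
            if (conf[i] > lo or (b == 0 and conf[i] == 0.0)) and conf[i] <= hi
        ]
        if not members:
            continue
        acc = sum(1 for i in members if pred[i] == y_true[i]) / len(members)
        avg_conf = sum(conf[i] for i in members) / len(members)
        total += len(members) / n * abs(acc - avg_conf)
    return total


def binomial_quantile_threshold_bruteforce(n: int, p: float, alpha: float) -> float:
    """Smallest k with Binomial(n, p) CDF >= 1 - alpha, by direct enumeration."""
    cdf = 0.0
    for k in range(n + 1):
        cdf += math.comb(n, k) * p**k * (1 - p) ** (n - k)
        if cdf >= 1 - alpha:
            return k / n
    return 1.0


def fleiss_kappa_bruteforce(counts) -> float:
    """Textbook fixed-panel formulation: kappa = (Pbar - Pe) / (1 - Pe)."""
    counts = np.asarray(counts, dtype=float)
    n_items, _ = counts.shape
    m = counts[0].sum()  # raters per item
    p_item = [(row @ row - m) / (m * (m - 1)) for row in counts]
    p_bar = sum(p_item) / n_items
    shares = counts.sum(axis=0) / counts.sum()
    p_e = float(shares @ shares)
    if p_e == 1.0:
        return 1.0
    return (p_bar - p_e) / (1 - p_e)


def stratified_apportionments(class_count: int, sizes: tuple[int, ...]) -> set[tuple[int, ...]]:
    """All integer allocations of one class across splits that round the
    proportional quota up or down in every split and hit the class total."""
    total = sum(sizes)
    quotas = [class_count * s / total for s in sizes]
    options = [
        sorted({math.floor(q), math.ceil(q)}) for q in quotas
    ]
    out = set()

    def rec(i, acc):
        if i == len(options):
            if sum(acc) == class_count:
                out.add(tuple(acc))
            return
        for v in options[i]:
            rec(i + 1, acc + [v])

    rec(0, [])
    return out
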