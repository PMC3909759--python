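"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the defining formula with explicit loops and
enumeration, deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def kappa_bruteforce(counts: np.ndarray) -> float:
    """Cohen's kappa via explicit marginal sums."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    p_o = sum(counts[i, i] for i in range(k)) / n
    p_e = 0.0
    for i in range(k):
        row = sum(counts[i, j] for j in range(k))
        col = sum(counts[j, i] for j in range(k))
        p_e += (row / n) * (col / n)
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def class_metrics_bruteforce(counts: np.ndarray) -> dict:
    """One-vs-rest metrics from explicitly counted TP/FP/FN/TN."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    k = counts.shape[0]
    out = {"accuracy": sum(counts[i, i] for i in range(k)) / n, "per_class": []}
    for c in range(k):
        tp = counts[c, c]
        fp = sum(counts[r, c] for r in range(k)) - tp
        fn = sum(counts[c, r] for r in range(k)) - tp
        tn = n - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        out["per_class"].append(
            {"precision": precision, "recall": recall,
             "specificity": specificity, "f_measure": f}
        )
    return out


def hypergeom_tail_enumeration(overlap: int, universe: int, successes: int,
                               draws: int) -> float:
    """P(X >= overlap) by enumerating every equally likely draw of size `draws`
    from a universe in which the first `successes` items are the set members.
    Only feasible for small universes."""
    items = range(universe)
    good = set(range(successes))
    total = 0
    favourable = 0
    for combo in itertools.combinations(items, draws):
        total += 1
        if len(good.intersection(combo)) >= overlap:
            favourable += 1
    return favourable / total


def relief_f_bruteforce(values: np.ndarray, labels: list[str], k: int) -> np.ndarray:
    """Multiclass ReliefF visiting every sample once, written longhand."""
    x = np.asarray(values, dtype=float)
    n_genes, n_samples = x.shape

    lo = np.zeros(n_genes)
    hi = np.zeros(n_genes)
    for gi in range(n_genes):
        obs = [v for v in x[gi] if not math.isnan(v)]
        lo[gi] = min(obs) if obs else 0.0
        hi[gi] = max(obs) if obs else 0.0

    def diff(gi, a, b):
        if hi[gi] == lo[gi]:
            return 0.0
        va, vb = x[gi, a], x[gi, b]
        if math.isnan(va) or math.isnan(vb):
            return 0.5
        return abs(va - vb) / (hi[gi] - lo[gi])

    def dist(a, b):
        return sum(diff(gi, a, b) for gi in range(n_genes))

    classes = sorted(set(labels))
    prior = {c: labels.count(c) / n_samples for c in classes}
    weights = np.zeros(n_genes)
    m = n_samples
    for r in range(n_samples):
        others = sorted(
            (j for j in range(n_samples) if j != r),
            key=lambda j: (dist(r, j), j),
        )
        hits = [j for j in others if labels[j] == labels[r]][:k]
        for gi in range(n_genes):
            for h in hits:
                weights[gi] -= diff(gi, r, h) / (m * k)
            for c in classes:
                if c == labels[r]:
                    continue
                misses = [j for j in others if labels[j] == c][:k]
                factor = prior[c] / (1.0 - prior[labels[r]])
                for mi in misses:
                    weights[gi] += factor * diff(gi, r, mi) / (m * k)
    return weights
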