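"""Independent brute-force reference implementations used only by tests.

Each oracle is written as directly as possible from the defining formula —
explicit loops, no shared code with the package — so agreement is evidence,
not tautology.
"""
from __future__ import annotations

import math

import numpy as np


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation of two sequences."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def softmax_direct(eta) -> list[float]:
    ex = [math.exp(v) for v in eta]
    s = sum(ex)
    return [v / s for v in ex]


def categorical_ce_direct(probs, true_idx) -> float:
    """-mean log p at the true class, probs a list of rows."""
    return -sum(math.log(row[k]) for row, k in zip(probs, true_idx)) / len(probs)


def binary_ce_direct(probs, targets) -> float:
    total = 0.0
    for p, t in zip(probs, targets):
        total += t * math.log(p) + (1 - t) * math.log(1 - p)
    return -total / len(probs)


def sensitivity_direct(X, labels, gene, ctype) -> float:
    """Sen_gk by counting cells one by one; 0 when no cell expresses the gene."""
    num = 0
    den = 0
    for c in range(X.shape[1]):
        if X[gene, c] > 0:
            den += 1
            if labels[c] == ctype:
                num += 1
    return num / den if den else 0.0


def ari_pair_counting(a, b) -> float:
    """Adjusted Rand index by explicit enumeration of all cell pairs."""
    n = len(a)
    n11 = n00 = n10 = n01 = 0
    for i in range(n):
        for j in range(i + 1, n):
            sa = a[i] == a[j]
            sb = b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif not sa and sb:
                n01 += 1
            else:
                n00 += 1
    total = n11 + n10 + n01 + n00
    expected = (n11 + n10) * (n11 + n01) / total
    max_index = 0.5 * ((n11 + n10) + (n11 + n01))
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def complete_linkage_merges(points: np.ndarray, names: list[str]):
    """O(K^3) agglomerative complete linkage on row-vector points.

    Returns the merge sequence as a list of (frozenset_left, frozenset_right,
    height) in merge order (left/right unordered by the caller's comparison).
    """
    clusters: list[frozenset] = [frozenset([nm]) for nm in names]
    members: dict[frozenset, list[int]] = {
        frozenset([nm]): [i] for i, nm in enumerate(names)
    }
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(
                    d[a, b] for a in members[clusters[i]] for b in members[clusters[j]]
                )
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        ci, cj = clusters[i], clusters[j]
        merged = ci | cj
        merges.append((ci, cj, dist))
        members[merged] = members[ci] + members[cj]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def welch_t_direct(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Per-gene Welch t-statistic, computed row by row."""
    out = np.empty(left.shape[0])
    for g in range(left.shape[0]):
        a, b = left[g], right[g]
        va, vb = a.var(ddof=1), b.var(ddof=1)
        denom = math.sqrt(va / len(a) + vb / len(b))
        out[g] = (a.mean() - b.mean()) / denom if denom > 0 else 0.0
    return out
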