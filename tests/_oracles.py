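"""Independent brute-force oracles used to validate the fast implementations.

Everything here deliberately avoids the package's own algorithms: the JT
null pmfs are obtained by raw enumeration of rank arrangements, BH by a
literal transcription of the step-up rule, and AUC by O(n^2) pairwise
comparison.
"""

from itertools import combinations, permutations

import numpy as np


def perm_jt_pmf(sizes):
    """Exact JT null pmf by enumerating all N! rank permutations.

    Within-group permutations overcount every assignment uniformly, so
    the pmf over distinct assignments is unchanged.  Feasible for
    N <= 8.
    """
    sizes = list(sizes)
    N = sum(sizes)
    group = np.repeat(np.arange(len(sizes)), sizes)
    perms = np.array(list(permutations(range(N))))
    stat = np.zeros(len(perms))
    for i in range(N):
        for j in range(N):
            if group[i] < group[j]:
                stat += perms[:, j] > perms[:, i]
    support, counts = np.unique(stat, return_counts=True)
    return support, counts / counts.sum()


def partition_jt_pmf(sizes):
    """Exact JT null pmf by enumerating ordered set partitions.

    Assigns distinct ranks to groups left to right; each block's
    contribution is its number of concordant pairs against everything
    still unassigned.  Handles moderate N (a few hundred thousand
    partitions).
    """
    sizes = list(sizes)
    N = sum(sizes)
    counts: dict[float, int] = {}

    def rec(remaining, idx, stat):
        if idx == len(sizes):
            counts[stat] = counts.get(stat, 0) + 1
            return
        for block in combinations(sorted(remaining), sizes[idx]):
            rest = remaining - set(block)
            add = sum(1 for a in block for b in rest if b > a)
            rec(rest, idx + 1, stat + add)

    rec(frozenset(range(N)), 0, 0)
    support = np.array(sorted(counts))
    pmf = np.array([counts[s] for s in support], dtype=float)
    return support, pmf / pmf.sum()


def step_up_bh(p):
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def pairwise_auc(scores, labels):
    """AUC = P(score_pos > score_neg) + 0.5 P(tie), by O(n^2) comparison.

    ``scores`` must be oriented so that larger means more positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def all_compositions(total, min_parts=2):
    """Every ordered group-size vector with the given total (parts >= 1)."""
    out = []

    def rec(left, acc):
        if left == 0:
            if len(acc) >= min_parts:
                out.append(tuple(acc))
            return
        for part in range(1, left + 1):
            rec(left - part, acc + [part])

    rec(total, [])
    return out
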