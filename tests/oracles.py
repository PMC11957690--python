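"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (integer combinatorics,
exhaustive enumeration) so it stays independent of the library code paths it
checks.
"""

from functools import lru_cache
from math import comb

import numpy as np


def fisher_tail_exact(a, b, c, d):
    """One-sided Fisher p by exact enumeration of the hypergeometric tail.

    All 2x2 tables with the margins of (a, b; c, d) are enumerated; the
    p-value is the exact rational tail P(overlap >= a), returned as float.
    """
    n = a + b + c + d
    row = a + b
    col = a + c
    lo = max(0, row + col - n)
    hi = min(row, col)
    denom = comb(n, row)
    num = sum(comb(col, k) * comb(n - col, row - k) for k in range(a, hi + 1))
    return num / denom


def hypergeom_tail_table(n, row, col):
    """Exact tail p for every achievable overlap a given fixed margins.

    Returns (support, tails): the achievable overlaps and, for each, the
    rational tail sum P(X >= a) evaluated with integer combinatorics.
    """
    lo = max(0, row + col - n)
    hi = min(row, col)
    denom = comb(n, row)
    pmf_num = [comb(col, k) * comb(n - col, row - k) for k in range(lo, hi + 1)]
    tails = []
    acc = 0
    for x in reversed(pmf_num):
        acc += x
        tails.append(acc)
    tails = [t / denom for t in reversed(tails)]
    return list(range(lo, hi + 1)), tails


def set_partitions(items):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def modularity_by_enumeration(weights, null_weights=None):
    """Max bipartite (or differential) modularity by exhaustive enumeration.

    ``Q(partition) = (1/m') sum over in-community TF-gene pairs of
    (A_ij - k_i d_j / m)`` with strengths and m from the null network
    (defaults to the scored network itself).  Returns (best_q, best_partition,
    q_of) where q_of maps a (tf_labels, gene_labels) assignment to its Q.
    """
    a = np.asarray(weights, dtype=float)
    null = a if null_weights is None else np.asarray(null_weights, dtype=float)
    n_tf, n_gene = a.shape
    k = null.sum(axis=1)
    d = null.sum(axis=0)
    m = null.sum()
    m_prime = a.sum()
    b = a - np.outer(k, d) / m

    def q_of(tf_labels, gene_labels):
        total = 0.0
        for i in range(n_tf):
            for j in range(n_gene):
                if tf_labels[i] == gene_labels[j]:
                    total += b[i, j]
        return total / m_prime

    nodes = [("tf", i) for i in range(n_tf)] + [("gene", j) for j in range(n_gene)]
    best_q, best_partition = -np.inf, None
    for partition in set_partitions(nodes):
        tf_labels = [0] * n_tf
        gene_labels = [0] * n_gene
        for ci, community in enumerate(partition):
            for ns, idx in community:
                if ns == "tf":
                    tf_labels[idx] = ci
                else:
                    gene_labels[idx] = ci
        q = q_of(tf_labels, gene_labels)
        if q > best_q:
            best_q, best_partition = q, partition
    return best_q, best_partition, q_of
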