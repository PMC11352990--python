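"""Independent brute-force oracles shared by unit and acceptance tests.

Each function here is deliberately written from the textbook definition
(loops, explicit enumeration) and never calls the implementation path it
is used to check.
"""

import itertools
import math

import numpy as np


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


def auc_by_pair_counting(scores, is_positive):
    """P(random positive outscores random negative), ties counted half."""
    pos = [s for s, y in zip(scores, is_positive) if y]
    neg = [s for s, y in zip(scores, is_positive) if not y]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        if sp > sn:
            total += 1.0
        elif sp == sn:
            total += 0.5
    return total / (len(pos) * len(neg))


def exact_first_order_kernel(W):
    """Row-normalised weights: the p=q=1 walk transition matrix."""
    W = np.asarray(W, dtype=float)
    return W / W.sum(axis=1, keepdims=True)


def empirical_transition_matrix(corpus, n_nodes):
    """Conditional next-node frequencies observed in a walk corpus."""
    counts = np.zeros((n_nodes, n_nodes))
    for walk in corpus.walks:
        for a, b in zip(walk, walk[1:]):
            counts[a, b] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals, int(counts.sum())


def cosine_distance_by_hand(a, b):
    num = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return 1.0 - num / (na * nb)
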