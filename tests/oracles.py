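"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by direct enumeration or
step-by-step textbook formulas, sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


def wc_theta_one_locus(genosA, genosB):
    """Step-by-step Weir-Cockerham (1984) theta for one locus, r = 2.

    ``genosA``/``genosB`` are lists of (a1, a2) integer tuples (typed
    individuals only). Returns None for a locus monomorphic across both
    samples. Pure-python, loop-per-allele, no shared code with popgen.
    """
    nA, nB = len(genosA), len(genosB)
    r = 2
    alleles = sorted({a for g in genosA + genosB for a in g})
    if len(alleles) < 2:
        return None
    nbar = (nA + nB) / 2
    nc = (r * nbar - (nA**2 + nB**2) / (r * nbar)) / (r - 1)
    num = den = 0.0
    for al in alleles:
        pA = sum(g.count(al) for g in genosA) / (2 * nA)
        pB = sum(g.count(al) for g in genosB) / (2 * nB)
        hA = sum(1 for g in genosA if (g[0] == al) != (g[1] == al)) / nA
        hB = sum(1 for g in genosB if (g[0] == al) != (g[1] == al)) / nB
        pbar = (nA * pA + nB * pB) / (r * nbar)
        s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (nA * hA + nB * hB) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def distinct_label_arrangements(labels):
    """All distinct orderings of a label multiset (uniform over splits)."""
    return sorted(set(itertools.permutations(labels)))


def exhaustive_perm_p(values, labels, statfn, two_sided=True):
    """Exact permutation p: fraction of distinct relabelings at least as
    extreme as the observed arrangement (observed included)."""
    obs = statfn(values, list(labels))
    arrangements = distinct_label_arrangements(labels)
    if two_sided:
        n_ext = sum(abs(statfn(values, list(a))) >= abs(obs) for a in arrangements)
    else:
        n_ext = sum(statfn(values, list(a)) >= obs for a in arrangements)
    return n_ext / len(arrangements)


def exhaustive_extreme_fraction(values, labels, statfn, two_sided=True):
    """P(|T*| >= |T_obs|) under a uniformly random relabeling (the
    expectation of the Monte-Carlo extreme-count rate)."""
    return exhaustive_perm_p(values, labels, statfn, two_sided)


def min_spanning_weight(dist):
    """Minimum spanning-tree weight by exhaustive enumeration of all edge
    subsets of size n-1 that connect the graph (n <= 7 or so)."""
    n = len(dist)
    if n == 1:
        return 0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(dist[i][j] for i, j in subset))
    return best
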