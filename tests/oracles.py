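"""Independent brute-force oracles.

Deliberately naive re-implementations (plain Python loops, independent
libraries) of the quantities the package computes, kept free of any
skyground internals so oracle agreement is a genuine two-route check.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np


def shannon(p) -> float:
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def simpson(p) -> float:
    return 1.0 - sum(pi * pi for pi in p)


def mpd_brute(D, members_idx) -> float:
    pairs = []
    for i, a in enumerate(members_idx):
        for b in members_idx[i + 1 :]:
            pairs.append(D[a][b])
    return sum(pairs) / len(pairs)


def faith_pd_brute(tree: dendropy.Tree, members) -> float:
    """Union of edges on root-to-tip paths of the members."""
    edges = set()
    for lf in tree.leaf_node_iter():
        if lf.taxon.label not in members:
            continue
        nd = lf
        while nd.parent_node is not None:
            edges.add(id(nd.edge))
            nd = nd.parent_node
    total = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and id(nd.edge) in edges:
            total += nd.edge.length or 0.0
    return total


def patristic_brute(tree: dendropy.Tree):
    """Tip distances through dendropy's own distance matrix machinery."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.patristic_distance(taxa[i], taxa[j])
    return labels, D


def dispersion_brute(D, p, q) -> float:
    """qD(.M) straight through the formula chain with loops."""
    S = len(p)
    if S == 1:
        return 1.0
    m = []
    for i in range(S):
        m.append(sum(D[i][j] for j in range(S) if j != i) / (S - 1))
    M = sum(m) / S
    if q == 0:
        qdt = float(S)
    else:
        w = [p[i] * m[i] for i in range(S)]
        tot = sum(w)
        if tot == 0:
            return 1.0
        w = [wi / tot for wi in w if wi > 0]
        if q == 1:
            qdt = math.exp(-sum(wi * math.log(wi) for wi in w))
        else:
            qdt = sum(wi**q for wi in w) ** (1.0 / (1.0 - q))
    return 1.0 + (S - 1) * (qdt / S) * M


def upgma_merge_order(D, labels):
    """Hand agglomeration: returns frozensets merged at each step."""
    clusters = {frozenset([lab]): None for lab in labels}
    dist = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                dist[(frozenset([a]), frozenset([b]))] = D[i][j]

    def get(a, b):
        return dist.get((a, b), dist.get((b, a)))

    merges = []
    active = list(clusters)
    while len(active) > 1:
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                d = get(a, b)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = a | b
        merges.append((merged, d))
        for c in active:
            if c in (a, b):
                continue
            na, nb = len(a), len(b)
            dist[(merged, c)] = (na * get(a, c) + nb * get(b, c)) / (na + nb)
        active = [c for c in active if c not in (a, b)] + [merged]
    return merges
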