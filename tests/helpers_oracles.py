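"""Independent reference implementations used as test oracles.

These are deliberately written without reusing any code from the package
under test: dense-matrix MCL iteration, brute-force contingency-table NMI,
and a literal term-by-term transcription of the cover-NMI formula.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# dense MCL oracle


def mcl_oracle(graph: nx.Graph, inflation: float = 2.0, expansion: int = 2,
               self_loop: float = 1.0, max_iter: int = 500, tol: float = 1e-10):
    """Dense normalize -> expand -> inflate iteration until idempotent,
    attractor-row interpretation. Returns a set of frozensets of node labels."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    mat = np.zeros((n, n))
    for u, v, d in graph.edges(data=True):
        w = float(d.get("weight", 1.0))
        mat[idx[u], idx[v]] = w
        mat[idx[v], idx[u]] = w
    for i in range(n):
        mat[i, i] += self_loop
    mat = mat / mat.sum(axis=0)

    for _ in range(max_iter):
        nxt = np.linalg.matrix_power(mat, expansion) ** inflation
        nxt = nxt / nxt.sum(axis=0)
        if np.abs(nxt - mat).max() < tol:
            mat = nxt
            break
        mat = nxt

    eps = 1e-6
    # attractor rows -> cluster supports, merged when they overlap
    support = nx.Graph()
    support.add_nodes_from(range(n))
    attractors = [i for i in range(n) if mat[i, i] > eps]
    for i in attractors:
        for j in range(n):
            if mat[i, j] > eps:
                support.add_edge(i, j)
    # tie-resolution consistent with the stated contract: a node attached to
    # several attractor systems goes to the one holding the smallest label
    systems = []
    merged = nx.Graph()
    merged.add_nodes_from(attractors)
    for i, j in itertools.combinations(attractors, 2):
        if mat[i, j] > eps or mat[j, i] > eps:
            merged.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(merged)]
    assign = {}
    for j in range(n):
        cands = [c for c in comps if any(mat[i, j] > eps for i in c)]
        if not cands:
            assign[j] = ("orphan", j)
            continue
        best = min(cands, key=lambda c: min(nodes[i] for i in c))
        assign[j] = ("sys", min(best))
    clusters: dict = {}
    for j, key in assign.items():
        clusters.setdefault(key, set()).add(nodes[j])
    return {frozenset(c) for c in clusters.values()}


# ---------------------------------------------------------------------------
# partition NMI oracle


def nmi_oracle(labels_a: dict, labels_b: dict) -> float:
    """Brute-force contingency-table NMI, 2I/(Ha+Hb), natural logs.

    ``labels_a`` / ``labels_b`` map each universe element to a cluster label.
    """
    assert set(labels_a) == set(labels_b)
    n = len(labels_a)
    joint = Counter((labels_a[x], labels_b[x]) for x in labels_a)
    ca = Counter(labels_a.values())
    cb = Counter(labels_b.values())

    def h(counter):
        return -sum((c / n) * math.log(c / n) for c in counter.values() if c)

    ha, hb = h(ca), h(cb)
    if ha + hb == 0:
        return 1.0
    mi = 0.0
    for (i, j), nij in joint.items():
        mi += (nij / n) * math.log((nij * n) / (ca[i] * cb[j]))
    return 2 * mi / (ha + hb)


# ---------------------------------------------------------------------------
# cover NMI oracle (normalized conditional-entropy form, term by term)


def _hterm(p: float) -> float:
    return -p * math.log(p) if p > 0 else 0.0


def cover_nmi_oracle(cover_x: list, cover_y: list, universe: set) -> float:
    """Literal transcription of the cover-NMI formula.

    For each module X_k, H(X_k|Y) is the minimum admissible conditional
    indicator entropy over modules of Y (falling back to H(X_k)); the
    normalized conditional entropies of both directions are averaged and
    subtracted from 1.
    """
    n = len(universe)

    def hx(x):
        return _hterm(len(x) / n) + _hterm(1 - len(x) / n)

    def h_cond_norm(xs, ys):
        terms = []
        for x in xs:
            hxk = hx(x)
            if hxk == 0:
                continue
            best = hxk
            for y in ys:
                p11 = len(x & y) / n
                p10 = len(x - y) / n
                p01 = len(y - x) / n
                p00 = 1 - p11 - p10 - p01
                if _hterm(p11) + _hterm(p00) < _hterm(p10) + _hterm(p01):
                    continue
                joint = _hterm(p11) + _hterm(p10) + _hterm(p01) + _hterm(p00)
                hy = _hterm(len(y) / n) + _hterm(1 - len(y) / n)
                best = min(best, joint - hy)
            terms.append(best / hxk)
        if not terms:
            return 0.0
        return sum(terms) / len(terms)

    xs = [frozenset(x) & frozenset(universe) for x in cover_x]
    ys = [frozenset(y) & frozenset(universe) for y in cover_y]
    xs = [x for x in xs if x]
    ys = [y for y in ys if y]
    return 1.0 - (h_cond_norm(xs, ys) + h_cond_norm(ys, xs)) / 2.0


# ---------------------------------------------------------------------------
# random partitions for NMI agreement checks


def random_partition(rng: np.random.Generator, universe: list, max_clusters: int = 6) -> dict:
    k = int(rng.integers(1, max_clusters + 1))
    return {x: int(rng.integers(k)) for x in universe}
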