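"""Markov Cluster algorithm (MCL), implemented from scratch.

The flow simulation alternates expansion (matrix power of the
column-stochastic transition matrix) with inflation (entrywise power followed
by column renormalization) until the matrix is (numerically) idempotent;
clusters are read off the attractor rows of the limit matrix.

Determinism contract: nodes are processed in lexicographic order, so
identical inputs give identical module sets across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .datasets_io import ModuleSet

log = logging.getLogger(__name__)

__all__ = ["MclParameters", "MclError", "mcl_cluster", "interpret_limit_matrix"]


class MclError(ValueError):
    """Raised for invalid MCL input (e.g. an empty network)."""


@dataclass(frozen=True)
class MclParameters:
    """MCL knobs. Defaults are documented and stable across releases.

    ``self_loop_weight`` may be a non-negative number added to every diagonal
    entry before normalization, or the string ``"max-degree"`` to use each
    column's maximum edge weight.
    """

    inflation: float = 2.0
    expansion: int = 2
    self_loop_weight: float | str = 1.0
    prune_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if isinstance(self.self_loop_weight, str):
            if self.self_loop_weight != "max-degree":
                raise ValueError("self_loop_weight must be a number or 'max-degree'")
        elif self.self_loop_weight < 0:
            raise ValueError("self_loop_weight must be non-negative")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be > 0")


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    if np.any(sums <= 0):
        raise MclError("matrix has an all-zero column after pruning")
    return m / sums


def mcl_cluster(
    network: nx.Graph,
    params: MclParameters | None = None,
    name: str = "mcl_modules",
) -> ModuleSet:
    """Cluster a weighted network into disjoint modules covering all nodes.

    All edge weights must be positive. Raises :class:`MclError` on an empty
    network (distinct from the one-module outcome).
    """
    if params is None:
        params = MclParameters()
    nodes = sorted(network.nodes)
    if not nodes:
        raise MclError("cannot cluster an empty network")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    a = np.zeros((n, n), dtype=float)
    for u, v, data in network.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise MclError(f"non-positive edge weight {w!r} on ({u!r},{v!r})")
        i, j = index[u], index[v]
        a[i, j] = w
        a[j, i] = w

    if params.self_loop_weight == "max-degree":
        col_max = a.max(axis=0)
        col_max[col_max == 0] = 1.0
        np.fill_diagonal(a, col_max)
    else:
        np.fill_diagonal(a, np.diag(a) + float(params.self_loop_weight))
        # isolated node with zero self-loop would yield a zero column
        zero_cols = a.sum(axis=0) == 0
        if np.any(zero_cols):
            idx = np.where(zero_cols)[0]
            a[idx, idx] = 1.0

    m = _normalize_columns(a)
    converged = False
    for _ in range(params.max_iterations):
        expanded = np.linalg.matrix_power(m, params.expansion)
        inflated = expanded ** params.inflation
        if params.prune_threshold > 0:
            inflated[inflated < params.prune_threshold] = 0.0
        new = _normalize_columns(inflated)
        if np.max(np.abs(new - m)) < params.convergence_tolerance:
            m = new
            converged = True
            break
        m = new
    if not converged:
        log.warning("MCL did not converge within %d iterations", params.max_iterations)

    return interpret_limit_matrix(m, nodes, name=name)


def interpret_limit_matrix(
    limit: np.ndarray,
    node_order: Sequence[str],
    name: str = "mcl_modules",
    tolerance: float = 1e-6,
) -> ModuleSet:
    """Read disjoint modules off an (approximately idempotent) limit matrix.

    Attractors are nodes with a positive diagonal entry; overlapping attractor
    systems are merged; every node is assigned to the attractor system from
    which it receives positive mass. A node tied between systems goes to the
    system containing the lexicographically smallest node label. Columns must
    sum to 1 within ``tolerance``.
    """
    limit = np.asarray(limit, dtype=float)
    n = len(node_order)
    if limit.shape != (n, n):
        raise ValueError(f"limit matrix shape {limit.shape} != ({n},{n})")
    col_sums = limit.sum(axis=0)
    if np.any(np.abs(col_sums - 1.0) > tolerance):
        bad = int(np.argmax(np.abs(col_sums - 1.0)))
        raise ValueError(
            f"column {node_order[bad]!r} sums to {col_sums[bad]:.6g}, not 1"
        )

    eps = tolerance
    attractors = [i for i in range(n) if limit[i, i] > eps]
    if not attractors:
        # degenerate non-converged input: everything in one module
        return ModuleSet(name=name, modules=[("M001", frozenset(node_order))])

    # union attractors that support each other into attractor systems
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in attractors:
        for j in attractors:
            if i < j and (limit[i, j] > eps or limit[j, i] > eps):
                union(i, j)

    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)

    # assign every node to the system with positive incoming mass; ties go to
    # the system containing the lexicographically smallest node label
    members: dict[int, set[str]] = {root: set() for root in systems}
    for j in range(n):
        candidates = []
        for root, attrs in systems.items():
            mass = max(limit[i, j] for i in attrs)
            if mass > eps:
                candidates.append(root)
        if not candidates:
            # unconverged leftover: its own singleton system
            members.setdefault(-j - 1, set()).add(node_order[j])
            continue
        if len(candidates) == 1:
            chosen = candidates[0]
        else:
            chosen = min(
                candidates,
                key=lambda r: min(node_order[i] for i in systems[r]),
            )
        members[chosen].add(node_order[j])

    groups = sorted(
        (sorted(ms) for ms in members.values() if ms),
        key=lambda g: g[0],
    )
    width = max(3, len(str(len(groups))))
    modules = [
        (f"M{idx:0{width}d}", frozenset(g)) for idx, g in enumerate(groups, start=1)
    ]
    return ModuleSet(name=name, modules=modules)
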