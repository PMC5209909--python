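"""Normalized Mutual Information between module sets.

Two variants:

* :func:`nmi` — partition NMI, ``2 I(A;B) / (H(A) + H(B))`` with natural-log
  entropies from the contingency table. Members not covered by any module
  become singletons; overlapping input modules are flattened by first-listed
  assignment (count logged).
* :func:`overlapping_nmi` — cover NMI based on normalized conditional
  entropies, valid when modules overlap.

Both expect the two sets to be compared over a common universe; use
:func:`restrict_to_common_universe` first when universes differ.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

from .datasets_io import ModuleSet

log = logging.getLogger(__name__)

__all__ = ["restrict_to_common_universe", "nmi", "overlapping_nmi"]


def restrict_to_common_universe(
    a: ModuleSet, b: ModuleSet
) -> tuple[ModuleSet, ModuleSet, frozenset[str]]:
    """Restrict both module sets to the intersection of their universes.

    Emptied modules are dropped. Raises ``ValueError`` when the sets share no
    members.
    """
    universe = frozenset(a.universe() & b.universe())
    if not universe:
        raise ValueError(
            f"module sets {a.name!r} and {b.name!r} share no members"
        )

    def restrict(ms: ModuleSet) -> ModuleSet:
        kept = []
        for label, members in ms.modules:
            inter = members & universe
            if inter:
                kept.append((label, frozenset(inter)))
        return ModuleSet(name=ms.name, modules=kept)

    return restrict(a), restrict(b), universe


def _as_partition(ms: ModuleSet, universe: Iterable[str]) -> dict[str, int]:
    """Flatten a module set into a partition label per universe member.

    Overlaps resolve to the first-listed module (reassignments logged);
    uncovered members become singletons.
    """
    universe = set(universe)
    assignment: dict[str, int] = {}
    reassigned = 0
    for idx, (_, members) in enumerate(ms.modules):
        for m in members:
            if m not in universe:
                continue
            if m in assignment:
                reassigned += 1
                continue
            assignment[m] = idx
    if reassigned:
        log.info(
            "module set %s: %d overlapping memberships resolved to first-listed module",
            ms.name, reassigned,
        )
    next_label = len(ms.modules)
    for m in sorted(universe - assignment.keys()):
        assignment[m] = next_label
        next_label += 1
    return assignment


def _entropy(counts: Iterable[int], n: int) -> float:
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log(p)
    return h


def nmi(a: ModuleSet, b: ModuleSet, universe: Iterable[str] | None = None) -> float:
    """Partition NMI = 2 I(A;B) / (H(A) + H(B)), natural logs.

    Symmetric; 1 for identical partitions (up to relabeling); 0 against the
    single all-inclusive module. ``0 * log 0 := 0``; when both partitions are
    the trivial one-module partition (H(A) + H(B) = 0) the value is defined
    as 1.
    """
    if universe is None:
        universe = a.universe() | b.universe()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    pa = _as_partition(a, universe)
    pb = _as_partition(b, universe)
    n = len(universe)

    joint: dict[tuple[int, int], int] = {}
    ca: dict[int, int] = {}
    cb: dict[int, int] = {}
    for m in universe:
        i, j = pa[m], pb[m]
        joint[(i, j)] = joint.get((i, j), 0) + 1
        ca[i] = ca.get(i, 0) + 1
        cb[j] = cb.get(j, 0) + 1

    ha = _entropy(ca.values(), n)
    hb = _entropy(cb.values(), n)
    if ha + hb == 0.0:
        return 1.0  # both trivial single-module partitions: identical
    mi = 0.0
    for (i, j), nij in joint.items():
        if nij > 0:
            mi += (nij / n) * math.log(nij * n / (ca[i] * cb[j]))
    val = 2.0 * mi / (ha + hb)
    return min(1.0, max(0.0, val))


def _h(p: float) -> float:
    return -p * math.log(p) if p > 0 else 0.0


def _indicator_entropy(size: int, n: int) -> float:
    return _h(size / n) + _h((n - size) / n)


def _cond_entropy_normalized(
    xs: Sequence[frozenset[str]], ys: Sequence[frozenset[str]], n: int
) -> float:
    """Mean over modules X_i of H(X_i | Y) / H(X_i), cover-NMI style.

    H(X_i | Y_j) is admitted only when the joint indicator entropy satisfies
    h(both) + h(neither) >= h(only X) + h(only Y), preventing a complementary
    module from spuriously explaining X_i; otherwise H(X_i | Y) falls back to
    the unconditional H(X_i).
    """
    total = 0.0
    counted = 0
    for x in xs:
        hx = _indicator_entropy(len(x), n)
        if hx == 0.0:
            continue  # module covering everything carries no information
        best = hx
        for y in ys:
            both = len(x & y)
            only_x = len(x) - both
            only_y = len(y) - both
            neither = n - both - only_x - only_y
            h11 = _h(both / n)
            h10 = _h(only_x / n)
            h01 = _h(only_y / n)
            h00 = _h(neither / n)
            if h11 + h00 < h10 + h01:
                continue
            hy = _indicator_entropy(len(y), n)
            h_cond = h11 + h10 + h01 + h00 - hy
            best = min(best, h_cond)
        total += best / hx
        counted += 1
    if counted == 0:
        return 0.0
    return total / counted


def overlapping_nmi(
    a: ModuleSet, b: ModuleSet, universe: Iterable[str] | None = None
) -> float:
    """Cover NMI: 1 - (H(A|B)_norm + H(B|A)_norm) / 2.

    Handles overlapping module sets; equals 1 for identical covers (duplicate
    modules carry no new information) and lies in [0, 1]. For partitions it is
    consistent with partition behavior but not numerically forced to coincide
    with :func:`nmi`.
    """
    if universe is None:
        universe = a.universe() | b.universe()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    n = len(universe)
    xs = [frozenset(m & universe) for _, m in a.modules if m & universe]
    ys = [frozenset(m & universe) for _, m in b.modules if m & universe]
    if not xs or not ys:
        raise ValueError("a module set is empty after restriction to the universe")
    h_a_given_b = _cond_entropy_normalized(xs, ys, n)
    h_b_given_a = _cond_entropy_normalized(ys, xs, n)
    val = 1.0 - (h_a_given_b + h_b_given_a) / 2.0
    return min(1.0, max(0.0, val))
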