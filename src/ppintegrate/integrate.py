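"""Combine per-dataset interaction evidence into one weighted network.

Each dataset carries a single confidence score; the combined edge weight for
a protein pair is the noisy-OR / naive-Bayes combination

    similarity = 1 - prod_p (1 - w_p)

over the datasets containing the pair. Datasets with role
``FIXED_FULL_CONFIDENCE`` contribute weight 1, so any pair they contain gets
combined weight 1. Pairs with combined weight 0 are omitted from the network.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .datasets_io import InteractionDataset, Pair, Role

log = logging.getLogger(__name__)

__all__ = ["combine_pair_score", "build_weighted_network"]


def combine_pair_score(effective_weights: Iterable[float]) -> float:
    """Noisy-OR combination of per-dataset confidences for one pair.

    Returns ``1 - prod(1 - w)``; 0 for an empty or all-zero list, 1 if any
    weight is 1. Invariant under permutation. Raises ``ValueError`` for a
    weight outside [0, 1].
    """
    prod = 1.0
    for w in effective_weights:
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight {w!r} outside [0, 1]")
        prod *= 1.0 - w
    return 1.0 - prod


def _effective_weight(dataset: InteractionDataset, weights: Mapping[str, float]) -> float:
    if dataset.role is Role.FIXED_FULL_CONFIDENCE:
        return 1.0
    if dataset.name not in weights:
        raise KeyError(f"free dataset {dataset.name!r} missing from weight vector")
    w = weights[dataset.name]
    # defense in depth: the optimizer guarantees bounds, clamp anyway
    return min(1.0, max(0.0, float(w)))


def build_weighted_network(
    datasets: Sequence[InteractionDataset], weights: Mapping[str, float]
) -> nx.Graph:
    """Build the integrated weighted network from datasets and a weight vector.

    ``weights`` must contain an entry for every free dataset; fixed datasets
    get effective weight 1. Edges with combined score 0 are dropped, and the
    node set is exactly the endpoints of retained edges (proteins seen only in
    zero-weight datasets do not appear).
    """
    per_pair: dict[Pair, list[float]] = {}
    for ds in datasets:
        w = _effective_weight(ds, weights)
        if w == 0.0:
            continue
        for pair in ds.pairs:
            per_pair.setdefault(pair, []).append(w)

    g = nx.Graph()
    for (a, b), ws in per_pair.items():
        score = combine_pair_score(ws)
        if score > 0.0:
            g.add_edge(a, b, weight=score)
    return g
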