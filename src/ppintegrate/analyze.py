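"""Downstream analysis of detected modules.

Central ("hub") proteins, per-pair co-expression, the co-expression display
cutoff, module/complex mapping, and overlap reporting against an external
interaction dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .datasets_io import (
    ExpressionMatrix,
    InteractionDataset,
    ModuleSet,
    Pair,
    normalize_pair,
)

log = logging.getLogger(__name__)

__all__ = [
    "HubReport",
    "OverlapReport",
    "ComplexMapping",
    "detect_central_proteins",
    "hub_report",
    "pairwise_coexpression",
    "coexpression_cutoff",
    "overlay_coexpression",
    "map_modules_to_complexes",
    "compare_external_dataset",
]


# ---------------------------------------------------------------------------
# central proteins


@dataclass
class HubReport:
    """Per-module hub statistics. The hub set contains members whose
    within-module degree is strictly greater than twice the module mean."""

    module_label: str
    members: list[str]
    degrees: dict[str, int]
    mean_degree: float
    threshold: float
    hubs: set[str]


def detect_central_proteins(
    members: Iterable[str], network: nx.Graph, weighted: bool = False
) -> set[str]:
    """Hub members of a module: degree strictly above 2x the module's mean.

    Degree is the unweighted neighbor count in the subgraph induced by the
    module members (weighted degree available as an option). Empty hub sets
    are valid (e.g. any clique).
    """
    members = sorted(set(members))
    if not members:
        raise ValueError("module is empty")
    sub = network.subgraph(members)
    if weighted:
        degrees = {m: float(sub.degree(m, weight="weight")) if m in sub else 0.0 for m in members}
    else:
        degrees = {m: int(sub.degree(m)) if m in sub else 0 for m in members}
    mean = sum(degrees.values()) / len(members)
    threshold = 2.0 * mean
    return {m for m in members if degrees[m] > threshold}


def hub_report(modules: ModuleSet, network: nx.Graph, weighted: bool = False) -> list[HubReport]:
    """Full per-module hub report for all modules."""
    reports = []
    for label, members in modules.modules:
        ms = sorted(members)
        sub = network.subgraph(ms)
        if weighted:
            degrees = {m: float(sub.degree(m, weight="weight")) if m in sub else 0.0 for m in ms}
        else:
            degrees = {m: int(sub.degree(m)) if m in sub else 0 for m in ms}
        mean = sum(degrees.values()) / len(ms)
        threshold = 2.0 * mean
        hubs = {m for m in ms if degrees[m] > threshold}
        reports.append(
            HubReport(
                module_label=label,
                members=ms,
                degrees=degrees,
                mean_degree=mean,
                threshold=threshold,
                hubs=hubs,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# co-expression


def pairwise_coexpression(
    expr: ExpressionMatrix, pairs: Iterable[tuple[str, str]]
) -> dict[Pair, float]:
    """Pearson correlation over all conditions for each gene pair.

    Pairs with a gene missing from the matrix are absent from the result (not
    zero); zero-variance genes likewise yield no entry, with a warning —
    silently reporting 0 would corrupt downstream cutoff estimation. Raises
    ``ValueError`` when fewer than 3 conditions are available.
    """
    if len(expr.conditions) < 3:
        raise ValueError(
            f"need >=3 conditions for correlation, got {len(expr.conditions)}"
        )
    out: dict[Pair, float] = {}
    n_missing = n_constant = 0
    cache: dict[str, tuple[np.ndarray, float]] = {}

    def centered(gene: str) -> tuple[np.ndarray, float]:
        if gene not in cache:
            x = expr.row(gene)
            xc = x - x.mean()
            cache[gene] = (xc, float(np.sqrt((xc * xc).sum())))
        return cache[gene]

    for a, b in pairs:
        pair = normalize_pair(a, b)
        if a not in expr or b not in expr:
            n_missing += 1
            continue
        if a == b:
            out[pair] = 1.0
            continue
        xa, na = centered(a)
        xb, nb = centered(b)
        if na == 0.0 or nb == 0.0:
            n_constant += 1
            continue
        out[pair] = float((xa * xb).sum() / (na * nb))
    if n_missing:
        log.info("%d pairs skipped: gene absent from expression matrix", n_missing)
    if n_constant:
        log.warning("%d pairs skipped: zero-variance expression row", n_constant)
    return out


def coexpression_cutoff(
    correlations: Sequence[float], exceed_fraction: float = 0.70
) -> float:
    """The largest value c such that at least ``exceed_fraction`` of the
    inputs are >= c.

    Computed as the order statistic at rank ``n - ceil(f * n)`` (the
    empirical (1 - f)-quantile with the "lower" rule), which makes the
    postcondition exact on finite samples.
    """
    values = sorted(float(v) for v in correlations)
    if not values:
        raise ValueError("empty correlation list")
    if not 0.0 < exceed_fraction < 1.0:
        raise ValueError("exceed_fraction must be in (0, 1)")
    n = len(values)
    need = math.ceil(exceed_fraction * n - 1e-9)
    return values[n - need]


def overlay_coexpression(
    modules: ModuleSet, expr: ExpressionMatrix, cutoff: float
) -> list[tuple[str, str, str, float]]:
    """Within-module gene pairs with correlation strictly above ``cutoff``.

    Returns rows ``(module_label, gene_a, gene_b, correlation)`` suitable for
    an edge-attribute TSV consumed by graph-visualization tools.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    rows: list[tuple[str, str, str, float]] = []
    for label, members in modules.modules:
        ms = sorted(members)
        pairs = [(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))]
        corr = pairwise_coexpression(expr, pairs)
        for (a, b), r in sorted(corr.items()):
            if r > cutoff:
                rows.append((label, a, b, r))
    return rows


# ---------------------------------------------------------------------------
# complex mapping


@dataclass
class ComplexMapping:
    """How one reference complex distributes over detected modules."""

    complex_label: str
    size: int
    best_module: str | None
    coverage: float  # plurality overlap / complex size
    split: int  # number of modules touched by >=1 member


def map_modules_to_complexes(
    modules: ModuleSet, complexes: ModuleSet
) -> list[ComplexMapping]:
    """For each reference complex, the detected module holding the plurality
    of its members, the coverage fraction, and the number of modules its
    members are split across. Plurality ties break to the smaller module
    label."""
    results = []
    for clabel, cmembers in complexes.modules:
        overlaps: dict[str, int] = {}
        for mlabel, mmembers in modules.modules:
            k = len(cmembers & mmembers)
            if k:
                overlaps[mlabel] = k
        if overlaps:
            best = min(overlaps, key=lambda l: (-overlaps[l], l))
            coverage = overlaps[best] / len(cmembers)
            split = len(overlaps)
        else:
            best, coverage, split = None, 0.0, 0
        results.append(
            ComplexMapping(
                complex_label=clabel,
                size=len(cmembers),
                best_module=best,
                coverage=coverage,
                split=split,
            )
        )
    return results


# ---------------------------------------------------------------------------
# external dataset overlap


@dataclass
class OverlapReport:
    """Cumulative overlap of an external interaction dataset with the
    analysis: pairs found in any used dataset; additionally pairs whose
    endpoints share a detected module; additionally pairs touching a hub
    protein. Fractions are relative to annotated external pairs."""

    external_name: str
    n_external: int
    n_annotated: int
    n_in_datasets: int
    n_in_datasets_or_comodular: int
    n_in_datasets_or_comodular_or_hub: int
    fraction_in_datasets: float
    fraction_in_datasets_or_comodular: float
    fraction_in_datasets_or_comodular_or_hub: float
    mean_coexpression: float | None = None


def compare_external_dataset(
    external: InteractionDataset,
    used: Sequence[InteractionDataset],
    modules: ModuleSet,
    hubs: Iterable[str] = (),
    expr: ExpressionMatrix | None = None,
) -> OverlapReport:
    """Overlap report of ``external`` against the used datasets, the detected
    modules, and the hub set.

    "Annotated" external pairs are those with both endpoints in the analysis
    universe (union of used-dataset proteins and module members). The three
    counts are cumulative unions, so each is <= the next and <= annotated.
    """
    universe: set[str] = set()
    used_pairs: set[Pair] = set()
    for ds in used:
        universe |= ds.proteins()
        used_pairs |= ds.pairs
    universe |= modules.universe()
    hubs = set(hubs)

    membership: dict[str, set[str]] = {}
    for label, members in modules.modules:
        for m in members:
            membership.setdefault(m, set()).add(label)

    annotated = [p for p in sorted(external.pairs) if p[0] in universe and p[1] in universe]
    n_ann = len(annotated)

    in_ds = 0
    in_ds_or_mod = 0
    in_ds_or_mod_or_hub = 0
    for a, b in annotated:
        pair_in_ds = (a, b) in used_pairs
        comodular = bool(membership.get(a, set()) & membership.get(b, set()))
        touches_hub = a in hubs or b in hubs
        if pair_in_ds:
            in_ds += 1
        if pair_in_ds or comodular:
            in_ds_or_mod += 1
        if pair_in_ds or comodular or touches_hub:
            in_ds_or_mod_or_hub += 1

    mean_coexpr: float | None = None
    if expr is not None and annotated:
        corr = pairwise_coexpression(expr, annotated)
        if corr:
            mean_coexpr = float(np.mean(list(corr.values())))

    def frac(k: int) -> float:
        return k / n_ann if n_ann else 0.0

    return OverlapReport(
        external_name=external.name,
        n_external=len(external.pairs),
        n_annotated=n_ann,
        n_in_datasets=in_ds,
        n_in_datasets_or_comodular=in_ds_or_mod,
        n_in_datasets_or_comodular_or_hub=in_ds_or_mod_or_hub,
        fraction_in_datasets=frac(in_ds),
        fraction_in_datasets_or_comodular=frac(in_ds_or_mod),
        fraction_in_datasets_or_comodular_or_hub=frac(in_ds_or_mod_or_hub),
        mean_coexpression=mean_coexpr,
    )
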