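"""Outer optimization loop: weights -> integrated network -> MCL modules ->
NMI against reference modules -> harmony-search update.

The objective restricts detected and reference modules to their common
universe (uncovered members become singletons) in exactly one place, so the
optimizer and the reported NMI always agree. Objective values are cached on
the weight vector rounded to 12 decimals; the objective is deterministic, so
caching cannot change results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .datasets_io import InteractionDataset, ModuleSet, Role
from .harmony import HarmonyParameters, OptimizationTrace, harmony_search
from .integrate import build_weighted_network
from .mcl import MclParameters, mcl_cluster
from .similarity import nmi, overlapping_nmi

log = logging.getLogger(__name__)

__all__ = ["FitResult", "objective", "fit_weights", "free_dataset_names"]


def free_dataset_names(datasets: Sequence[InteractionDataset]) -> list[str]:
    """Names of the free (optimizable) datasets, in roster order."""
    return [d.name for d in datasets if d.role is Role.FREE]


def _score_modules(
    detected: ModuleSet, reference: ModuleSet, variant: str
) -> float:
    # evaluated over the union of the network nodes and the reference
    # universe: members uncovered on either side become singletons, so
    # spurious co-clustering of non-reference proteins is penalized
    universe = detected.universe() | reference.universe()
    if not universe:
        log.warning("no proteins to score against %s; NMI = 0", reference.name)
        return 0.0
    if variant == "partition":
        return nmi(detected, reference, universe)
    if variant == "overlap":
        return overlapping_nmi(detected, reference, universe)
    raise ValueError(f"unknown NMI variant {variant!r}")


def objective(
    weights: Mapping[str, float],
    datasets: Sequence[InteractionDataset],
    reference: ModuleSet,
    mcl_params: MclParameters | None = None,
    nmi_variant: str = "partition",
) -> float:
    """NMI of the MCL modules of the integrated network against ``reference``.

    Deterministic in its inputs. An empty integrated network (all free
    weights zero and no fixed datasets) scores 0 with a warning rather than
    raising.
    """
    network = build_weighted_network(datasets, weights)
    if network.number_of_nodes() == 0:
        log.warning("integrated network is empty; objective = 0")
        return 0.0
    detected = mcl_cluster(network, mcl_params)
    return _score_modules(detected, reference, nmi_variant)


@dataclass
class FitResult:
    """Outcome of a weight fit.

    ``modules`` is exactly ``mcl_cluster(build_weighted_network(datasets,
    best_weights), mcl_params)`` — recomputable from the weights.
    ``extra_reference_nmi`` maps each extra reference set name to the
    per-iteration NMI of the best-so-far modules against it (curves that are
    observed, never optimized).
    """

    best_weights: dict[str, float]
    best_nmi: float
    modules: ModuleSet
    trace: OptimizationTrace
    extra_reference_nmi: dict[str, list[float]] = field(default_factory=dict)


def fit_weights(
    datasets: Sequence[InteractionDataset],
    reference: ModuleSet,
    hs_params: HarmonyParameters | None = None,
    mcl_params: MclParameters | None = None,
    nmi_variant: str = "partition",
    extra_references: Sequence[ModuleSet] = (),
    iterations: int | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit per-dataset confidence weights by harmony search over [0, 1]^k.

    ``k`` equals the number of free datasets; fixed-role datasets always
    contribute weight 1. ``iterations`` and ``seed`` override the
    corresponding ``hs_params`` fields when given. Fully deterministic given
    the seed.
    """
    names = free_dataset_names(datasets)
    if not names:
        raise ValueError("no free datasets: nothing to optimize")
    k = len(names)

    if hs_params is None:
        hs_params = HarmonyParameters(n_variables=k)
    if hs_params.n_variables != k:
        raise ValueError(
            f"hs_params.n_variables = {hs_params.n_variables} but roster has {k} free datasets"
        )
    overrides = {}
    if iterations is not None:
        overrides["iterations"] = iterations
    if seed is not None:
        overrides["seed"] = seed
    if overrides:
        from dataclasses import replace

        hs_params = replace(hs_params, **overrides)
    if mcl_params is None:
        mcl_params = MclParameters()

    cache: dict[tuple[float, ...], float] = {}

    def vector_objective(x: np.ndarray) -> float:
        key = tuple(round(float(v), 12) for v in x)
        if key not in cache:
            weights = dict(zip(names, (float(v) for v in x)))
            cache[key] = objective(weights, datasets, reference, mcl_params, nmi_variant)
        return cache[key]

    # extra-reference curves: NMI of the best-so-far modules per iteration,
    # recomputed only when the incumbent changes
    extra_curves: dict[str, list[float]] = {ref.name: [] for ref in extra_references}
    last_best: tuple[float, ...] | None = None
    last_extra: dict[str, float] = {}

    def tracked_objective(x: np.ndarray) -> float:
        return vector_objective(x)

    best_vec, best_obj, trace = harmony_search(tracked_objective, hs_params)

    if extra_references:
        for rec in trace.records:
            if rec.best_vector != last_best:
                last_best = rec.best_vector
                weights = dict(zip(names, rec.best_vector))
                network = build_weighted_network(datasets, weights)
                if network.number_of_nodes() == 0:
                    last_extra = {ref.name: 0.0 for ref in extra_references}
                else:
                    detected = mcl_cluster(network, mcl_params)
                    last_extra = {
                        ref.name: _score_modules(detected, ref, nmi_variant)
                        for ref in extra_references
                    }
            for ref in extra_references:
                extra_curves[ref.name].append(last_extra[ref.name])

    best_weights = dict(zip(names, (float(v) for v in best_vec)))
    network = build_weighted_network(datasets, best_weights)
    if network.number_of_nodes() == 0:
        log.warning("best network is empty; returning empty module set")
        modules = ModuleSet(name="mcl_modules", modules=[])
        final_nmi = 0.0
    else:
        modules = mcl_cluster(network, mcl_params)
        final_nmi = _score_modules(modules, reference, nmi_variant)

    if abs(final_nmi - best_obj) > 1e-9:
        log.warning(
            "re-evaluated best NMI %.6f differs from trace best %.6f", final_nmi, best_obj
        )

    return FitResult(
        best_weights=best_weights,
        best_nmi=final_nmi,
        modules=modules,
        trace=trace,
        extra_reference_nmi=extra_curves,
    )
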