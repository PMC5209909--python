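"""Harmony search: bounded-domain stochastic maximizer.

Each new candidate (harmony) is improvised per variable: with probability
``memory_considering_rate`` the value is recalled from a uniformly chosen
memory row and, with probability ``pitch_adjusting_rate``, perturbed by a
uniform draw in ``[-bandwidth, +bandwidth]`` (clipped to bounds); otherwise
it is drawn uniformly from the variable's bounds. The candidate replaces the
worst memory row only when strictly better, so the best-so-far sequence is
non-decreasing and flat objectives cannot cause drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["HarmonyParameters", "TraceRecord", "OptimizationTrace", "harmony_search"]


@dataclass(frozen=True)
class HarmonyParameters:
    """Harmony search configuration.

    Defaults follow the common published parameterization for this problem
    class: memory size 100, memory considering rate 0.8, pitch adjusting
    rate 0.3, bandwidth 0.5, 10000 iterations.
    """

    n_variables: int
    memory_size: int = 100
    memory_considering_rate: float = 0.8
    pitch_adjusting_rate: float = 0.3
    bandwidth: float = 0.5
    iterations: int = 10000
    bounds: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variables < 1:
            raise ValueError("n_variables must be positive")
        if self.memory_size < 1:
            raise ValueError("memory_size must be positive")
        if not 0.0 <= self.memory_considering_rate <= 1.0:
            raise ValueError("memory_considering_rate must be in [0, 1]")
        if not 0.0 <= self.pitch_adjusting_rate <= 1.0:
            raise ValueError("pitch_adjusting_rate must be in [0, 1]")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be positive")
        bounds = self.resolved_bounds()
        for lo, hi in bounds:
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
                raise ValueError(f"invalid bounds ({lo}, {hi})")

    def resolved_bounds(self) -> tuple[tuple[float, float], ...]:
        if self.bounds is None:
            return tuple((0.0, 1.0) for _ in range(self.n_variables))
        if len(self.bounds) != self.n_variables:
            raise ValueError("bounds length must equal n_variables")
        return tuple((float(lo), float(hi)) for lo, hi in self.bounds)


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    candidate: tuple[float, ...]
    candidate_objective: float
    best_objective: float
    best_vector: tuple[float, ...]


@dataclass
class OptimizationTrace:
    """Per-iteration optimization record; best_objective is non-decreasing."""

    records: list[TraceRecord] = field(default_factory=list)

    def best_objectives(self) -> list[float]:
        return [r.best_objective for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


def _check_finite(value: float, candidate: np.ndarray) -> float:
    value = float(value)
    if not np.isfinite(value):
        raise ValueError(
            f"objective returned non-finite value {value!r} at candidate {candidate.tolist()}"
        )
    return value


def harmony_search(
    objective: Callable[[np.ndarray], float],
    params: HarmonyParameters,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Maximize ``objective`` over the bounded box. Fully seeded.

    Returns (best vector, best objective, trace). Memory is initialized with
    ``memory_size`` uniform samples over the bounds, all evaluated.
    """
    rng = np.random.default_rng(params.seed)
    bounds = np.asarray(params.resolved_bounds(), dtype=float)
    lows, highs = bounds[:, 0], bounds[:, 1]
    k = params.n_variables
    ms = params.memory_size

    memory = rng.uniform(lows, highs, size=(ms, k))
    scores = np.array([_check_finite(objective(memory[i]), memory[i]) for i in range(ms)])

    best_idx = int(np.argmax(scores))
    best_vec = memory[best_idx].copy()
    best_obj = float(scores[best_idx])

    trace = OptimizationTrace()
    # record 0 captures the initialization: best row of the initial memory
    trace.records.append(
        TraceRecord(
            iteration=0,
            candidate=tuple(best_vec.tolist()),
            candidate_objective=best_obj,
            best_objective=best_obj,
            best_vector=tuple(best_vec.tolist()),
        )
    )
    for it in range(1, params.iterations + 1):
        new = np.empty(k)
        for j in range(k):
            if rng.random() < params.memory_considering_rate:
                row = int(rng.integers(ms))
                v = memory[row, j]
                if rng.random() < params.pitch_adjusting_rate:
                    v += rng.uniform(-params.bandwidth, params.bandwidth)
            else:
                v = rng.uniform(lows[j], highs[j])
            new[j] = min(highs[j], max(lows[j], v))

        f = _check_finite(objective(new), new)
        worst = int(np.argmin(scores))
        if f > scores[worst]:  # ties keep the incumbent
            memory[worst] = new
            scores[worst] = f
        if f > best_obj:
            best_obj = f
            best_vec = new.copy()
        trace.records.append(
            TraceRecord(
                iteration=it,
                candidate=tuple(new.tolist()),
                candidate_objective=f,
                best_objective=best_obj,
                best_vector=tuple(best_vec.tolist()),
            )
        )

    return best_vec, best_obj, trace
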