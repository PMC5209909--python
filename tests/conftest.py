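from __future__ import annotations

import pytest

from ppintegrate.datasets_io import InteractionDataset, ModuleSet, Role
from ppintegrate.simulate import BenchmarkSpec, DatasetSpec, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-complex benchmark shared across tests (seed-fixed)."""
    spec = BenchmarkSpec(
        n_proteins=60,
        n_complexes=6,
        complex_size=(5, 8),
        datasets=(
            DatasetSpec("good_a", tp=0.9, fp=0.01),
            DatasetSpec("good_b", tp=0.8, fp=0.01),
            DatasetSpec("junk", tp=0.02, fp=0.02),
        ),
        n_conditions=40,
        rho=0.8,
        reference_swap_rate=0.1,
        seed=11,
    )
    return generate_benchmark(spec)


@pytest.fixture
def clique_dataset():
    """Two disjoint 4-cliques as a single free dataset, plus the matching
    reference partition."""
    groups = [["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]]
    pairs = []
    for g in groups:
        for i in range(len(g)):
            for j in range(i + 1, len(g)):
                pairs.append((g[i], g[j]))
    ds = InteractionDataset.from_pairs("cliques", pairs, role=Role.FREE)
    reference = ModuleSet(
        name="ref",
        modules=[("A", frozenset(groups[0])), ("B", frozenset(groups[1]))],
    )
    return ds, reference
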