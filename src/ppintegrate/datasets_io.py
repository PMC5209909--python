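"""On-disk artifact readers and writers.

Formats handled here:

* edge lists — TSV/whitespace-delimited, two or more columns, extra columns
  ignored;
* gene/module sets — GMT dialect (``name<TAB>description<TAB>member...``);
* expression matrices — TSV, first column gene identifier, header row of
  condition identifiers;
* weight vectors — TSV ``dataset_name<TAB>weight<TAB>role``;
* optimization traces — TSV with candidate and best-so-far columns;
* weighted networks — three-column TSV ``protein_a<TAB>protein_b<TAB>weight``.

All writers round-trip losslessly through their matching reader.
Protein identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Pair = tuple[str, str]


class Role(str, enum.Enum):
    """Weight role of an interaction dataset.

    ``FREE`` datasets carry an optimizable confidence score; datasets with
    ``FIXED_FULL_CONFIDENCE`` (gold-standard interactions, co-complex pairs)
    always contribute evidence with weight 1.
    """

    FREE = "free"
    FIXED_FULL_CONFIDENCE = "fixed_full_confidence"


def normalize_pair(a: str, b: str) -> Pair:
    """Return the pair ordered lexicographically (smaller identifier first)."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionDataset:
    """A named set of unordered protein pairs with a weight role.

    Pairs are stored order-normalized ``(a, b)`` with ``a < b``; self-pairs
    are rejected at construction.
    """

    name: str
    pairs: frozenset[Pair]
    role: Role = Role.FREE

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"dataset {self.name!r}: self-pair ({a!r},{b!r})")
            if a > b:
                raise ValueError(
                    f"dataset {self.name!r}: pair ({a!r},{b!r}) is not order-normalized"
                )

    @classmethod
    def from_pairs(
        cls, name: str, pairs: Iterable[tuple[str, str]], role: Role = Role.FREE
    ) -> "InteractionDataset":
        """Build a dataset from raw pairs: normalize order, drop self-pairs,
        collapse duplicates. Drop counts are logged."""
        seen: set[Pair] = set()
        n_raw = n_self = 0
        for a, b in pairs:
            n_raw += 1
            if a == b:
                n_self += 1
                continue
            seen.add(normalize_pair(a, b))
        n_dup = n_raw - n_self - len(seen)
        if n_self or n_dup:
            log.info(
                "dataset %s: %d raw pairs, %d self-pairs dropped, %d duplicates collapsed",
                name, n_raw, n_self, n_dup,
            )
        return cls(name=name, pairs=frozenset(seen), role=role)

    def proteins(self) -> set[str]:
        """Set of all proteins appearing in at least one pair."""
        out: set[str] = set()
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ModuleSet:
    """A named, ordered collection of labelled protein/gene sets.

    Modules from a clustering are disjoint; reference sets may overlap.
    Labels are unique and every module is non-empty.
    """

    name: str
    modules: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [lbl for lbl, _ in self.modules]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"module set {self.name!r}: duplicate labels {dup}")
        for lbl, members in self.modules:
            if not members:
                raise ValueError(f"module set {self.name!r}: module {lbl!r} is empty")

    def universe(self) -> set[str]:
        """Union of all module members."""
        out: set[str] = set()
        for _, members in self.modules:
            out |= members
        return out

    def labels(self) -> list[str]:
        return [lbl for lbl, _ in self.modules]

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(self.modules)

    def __len__(self) -> int:
        return len(self.modules)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleSet):
            return NotImplemented
        return self.name == other.name and self.modules == other.modules


@dataclass
class ExpressionMatrix:
    """Genes x conditions real-valued expression levels.

    ``values`` is a pandas DataFrame indexed by gene identifier with condition
    identifiers as columns. Row identifiers must be unique.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = sorted(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def row(self, gene: str) -> np.ndarray:
        return self.values.loc[gene].to_numpy(dtype=float)

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path, role: Role = Role.FREE, name: str | None = None) -> InteractionDataset:
    """Read a 2+-column whitespace/TSV edge list into an order-normalized,
    deduplicated, self-pair-free :class:`InteractionDataset`.

    Columns beyond the second are ignored. Raises ``ValueError`` naming the
    line number on a line with fewer than two fields.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    raw: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            fields = [f for f in fields if f != ""]
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 fields, got {len(fields)}")
            raw.append((fields[0], fields[1]))
    return InteractionDataset.from_pairs(name, raw, role=role)


def write_edge_list(dataset: InteractionDataset, path: str | Path) -> None:
    """Write pairs as a two-column TSV, sorted for determinism."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b in sorted(dataset.pairs):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path, name: str | None = None) -> ModuleSet:
    """Read a GMT file (``name<TAB>description<TAB>member...``) into a
    :class:`ModuleSet`, preserving file order.

    Duplicate members within a line collapse; a duplicate module label or a
    line with fewer than three fields is an error.
    """
    path = Path(path)
    if name is None:
        name = path.stem
    modules: list[tuple[str, frozenset[str]]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            label = fields[0]
            if label in seen:
                raise ValueError(f"{path}:{lineno}: duplicate module label {label!r}")
            seen.add(label)
            members = frozenset(m for m in fields[2:] if m != "")
            if not members:
                raise ValueError(f"{path}:{lineno}: module {label!r} has no members")
            modules.append((label, members))
    return ModuleSet(name=name, modules=modules)


def write_gene_sets(module_set: ModuleSet, path: str | Path, description: str = "na") -> None:
    """Write a :class:`ModuleSet` as GMT; members sorted for determinism."""
    path = Path(path)
    with path.open("w") as fh:
        for label, members in module_set.modules:
            fh.write(label + "\t" + description + "\t" + "\t".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header row of
    condition ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(values=df.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# weight vectors


def read_weights(path: str | Path) -> tuple[dict[str, float], dict[str, Role]]:
    """Read a weights TSV (``dataset_name<TAB>weight<TAB>role``). Returns
    (weights, roles) mappings."""
    weights: dict[str, float] = {}
    roles: dict[str, Role] = {}
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("dataset\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            name, w, role = fields[0], float(fields[1]), Role(fields[2])
            if name in weights:
                raise ValueError(f"{path}:{lineno}: duplicate dataset {name!r}")
            weights[name] = w
            roles[name] = role
    return weights, roles


def write_weights(weights: Mapping[str, float], roles: Mapping[str, Role], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("dataset\tweight\trole\n")
        for name in weights:
            fh.write(f"{name}\t{weights[name]!r}\t{roles[name].value}\n")


# ---------------------------------------------------------------------------
# optimization traces


def write_trace(trace, variable_names: Sequence[str], path: str | Path) -> None:
    """Write an optimization trace as TSV.

    Columns: iteration, candidate_nmi, best_nmi, then the candidate vector
    (``cand_<name>``) and best-so-far vector (``w_<name>``) per variable.
    The ``repr`` float format makes the round-trip exact.
    """
    path = Path(path)
    with path.open("w") as fh:
        header = (
            ["iteration", "candidate_nmi", "best_nmi"]
            + [f"cand_{n}" for n in variable_names]
            + [f"w_{n}" for n in variable_names]
        )
        fh.write("\t".join(header) + "\n")
        for rec in trace.records:
            row = (
                [str(rec.iteration), repr(rec.candidate_objective), repr(rec.best_objective)]
                + [repr(v) for v in rec.candidate]
                + [repr(v) for v in rec.best_vector]
            )
            fh.write("\t".join(row) + "\n")


def read_trace(path: str | Path):
    """Read a trace written by :func:`write_trace`. Returns
    (OptimizationTrace, variable_names)."""
    from .harmony import OptimizationTrace, TraceRecord

    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = [c[len("cand_"):] for c in header if c.startswith("cand_")]
        k = len(names)
        records = []
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 + 2 * k:
                continue
            records.append(
                TraceRecord(
                    iteration=int(f[0]),
                    candidate=tuple(float(x) for x in f[3:3 + k]),
                    candidate_objective=float(f[1]),
                    best_objective=float(f[2]),
                    best_vector=tuple(float(x) for x in f[3 + k:3 + 2 * k]),
                )
            )
    return OptimizationTrace(records=records), names


# ---------------------------------------------------------------------------
# weighted networks


def write_weighted_network(network: nx.Graph, path: str | Path, header: bool = True) -> None:
    """Write a weighted network as a three-column TSV with ``a < b`` per row.

    Weights are printed with ``repr`` (shortest exact representation), so the
    matching reader reconstructs them bit-for-bit. An empty network yields a
    header-only file when ``header`` is true, else an empty file.
    """
    path = Path(path)
    rows = sorted(normalize_pair(a, b) + (d["weight"],) for a, b, d in network.edges(data=True))
    with path.open("w") as fh:
        if header:
            fh.write("protein_a\tprotein_b\tweight\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def read_weighted_network(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_weighted_network`."""
    g = nx.Graph()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("protein_a\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            a, b, w = fields[0], fields[1], float(fields[2])
            g.add_edge(*normalize_pair(a, b), weight=w)
    return g
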