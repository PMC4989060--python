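"""Core containers for the differential-coexpression biomarker pipeline.

The pipeline moves through a fixed sequence of representations:

``ExpressionMatrix`` (genes x samples, one per condition)
    -> ``EdgeStatusTable`` (ternary coexpression status per gene pair,
       one per condition)
    -> ``SpecificNetwork`` (binary graph: score-filtered functional
       association edges that are coexpressed in at least one condition)
    -> ``ModuleSet`` / ``ModuleResult`` (graph partition + differential
       statistics per module)
    -> ``BiomarkerScore`` (per-gene specificity x coexpression-change
       product).

All gene pairs are stored as unordered, lexicographically sorted
2-tuples; :func:`gene_pair` is the single canonicalisation point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

from .errors import ConfigurationError

GenePair = tuple[str, str]


def gene_pair(a: str, b: str) -> GenePair:
    """Canonical unordered gene pair (lexicographically sorted tuple)."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued expression on log2 scale.

    ``data`` is indexed by gene id with one column per sample id.
    ``condition`` labels the cohort the samples come from
    (conventionally ``"normal"`` or ``"cancer"``).
    """

    data: pd.DataFrame
    condition: str

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.data.shape[1] < 2:
            raise ValueError("an expression matrix needs at least 2 samples")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EdgeStatusTable:
    """Ternary coexpression status per gene pair for one condition.

    Only nonzero statuses are stored; any pair absent from ``status``
    has status 0. ``pcc`` optionally retains the Pearson correlation of
    the stored pairs (or of every evaluated pair when requested).
    """

    condition: str
    status: dict[GenePair, int]
    pcc: dict[GenePair, float] | None = None
    n_pairs_evaluated: int = 0

    def __post_init__(self) -> None:
        bad = {p: s for p, s in self.status.items() if s not in (-1, 1)}
        if bad:
            raise ValueError(f"stored statuses must be +1/-1, got {bad}")

    def get(self, a: str, b: str) -> int:
        return self.status.get(gene_pair(a, b), 0)

    @property
    def positive_pairs(self) -> set[GenePair]:
        return {p for p, s in self.status.items() if s == 1}

    @property
    def negative_pairs(self) -> set[GenePair]:
        return {p for p, s in self.status.items() if s == -1}


@dataclass
class FunctionalNetwork:
    """Weighted functional-association edge list (STRING dialect).

    ``scores`` maps unordered gene pairs to integer combined scores in
    [0, 1000].
    """

    scores: dict[GenePair, int]

    def __post_init__(self) -> None:
        for (a, b), s in self.scores.items():
            if not (a < b):
                raise ValueError(f"pair {(a, b)} is not canonical; use gene_pair()")
            if not 0 <= s <= 1000:
                raise ValueError(f"score {s} for pair {(a, b)} outside [0, 1000]")

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, int]]) -> "FunctionalNetwork":
        """Build from (gene1, gene2, score) triples; duplicate unordered
        pairs keep the maximum score."""
        scores: dict[GenePair, int] = {}
        for a, b, s in edges:
            p = gene_pair(a, b)
            s = int(s)
            if p in scores:
                scores[p] = max(scores[p], s)
            else:
                scores[p] = s
        return cls(scores)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.scores:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: GenePair) -> bool:
        return pair in self.scores


@dataclass
class SpecificNetwork:
    """Condition-specific binary gene network.

    Every edge survives the functional-association score filter and is
    coexpressed (status +1 or -1) in at least one condition; each edge
    carries the pair ``(status_normal, status_cancer)``.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)

    def edge_statuses(self, gene: str) -> list[tuple[int, int]]:
        """(status_normal, status_cancer) for every edge incident to *gene*."""
        return [
            (d["status_normal"], d["status_cancer"])
            for _, _, d in self.graph.edges(gene, data=True)
        ]

    def iter_edges(self) -> Iterator[tuple[str, str, int, int]]:
        for u, v, d in self.graph.edges(data=True):
            a, b = gene_pair(u, v)
            yield a, b, d["status_normal"], d["status_cancer"]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.iter_edges())
        return pd.DataFrame(
            rows, columns=["gene1", "gene2", "status_normal", "status_cancer"]
        )


@dataclass(frozen=True)
class GeneModule:
    """A named disjoint gene set produced by network partitioning."""

    module_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"module {self.module_id} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    """A disjoint collection of gene modules from one partition run."""

    modules: list[GeneModule]
    partition_seed: int = 0
    algorithm_tag: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.modules:
            overlap = seen & m.genes
            if overlap:
                raise ValueError(
                    f"module {m.module_id} overlaps earlier modules: {sorted(overlap)[:5]}"
                )
            seen |= m.genes

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self) -> Iterator[GeneModule]:
        return iter(self.modules)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.genes
        return out

    def membership(self) -> dict[str, str]:
        return {g: m.module_id for m in self.modules for g in m.genes}

    def by_id(self, module_id: str) -> GeneModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


@dataclass
class ModuleResult:
    """Differential-expression statistics for one module."""

    module_id: str
    n_genes: int
    representative_normal: pd.Series
    representative_cancer: pd.Series
    t_pvalue: float
    adj_pvalue: float
    log_fold_change: float
    auc: float
    selected: bool
    direction: str  # "up" | "down"


@dataclass
class BiomarkerScore:
    """Per-gene biomarker candidacy score.

    ``final_score = (module_auc - 0.5) * change_score``; its sign gives
    the predicted regulation direction in the disease condition.
    """

    gene_id: str
    module_id: str
    module_auc: float
    specificity: float
    n_partners: int
    change_score: float
    final_score: float
    direction: str  # "up" | "down" | "none"
    rank: int | None = None


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)
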