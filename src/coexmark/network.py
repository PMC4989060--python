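"""Condition-specific network construction.

Per condition, every gene pair's Pearson correlation is computed and
the most extreme tails are labelled: the top fraction (default 1%) of
pairs ranked by PCC get coexpression status +1, the bottom fraction -1,
everything else 0. The functional-association network is filtered to
combined scores strictly greater than a cutoff (default 500), and the
condition-specific network keeps exactly the filtered edges whose pair
is coexpressed (nonzero status) in at least one condition. The result
is a binary graph whose edges carry both conditions' statuses.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .datatypes import (
    EdgeStatusTable,
    ExpressionMatrix,
    FunctionalNetwork,
    GenePair,
    SpecificNetwork,
    gene_pair,
)
from .errors import ConfigurationError
from .io import read_expression  # re-exported: loading lives with the builder

__all__ = [
    "read_expression",
    "normalize",
    "coexpression_status",
    "filter_functional_network",
    "build_specific_network",
]

logger = logging.getLogger(__name__)


def normalize(matrix: ExpressionMatrix, method: str = "quantile") -> ExpressionMatrix:
    """Normalise expression across samples.

    ``"quantile"`` forces every sample (column) onto the same empirical
    distribution — the mean of the column-wise sorted values; ties
    within a column receive the mean of their rank positions.
    ``"none"`` returns the input unchanged.
    """
    if method == "none":
        return matrix
    if method != "quantile":
        raise ConfigurationError(f"unknown normalization method {method!r}")
    values = matrix.data.to_numpy(dtype=float)
    n = values.shape[0]
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    from scipy.stats import rankdata

    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    data = matrix.data.copy()
    data.iloc[:, :] = out
    return ExpressionMatrix(data, condition=matrix.condition)


def _pair_universe_all(genes: Sequence[str]) -> list[GenePair]:
    ordered = sorted(genes)
    return [
        (ordered[i], ordered[j])
        for i in range(len(ordered))
        for j in range(i + 1, len(ordered))
    ]


def coexpression_status(
    matrix: ExpressionMatrix,
    pair_universe: Iterable[GenePair] | None = None,
    top_fraction: float = 0.01,
    keep_pcc: bool = False,
) -> EdgeStatusTable:
    """Ternary coexpression status for every pair in the universe.

    The universe defaults to all C(n, 2) pairs of the matrix; a supplied
    pair list (e.g. the filtered functional network's pairs) restricts
    it, silently skipping pairs with genes absent from the matrix. Pairs
    are ranked by PCC with ties broken by lexicographic pair order; the
    top ``ceil(top_fraction * N)`` become +1 and the bottom as many -1
    (never overlapping). Constant genes get PCC 0 for all their pairs,
    with a warning.
    """
    if not 0.0 < top_fraction < 0.5:
        raise ConfigurationError(f"top_fraction must lie in (0, 0.5), got {top_fraction}")
    if matrix.n_genes < 2:
        raise ValueError("need at least 2 genes to correlate")

    genes = matrix.gene_ids
    index = {g: i for i, g in enumerate(genes)}
    values = matrix.data.to_numpy(dtype=float)

    sd = values.std(axis=1)
    constant = [g for g, s in zip(genes, sd) if s == 0.0]
    if constant:
        logger.warning(
            "%d constant gene(s) (zero variance); their pairs get PCC 0: %s",
            len(constant), constant[:5],
        )

    if pair_universe is None:
        pairs = _pair_universe_all(genes)
    else:
        seen: set[GenePair] = set()
        pairs = []
        for a, b in pair_universe:
            p = gene_pair(a, b)
            if p[0] in index and p[1] in index and p not in seen:
                seen.add(p)
                pairs.append(p)
        pairs.sort()
    n_pairs = len(pairs)
    if n_pairs == 0:
        return EdgeStatusTable(condition=matrix.condition, status={}, n_pairs_evaluated=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)

    ii = np.fromiter((index[a] for a, _ in pairs), dtype=int, count=n_pairs)
    jj = np.fromiter((index[b] for _, b in pairs), dtype=int, count=n_pairs)
    pcc = corr[ii, jj]

    k = math.ceil(top_fraction * n_pairs)
    # pairs are in lexicographic order, so a stable sort on the PCC key
    # breaks ties by pair order
    top_order = np.argsort(-pcc, kind="stable")
    top_idx = top_order[:k]
    top_set = set(top_idx.tolist())
    bottom_order = np.argsort(pcc, kind="stable")
    bottom_idx = [i for i in bottom_order.tolist() if i not in top_set][:k]

    status: dict[GenePair, int] = {}
    for i in top_idx.tolist():
        status[pairs[i]] = 1
    for i in bottom_idx:
        status[pairs[i]] = -1

    pcc_map: dict[GenePair, float] | None = None
    if keep_pcc:
        pcc_map = {pairs[i]: float(pcc[i]) for i in range(n_pairs)}
    else:
        pcc_map = {p: float(pcc[i]) for i, p in ((i, pairs[i]) for i in list(top_idx) + bottom_idx)}
    return EdgeStatusTable(
        condition=matrix.condition,
        status=status,
        pcc=pcc_map,
        n_pairs_evaluated=n_pairs,
    )


def filter_functional_network(
    network: FunctionalNetwork, min_score: int = 500
) -> FunctionalNetwork:
    """Keep edges with combined score strictly greater than ``min_score``."""
    return FunctionalNetwork(
        {p: s for p, s in network.scores.items() if s > min_score}
    )


def build_specific_network(
    status_normal: EdgeStatusTable,
    status_cancer: EdgeStatusTable,
    filtered: FunctionalNetwork,
) -> SpecificNetwork:
    """Intersect coexpressed pairs with the filtered functional network.

    An edge enters the condition-specific network iff it survives the
    score filter and has nonzero coexpression status in at least one
    condition; it is annotated with ``(status_normal, status_cancer)``.
    Genes without any such edge are absent from the result.
    """
    graph = nx.Graph()
    for pair in sorted(filtered.scores):
        sn = status_normal.status.get(pair, 0)
        sc = status_cancer.status.get(pair, 0)
        if sn != 0 or sc != 0:
            graph.add_edge(pair[0], pair[1], status_normal=sn, status_cancer=sc)
    if graph.number_of_edges() == 0:
        logger.warning(
            "specific network is empty: no filtered functional edge is "
            "coexpressed in either condition"
        )
    return SpecificNetwork(graph)
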