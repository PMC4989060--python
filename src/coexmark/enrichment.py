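"""Gene-set enrichment and prediction-overlap validation.

Module enrichment uses the one-sided Fisher exact test for
over-representation of an annotated gene set within a module, against
a stated gene universe (by default the genes of the specific network,
since modules are drawn from it), with Benjamini-Hochberg adjustment
across all (module, set) tests.

The overlap-randomization test asks whether two predicted gene lists
share more genes than chance: it redraws one list uniformly from the
universe ``n_rand`` times and reports the add-one-corrected empirical
tail probability, alongside the closed-form hypergeometric tail as an
analytic companion.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneModule, GeneSetCollection
from .selection import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_enrichment",
    "enrich_modules",
    "overlap_randomization_test",
]


def fisher_enrichment(
    query: set[str], annotated: set[str], universe: set[str]
) -> float:
    """One-sided Fisher exact p for over-representation of *annotated* in *query*.

    Genes outside the universe are dropped (intersected) before
    building the 2x2 table.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    q = query & universe
    s = annotated & universe
    if len(q) < len(query) or len(s) < len(annotated):
        logger.debug(
            "intersected query/set with universe: %d/%d genes dropped",
            len(query) - len(q), len(annotated) - len(s),
        )
    a = len(q & s)
    b = len(q) - a
    c = len(s) - a
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def enrich_modules(
    modules: Iterable[GeneModule],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of every module against every gene set.

    Returns one row per (module, set) with the raw and BH-adjusted
    p-value (adjusted across all tests) and a flag marking each
    module's top set. ``universe`` defaults to the collection's.
    """
    universe = universe if universe is not None else collection.universe
    rows = []
    for module in modules:
        query = set(module.genes)
        for name in sorted(collection.sets):
            annotated = collection.sets[name]
            overlap = len(query & annotated & universe)
            p = fisher_enrichment(query, annotated, universe)
            rows.append(
                {"module": module.module_id, "gene_set": name,
                 "overlap": overlap, "p_value": p}
            )
    if not rows:
        return pd.DataFrame(columns=["module", "gene_set", "overlap", "p_value",
                                     "adj_p_value", "top_set"])
    table = pd.DataFrame(rows)
    table["adj_p_value"] = bh_adjust(table["p_value"].to_numpy())
    # per-module top hit: smallest p, ties by set name for reproducibility
    table = table.sort_values(["module", "p_value", "gene_set"], kind="stable")
    table["top_set"] = False
    top_idx = table.groupby("module", sort=False).head(1).index
    table.loc[top_idx, "top_set"] = True
    return table.reset_index(drop=True)


def overlap_randomization_test(
    list_a: set[str],
    list_b: set[str],
    universe: set[str],
    n_rand: int = 10_000,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Is the overlap of two gene lists larger than chance?

    Draws ``n_rand`` uniform without-replacement samples of size
    ``|list_b|`` from the universe and counts how often their overlap
    with ``list_a`` reaches the observed one. Returns
    ``(observed_overlap, empirical_p, hypergeometric_p)`` where the
    empirical p carries the add-one correction
    ``(1 + #{overlap >= observed}) / (n_rand + 1)`` — it can never be
    exactly 0 — and the hypergeometric p is the upper tail
    ``P(X >= observed)`` for ``X ~ Hypergeom(|U|, |A|, |B|)``.
    """
    if not list_a <= universe or not list_b <= universe:
        raise ValueError("both gene lists must be subsets of the universe")
    genes = sorted(universe)
    n = len(genes)
    if len(list_a) > n or len(list_b) > n:
        raise ValueError("gene lists larger than the universe")
    observed = len(list_a & list_b)
    in_a = np.fromiter((g in list_a for g in genes), dtype=bool, count=n)
    k = len(list_b)
    rng = np.random.default_rng(seed)

    hits = 0
    chunk = max(1, min(n_rand, int(5e7 // max(n, 1))))
    done = 0
    while done < n_rand:
        m = min(chunk, n_rand - done)
        # without-replacement sample per row: k smallest random keys
        keys = rng.random((m, n))
        picked = np.argpartition(keys, k - 1, axis=1)[:, :k] if k > 0 else np.empty((m, 0), int)
        overlaps = in_a[picked].sum(axis=1)
        hits += int((overlaps >= observed).sum())
        done += m
    empirical_p = (1 + hits) / (n_rand + 1)
    hyper_p = float(stats.hypergeom.sf(observed - 1, n, len(list_a), k))
    return observed, empirical_p, hyper_p
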