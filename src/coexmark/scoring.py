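"""Biomarker scoring and ranking.

Each gene of a selected module receives two component scores:

* cancer specificity — its module's AUC minus 0.5, so the sign encodes
  the module's regulation direction and the magnitude its
  discriminative power;
* coexpression change — the mean, over the gene's edges in the
  condition-specific network, of ``|status_cancer - status_normal|``
  (statuses in {+1, -1, 0}), which lies in [0, 2]: 2 means every
  partner correlation fully reversed sign, 0 means nothing changed.

The final score is their product; positive scores predict upregulated
biomarkers, negative downregulated ones, and genes whose coexpression
pattern did not change score 0 and are excluded from the ranking.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .datatypes import BiomarkerScore, ModuleResult, ModuleSet, SpecificNetwork

logger = logging.getLogger(__name__)

__all__ = ["change_score", "score_genes", "rank_biomarkers", "scores_frame"]


def change_score(
    gene: str, network: SpecificNetwork, within_module: frozenset[str] | None = None
) -> float:
    """Mean absolute coexpression-status difference over the gene's edges.

    ``within_module`` optionally restricts the partners counted to a
    gene set (the gene's own module); by default every network partner
    counts. A gene with no (counted) partner scores 0.
    """
    if gene not in network:
        raise KeyError(f"gene {gene!r} is not a node of the specific network")
    diffs = [
        abs(d["status_cancer"] - d["status_normal"])
        for _, v, d in network.graph.edges(gene, data=True)
        if within_module is None or v in within_module
    ]
    if not diffs:
        return 0.0
    return sum(diffs) / len(diffs)


def score_genes(
    selected: Iterable[ModuleResult],
    modules: ModuleSet,
    network: SpecificNetwork,
    within_module_only: bool = False,
) -> list[BiomarkerScore]:
    """Score every gene of every selected module.

    Genes absent from the network (or with no counted partner) get a
    change score of 0 and hence a zero final score.
    """
    scores: list[BiomarkerScore] = []
    for result in selected:
        if not result.selected:
            continue
        module = modules.by_id(result.module_id)
        restrict = module.genes if within_module_only else None
        specificity = result.auc - 0.5
        for gene in sorted(module.genes):
            if gene in network:
                cs = change_score(gene, network, within_module=restrict)
                n_partners = network.degree(gene)
            else:
                logger.warning(
                    "gene %s of module %s is absent from the specific network; "
                    "change score 0", gene, result.module_id,
                )
                cs = 0.0
                n_partners = 0
            final = specificity * cs
            direction = "up" if final > 0 else ("down" if final < 0 else "none")
            scores.append(
                BiomarkerScore(
                    gene_id=gene,
                    module_id=result.module_id,
                    module_auc=result.auc,
                    specificity=specificity,
                    n_partners=n_partners,
                    change_score=cs,
                    final_score=final,
                    direction=direction,
                )
            )
    return scores


def rank_biomarkers(
    scores: Iterable[BiomarkerScore], top_k: int = 10
) -> tuple[list[BiomarkerScore], list[BiomarkerScore]]:
    """Top-k upregulated and downregulated biomarker candidates.

    Genes with positive final score are ranked descending, negative
    ones ascending (most negative first); zero-score genes are
    excluded. Ties are broken by larger change score, then gene id.
    """
    up = [s for s in scores if s.final_score > 0]
    down = [s for s in scores if s.final_score < 0]
    up.sort(key=lambda s: (-s.final_score, -s.change_score, s.gene_id))
    down.sort(key=lambda s: (s.final_score, -s.change_score, s.gene_id))
    up, down = up[:top_k], down[:top_k]
    for rank, s in enumerate(up, start=1):
        s.rank = rank
    for rank, s in enumerate(down, start=1):
        s.rank = rank
    return up, down


def scores_frame(scores: Iterable[BiomarkerScore]) -> pd.DataFrame:
    """Tabular view of biomarker scores (one row per gene)."""
    rows = [
        {
            "gene": s.gene_id,
            "module": s.module_id,
            "auc": s.module_auc,
            "specificity": s.specificity,
            "n_partners": s.n_partners,
            "change_score": s.change_score,
            "final_score": s.final_score,
            "direction": s.direction,
            "rank": s.rank if s.rank is not None else "",
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "module", "auc", "specificity", "n_partners",
            "change_score", "final_score", "direction", "rank",
        ],
    )
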