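"""Disease-specific module identification.

Each module is summarised per sample by the median expression of its
genes ("representative expression"). Modules are then tested for
differential expression between conditions with a two-sided Welch
t-test, Benjamini-Hochberg adjusted across modules, and selected when
``adj_p <= fdr_cut`` and ``|log2 fold change| >= lfc_cut``. Module
specificity is quantified by the AUC of the ROC curve that uses the
representative expression to discriminate cancer (label 1) from normal
(label 0) samples: AUC > 0.5 means upregulated in cancer, < 0.5
downregulated, and distance from 0.5 measures specificity.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneModule, ModuleResult, ModuleSet

logger = logging.getLogger(__name__)

__all__ = [
    "representative_expression",
    "module_t_test",
    "bh_adjust",
    "module_log_fold_change",
    "module_auc",
    "select_specific_modules",
]


def representative_expression(
    module: GeneModule, matrix: ExpressionMatrix
) -> pd.Series:
    """Per-sample median expression over the module's genes.

    Genes absent from the matrix are dropped with a warning; a module
    with no gene in the matrix is an error.
    """
    present = [g for g in sorted(module.genes) if g in matrix.data.index]
    missing = len(module.genes) - len(present)
    if not present:
        raise ValueError(
            f"module {module.module_id}: none of its {len(module.genes)} genes "
            f"are in the {matrix.condition} matrix"
        )
    if missing:
        logger.warning(
            "module %s: %d gene(s) absent from the %s matrix, using %d",
            module.module_id, missing, matrix.condition, len(present),
        )
    return matrix.data.loc[present].median(axis=0)


def module_t_test(rep_normal: Sequence[float], rep_cancer: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value between representative vectors.

    Degenerate input (both vectors constant) yields p = 1 with a
    warning, since no variance estimate exists.
    """
    a = np.asarray(rep_normal, dtype=float)
    b = np.asarray(rep_cancer, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs >= 2 values per group")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        logger.warning("both representative vectors are constant; returning p = 1")
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # pragma: no cover - guarded above
        return 1.0
    return p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def module_log_fold_change(
    rep_normal: Sequence[float],
    rep_cancer: Sequence[float],
    scale: str = "linear",
) -> float:
    """log2 fold change of cancer over normal representative expression.

    ``scale="linear"`` (default) back-transforms the log2-scale
    representative values to linear scale before averaging:
    ``log2(mean(2**rep_cancer) / mean(2**rep_normal))``. ``scale="log"``
    takes the difference of the log2-scale means directly.
    """
    a = np.asarray(rep_normal, dtype=float)
    b = np.asarray(rep_cancer, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("representative vectors must be nonempty")
    if scale == "log":
        return float(b.mean() - a.mean())
    if scale != "linear":
        raise ValueError(f"unknown fold-change scale {scale!r}")
    mean_n = np.exp2(a).mean()
    mean_c = np.exp2(b).mean()
    if mean_n <= 0 or mean_c <= 0:
        raise ValueError("linear-scale means must be positive")
    return float(np.log2(mean_c / mean_n))


def module_auc(rep_values: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve for binary labels (1 = cancer).

    Computed as the Mann-Whitney U statistic normalised by ``n1 * n0``,
    with tied values receiving half credit — identical to sweeping a
    threshold over the sorted values and integrating the ROC curve by
    the trapezoid rule.
    """
    v = np.asarray(rep_values, dtype=float)
    y = np.asarray(labels)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    ranks = stats.rankdata(v)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def select_specific_modules(
    mods: ModuleSet | Iterable[GeneModule],
    normal: ExpressionMatrix,
    cancer: ExpressionMatrix,
    fdr_cut: float = 0.01,
    lfc_cut: float = 2.0,
    lfc_scale: str = "linear",
) -> list[ModuleResult]:
    """Test every module and flag the disease-specific ones.

    A module is selected iff its BH-adjusted Welch p-value is at most
    ``fdr_cut`` and its absolute log2 fold change is at least
    ``lfc_cut``. The AUC is computed on the concatenated representative
    values with cancer samples labelled 1 and normal samples 0.
    """
    modules = list(mods)
    if not modules:
        return []
    shared = set(normal.sample_ids) & set(cancer.sample_ids)
    if shared:
        raise ValueError(
            f"normal and cancer matrices share sample ids (e.g. {sorted(shared)[:3]})"
        )

    reps = [
        (representative_expression(m, normal), representative_expression(m, cancer))
        for m in modules
    ]
    pvals = [module_t_test(rn, rc) for rn, rc in reps]
    adj = bh_adjust(pvals)

    results: list[ModuleResult] = []
    for m, (rn, rc), p, q in zip(modules, reps, pvals, adj):
        lfc = module_log_fold_change(rn, rc, scale=lfc_scale)
        values = np.concatenate([rn.to_numpy(), rc.to_numpy()])
        labels = np.concatenate([np.zeros(len(rn), dtype=int), np.ones(len(rc), dtype=int)])
        auc = module_auc(values, labels)
        selected = bool(q <= fdr_cut and abs(lfc) >= lfc_cut)
        results.append(
            ModuleResult(
                module_id=m.module_id,
                n_genes=len(m.genes),
                representative_normal=rn,
                representative_cancer=rc,
                t_pvalue=float(p),
                adj_pvalue=float(q),
                log_fold_change=lfc,
                auc=auc,
                selected=selected,
                direction="up" if auc > 0.5 else "down",
            )
        )
    n_sel = sum(r.selected for r in results)
    logger.info("selected %d of %d modules (FDR <= %g, |log2FC| >= %g)",
                n_sel, len(results), fdr_cut, lfc_cut)
    return results


def results_frame(results: Iterable[ModuleResult]) -> pd.DataFrame:
    """Tabular summary of module results (one row per module)."""
    rows = [
        {
            "module_id": r.module_id,
            "n_genes": r.n_genes,
            "t_pvalue": r.t_pvalue,
            "adj_pvalue": r.adj_pvalue,
            "log_fold_change": r.log_fold_change,
            "auc": r.auc,
            "selected": r.selected,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
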