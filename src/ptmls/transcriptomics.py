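"""PTM-related differential expression screen.

Differentially expressed genes among a curated post-translational-
modification (PTM) gene list are called on log2-scale expression with a
Welch two-sample t-test and Benjamini-Hochberg FDR over the tested PTM
genes; a gene is significant iff FDR < 0.05 and |log2 fold change| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["DEGResult", "bh_fdr", "differential_expression",
           "PTM_CATEGORIES", "FDR_CUTOFF", "LOG2FC_CUTOFF"]

FDR_CUTOFF = 0.05
LOG2FC_CUTOFF = 1.0

PTM_CATEGORIES = (
    "ubiquitination", "glycosylation", "deubiquitination", "methylation",
    "neddylation", "palmitoylation", "phosphorylation", "succinylation",
    "S-nitrosylation", "sumoylation", "acetylation", "other",
)


@dataclass
class DEGResult:
    gene: str
    log2fc: float
    p: float
    fdr: float
    ptm_category: str
    significant: bool


def bh_fdr(pvals):
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(expr, groups, ptm_genes):
    """Welch-t + BH screen restricted to PTM genes.

    Parameters
    ----------
    expr : DataFrame, genes x samples, log2-scale normalized values.
    groups : mapping or Series sample -> {0, 1} (0 = reference, e.g. normal).
    ptm_genes : mapping gene -> PTM category.

    Returns
    -------
    list of DEGResult, one per tested gene (PTM list ∩ matrix rows), in
    matrix row order. log2fc = mean(group1) - mean(group0).
    """
    groups = pd.Series(groups)
    groups = groups.reindex(expr.columns).dropna().astype(int)
    g0 = groups.index[groups == 0]
    g1 = groups.index[groups == 1]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("each group needs >= 2 samples")
    if not ptm_genes:
        raise ValueError("ptm_genes must be nonempty")
    tested = [g for g in expr.index if g in ptm_genes]
    if not tested:
        return []
    x0 = expr.loc[tested, g0].to_numpy(float)
    x1 = expr.loc[tested, g1].to_numpy(float)
    lfc = x1.mean(axis=1) - x0.mean(axis=1)
    t, p = stats.ttest_ind(x1, x0, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = bh_fdr(p)
    res = []
    for i, g in enumerate(tested):
        sig = bool(fdr[i] < FDR_CUTOFF and abs(lfc[i]) > LOG2FC_CUTOFF)
        cat = ptm_genes[g]
        if cat not in PTM_CATEGORIES:
            cat = "other"
        res.append(DEGResult(gene=g, log2fc=float(lfc[i]), p=float(p[i]),
                             fdr=float(fdr[i]), ptm_category=cat,
                             significant=sig))
    return res


def deg_table(results):
    """DEGResult list as a tidy DataFrame."""
    return pd.DataFrame([r.__dict__ for r in results])
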