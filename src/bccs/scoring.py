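"""Per-sample signature and module scores.

The cell cycle score (CCS) of a sample is the plain sum of its log
expression over the signature genes; a proliferation metagene or hormone
module is instead summarised as the mean of per-gene z-scores so that
modules of unequal size stay comparable. Signature genes absent from the
matrix are counted and dropped, never imputed; scoring aborts if more than
a configurable fraction of the signature is missing.
"""

from __future__ import annotations

import logging
from typing import Tuple

from scipy import stats

from .containers import ExpressionMatrix, GeneSet, ScoreTable, ValidationError

logger = logging.getLogger(__name__)


def compute_signature_score(
    expr: ExpressionMatrix,
    signature: GeneSet,
    max_missing_frac: float = 0.2,
) -> ScoreTable:
    """Sum log-expression of the signature genes present in the matrix."""
    present = [g for g in expr.gene_ids if g in signature.genes]
    n_missing = len(signature) - len(present)
    if not present:
        raise ValidationError(
            f"signature {signature.name!r} has no genes in the expression matrix"
        )
    if n_missing / len(signature) > max_missing_frac:
        raise ValidationError(
            f"signature {signature.name!r}: {n_missing}/{len(signature)} genes "
            f"missing exceeds the {max_missing_frac:.0%} ceiling"
        )
    if n_missing:
        logger.warning(
            "signature %s: %d of %d genes missing from matrix; dropped",
            signature.name, n_missing, len(signature),
        )
    raw = expr.frame.loc[present].sum(axis=0)
    return ScoreTable(
        raw=raw,
        signature_name=signature.name,
        n_genes_used=len(present),
        n_genes_missing=n_missing,
    )


def minmax_rescale(scores: ScoreTable) -> ScoreTable:
    """Affinely map raw scores onto [0, 1]; rank order is preserved."""
    if len(scores.raw) < 2:
        raise ValidationError("need at least 2 samples to rescale")
    lo, hi = float(scores.raw.min()), float(scores.raw.max())
    if hi == lo:
        raise ValidationError("degenerate range: all scores equal")
    scaled = (scores.raw - lo) / (hi - lo)
    return ScoreTable(
        raw=scores.raw,
        signature_name=scores.signature_name,
        n_genes_used=scores.n_genes_used,
        n_genes_missing=scores.n_genes_missing,
        scaled=scaled,
    )


def compute_module_score(expr: ExpressionMatrix, module: GeneSet) -> ScoreTable:
    """Mean of per-gene z-scored expression over the module genes.

    Zero-variance genes carry no ranking information and would divide by
    zero, so they are excluded with a warning.
    """
    present = [g for g in expr.gene_ids if g in module.genes]
    if not present:
        raise ValidationError(
            f"module {module.name!r} has no genes in the expression matrix"
        )
    sub = expr.frame.loc[present]
    sd = sub.std(axis=1, ddof=1)
    usable = sd[sd > 0].index
    dropped = len(present) - len(usable)
    if dropped:
        logger.warning(
            "module %s: %d zero-variance gene(s) excluded", module.name, dropped
        )
    if not len(usable):
        raise ValidationError(
            f"module {module.name!r}: all genes have zero variance"
        )
    sub = sub.loc[usable]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[usable], axis=0)
    return ScoreTable(
        raw=z.mean(axis=0),
        signature_name=module.name,
        n_genes_used=len(usable),
        n_genes_missing=len(module) - len(usable),
    )


def correlate_scores(
    a: ScoreTable, b: ScoreTable, method: str = "pearson"
) -> Tuple[float, float]:
    """Correlate two score tables over their shared samples (two-sided)."""
    shared = a.raw.index.intersection(b.raw.index)
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared samples")
    x = a.raw.loc[shared].to_numpy()
    y = b.raw.loc[shared].to_numpy()
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(r), float(p)
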