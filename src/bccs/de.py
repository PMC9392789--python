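"""Covariate-adjusted differential expression with empirical-Bayes
moderated t-statistics.

Each gene is fit by ordinary least squares on a cell-means design (one
indicator per cancer type, so the grouping is nested without collinearity)
plus the ESR1 log expression as a continuous covariate to absorb the broad
hormonal axis. The group-2 vs group-1 effect is the contrast

    log2FC = mean(group-2 type means) - mean(group-1 type means),

and per-gene residual variances s_g^2 (d residual df each) are shrunk
toward a prior s0^2 with d0 prior df,

    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

where (d0, s0^2) are estimated by moment matching of log s_g^2 against the
scaled-F distribution it follows under the hierarchical model. The
moderated t = log2FC / (se * s~_g) is referred to a t distribution with
d0 + d degrees of freedom. d0 = 0 recovers the ordinary OLS t; d0 = inf
pools every gene's variance at s0^2.
"""

from __future__ import annotations

import logging
import warnings
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import (
    ExpressionMatrix,
    GroupAssignment,
    SampleManifest,
    ScoreTable,
    ValidationError,
)
from .genomic import benjamini_hochberg

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df_resid: float) -> Tuple[float, float]:
    """Moment-match (prior_df d0, prior_var s0^2) from per-gene sample
    variances with common residual df.

    Works on z = log(s^2): under the model z - log(s0^2) is a log-F
    variate whose mean and variance are digamma/trigamma expressions in
    (d/2, d0/2); matching the empirical mean and variance of z yields the
    estimates. An empirical variance no larger than the sampling noise
    trigamma(d/2) gives d0 = inf (all true variances equal).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        raise ValidationError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - special.polygamma(0, df_resid / 2) + np.log(df_resid / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df_resid / 2)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.polygamma(0, d0 / 2) - np.log(d0 / 2))
    else:
        d0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(d0), float(s0_sq)


def moderate_variances(
    s2: np.ndarray, df_resid: float, d0: float, s0_sq: float
) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s0_sq)
    if d0 == 0:
        return np.asarray(s2, dtype=float)
    return (d0 * s0_sq + df_resid * np.asarray(s2, dtype=float)) / (d0 + df_resid)


# ---------------------------------------------------------------------------
# design + fit


def _build_design(
    expr: ExpressionMatrix,
    manifest: SampleManifest,
    groups: GroupAssignment,
    esr1_gene: Optional[str],
) -> Tuple[List[str], np.ndarray, np.ndarray, List[str]]:
    """Sample ids, design matrix, contrast vector, column names."""
    frame = manifest.frame
    tumors = frame[
        (frame["study"] == "TCGA_TUMOR")
        & frame["cancer_type"].isin(groups.group1 | groups.group2)
        & frame["sample_id"].isin(expr.sample_ids)
    ]
    if tumors.empty:
        raise ValidationError("no tumour samples from either group in the matrix")
    sample_ids = list(tumors["sample_id"])
    types = sorted(set(tumors["cancer_type"]))
    type_of = tumors.set_index("sample_id")["cancer_type"]
    columns = []
    names = []
    for t in types:
        columns.append((type_of.loc[sample_ids] == t).to_numpy(dtype=float))
        names.append(f"type_{t}")
    if esr1_gene is not None:
        if esr1_gene not in expr.gene_ids:
            raise ValidationError(
                f"covariate gene {esr1_gene!r} absent from the expression matrix"
            )
        columns.append(expr.frame.loc[esr1_gene, sample_ids].to_numpy(dtype=float))
        names.append(esr1_gene)
    X = np.column_stack(columns)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _find_aliased(X, names)
        raise ValidationError(f"rank-deficient design; aliased column(s): {aliased}")
    g1_types = [t for t in types if t in groups.group1]
    g2_types = [t for t in types if t in groups.group2]
    if not g1_types or not g2_types:
        raise ValidationError("each group needs at least one cancer type with samples")
    contrast = np.zeros(X.shape[1])
    for t in g2_types:
        contrast[names.index(f"type_{t}")] = 1.0 / len(g2_types)
    for t in g1_types:
        contrast[names.index(f"type_{t}")] = -1.0 / len(g1_types)
    return sample_ids, X, contrast, names


def _find_aliased(X: np.ndarray, names: List[str]) -> List[str]:
    aliased = []
    full_rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1]):
        reduced = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            aliased.append(names[j])
    return aliased or names


def fit_moderated_de(
    expr: ExpressionMatrix,
    manifest: SampleManifest,
    groups: GroupAssignment = GroupAssignment(),
    esr1_gene: Optional[str] = "ESR1",
    prior_df: Optional[float] = None,
    lfc_threshold: float = 2.0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Moderated differential expression of group 2 vs group 1.

    Returns a frame with columns gene_id, log2_fc, t_moderated, p, q,
    significant (|log2FC| strictly above ``lfc_threshold`` and q below
    ``fdr``); the estimated (d0, s0^2) are stored in ``.attrs``. Pass
    ``prior_df`` to override the estimated prior df (0 disables shrinkage,
    ``np.inf`` pools all variances).
    """
    sample_ids, X, contrast, names = _build_design(expr, manifest, groups, esr1_gene)
    test_genes = [g for g in expr.gene_ids if g != esr1_gene]
    if esr1_gene in expr.gene_ids and esr1_gene is not None:
        logger.info("covariate gene %s excluded from the tested genes", esr1_gene)
    Y = expr.frame.loc[test_genes, sample_ids].to_numpy()  # genes x samples
    n, p_cols = X.shape
    df_resid = n - p_cols
    if df_resid < 2:
        raise ValidationError(f"only {df_resid} residual df; need >= 2")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # genes x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid
    c_var = float(contrast @ xtx_inv @ contrast)

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, df_resid)
    s2_mod = moderate_variances(s2, df_resid, d0, s0_sq)

    log2_fc = beta @ contrast
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2_fc / np.sqrt(c_var * s2_mod)
    df_total = d0 + df_resid
    zero_var = s2_mod == 0
    if zero_var.any():
        logger.warning(
            "%d gene(s) with zero moderated variance: p set to 0 (nonzero "
            "effect) or 1 (zero effect)", int(zero_var.sum()),
        )
        t = np.where(zero_var & (log2_fc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(np.isnan(t), 1.0, p)
    t = np.nan_to_num(t, nan=0.0)

    q = benjamini_hochberg(p)
    result = pd.DataFrame(
        {
            "gene_id": test_genes,
            "log2_fc": log2_fc,
            "t_moderated": t,
            "p": p,
            "q": q,
        }
    )
    result["significant"] = (np.abs(result["log2_fc"]) > lfc_threshold) & (
        result["q"] < fdr
    )
    result.attrs["d0"] = d0
    result.attrs["s0_sq"] = s0_sq
    result.attrs["df_resid"] = df_resid
    result.attrs["design_columns"] = names
    return result


def volcano_partition(
    results: pd.DataFrame, lfc_threshold: float = 2.0
) -> Tuple[List[str], List[str]]:
    """Significant genes split into up (log2FC > threshold, strict) and
    down (log2FC < -threshold) lists."""
    if results.empty:
        return [], []
    sig = results[results["significant"]]
    up = list(sig.loc[sig["log2_fc"] > lfc_threshold, "gene_id"])
    down = list(sig.loc[sig["log2_fc"] < -lfc_threshold, "gene_id"])
    return up, down


def rank_statistic(results: pd.DataFrame, mode: str = "signed_logp") -> pd.Series:
    """Gene ranking for preranked GSEA, ordered from most up- to most
    down-regulated.

    Default ``signed_logp`` combines effect direction and evidence:
    sign(log2FC) * (-log10 p). Ties are broken by |log2FC| (descending),
    then gene id.
    """
    if results["p"].isna().any():
        raise ValidationError("NaN p-values in DE results")
    res = results.copy()
    if (res["p"] == 0).any():
        tiny = np.nextafter(0, 1)
        warnings.warn("p == 0 replaced by smallest positive float for ranking")
        res.loc[res["p"] == 0, "p"] = tiny
    if mode == "signed_logp":
        stat = np.sign(res["log2_fc"]) * (-np.log10(res["p"]))
    elif mode == "t_stat":
        stat = res["t_moderated"].astype(float)
    elif mode == "log2fc":
        stat = res["log2_fc"].astype(float)
    else:
        raise ValueError(f"unknown rank statistic mode: {mode!r}")
    res = res.assign(_stat=stat.to_numpy(), _abs_fc=res["log2_fc"].abs())
    res = res.sort_values(
        ["_stat", "_abs_fc", "gene_id"], ascending=[False, False, True]
    )
    return pd.Series(res["_stat"].to_numpy(), index=res["gene_id"].to_numpy(),
                     name=mode)


# ---------------------------------------------------------------------------
# module t-tests and per-gene correlation to BC-CCS

_STAR_LEVELS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def _stars(q: float) -> str:
    for cutoff, stars in _STAR_LEVELS:
        if q < cutoff:
            return stars
    return "ns"


ScoreLike = Union[ScoreTable, pd.Series]


def _as_series(scores: ScoreLike) -> pd.Series:
    return scores.raw if isinstance(scores, ScoreTable) else scores


def module_ttest(
    scores_g1: Mapping[str, ScoreLike],
    scores_g2: Mapping[str, ScoreLike],
) -> pd.DataFrame:
    """Two-sided Student's t-test per module, BH-corrected across modules,
    with significance stars mapped from q."""
    modules = list(scores_g1)
    if set(modules) != set(scores_g2):
        raise ValidationError("module names differ between groups")
    rows = []
    for name in modules:
        x = _as_series(scores_g1[name]).to_numpy(dtype=float)
        y = _as_series(scores_g2[name]).to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise ValidationError(f"module {name!r}: need >= 2 samples per group")
        if np.var(x) == 0 and np.var(y) == 0:
            if np.mean(x) == np.mean(y):
                t_val, p_val = 0.0, 1.0
            else:
                raise ValidationError(
                    f"module {name!r}: zero within-group variance in both groups"
                )
        else:
            t_val, p_val = stats.ttest_ind(x, y)
        rows.append({"module": name, "t": float(t_val), "p": float(p_val)})
    result = pd.DataFrame(rows)
    result["q"] = benjamini_hochberg(result["p"])
    result["stars"] = result["q"].map(_stars)
    return result


def correlate_genes_to_bccs(
    expr: ExpressionMatrix,
    bc: pd.DataFrame,
    genes: Sequence[str],
    rho_reference: float = 0.3,
) -> pd.DataFrame:
    """Spearman correlation of each gene's expression to the scaled BC-CCS.

    ``passes_reference_line`` marks rho strictly above ``rho_reference``;
    constant genes get NaN rho with a warning.
    """
    shared = [s for s in bc.index if s in set(expr.sample_ids)]
    if len(shared) < 10:
        raise ValidationError("need at least 10 shared samples")
    target = bc.loc[shared, "bc_scaled"].to_numpy(dtype=float)
    rows = []
    for gene in genes:
        if gene not in expr.gene_ids:
            raise ValidationError(f"gene {gene!r} not in expression matrix")
        x = expr.frame.loc[gene, shared].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("gene %s is constant; rho undefined", gene)
            rows.append({"gene_id": gene, "rho": np.nan, "p": np.nan,
                         "passes_reference_line": False})
            continue
        rho, p = stats.spearmanr(x, target)
        rows.append(
            {
                "gene_id": gene,
                "rho": float(rho),
                "p": float(p),
                "passes_reference_line": bool(rho > rho_reference),
            }
        )
    return pd.DataFrame(rows)
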