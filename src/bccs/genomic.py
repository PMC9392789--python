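"""Group 1 vs group 2 comparisons of driver mutations and arm-level calls.

Displayed frequencies are macro-averaged over cancer types (the mean of
within-type frequencies), so a large cancer type cannot dominate the
percentage; the Fisher exact test is run on pooled per-group counts, with
a Cochran-Mantel-Haenszel stratified alternative available. Amplifications
(+1) and deletions (-1) are tested separately per chromosome arm, each
direction carrying its own BH-FDR correction.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .containers import (
    GroupAssignment,
    SampleManifest,
    ValidationError,
    validate_arm_calls,
    validate_binary_matrix,
)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@lru_cache(maxsize=8)
def _log_factorials(n_max: int) -> np.ndarray:
    return special.gammaln(np.arange(n_max + 2, dtype=float) + 1.0)


def fisher_feature_test(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    The p-value sums the conditional hypergeometric probabilities of every
    table (with the same margins) no more probable than the observed one —
    the same two-sided rule scipy applies, evaluated here over the whole
    support at once via log-gamma, which keeps exhaustive screens over
    many tables fast. The odds ratio is the sample cross-product ratio
    (inf when only the k2 margin carries the zero cell).
    """
    for value in (k1, n1, k2, n2):
        if value < 0:
            raise ValidationError("counts must be non-negative")
    if k1 > n1 or k2 > n2:
        raise ValidationError("k cannot exceed n")
    if n1 < 1 or n2 < 1:
        raise ValidationError("both groups must be non-empty")
    K, N = k1 + k2, n1 + n2
    lf = _log_factorials(max(N, 1024))
    lo, hi = max(0, K - n2), min(K, n1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        lf[n1] - lf[support] - lf[n1 - support]
        + lf[n2] - lf[K - support] - lf[n2 - (K - support)]
        - (lf[N] - lf[K] - lf[N - K])
    )
    pmf = np.exp(logpmf)
    observed = pmf[k1 - lo]
    # relative slop absorbs floating-point ties, as in scipy.stats.fisher_exact
    p = min(1.0, float(pmf[pmf <= observed * (1 + 1e-7)].sum()))
    num = k1 * (n2 - k2)
    den = (n1 - k1) * k2
    if den == 0:
        odds = np.nan if num == 0 else np.inf
    else:
        odds = num / den
    return float(odds), p


def _group_samples(
    manifest: SampleManifest, groups: GroupAssignment, available: Iterable[str]
) -> Tuple[pd.Series, pd.Series]:
    frame = manifest.frame
    known_types = set(frame["cancer_type"])
    for label, group in (("group1", groups.group1), ("group2", groups.group2)):
        unknown = sorted(set(group) - known_types)
        if unknown:
            raise ValidationError(f"{label} cancer type(s) not in manifest: {unknown}")
    available = set(available)
    tumors = frame[(frame["study"] == "TCGA_TUMOR") & frame["sample_id"].isin(available)]
    g1 = tumors[tumors["cancer_type"].isin(groups.group1)]
    g2 = tumors[tumors["cancer_type"].isin(groups.group2)]
    if len(g1) == 0 or len(g2) == 0:
        raise ValidationError("a comparison group has no samples with data")
    return g1.set_index("sample_id")["cancer_type"], g2.set_index("sample_id")["cancer_type"]


def adjusted_frequency(
    binary_feature: pd.Series,
    manifest: SampleManifest,
    group: Iterable[str],
) -> float:
    """Macro-averaged percentage: mean over the group's cancer types of the
    within-type feature frequency, x100."""
    group = set(group)
    if not group:
        raise ValidationError("empty group")
    frame = manifest.frame
    tumors = frame[
        (frame["study"] == "TCGA_TUMOR")
        & frame["cancer_type"].isin(group)
        & frame["sample_id"].isin(binary_feature.index)
    ]
    if tumors.empty:
        raise ValidationError("no samples with feature data in group")
    per_type = binary_feature.loc[tumors["sample_id"]].groupby(
        tumors.set_index("sample_id")["cancer_type"]
    ).mean()
    missing = sorted(group - set(per_type.index))
    if missing:
        raise ValidationError(f"cancer type(s) without feature data: {missing}")
    return float(per_type.mean() * 100.0)


def _cmh_test(
    feature: pd.Series, g1: pd.Series, g2: pd.Series, strata: pd.Series
) -> Tuple[float, float]:
    """Cochran-Mantel-Haenszel test across user-supplied strata.

    Cancer type cannot serve as the stratum because types are nested
    within the two groups (every stratum would contain a single group);
    the caller must supply a stratum label that cuts across both groups.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    membership = pd.Series(
        np.concatenate([np.zeros(len(g1), dtype=int), np.ones(len(g2), dtype=int)]),
        index=list(g1.index) + list(g2.index),
    )
    tables = []
    for _, ids in strata.loc[membership.index].groupby(
        strata.loc[membership.index]
    ).groups.items():
        f = feature.loc[ids].to_numpy()
        m = membership.loc[ids].to_numpy()
        if len(set(m)) < 2:
            raise ValidationError(
                "a CMH stratum contains members of only one group; "
                "strata must cut across both groups"
            )
        tables.append(
            np.array(
                [
                    [(f[m == 1] == 1).sum(), (f[m == 1] == 0).sum()],
                    [(f[m == 0] == 1).sum(), (f[m == 0] == 0).sum()],
                ]
            )
        )
    st = StratifiedTable(tables)
    result = st.test_null_odds(correction=False)
    return float(st.oddsratio_pooled), float(result.pvalue)


def _compare_features(
    matrix: pd.DataFrame,
    manifest: SampleManifest,
    groups: GroupAssignment,
    method: str,
    strata: Optional[pd.Series] = None,
) -> pd.DataFrame:
    g1, g2 = _group_samples(manifest, groups, matrix.columns)
    g1_ids, g2_ids = list(g1.index), list(g2.index)
    if method == "cmh" and strata is None:
        raise ValidationError("cmh method requires a strata series")
    rows = []
    for feature_id, feature in matrix.iterrows():
        k1 = int(feature.loc[g1_ids].sum())
        k2 = int(feature.loc[g2_ids].sum())
        n1, n2 = len(g1_ids), len(g2_ids)
        if method == "pooled":
            odds, p = fisher_feature_test(k1, n1, k2, n2)
        elif method == "cmh":
            odds, p = _cmh_test(feature, g1, g2, strata)
        else:
            raise ValueError(f"unknown method: {method!r}")
        rows.append(
            {
                "feature_id": feature_id,
                "adj_freq_g1": adjusted_frequency(feature, manifest, groups.group1),
                "adj_freq_g2": adjusted_frequency(feature, manifest, groups.group2),
                "k1": k1,
                "n1": n1,
                "k2": k2,
                "n2": n2,
                "odds_ratio": odds,
                "p": p,
            }
        )
    result = pd.DataFrame(rows)
    result["q"] = benjamini_hochberg(result["p"])
    return result


def compare_mutations(
    mutations: pd.DataFrame,
    manifest: SampleManifest,
    groups: GroupAssignment = GroupAssignment(),
    method: str = "pooled",
    strata: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per driver gene: macro-averaged frequencies, Fisher p, BH q.

    Sort by ``adj_freq_g1``/``adj_freq_g2`` to reproduce a top-20 most
    mutated view, or filter ``adj_freq_g2 > adj_freq_g1`` with ``q < 0.05``
    for the group-2-enriched genes.
    """
    mutations = validate_binary_matrix(mutations, "mutation")
    return _compare_features(mutations, manifest, groups, method, strata)


def compare_arm_calls(
    arm_calls: pd.DataFrame,
    manifest: SampleManifest,
    groups: GroupAssignment = GroupAssignment(),
    method: str = "pooled",
    strata: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per arm and direction: amplification (+1) and deletion (-1) calls
    tested separately, BH-FDR within each direction."""
    arm_calls = validate_arm_calls(arm_calls)
    pieces = []
    for direction, code, suffix in (("amplification", 1, "amp"), ("deletion", -1, "del")):
        binary = (arm_calls == code).astype(int)
        result = _compare_features(binary, manifest, groups, method, strata)
        result["arm"] = result["feature_id"]
        result["direction"] = direction
        result["feature_id"] = result["arm"].astype(str) + "_" + suffix
        pieces.append(result)
    return pd.concat(pieces, ignore_index=True)


def enriched_in_group2(results: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Features significant at the given FDR with a higher macro-averaged
    frequency in group 2 (a post-hoc direction filter on two-sided tests)."""
    mask = (results["q"] < fdr) & (results["adj_freq_g2"] > results["adj_freq_g1"])
    return results[mask].reset_index(drop=True)
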