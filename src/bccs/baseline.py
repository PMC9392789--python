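"""Baseline correction of tumour cell-cycle scores and quadrant calls.

A tumour's baseline-corrected score (BC-CCS) is its CCS minus the median
CCS of normal samples from its tissue of origin — GTEx normals only, since
they anchor the baseline; TCGA adjacent-normals are kept for plotting but
never enter the median. The corrected score is then multiplied by the
tumour's purity (the fraction of malignant cells, so a low-purity sample's
apparent uplift is discounted), and finally min-max rescaled to [0, 1].
The order of operations is fixed: subtract baseline, multiply by purity,
rescale.
"""

from __future__ import annotations

import logging
import numpy as np
import pandas as pd

from .containers import (
    SampleManifest,
    ScoreTable,
    ValidationError,
    validate_purity,
)

logger = logging.getLogger(__name__)

QUADRANTS = ("LOW_LOW", "LOW_HIGH", "HIGH_LOW", "HIGH_HIGH")


def compute_baselines(scores: ScoreTable, manifest: SampleManifest) -> pd.DataFrame:
    """Per-tissue median CCS over GTEX normal samples.

    Returns a frame indexed by tissue with columns ``median_normal_ccs``
    and ``n_normals``. Every tissue that carries tumours must have at least
    one scored GTEX normal.
    """
    frame = manifest.frame
    gtex = frame[frame["study"] == "GTEX"]
    gtex = gtex[gtex["sample_id"].isin(scores.raw.index)]
    grouped = scores.raw.loc[gtex["sample_id"]].groupby(
        gtex.set_index("sample_id")["tissue"]
    )
    baselines = pd.DataFrame(
        {"median_normal_ccs": grouped.median(), "n_normals": grouped.size()}
    )
    tumor_tissues = set(frame.loc[frame["study"] == "TCGA_TUMOR", "tissue"])
    missing = sorted(tumor_tissues - set(baselines.index))
    if missing:
        raise ValidationError(
            f"tumour tissue(s) without scored GTEX normals: {missing}"
        )
    return baselines


def compute_bc_ccs(
    tumor_scores: ScoreTable,
    baselines: pd.DataFrame,
    manifest: SampleManifest,
) -> pd.DataFrame:
    """Subtract each tumour's tissue baseline from its CCS.

    Returns the BC score table: a frame indexed by sample_id with columns
    ``tissue``, ``cancer_type``, ``bc_raw`` (signed), and placeholders for
    the purity-adjusted and rescaled values filled in by
    :func:`adjust_for_purity`.
    """
    frame = manifest.frame.set_index("sample_id")
    ids = [s for s in tumor_scores.raw.index if frame.loc[s, "study"] == "TCGA_TUMOR"]
    tissues = frame.loc[ids, "tissue"]
    missing = sorted(set(tissues) - set(baselines.index))
    if missing:
        raise ValidationError(f"no baseline for tissue(s): {missing}")
    bc_raw = tumor_scores.raw.loc[ids] - baselines["median_normal_ccs"].loc[
        tissues
    ].to_numpy()
    return pd.DataFrame(
        {
            "tissue": tissues,
            "cancer_type": frame.loc[ids, "cancer_type"],
            "bc_raw": bc_raw,
            "purity": np.nan,
            "bc_purity_adjusted": np.nan,
            "bc_scaled": np.nan,
        }
    )


def adjust_for_purity(
    bc: pd.DataFrame,
    purity: pd.Series,
    missing_policy: str = "drop",
) -> pd.DataFrame:
    """Multiply each tumour's bc_raw by its purity, then min-max rescale.

    Tumours without a purity value are dropped (default) or imputed with
    their cancer type's mean purity (``missing_policy="impute"``).
    """
    purity = validate_purity(purity)
    out = bc.copy()
    have = out.index.intersection(purity.index)
    out.loc[have, "purity"] = purity.loc[have]
    missing = out.index[out["purity"].isna()]
    if len(missing):
        if missing_policy == "drop":
            logger.warning("dropping %d tumour(s) without purity", len(missing))
            out = out.drop(index=missing)
        elif missing_policy == "impute":
            type_means = out.groupby("cancer_type")["purity"].transform("mean")
            if type_means.loc[missing].isna().any():
                raise ValidationError(
                    "cannot impute purity: some cancer types have no values"
                )
            out.loc[missing, "purity"] = type_means.loc[missing]
            logger.warning("imputed purity for %d tumour(s)", len(missing))
        else:
            raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    if len(out) == 0:
        raise ValidationError("no tumours left after purity handling")
    out["bc_purity_adjusted"] = out["bc_raw"] * out["purity"]
    lo = out["bc_purity_adjusted"].min()
    hi = out["bc_purity_adjusted"].max()
    if hi > lo:
        out["bc_scaled"] = (out["bc_purity_adjusted"] - lo) / (hi - lo)
    else:
        out["bc_scaled"] = 0.5
    return out


def classify_quadrants(
    normal_scores: ScoreTable,
    tumor_scores: ScoreTable,
    manifest: SampleManifest,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Place each tissue into a low/high normal x low/high tumour quadrant.

    Per-tissue medians of normal and tumour CCS are computed, each axis is
    min-max rescaled to [0, 1] across tissues, and the quadrant follows
    from comparing each axis to ``threshold`` (ties count as HIGH). Because
    each axis is rescaled, the call is invariant to any common affine
    transform of the raw scores.
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    frame = manifest.frame.set_index("sample_id")

    def tissue_medians(scores: ScoreTable, tumor: bool) -> pd.Series:
        want = "TCGA_TUMOR" if tumor else ("GTEX", "TCGA_NORMAL")
        ids = [
            s
            for s in scores.raw.index
            if s in frame.index
            and (
                frame.loc[s, "study"] == want
                if tumor
                else frame.loc[s, "study"] in want
            )
        ]
        return scores.raw.loc[ids].groupby(frame.loc[ids, "tissue"]).median()

    med_normal = tissue_medians(normal_scores, tumor=False)
    med_tumor = tissue_medians(tumor_scores, tumor=True)
    tissues = sorted(set(med_normal.index) & set(med_tumor.index))
    if len(tissues) < 2:
        raise ValidationError("need at least 2 tissues with both normals and tumours")

    def rescale(series: pd.Series) -> pd.Series:
        lo, hi = series.min(), series.max()
        if hi == lo:
            raise ValidationError("degenerate axis: all tissue medians equal")
        return (series - lo) / (hi - lo)

    norm_axis = rescale(med_normal.loc[tissues])
    tumor_axis = rescale(med_tumor.loc[tissues])
    rows = []
    for t in tissues:
        hi_n = norm_axis[t] >= threshold
        hi_t = tumor_axis[t] >= threshold
        quadrant = f"{'HIGH' if hi_n else 'LOW'}_{'HIGH' if hi_t else 'LOW'}"
        rows.append((t, norm_axis[t], tumor_axis[t], quadrant))
    return pd.DataFrame(
        rows,
        columns=["tissue", "median_normal_scaled", "median_tumor_scaled", "quadrant"],
    ).set_index("tissue")
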