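"""Core in-memory containers shared across the pipeline.

Everything tabular is held in pandas objects; the thin dataclass wrappers
exist to attach validation and domain vocabulary (studies, exclusion
classes, arm codes) to otherwise generic frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

STUDIES = ("GTEX", "TCGA_NORMAL", "TCGA_TUMOR")
NORMAL_STUDIES = ("GTEX", "TCGA_NORMAL")

EXCLUSION_CLASSES = (
    "NONE",
    "OTHER_DATASET",
    "NO_MRNA",
    "NO_MATCHED_SITE",
    "SMALL_GROUP",
    "TESTIS",
    "EMBEDDING_OUTLIER",
)

#: The four label-driven stages applied first, in cascade order.
PRIMARY_EXCLUSIONS = ("OTHER_DATASET", "NO_MRNA", "NO_MATCHED_SITE", "SMALL_GROUP")

MANIFEST_COLUMNS = ("sample_id", "study", "tissue", "cancer_type", "exclusion_class")

#: Human autosomal chromosome arms with callable copy-number: the p-arms of
#: the acrocentric chromosomes 13, 14, 15, 21 and 22 are excluded, leaving 39.
AUTOSOMAL_ARMS = tuple(
    f"{chrom}{arm}"
    for chrom in range(1, 23)
    for arm in ("p", "q")
    if not (arm == "p" and chrom in (13, 14, 15, 21, 22))
)


class ValidationError(ValueError):
    """An on-disk artefact or in-memory container violated its contract."""


@dataclass
class SampleManifest:
    """Per-sample study / tissue / cancer-type labels plus exclusion flags.

    ``frame`` has exactly the columns in :data:`MANIFEST_COLUMNS`; the
    ``cancer_type`` column is the empty string for all non-tumour samples.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"manifest missing column(s): {missing}")
        self.frame = self.frame.loc[:, list(MANIFEST_COLUMNS)].reset_index(drop=True)
        for col in MANIFEST_COLUMNS:
            self.frame[col] = self.frame[col].fillna("").astype(str)
        dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate sample_id(s): {sorted(set(dup))[:10]}"
            )
        bad_study = set(self.frame["study"]) - set(STUDIES)
        if bad_study:
            raise ValidationError(f"unknown study token(s): {sorted(bad_study)}")
        bad_excl = set(self.frame["exclusion_class"]) - set(EXCLUSION_CLASSES)
        if bad_excl:
            raise ValidationError(
                f"unknown exclusion_class token(s): {sorted(bad_excl)}"
            )
        is_tumor = self.frame["study"] == "TCGA_TUMOR"
        has_type = self.frame["cancer_type"] != ""
        offending = self.frame.loc[is_tumor != has_type, "sample_id"]
        if len(offending):
            raise ValidationError(
                "cancer_type must be set exactly for TCGA_TUMOR samples; "
                f"violations: {list(offending[:10])}"
            )

    # -- convenience views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> pd.Series:
        return self.frame["sample_id"]

    @property
    def is_tumor(self) -> pd.Series:
        return self.frame["study"] == "TCGA_TUMOR"

    @property
    def is_normal(self) -> pd.Series:
        return self.frame["study"].isin(NORMAL_STUDIES)

    def subset(self, sample_ids: Iterable[str]) -> "SampleManifest":
        keep = set(sample_ids)
        return SampleManifest(self.frame[self.frame["sample_id"].isin(keep)].copy())

    def drop(self, sample_ids: Iterable[str]) -> "SampleManifest":
        lose = set(sample_ids)
        return SampleManifest(self.frame[~self.frame["sample_id"].isin(lose)].copy())

    def tissue_of(self) -> pd.Series:
        """sample_id -> tissue mapping."""
        return self.frame.set_index("sample_id")["tissue"]

    def cancer_type_of(self) -> pd.Series:
        return self.frame.set_index("sample_id")["cancer_type"]

    def check_site_matching(self) -> None:
        """Assert every tumour's tissue also occurs among normal samples."""
        normal_tissues = set(self.frame.loc[self.is_normal, "tissue"])
        orphan = sorted(set(self.frame.loc[self.is_tumor, "tissue"]) - normal_tissues)
        if orphan:
            raise ValidationError(
                f"tumour tissue(s) with no normal counterpart: {orphan}"
            )


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression; dense, finite, uniquely labelled."""

    frame: pd.DataFrame  # index = gene_ids, columns = sample_ids

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()]
            raise ValidationError(f"duplicate gene_id(s): {sorted(set(dups))[:10]}")
        if self.frame.columns.duplicated().any():
            dups = self.frame.columns[self.frame.columns.duplicated()]
            raise ValidationError(f"duplicate sample_id(s): {sorted(set(dups))[:10]}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            self.frame = self.frame.astype(float)
            values = self.frame.to_numpy()
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{self.frame.index[i]!r}, sample {self.frame.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list:
        return list(self.frame.columns)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[:, list(sample_ids)].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.frame.loc[list(gene_ids), :].copy())


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty, duplicate-free collection of gene identifiers."""

    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ScoreTable:
    """Per-sample signature scores (raw sums, optionally min-max rescaled)."""

    raw: pd.Series  # index = sample_id
    signature_name: str
    n_genes_used: int
    n_genes_missing: int = 0
    scaled: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.raw.index.duplicated().any():
            raise ValidationError("duplicate sample_id in score table")
        if self.scaled is not None:
            s = self.scaled.to_numpy(dtype=float)
            if s.min() < -1e-12 or s.max() > 1 + 1e-12:
                raise ValidationError("scaled scores outside [0, 1]")

    @property
    def sample_ids(self) -> list:
        return list(self.raw.index)

    def subset(self, sample_ids: Sequence[str]) -> "ScoreTable":
        ids = list(sample_ids)
        return ScoreTable(
            raw=self.raw.loc[ids].copy(),
            signature_name=self.signature_name,
            n_genes_used=self.n_genes_used,
            n_genes_missing=self.n_genes_missing,
            scaled=None if self.scaled is None else self.scaled.loc[ids].copy(),
        )


def validate_purity(purity: pd.Series) -> pd.Series:
    """Check a sample_id -> purity mapping lies in [0, 1] and is unique."""
    if purity.index.duplicated().any():
        raise ValidationError("duplicate sample_id in purity table")
    values = purity.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("non-finite purity value")
    if values.min() < 0 or values.max() > 1:
        raise ValidationError("purity values must lie in [0, 1]")
    return purity.astype(float)


def validate_binary_matrix(frame: pd.DataFrame, what: str = "mutation") -> pd.DataFrame:
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValidationError(f"{what} matrix must be binary (0/1)")
    return frame.astype(int)


def validate_arm_calls(frame: pd.DataFrame) -> pd.DataFrame:
    """Arms x samples calls in {-1, 0, +1}, arm ids from the canonical 39."""
    values = frame.to_numpy()
    if not np.isin(values, (-1, 0, 1)).all():
        raise ValidationError("arm calls must be in {-1, 0, +1}")
    unknown = sorted(set(frame.index) - set(AUTOSOMAL_ARMS))
    if unknown:
        raise ValidationError(f"unknown chromosome arm id(s): {unknown}")
    return frame.astype(int)


@dataclass(frozen=True)
class GroupAssignment:
    """The two cancer-type groups contrasted throughout the comparison stages.

    Defaults mirror the low-BC-CCS group (HNSC, KICH, KIRP plus the UCEC
    internal control) versus the high-BC-CCS gynaecological group
    (CESC, OV, UCS).
    """

    group1: frozenset = frozenset({"HNSC", "KICH", "KIRP", "UCEC"})
    group2: frozenset = frozenset({"CESC", "OV", "UCS"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "group1", frozenset(self.group1))
        object.__setattr__(self, "group2", frozenset(self.group2))
        if not self.group1 or not self.group2:
            raise ValidationError("both groups must be non-empty")
        overlap = self.group1 & self.group2
        if overlap:
            raise ValidationError(f"groups overlap: {sorted(overlap)}")

    def label_of(self, cancer_type: str) -> Optional[int]:
        if cancer_type in self.group1:
            return 1
        if cancer_type in self.group2:
            return 2
        return None
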