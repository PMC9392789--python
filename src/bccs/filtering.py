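"""CONSORT-style exclusion cascade with stage-by-stage bookkeeping.

The cascade is label-driven and order-fixed: non-compendium samples, then
samples without mRNA, then samples without a matched site in both studies,
then small groups; testis samples and embedding outliers are removed in a
second, flag-driven pass. Stage counts always reconcile (initial n minus
the sum of removals equals the final n) and re-applying any stage to its
own output removes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Tuple

from .containers import (
    PRIMARY_EXCLUSIONS,
    SampleManifest,
    ValidationError,
)


@dataclass
class FilterReport:
    """Ordered (stage, n_removed, n_remaining) records plus final split."""

    stages: List[Tuple[str, int, int]] = field(default_factory=list)
    final_n_normals: int = 0
    final_n_tumors: int = 0

    def add_stage(self, name: str, n_removed: int, n_remaining: int) -> None:
        if self.stages:
            prev_remaining = self.stages[-1][2]
            if n_remaining != prev_remaining - n_removed:
                raise ValidationError(
                    f"stage {name!r} does not reconcile: "
                    f"{prev_remaining} - {n_removed} != {n_remaining}"
                )
        self.stages.append((name, n_removed, n_remaining))

    @property
    def n_remaining(self) -> int:
        return self.stages[-1][2] if self.stages else 0

    def finalize(self, manifest: SampleManifest) -> None:
        self.final_n_normals = int(manifest.is_normal.sum())
        self.final_n_tumors = int(manifest.is_tumor.sum())
        if self.stages and self.final_n_normals + self.final_n_tumors != self.n_remaining:
            raise ValidationError("final normal/tumour split does not reconcile")

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"stage": s, "n_removed": r, "n_remaining": m}
                for s, r, m in self.stages
            ],
            "final_n_normals": self.final_n_normals,
            "final_n_tumors": self.final_n_tumors,
        }


def apply_consort_filters(
    manifest: SampleManifest,
) -> Tuple[SampleManifest, FilterReport]:
    """Remove the four primary exclusion classes in cascade order."""
    report = FilterReport()
    report.add_stage("initial", 0, len(manifest))
    current = manifest
    for stage in PRIMARY_EXCLUSIONS:
        flagged = current.frame.loc[
            current.frame["exclusion_class"] == stage, "sample_id"
        ]
        current = current.drop(flagged)
        report.add_stage(stage, len(flagged), len(current))
    report.finalize(current)
    return current, report


def apply_small_group_rule(manifest: SampleManifest, min_n: int = 10) -> SampleManifest:
    """Drop every normal-tissue group and cancer-type group with fewer than
    ``min_n`` samples, then re-enforce site matching both ways.

    Site matching is re-checked after the size rule because removing a small
    normal group orphans its tumours (and vice versa).
    """
    if min_n < 1:
        raise ValidationError("min_n must be >= 1")
    frame = manifest.frame
    normal_sizes = frame.loc[manifest.is_normal].groupby("tissue").size()
    small_tissues = set(normal_sizes[normal_sizes < min_n].index)
    type_sizes = frame.loc[manifest.is_tumor].groupby("cancer_type").size()
    small_types = set(type_sizes[type_sizes < min_n].index)

    keep = ~(
        (manifest.is_normal & frame["tissue"].isin(small_tissues))
        | (manifest.is_tumor & frame["cancer_type"].isin(small_types))
    )
    frame = frame[keep]

    normal_tissues = set(frame.loc[frame["study"] != "TCGA_TUMOR", "tissue"])
    tumor_tissues = set(frame.loc[frame["study"] == "TCGA_TUMOR", "tissue"])
    matched = normal_tissues & tumor_tissues
    frame = frame[frame["tissue"].isin(matched)]
    return SampleManifest(frame.copy())


def remove_flagged_outliers(
    manifest: SampleManifest,
    flags: Iterable[str],
    reason: str,
    report: FilterReport | None = None,
) -> Tuple[SampleManifest, FilterReport]:
    """Remove an explicit set of flagged samples (testis or embedding
    outliers), extending an existing report if given."""
    if reason not in ("TESTIS", "EMBEDDING_OUTLIER"):
        raise ValidationError(f"unknown outlier reason: {reason!r}")
    flags = set(flags)
    unknown = flags - set(manifest.sample_ids)
    if unknown:
        raise ValidationError(f"unknown sample id(s) in flags: {sorted(unknown)[:10]}")
    if report is None:
        report = FilterReport()
        report.add_stage("initial", 0, len(manifest))
    filtered = manifest.drop(flags)
    report.add_stage(reason, len(flags), len(filtered))
    report.finalize(filtered)
    return filtered, report


def run_full_cascade(manifest: SampleManifest) -> Tuple[SampleManifest, FilterReport]:
    """Primary cascade, then label-driven testis and embedding-outlier
    removal, in the fixed published order."""
    current, report = apply_consort_filters(manifest)
    for reason in ("TESTIS", "EMBEDDING_OUTLIER"):
        flags = current.frame.loc[
            current.frame["exclusion_class"] == reason, "sample_id"
        ]
        current, report = remove_flagged_outliers(current, flags, reason, report)
    return current, report
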