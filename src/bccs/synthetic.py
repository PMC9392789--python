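"""Synthetic paired normal/tumour pan-cancer cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes of
co-normalised bulk RNA-seq compendia: tissue-specific baseline expression of
cell-cycle signature genes, a tumour-specific uplift on top of that baseline,
Beta-distributed tumour purity, group-enriched driver-gene mutation rates and
chromosome-arm alteration rates, and hormone-module expression shifts in the
high-activity group. Expression is Gaussian on the log scale — the pipeline
consumes already-normalised log expression and never models counts.

A deterministic CONSORT fixture manifest reproducing the filter-cascade
bookkeeping of the real 19,131-sample compendium is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, NamedTuple, Tuple

import numpy as np
import pandas as pd

from .containers import (
    AUTOSOMAL_ARMS,
    ExpressionMatrix,
    GeneSet,
    SampleManifest,
    ValidationError,
)

# Fixed sub-stream indices; appending new components must never perturb
# draws of existing ones.
_STREAMS = {"expression": 0, "purity": 1, "mutations": 2, "arms": 3, "gene_sets": 4}


@dataclass(frozen=True)
class TissueSpec:
    """One tissue of origin and its matched cancer type.

    ``baseline_ccs_level`` is the per-gene mean log2 expression of signature
    genes in normal samples of this tissue; ``tumor_uplift`` is added to each
    signature gene's mean in tumours, so the expected CCS gap between tumour
    and normal is ``tumor_uplift * n_signature_genes``.
    """

    name: str
    cancer_type: str
    n_normal: int = 30
    n_tumor: int = 60
    baseline_ccs_level: float = 5.0
    tumor_uplift: float = 1.0


@dataclass
class SyntheticConfig:
    tissues: List[TissueSpec] = field(default_factory=list)
    n_signature_genes: int = 50
    n_metagene_genes: int = 20
    n_background_genes: int = 200
    n_de_genes: int = 30
    de_log2fc: float = 3.0
    noise_sd: float = 1.0
    purity_beta_params: Tuple[float, float] = (5.0, 2.0)
    #: driver gene -> per-tumour base mutation probability
    mutation_base_rate: Dict[str, float] = field(default_factory=dict)
    #: driver gene -> odds multiplier applied in group-2 tumours
    mutation_enrichment: Dict[str, float] = field(default_factory=dict)
    #: arm -> (rate in group 1, rate in group 2, direction: +1 gain / -1 loss)
    arm_enrichment: Dict[str, Tuple[float, float, int]] = field(default_factory=dict)
    arm_background_rate: float = 0.10
    hormone_module_shift: float = 1.5
    group1_cancer_types: Tuple[str, ...] = ()
    group2_cancer_types: Tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if len(self.tissues) < 2:
            raise ValidationError("need at least 2 tissues")
        for t in self.tissues:
            if t.n_normal < 1 or t.n_tumor < 1:
                raise ValidationError(f"tissue {t.name}: n_normal, n_tumor must be >= 1")
            if t.tumor_uplift < 0:
                raise ValidationError(f"tissue {t.name}: tumor_uplift must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        a, b = self.purity_beta_params
        if a <= 0 or b <= 0:
            raise ValidationError("purity beta parameters must be > 0")
        for g, p in self.mutation_base_rate.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"mutation rate for {g} outside [0, 1]")
        for arm, (p1, p2, direction) in self.arm_enrichment.items():
            if arm not in AUTOSOMAL_ARMS:
                raise ValidationError(f"unknown arm {arm!r}")
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValidationError(f"arm rate for {arm} outside [0, 1]")
            if direction not in (-1, 1):
                raise ValidationError(f"arm direction for {arm} must be +1 or -1")
        if not 0 <= self.arm_background_rate <= 1:
            raise ValidationError("arm_background_rate outside [0, 1]")
        overlap = set(self.group1_cancer_types) & set(self.group2_cancer_types)
        if overlap:
            raise ValidationError(f"group-1/group-2 cancer types overlap: {overlap}")


@dataclass
class SyntheticTruth:
    """Ground-truth generator parameters, kept for recovery tests."""

    baselines: Dict[str, float]
    uplifts: Dict[str, float]
    signature_genes: List[str]
    metagene_genes: List[str]
    background_genes: List[str]
    de_genes: Dict[str, float]  # gene -> true log2FC (group 2 vs 1)
    hormone_genes: Dict[str, List[str]]  # module name -> genes
    hormone_module_shift: float
    mutation_rates: Dict[str, Dict[str, float]]  # gene -> {"group1": p, "group2": p}
    arm_rates: Dict[str, Dict[str, float]]  # arm -> {"group1", "group2", "direction"}
    group1_cancer_types: List[str]
    group2_cancer_types: List[str]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)


class SyntheticCohort(NamedTuple):
    manifest: SampleManifest
    expression: ExpressionMatrix
    purity: pd.Series
    mutations: pd.DataFrame
    arm_calls: pd.DataFrame
    truth: SyntheticTruth


def _rng(seed: int, component: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[component],))
    )


def default_config(seed: int = 0, n_normal: int = 30, n_tumor: int = 60) -> SyntheticConfig:
    """Study conditions for a small pan-cancer cohort.

    Eight tissues span the observed regimes: high-baseline/low-uplift head
    and neck tissue, low-baseline/high-uplift gynaecological tissues, and
    intermediate archetypes. Purity ~ Beta(5, 2) (mean ~0.71, matching
    typical consensus tumour-purity distributions); driver mutation rates
    follow the familiar pan-cancer ordering (TP53 > PIK3CA > PTEN > FBXW7);
    deletions of 16q/8p and gains of 3q/1q are enriched in the
    gynaecological group at 0.6 versus 0.2.
    """
    tissues = [
        TissueSpec("HeadNeck", "HNSC", n_normal, n_tumor, 7.0, 0.4),
        TissueSpec("Kidney", "KIRP", n_normal, n_tumor, 4.0, 0.7),
        TissueSpec("Endometrium", "UCEC", n_normal, n_tumor, 5.0, 1.0),
        TissueSpec("Brain", "GBM", n_normal, n_tumor, 3.5, 1.6),
        TissueSpec("Bladder", "BLCA", n_normal, n_tumor, 6.5, 1.9),
        TissueSpec("Uterus", "UCS", n_normal, n_tumor, 4.2, 2.4),
        TissueSpec("Ovary", "OV", n_normal, n_tumor, 3.8, 2.8),
        TissueSpec("Cervix", "CESC", n_normal, n_tumor, 4.5, 3.2),
    ]
    drivers = {
        "TP53": 0.45,
        "PIK3CA": 0.25,
        "PTEN": 0.15,
        "FBXW7": 0.08,
    }
    drivers.update({f"DRV{i:02d}": 0.02 + 0.005 * i for i in range(1, 17)})
    return SyntheticConfig(
        tissues=tissues,
        mutation_base_rate=drivers,
        mutation_enrichment={"FBXW7": 3.0, "DRV05": 2.5},
        arm_enrichment={
            "16q": (0.2, 0.6, -1),
            "8p": (0.2, 0.6, -1),
            "3q": (0.2, 0.6, +1),
            "1q": (0.2, 0.6, +1),
        },
        group1_cancer_types=("HNSC", "KIRP", "UCEC"),
        group2_cancer_types=("CESC", "OV", "UCS"),
        seed=seed,
    )


def _gene_names(config: SyntheticConfig) -> Dict[str, List[str]]:
    sig = [f"CCS{i:04d}" for i in range(config.n_signature_genes)]
    meta = [f"PROLIF{i:03d}" for i in range(config.n_metagene_genes)]
    hormones = {
        "ESTROGEN_MODULE": ["ESR1"] + [f"ESR1M{i}" for i in range(1, 6)],
        "PROGESTERONE_MODULE": ["PGR"] + [f"PGRM{i}" for i in range(1, 6)],
        "ANDROGEN_MODULE": ["AR"] + [f"ARM{i}" for i in range(1, 6)],
    }
    de = [f"DEG{i:03d}" for i in range(config.n_de_genes)]
    background = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    return {"signature": sig, "metagene": meta, "hormones": hormones, "de": de,
            "background": background}


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a full cohort (manifest, expression, purity, mutations, arm
    calls) plus its ground truth; identical seeds give identical outputs."""
    config.validate()
    names = _gene_names(config)
    group2 = set(config.group2_cancer_types)

    # ---- manifest --------------------------------------------------------
    rows = []
    for t in config.tissues:
        for i in range(t.n_normal):
            # every 4th normal is a TCGA adjacent-normal so that the
            # GTEX-only baseline rule is actually exercised
            study = "TCGA_NORMAL" if i % 4 == 3 else "GTEX"
            rows.append((f"{t.name}-N{i:04d}", study, t.name, "", "NONE"))
        for i in range(t.n_tumor):
            rows.append(
                (f"{t.cancer_type}-T{i:04d}", "TCGA_TUMOR", t.name, t.cancer_type, "NONE")
            )
    manifest = SampleManifest(
        pd.DataFrame(rows, columns=["sample_id", "study", "tissue", "cancer_type",
                                    "exclusion_class"])
    )
    sample_ids = list(manifest.sample_ids)
    tumor_ids = list(manifest.frame.loc[manifest.is_tumor, "sample_id"])
    in_group2 = manifest.frame.set_index("sample_id")["cancer_type"].isin(group2)

    # ---- expression ------------------------------------------------------
    rng = _rng(config.seed, "expression")
    all_genes = (
        names["signature"]
        + names["metagene"]
        + [g for genes in names["hormones"].values() for g in genes]
        + names["de"]
        + names["background"]
    )
    means = pd.DataFrame(0.0, index=all_genes, columns=sample_ids)
    for t in config.tissues:
        cols = [s for s in sample_ids if s.startswith(f"{t.name}-N")]
        tcols = [s for s in sample_ids if s.startswith(f"{t.cancer_type}-T")]
        coreg = names["signature"] + names["metagene"]
        means.loc[coreg, cols] = t.baseline_ccs_level
        means.loc[coreg, tcols] = t.baseline_ccs_level + t.tumor_uplift
    hormone_all = [g for genes in names["hormones"].values() for g in genes]
    g2_tumors = [s for s in tumor_ids if in_group2[s]]
    means.loc[hormone_all, :] += 2.0
    means.loc[hormone_all, g2_tumors] += config.hormone_module_shift
    means.loc[names["de"], g2_tumors] += config.de_log2fc
    values = means.to_numpy() + rng.normal(0.0, config.noise_sd, size=means.shape)
    expression = ExpressionMatrix(pd.DataFrame(values, index=all_genes,
                                               columns=sample_ids))

    # ---- purity ----------------------------------------------------------
    rng = _rng(config.seed, "purity")
    a, b = config.purity_beta_params
    purity = pd.Series(rng.beta(a, b, size=len(tumor_ids)), index=tumor_ids,
                       name="purity")

    # ---- mutations -------------------------------------------------------
    rng = _rng(config.seed, "mutations")
    driver_genes = sorted(config.mutation_base_rate)
    mut = np.zeros((len(driver_genes), len(tumor_ids)), dtype=int)
    g2_mask = in_group2[tumor_ids].to_numpy()
    mutation_rates: Dict[str, Dict[str, float]] = {}
    for gi, gene in enumerate(driver_genes):
        p1 = config.mutation_base_rate[gene]
        odds = config.mutation_enrichment.get(gene, 1.0)
        p2 = odds * p1 / (1 - p1 + odds * p1) if p1 < 1 else 1.0
        p = np.where(g2_mask, p2, p1)
        mut[gi] = rng.random(len(tumor_ids)) < p
        mutation_rates[gene] = {"group1": p1, "group2": p2}
    mutations = pd.DataFrame(mut, index=driver_genes, columns=tumor_ids)

    # ---- arm calls -------------------------------------------------------
    rng = _rng(config.seed, "arms")
    calls = np.zeros((len(AUTOSOMAL_ARMS), len(tumor_ids)), dtype=int)
    arm_rates: Dict[str, Dict[str, float]] = {}
    for ai, arm in enumerate(AUTOSOMAL_ARMS):
        if arm in config.arm_enrichment:
            p1, p2, direction = config.arm_enrichment[arm]
        else:
            p1 = p2 = config.arm_background_rate
            direction = 1 if arm.endswith("q") else -1
        p = np.where(g2_mask, p2, p1)
        altered = rng.random(len(tumor_ids)) < p
        calls[ai] = altered * direction
        arm_rates[arm] = {"group1": p1, "group2": p2, "direction": direction}
    arm_calls = pd.DataFrame(calls, index=list(AUTOSOMAL_ARMS), columns=tumor_ids)

    truth = SyntheticTruth(
        baselines={t.name: t.baseline_ccs_level for t in config.tissues},
        uplifts={t.cancer_type: t.tumor_uplift for t in config.tissues},
        signature_genes=names["signature"],
        metagene_genes=names["metagene"],
        background_genes=names["background"],
        de_genes={g: config.de_log2fc for g in names["de"]},
        hormone_genes={k: list(v) for k, v in names["hormones"].items()},
        hormone_module_shift=config.hormone_module_shift,
        mutation_rates=mutation_rates,
        arm_rates=arm_rates,
        group1_cancer_types=list(config.group1_cancer_types),
        group2_cancer_types=list(config.group2_cancer_types),
    )
    return SyntheticCohort(manifest, expression, purity, mutations, arm_calls, truth)


def cohort_gene_sets(truth: SyntheticTruth, seed: int = 0,
                     n_random: int = 3, random_size: int = 25) -> List[GeneSet]:
    """Gene sets for scoring/GSEA on a synthetic cohort: the cell-cycle
    signature, a disjoint proliferation metagene, the three hormone modules,
    the planted up-regulated set, and seeded random background sets."""
    sets = [
        GeneSet("CCS", frozenset(truth.signature_genes)),
        GeneSet("PROLIFERATION_METAGENE", frozenset(truth.metagene_genes)),
    ]
    for name, genes in truth.hormone_genes.items():
        sets.append(GeneSet(name, frozenset(genes)))
    sets.append(GeneSet("PLANTED_UP", frozenset(truth.de_genes)))
    rng = _rng(seed, "gene_sets")
    pool = np.array(sorted(truth.de_genes) + sorted(truth.background_genes))
    for k in range(n_random):
        picks = rng.choice(pool, size=random_size, replace=False)
        sets.append(GeneSet(f"RANDOM_SET_{k + 1}", frozenset(picks)))
    return sets


# ---------------------------------------------------------------------------
# CONSORT fixture


#: tissue -> matched cancer types used by the fixture's retained samples
_FIXTURE_TISSUES = [
    ("Bladder", ["BLCA"]),
    ("Brain", ["GBM", "LGG"]),
    ("Breast", ["BRCA"]),
    ("Cervix", ["CESC"]),
    ("Colon", ["COAD"]),
    ("Esophagus", ["ESCA"]),
    ("HeadNeck", ["HNSC"]),
    ("Kidney", ["KICH", "KIRC", "KIRP"]),
    ("Liver", ["LIHC"]),
    ("Lung", ["LUAD", "LUSC"]),
    ("Ovary", ["OV"]),
    ("Pancreas", ["PAAD"]),
    ("Prostate", ["PRAD"]),
    ("Skin", ["SKCM"]),
    ("Stomach", ["STAD"]),
    ("Thyroid", ["THCA"]),
    ("Uterus", ["UCEC", "UCS"]),
]

#: printed filter-cascade bookkeeping of the 19,131-sample compendium
CONSORT_COUNTS = {
    "total": 19131,
    "OTHER_DATASET": 734,
    "NO_MRNA": 92,
    "NO_MATCHED_SITE": 802,
    "SMALL_GROUP": 4043,
    "TESTIS": 319,
    "EMBEDDING_OUTLIER": 24,
    "final": 13117,
    "final_normals": 4979,
    "final_tumors": 8138,
}


def generate_consort_fixture() -> SampleManifest:
    """Deterministic 19,131-sample manifest reproducing the published filter
    cascade: 734 non-compendium, 92 without mRNA, 802 without a matched
    site, 4,043 in small groups, 319 testicular, 24 embedding outliers, and
    13,117 retained (4,979 normals + 8,138 tumours)."""
    rows: List[tuple] = []

    def add(n, study, tissue, cancer_type, exclusion):
        start = len(rows)
        for i in range(n):
            rows.append(
                (f"SYN-{start + i:05d}", study, tissue, cancer_type, exclusion)
            )

    # retained normals: 4,979 split across the 17 matched tissues
    n_tissues = len(_FIXTURE_TISSUES)
    base, extra = divmod(CONSORT_COUNTS["final_normals"], n_tissues)
    for ti, (tissue, _types) in enumerate(_FIXTURE_TISSUES):
        n = base + (1 if ti < extra else 0)
        n_tcga = n // 5  # minority adjacent-normals
        add(n - n_tcga, "GTEX", tissue, "", "NONE")
        add(n_tcga, "TCGA_NORMAL", tissue, "", "NONE")

    # retained tumours: 8,138 split across the 23 matched cancer types
    pairs = [(tissue, ct) for tissue, types in _FIXTURE_TISSUES for ct in types]
    base, extra = divmod(CONSORT_COUNTS["final_tumors"], len(pairs))
    for pi, (tissue, ct) in enumerate(pairs):
        add(base + (1 if pi < extra else 0), "TCGA_TUMOR", tissue, ct, "NONE")

    # exclusions, in cascade order
    add(CONSORT_COUNTS["OTHER_DATASET"], "GTEX", "NonCompendium", "", "OTHER_DATASET")
    add(CONSORT_COUNTS["NO_MRNA"], "GTEX", "Bladder", "", "NO_MRNA")
    add(CONSORT_COUNTS["NO_MATCHED_SITE"], "GTEX", "Spleen", "", "NO_MATCHED_SITE")
    small = CONSORT_COUNTS["SMALL_GROUP"]
    add(small // 2, "GTEX", "MinorTissue", "", "SMALL_GROUP")
    add(small - small // 2, "TCGA_TUMOR", "Adrenal", "ACC", "SMALL_GROUP")
    testis = CONSORT_COUNTS["TESTIS"]
    add(165, "GTEX", "Testis", "", "TESTIS")
    add(testis - 165, "TCGA_TUMOR", "Testis", "TGCT", "TESTIS")
    outliers = CONSORT_COUNTS["EMBEDDING_OUTLIER"]
    add(outliers // 2, "GTEX", "Bladder", "", "EMBEDDING_OUTLIER")
    add(outliers - outliers // 2, "TCGA_TUMOR", "Bladder", "BLCA", "EMBEDDING_OUTLIER")

    manifest = SampleManifest(
        pd.DataFrame(rows, columns=["sample_id", "study", "tissue", "cancer_type",
                                    "exclusion_class"])
    )
    assert len(manifest) == CONSORT_COUNTS["total"]
    return manifest
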