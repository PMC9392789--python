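"""Readers and writers for every on-disk artefact.

All tabular formats are plain TSV (tab-separated, UTF-8, no quoting, "."
decimal separator); expression can alternatively travel as Matrix Market
(.mtx) with ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars. Gene
sets use the standard GMT dialect (name, description, genes...).

The loaders validate but never transform: expression is consumed on the
log2-like scale it is stored on, matching an upstream pipeline that has
already co-normalised tumour and normal samples.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Union

import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    ExpressionMatrix,
    GeneSet,
    SampleManifest,
    ValidationError,
    validate_arm_calls,
    validate_binary_matrix,
    validate_purity,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: PathLike) -> SampleManifest:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return SampleManifest(frame)


def write_manifest(manifest: SampleManifest, path: PathLike) -> None:
    manifest.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression


def read_expression(path: PathLike, format: str = "tsv") -> ExpressionMatrix:
    """Load a genes x samples expression matrix.

    ``format="tsv"``: genes as rows, first column ``gene_id``.
    ``format="mtx"``: Matrix Market file; gene and sample names are read from
    ``<stem>.genes.txt`` and ``<stem>.samples.txt`` next to it.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index = frame.index.astype(str)
        frame.columns = frame.columns.astype(str)
        return ExpressionMatrix(frame)
    if format == "mtx":
        matrix = scipy.io.mmread(path)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        stem = path.with_suffix("")
        genes = _read_names(Path(f"{stem}.genes.txt"))
        samples = _read_names(Path(f"{stem}.samples.txt"))
        if matrix.shape != (len(genes), len(samples)):
            raise ValidationError(
                f"matrix shape {matrix.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        return ExpressionMatrix(pd.DataFrame(matrix, index=genes, columns=samples))
    raise ValueError(f"unknown expression format: {format!r}")


def write_expression(expr: ExpressionMatrix, path: PathLike, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        out = expr.frame.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(expr.frame.to_numpy()))
        stem = path.with_suffix("")
        _write_names(Path(f"{stem}.genes.txt"), expr.gene_ids)
        _write_names(Path(f"{stem}.samples.txt"), expr.sample_ids)
    else:
        raise ValueError(f"unknown expression format: {format!r}")


def _read_names(path: Path) -> List[str]:
    if not path.exists():
        raise ValidationError(f"missing sidecar file: {path}")
    return [line.strip() for line in path.read_text().splitlines() if line.strip()]


def _write_names(path: Path, names) -> None:
    path.write_text("\n".join(str(n) for n in names) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: PathLike) -> List[GeneSet]:
    """Parse a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    The description field is discarded. Duplicate genes within a set are
    deduplicated with a logged warning; a line with fewer than three fields
    is a hard error naming the line number.
    """
    sets: List[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, _description, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) < len(genes):
                logger.warning(
                    "gene set %r (line %d) contains duplicate genes; deduplicated",
                    name,
                    lineno,
                )
            sets.append(GeneSet(name, frozenset(genes)))
    return sets


def write_gmt(gene_sets: List[GeneSet], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in gene_sets:
            handle.write("\t".join([gs.name, "na", *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# purity, mutations, arm calls


def read_purity(path: PathLike) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in frame.columns or "purity" not in frame.columns:
        raise ValidationError("purity table needs columns sample_id, purity")
    series = frame.set_index("sample_id")["purity"]
    return validate_purity(series)


def write_purity(purity: pd.Series, path: PathLike) -> None:
    out = purity.rename("purity").rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_mutations(path: PathLike) -> pd.DataFrame:
    """Binary driver-gene x sample matrix (1 = non-silent mutation)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.isna().to_numpy().any():
        raise ValidationError("mutation matrix contains missing values")
    return validate_binary_matrix(frame, "mutation")


def write_mutations(mutations: pd.DataFrame, path: PathLike) -> None:
    out = mutations.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_arm_calls(path: PathLike) -> pd.DataFrame:
    """Arm x sample calls in {-1, 0, +1} over the 39 autosomal arms."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.isna().to_numpy().any():
        raise ValidationError("arm-call matrix contains missing values")
    return validate_arm_calls(frame)


def write_arm_calls(arms: pd.DataFrame, path: PathLike) -> None:
    out = arms.copy()
    out.index.name = "arm"
    out.to_csv(path, sep="\t")
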