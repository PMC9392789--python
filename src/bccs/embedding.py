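"""Variable-gene selection, PCA/UMAP embeddings and outlier flagging.

These replace a visual batch-effect and outlier inspection with
deterministic, parameterised surrogates: variance-ranked gene selection,
sign-fixed PCA, seeded UMAP, and a robust-Mahalanobis outlier rule on the
first two principal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix, ValidationError


@dataclass
class Embedding:
    sample_ids: List[str]
    coordinates: np.ndarray  # n_samples x k
    method: str  # "PCA" | "UMAP"
    gene_subset_name: str = ""
    explained_variance: Optional[np.ndarray] = None  # PCA only

    def __post_init__(self) -> None:
        if len(self.sample_ids) != self.coordinates.shape[0]:
            raise ValidationError("coordinate rows do not align with sample_ids")
        if self.explained_variance is not None:
            if self.explained_variance.sum() > 1 + 1e-9:
                raise ValidationError("explained-variance fractions sum to > 1")

    def frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def select_variable_genes(expr: ExpressionMatrix, n_top: int) -> List[str]:
    """The ``n_top`` genes with largest variance across samples; ties are
    broken by lexicographic gene id, so the result is deterministic."""
    if n_top < 1:
        raise ValidationError("n_top must be >= 1")
    if n_top > expr.n_genes:
        raise ValidationError(f"n_top={n_top} exceeds {expr.n_genes} genes")
    variances = expr.frame.var(axis=1, ddof=1)
    order = sorted(expr.gene_ids, key=lambda g: (-variances[g], g))
    return order[:n_top]


def run_pca(expr: ExpressionMatrix, genes: Sequence[str], k: int = 2) -> Embedding:
    """PCA on the given genes, centred per gene, with a deterministic sign
    convention (the largest-magnitude loading of each component is made
    positive)."""
    genes = list(genes)
    missing = sorted(set(genes) - set(expr.gene_ids))
    if missing:
        raise ValidationError(f"genes not in matrix: {missing[:10]}")
    X = expr.frame.loc[genes].to_numpy().T  # samples x genes
    if k > min(X.shape):
        raise ValidationError(f"k={k} exceeds min(n_samples, n_genes)={min(X.shape)}")
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValidationError("zero total variance")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(k):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] *= -1
            pca.components_[j] *= -1
    return Embedding(
        sample_ids=expr.sample_ids,
        coordinates=coords,
        method="PCA",
        explained_variance=pca.explained_variance_ratio_.copy(),
    )


def run_umap(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    seed: int = 0,
    n_neighbors: int = 15,
) -> Embedding:
    """2-D UMAP embedding; a fixed seed makes coordinates reproducible on a
    given platform. umap-learn is imported lazily because of its compile
    cost."""
    if expr.n_samples < 10:
        raise ValidationError("need at least 10 samples for UMAP")
    if expr.n_samples <= n_neighbors:
        raise ValidationError(
            f"n_samples={expr.n_samples} <= n_neighbors={n_neighbors}; "
            "lower n_neighbors"
        )
    import umap  # deferred: numba compilation is expensive

    X = expr.frame.loc[list(genes)].to_numpy().T
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors, random_state=seed)
    coords = reducer.fit_transform(X)
    return Embedding(sample_ids=expr.sample_ids, coordinates=np.asarray(coords),
                     method="UMAP")


def flag_embedding_outliers(emb: Embedding, alpha: float = 0.001) -> Set[str]:
    """Samples whose robust squared Mahalanobis distance in the first two
    components exceeds the chi-square(2) quantile at 1 - alpha.

    Location and scatter come from the minimum covariance determinant
    estimator, a standard high-breakdown choice, so a handful of gross
    outliers cannot mask themselves.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if emb.coordinates.shape[1] < 2:
        raise ValidationError("need an embedding with k >= 2")
    n = len(emb.sample_ids)
    if n < 5:
        raise ValidationError("need at least 5 samples to flag outliers")
    from sklearn.covariance import MinCovDet

    X = emb.coordinates[:, :2]
    mcd = MinCovDet(random_state=0).fit(X)
    d2 = mcd.mahalanobis(X)
    # small-sample consistency calibration: robust distances run liberal,
    # so rescale them to put the sample median at the chi-square(2) median
    med = np.median(d2)
    if med > 0:
        d2 = d2 * (stats.chi2.ppf(0.5, df=2) / med)
    cutoff = stats.chi2.ppf(1 - alpha, df=2)
    return {emb.sample_ids[i] for i in np.nonzero(d2 > cutoff)[0]}
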