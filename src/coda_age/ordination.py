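"""Compositional PCA (form/covariance biplots) and Ward clustering."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .coda_core import ClrMatrix

__all__ = [
    "OrdinationResult",
    "compositional_pca",
    "biplot_coordinates",
    "ward_cluster",
]


@dataclasses.dataclass
class OrdinationResult:
    """SVD of a column-centered clr matrix.

    ``scores`` are in the form-biplot convention (U*S), so pairwise Euclidean
    distances among full-dimensional scores equal Aitchison distances.
    """

    scores: pd.DataFrame          # samples x components, U*S
    loadings: pd.DataFrame        # OTUs x components, V
    singular_values: np.ndarray
    variance_fraction: np.ndarray
    log_base: str = "2"

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def axis_label(self, i: int) -> str:
        return f"PC{i + 1} ({100 * self.variance_fraction[i]:.1f}%)"


def compositional_pca(clr: ClrMatrix) -> OrdinationResult:
    """Column-center the clr matrix and decompose it by SVD.

    variance_fraction[i] = s_i^2 / sum(s^2).  Component signs are fixed so
    that each component's largest-magnitude loading is positive.
    """
    X = clr.values.to_numpy(dtype=float)
    S, D = X.shape
    if S < 3:
        raise ValueError(f"need at least 3 samples for PCA, got {S}")
    centered = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank = min(S - 1, D)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]

    # deterministic sign: largest-|loading| entry positive per component
    for i in range(rank):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0

    total = float((s ** 2).sum())
    varfrac = (s ** 2) / total if total > 0 else np.zeros(rank)
    comp_ids = [f"PC{i + 1}" for i in range(rank)]
    return OrdinationResult(
        scores=pd.DataFrame(U * s, index=clr.values.index, columns=comp_ids),
        loadings=pd.DataFrame(Vt.T, index=clr.values.columns, columns=comp_ids),
        singular_values=s,
        variance_fraction=varfrac,
        log_base=clr.log_base,
    )


def biplot_coordinates(
    res: OrdinationResult, kind: str = "form"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (sample_coords, otu_coords) for a biplot.

    ``form``: scores U*S, loadings V — sample distances approximate data
    distances.  ``covariance``: scores U, loadings V*S/sqrt(n-1) — each
    loading vector's length approximates the OTU's clr standard deviation.
    """
    if res.n_components < 2:
        raise ValueError("need at least 2 components for a biplot")
    if kind == "form":
        return res.scores.copy(), res.loadings.copy()
    if kind == "covariance":
        n = res.scores.shape[0]
        s = res.singular_values
        samples = res.scores / s
        otus = res.loadings * (s / np.sqrt(n - 1))
        return samples, otus
    raise ValueError(f"unknown biplot kind {kind!r}")


def ward_cluster(
    dist: pd.DataFrame, k: int | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """Agglomerative Ward clustering of a metric distance matrix.

    Uses the squared-distance (Ward.D2-style) update via scipy's ``ward``
    linkage on the condensed distances.  Ties break toward the
    lowest-index pair (scipy's deterministic ordering).

    Returns the linkage matrix and, when ``k`` is given, a Series of cluster
    labels (1..k) indexed by sample id.
    """
    arr = np.asarray(dist, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    condensed = squareform(arr, checks=False)
    Z = linkage(condensed, method="ward")
    labels = None
    if k is not None:
        flat = fcluster(Z, t=k, criterion="maxclust")
        index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(arr.shape[0])
        labels = pd.Series(flat, index=index, name="cluster")
    return Z, labels
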