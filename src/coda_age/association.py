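"""Expected-rho compositional association and threshold-graph clustering.

The symmetric proportionality statistic used here is

    rho(i, j) = 1 - var(x_i - x_j) / (var(x_i) + var(x_j))

computed on clr columns across samples, which simplifies to
``2 cov(x_i, x_j) / (var(x_i) + var(x_j))``.  Its expectation E(rho) is the
arithmetic mean over Dirichlet Monte-Carlo instances.  rho = 1 iff the ratio
of the two OTUs is constant across samples; unrelated OTUs give rho near 0.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .coda_core import ClrMatrix, McInstances
from .table_io import TaxonomyTable, UNCLASSIFIED

__all__ = [
    "RhoGraph",
    "ClusterSet",
    "rho_matrix",
    "expected_rho",
    "pair_diagnostics",
    "rho_clusters",
]


@dataclasses.dataclass
class RhoGraph:
    """Symmetric matrix of expected rho values over one OTU set.

    Cells flagged not-a-value (NaN) — zero-variance or excluded OTUs — carry
    no edge at any threshold.
    """

    rho: pd.DataFrame
    K: int = 1

    def __post_init__(self) -> None:
        r = self.rho
        if r.shape[0] != r.shape[1] or not r.index.equals(r.columns):
            raise ValueError("rho matrix must be square with matching ids")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.rho.index)

    def edges(self, cutoff: float) -> pd.DataFrame:
        """Upper-triangle pairs with rho strictly above ``cutoff``."""
        arr = self.rho.to_numpy()
        iu = np.triu_indices(arr.shape[0], k=1)
        vals = arr[iu]
        with np.errstate(invalid="ignore"):
            mask = vals > cutoff
        ids = np.asarray(self.otu_ids)
        return pd.DataFrame(
            {
                "otu_i": ids[iu[0][mask]],
                "otu_j": ids[iu[1][mask]],
                "rho": vals[mask],
            }
        )

    def to_tsv(self, path, cutoff: float | None = None) -> None:
        """Long-format dump (otu_i, otu_j, rho), optionally thresholded."""
        self.edges(-np.inf if cutoff is None else cutoff).to_csv(
            path, sep="\t", index=False
        )


@dataclasses.dataclass
class ClusterSet:
    """Disjoint OTU clusters from the thresholded rho graph."""

    clusters: list[list[str]]
    cutoff: float
    min_size: int
    genera: dict[str, str] = dataclasses.field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clusters)

    def membership(self) -> pd.DataFrame:
        rows = []
        for cid, members in enumerate(self.clusters):
            for otu in members:
                rows.append(
                    {
                        "cluster_id": chr(ord("A") + cid) if cid < 26 else str(cid),
                        "otu_id": otu,
                        "genus": self.genera.get(otu, UNCLASSIFIED),
                    }
                )
        return pd.DataFrame(rows, columns=["cluster_id", "otu_id", "genus"])

    def to_tsv(self, path) -> None:
        self.membership().to_csv(path, sep="\t", index=False)


def rho_matrix(X: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Symmetric rho on the columns of a samples x OTUs value matrix.

    Zero-variance columns produce NaN rows/columns (diagonal stays 1); rho is
    invariant to the variance denominator convention, exposed for the tests.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    C = np.cov(X, rowvar=False, ddof=ddof)
    v = np.diag(C).copy()
    denom = v[:, None] + v[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = 2.0 * C / denom
    degenerate = v <= 0
    rho[degenerate, :] = np.nan
    rho[:, degenerate] = np.nan
    np.fill_diagonal(rho, 1.0)
    return rho


def expected_rho(
    mc: McInstances,
    exclude_otus: Sequence[str] = (),
) -> RhoGraph:
    """E(rho) as the mean of per-instance rho matrices.

    ``exclude_otus`` (e.g. OTUs zero-imputed in nearly every sample) are kept
    in the matrix but flagged NaN so they contribute no edges.
    """
    D = mc.n_otus
    acc = np.zeros((D, D))
    nan_any = np.zeros((D, D), dtype=bool)
    for k in range(mc.K):
        r = rho_matrix(mc.data[k])
        nan_any |= np.isnan(r)
        acc += np.where(np.isnan(r), 0.0, r)
    with np.errstate(invalid="ignore"):
        mean = acc / mc.K
    mean[nan_any] = np.nan
    np.fill_diagonal(mean, 1.0)
    frame = pd.DataFrame(mean, index=mc.otu_ids, columns=mc.otu_ids)
    unknown = [o for o in exclude_otus if o not in frame.index]
    if unknown:
        raise ValueError(f"exclude_otus not in the OTU set: {unknown}")
    for o in exclude_otus:
        frame.loc[o, :] = np.nan
        frame.loc[:, o] = np.nan
        frame.loc[o, o] = 1.0
    return RhoGraph(frame, K=mc.K)


def pair_diagnostics(clr: ClrMatrix, i: str, j: str) -> dict[str, float]:
    """Slope and Pearson correlation of OTU j against OTU i in clr space.

    The slope is the standardized major-axis (total-least-squares under
    per-axis scaling) slope ``sign(cov) * sd(j) / sd(i)``; a perfectly
    proportional pair gives slope 1 and correlation 1.
    """
    x = clr.values[i].to_numpy(dtype=float)
    y = clr.values[j].to_numpy(dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx <= 0 or vy <= 0:
        raise ValueError("pair_diagnostics requires non-constant columns")
    cov = np.cov(x, y, ddof=1)[0, 1]
    corr = cov / np.sqrt(vx * vy)
    slope = (1.0 if cov >= 0 else -1.0) * np.sqrt(vy / vx)
    return {"slope": float(slope), "corr": float(corr)}


def rho_clusters(
    graph: RhoGraph,
    cutoff: float = 0.65,
    min_size: int = 3,
    taxonomy: TaxonomyTable | None = None,
) -> ClusterSet:
    """Connected components of the graph thresholded at ``rho > cutoff``.

    Components with fewer than ``min_size`` members are discarded.  Clusters
    are ordered by size (largest first), members alphabetically; the result
    is therefore invariant to edge insertion order.
    """
    edges = graph.edges(cutoff)
    ids = np.asarray(graph.otu_ids)
    index = {o: i for i, o in enumerate(ids)}
    n = len(ids)
    if len(edges):
        rows = edges["otu_i"].map(index).to_numpy()
        cols = edges["otu_j"].map(index).to_numpy()
        adj = csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    clusters: list[list[str]] = []
    for c in range(n_comp):
        members = sorted(ids[labels == c])
        if len(members) >= min_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), m[0]))

    genera: dict[str, str] = {}
    if taxonomy is not None:
        for members in clusters:
            for o in members:
                genera[o] = taxonomy.genus(o)
    return ClusterSet(clusters=clusters, cutoff=cutoff, min_size=min_size, genera=genera)
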