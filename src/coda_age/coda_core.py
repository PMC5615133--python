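"""Compositional geometry shared by every downstream stage.

Zero replacement (count-zero-multiplicative), the centered log-ratio
transform, Dirichlet Monte-Carlo posterior instances, and the Aitchison
distance.  Log base 2 is the default throughout; statistics expressed as
ratios of log quantities (rho, variance fractions, standardized effects) are
base-invariant.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .table_io import CountTable

__all__ = [
    "Composition",
    "ClrMatrix",
    "McInstances",
    "czm_replace",
    "clr_transform",
    "dirichlet_instances",
    "aitchison_distance",
    "clr_from_counts",
]

LogBase = Literal["2", "e", 2]

_LOG_DIVISOR = {"2": np.log(2.0), 2: np.log(2.0), "e": 1.0}


def _log_divisor(log_base) -> float:
    try:
        return _LOG_DIVISOR[log_base]
    except KeyError:
        raise ValueError(f"log_base must be 2 or 'e', got {log_base!r}") from None


@dataclasses.dataclass
class Composition:
    """Strictly positive samples x OTUs matrix with unit row sums."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr <= 0):
            raise ValueError("composition entries must be strictly positive")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("composition rows must sum to 1")


@dataclasses.dataclass
class ClrMatrix:
    """Row-centered log-ratio matrix tagged with its log base."""

    values: pd.DataFrame
    log_base: str = "2"

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        d = arr.shape[1]
        if np.any(np.abs(arr.sum(axis=1)) > 1e-8 * d):
            raise ValueError("clr rows must sum to 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclasses.dataclass
class McInstances:
    """K Dirichlet Monte-Carlo clr instances of one count table.

    ``data`` has shape (K, samples, OTUs); every instance is row-centered.
    """

    data: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    prior_mass: float
    seed: int
    log_base: str = "2"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("expected (K, S, D) array")
        if self.K < 2:
            raise ValueError(f"need K >= 2 instances, got {self.K}")

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_otus(self) -> int:
        return self.data.shape[2]

    def instance(self, k: int) -> ClrMatrix:
        return ClrMatrix(
            pd.DataFrame(self.data[k], index=self.sample_ids, columns=self.otu_ids),
            log_base=self.log_base,
        )

    def mean_clr(self) -> ClrMatrix:
        """Arithmetic mean over instances (itself row-centered)."""
        return ClrMatrix(
            pd.DataFrame(
                self.data.mean(axis=0), index=self.sample_ids, columns=self.otu_ids
            ),
            log_base=self.log_base,
        )


def czm_replace(table: CountTable, prior_mass: float = 0.5) -> Composition:
    """Count-zero-multiplicative replacement.

    Zeros in sample ``s`` become ``prior_mass / depth[s]`` (in proportion
    units); non-zero proportions are multiplicatively shrunk by
    ``1 - n_zeros * delta`` so the row still sums to 1.
    """
    if prior_mass <= 0:
        raise ValueError("prior_mass must be positive")
    counts = table.counts.to_numpy(dtype=float)
    depths = counts.sum(axis=1)
    if np.any(depths <= 0):
        bad = [s for s, d in zip(table.sample_ids, depths) if d <= 0]
        raise ValueError(f"all-zero samples cannot be imputed: {bad}")
    props = counts / depths[:, None]
    zero = counts == 0
    delta = prior_mass / depths  # per-sample imputed proportion
    imputed_mass = zero.sum(axis=1) * delta
    if np.any(imputed_mass >= 1.0):
        raise ValueError("imputed mass >= 1; prior too large for this depth")
    out = props * (1.0 - imputed_mass[:, None])
    out[zero] = np.broadcast_to(delta[:, None], out.shape)[zero]
    return Composition(
        pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    )


def clr_transform(comp: Composition, log_base="2") -> ClrMatrix:
    """Centered log-ratio: ``log(x_j) - mean_j log(x_j)`` per sample."""
    div = _log_divisor(log_base)
    arr = comp.values.to_numpy(dtype=float)
    if np.any(arr <= 0):
        raise ValueError("clr requires strictly positive input")
    logs = np.log(arr) / div
    centered = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(centered, index=comp.values.index, columns=comp.values.columns),
        log_base=str(log_base),
    )


def clr_from_counts(
    table: CountTable, prior_mass: float = 0.5, log_base="2"
) -> ClrMatrix:
    """Convenience: CZM zero replacement followed by the clr transform."""
    return clr_transform(czm_replace(table, prior_mass), log_base)


def dirichlet_instances(
    table: CountTable,
    K: int = 128,
    prior_mass: float = 0.5,
    seed: int = 0,
    log_base="2",
) -> McInstances:
    """Draw K clr-transformed posterior compositions per sample.

    For each instance and each sample, a composition is drawn from
    ``Dirichlet(counts + prior_mass)`` and clr-transformed.  Deterministic
    given ``seed``.
    """
    if K < 2:
        raise ValueError(f"need K >= 2 instances, got {K}")
    if prior_mass <= 0:
        raise ValueError("prior_mass must be positive")
    div = _log_divisor(log_base)
    counts = table.counts.to_numpy(dtype=float)
    alpha = counts + prior_mass
    rng = np.random.default_rng(seed)
    S, D = alpha.shape
    data = np.empty((K, S, D))
    for k in range(K):
        # gamma trick: normalised Gamma(alpha) rows are Dirichlet(alpha)
        g = rng.standard_gamma(alpha)
        g /= g.sum(axis=1, keepdims=True)
        logs = np.log(g) / div
        data[k] = logs - logs.mean(axis=1, keepdims=True)
    return McInstances(
        data=data,
        sample_ids=table.sample_ids,
        otu_ids=table.otu_ids,
        prior_mass=prior_mass,
        seed=seed,
        log_base=str(log_base),
    )


def aitchison_distance(clr: ClrMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distance between clr rows (the Aitchison metric)."""
    arr = clr.values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dm = squareform(pdist(arr, metric="euclidean"))
    ids = clr.values.index
    return pd.DataFrame(dm, index=ids, columns=ids)
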