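"""PERMANOVA on the Aitchison distance, group dispersion, and diversity.

PERMANOVA follows the classic partition of a Gower-centered squared-distance
matrix: with n samples in g groups,

    SS_total = (1/n) * sum_{i<j} d_ij^2
    SS_within = sum_groups (1/n_g) * sum_{i<j in group} d_ij^2
    pseudo_F = (SS_between / (g-1)) / (SS_within / (n-g))

and the p-value is estimated by permuting group labels (with the +1
correction), or computed exactly by enumerating every distinct label
assignment when requested.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .coda_core import ClrMatrix
from .table_io import CountTable

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "DiversityProfile",
    "permanova",
    "pairwise_permanova",
    "group_dispersion",
    "shannon_diversity",
    "depth_diversity_check",
    "smooth_age_trend",
]


@dataclasses.dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int | None
    n_samples: int
    groups: tuple[str, ...]
    method: str = "monte_carlo"

    def __post_init__(self) -> None:
        assert self.pseudo_F >= 0
        assert 0.0 <= self.R2 <= 1.0


@dataclasses.dataclass
class DispersionResult:
    """Per-group median (MCD) and IQR of member distances to the group
    centroid in clr space."""

    frame: pd.DataFrame  # columns: group, n, mcd, iqr

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class DiversityProfile:
    """Per-sample Shannon diversity (natural-log units) and read depth."""

    frame: pd.DataFrame  # index sample, columns: depth, shannon

    def to_tsv(self, path) -> None:
        self.frame.rename_axis("sample_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PERMANOVA


def _group_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Within-group sum of squared distances, each group scaled by 1/n_g."""
    ss = 0.0
    for g in groups:
        ix = np.flatnonzero(labels == g)
        sub = d2[np.ix_(ix, ix)]
        ss += sub[np.triu_indices(len(ix), k=1)].sum() / len(ix)
    return ss


def _f_stat(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    g = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = _group_ss(d2, labels, groups)
    ss_between = ss_total - ss_within
    F = (ss_between / (g - 1)) / (ss_within / (n - g))
    R2 = ss_between / ss_total
    return F, R2


def _multiset_permutations(items: Sequence) -> Iterator[tuple]:
    """Distinct orderings of a multiset (lexicographic, no repeats)."""
    items = sorted(items)
    n = len(items)
    seq = list(items)
    yield tuple(seq)
    while True:
        i = n - 2
        while i >= 0 and seq[i] >= seq[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while seq[j] <= seq[i]:
            j -= 1
        seq[i], seq[j] = seq[j], seq[i]
        seq[i + 1:] = reversed(seq[i + 1:])
        yield tuple(seq)


def permanova(
    dist: pd.DataFrame,
    labels,
    n_permutations: int = 999,
    seed: int | None = 0,
    method: str = "monte_carlo",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``method='monte_carlo'`` permutes labels ``n_permutations`` times and
    reports ``p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1)``.
    ``method='exact'`` enumerates all distinct label assignments (identity
    included) and reports the exact tail fraction; only feasible for small n.
    """
    dist = pd.DataFrame(dist)
    if isinstance(labels, pd.Series):
        labels = labels.loc[dist.index]
    labels = np.asarray(labels)
    n = dist.shape[0]
    if len(labels) != n:
        raise ValueError("labels length does not match distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = np.asarray(dist, dtype=float) ** 2
    if not np.isfinite(d2).all():
        raise ValueError("distance matrix contains non-finite values")
    F_obs, R2 = _f_stat(d2, labels, groups)

    if method == "exact":
        n_total = 0
        n_ge = 0
        for perm in _multiset_permutations(labels.tolist()):
            Fp, _ = _f_stat(d2, np.asarray(perm), groups)
            n_total += 1
            if Fp >= F_obs - 1e-12:
                n_ge += 1
        p = n_ge / n_total
        return PermanovaResult(
            pseudo_F=float(F_obs), R2=float(R2), p_value=float(p),
            n_permutations=n_total, seed=None, n_samples=n,
            groups=tuple(map(str, groups)), method="exact",
        )
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n_ge = 0
    perm_labels = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm_labels)
        Fp, _ = _f_stat(d2, perm_labels, groups)
        if Fp >= F_obs - 1e-12:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_F=float(F_obs), R2=float(R2), p_value=float(p),
        n_permutations=n_permutations, seed=seed, n_samples=n,
        groups=tuple(map(str, groups)),
    )


def pairwise_permanova(
    dist: pd.DataFrame,
    labels: pd.Series,
    pairs: Sequence[tuple[str, str]] | str = "all",
    n_permutations: int = 999,
    seed: int | None = 0,
) -> list[PermanovaResult]:
    """PERMANOVA per group pair on the corresponding sub-distance-matrix.

    No multiplicity correction is applied; raw p-values are reported.
    """
    labels = pd.Series(labels).loc[dist.index]
    groups = list(pd.unique(labels))
    if pairs == "all":
        pair_list = list(itertools.combinations(groups, 2))
    else:
        pair_list = [tuple(p) for p in pairs]
    results = []
    for a, b in pair_list:
        mask = labels.isin([a, b])
        ids = labels.index[mask]
        sub = dist.loc[ids, ids]
        results.append(
            permanova(sub, labels.loc[ids], n_permutations=n_permutations, seed=seed)
        )
    return results


# ---------------------------------------------------------------------------
# dispersion & diversity


def group_dispersion(clr: ClrMatrix, labels) -> DispersionResult:
    """Median and IQR of member distances to each group's clr centroid."""
    X = clr.values
    if isinstance(labels, pd.Series):
        labels = labels.loc[X.index]
    labels = pd.Series(np.asarray(labels), index=X.index)
    rows = []
    for g, ids in labels.groupby(labels).groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
        sub = X.loc[ids].to_numpy(dtype=float)
        centroid = sub.mean(axis=0)
        dists = np.linalg.norm(sub - centroid, axis=1)
        q25, q75 = np.percentile(dists, [25, 75])
        rows.append(
            {"group": g, "n": len(ids), "mcd": float(np.median(dists)),
             "iqr": float(q75 - q25)}
        )
    return DispersionResult(pd.DataFrame(rows, columns=["group", "n", "mcd", "iqr"]))


def shannon_diversity(table: CountTable) -> DiversityProfile:
    """Shannon diversity H = -sum p log p (natural log) over positive counts."""
    counts = table.counts.to_numpy(dtype=float)
    depth = counts.sum(axis=1)
    if np.any(depth <= 0):
        bad = [s for s, d in zip(table.sample_ids, depth) if d <= 0]
        raise ValueError(f"zero-depth samples: {bad}")
    p = counts / depth[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -terms.sum(axis=1)
    frame = pd.DataFrame(
        {"depth": depth.astype(int), "shannon": H}, index=table.counts.index
    )
    return DiversityProfile(frame)


@dataclasses.dataclass
class DepthDiversityCheck:
    spearman_r: float
    p_value: float
    depth_confounded: bool
    n_permutations: int


def depth_diversity_check(
    profile: DiversityProfile,
    n_permutations: int = 999,
    seed: int | None = 0,
    r_threshold: float = 0.3,
    p_threshold: float = 0.01,
) -> DepthDiversityCheck:
    """Spearman correlation of read depth vs Shannon H with a permutation p.

    Flags 'depth-confounded' when |r| exceeds ``r_threshold`` with
    ``p < p_threshold``.
    """
    frame = profile.frame
    if len(frame) < 10:
        raise ValueError("need at least 10 samples")
    depth = frame["depth"].to_numpy(dtype=float)
    H = frame["shannon"].to_numpy(dtype=float)
    if np.ptp(depth) == 0:
        raise ValueError("constant read depth; correlation undefined")
    rd = rankdata(depth)
    rh = rankdata(H)
    r_obs = np.corrcoef(rd, rh)[0, 1]
    rng = np.random.default_rng(seed)
    n_ge = 0
    perm = rh.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if abs(np.corrcoef(rd, perm)[0, 1]) >= abs(r_obs) - 1e-12:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return DepthDiversityCheck(
        spearman_r=float(r_obs),
        p_value=float(p),
        depth_confounded=bool(abs(r_obs) > r_threshold and p < p_threshold),
        n_permutations=n_permutations,
    )


def smooth_age_trend(
    values,
    ages,
    span: float = 0.75,
    grid=None,
) -> pd.DataFrame:
    """Locally weighted (tricube) linear regression of values on age.

    Evaluated on an integer age grid by default.  Backed by the lowess
    smoother, which is exact for data lying on a line.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(values) != len(ages):
        raise ValueError("values and ages differ in length")
    if len(values) < 10:
        raise ValueError("need at least 10 samples")
    distinct = np.unique(ages)
    if len(distinct) < 3:
        raise ValueError("need at least 3 distinct ages")
    if grid is None:
        grid = np.arange(int(np.floor(ages.min())), int(np.ceil(ages.max())) + 1)
    grid = np.asarray(grid, dtype=float)
    smoothed = sm.nonparametric.lowess(
        values, ages, frac=span, it=0, xvals=grid, is_sorted=False
    )
    return pd.DataFrame({"age": grid, "smoothed": smoothed})
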