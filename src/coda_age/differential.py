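"""Expected standardized effect sizes between sample groups.

For each Monte-Carlo instance and group pair (A, B), aligned random draws
give per-OTU between-group differences ``z = x_B - x_A`` and within-group
dispersions ``w = max(|x_A - x_A'|, |x_B - x_B'|)``; the instance effect is
``median(z / w)`` over draws, and the reported effect is the arithmetic mean
over instances (the expected value of the statistic).  An absolute effect of
1 means the between-group difference matches the larger within-group spread.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .association import RhoGraph
from .coda_core import McInstances
from .table_io import RANKS, TaxonomyTable, UNCLASSIFIED

__all__ = [
    "EffectTable",
    "SelectionResult",
    "effect_size",
    "pairwise_effects",
    "select_explanatory",
    "bin_by_taxon",
    "successive_pairs",
]


@dataclasses.dataclass
class EffectTable:
    """Long-format per-OTU, per-pair effect estimates.

    Columns: otu_id, group_a, group_b, diff_btw, diff_win, effect.
    """

    frame: pd.DataFrame

    REQUIRED = ("otu_id", "group_a", "group_b", "diff_btw", "diff_win", "effect")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"effect table missing columns: {missing}")

    @property
    def otu_ids(self) -> list[str]:
        return list(pd.unique(self.frame["otu_id"]))

    @property
    def pairs(self) -> list[tuple[str, str]]:
        seen = self.frame[["group_a", "group_b"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    def max_abs_effect(self) -> pd.Series:
        """Per-OTU maximum |effect| over all pairs present."""
        return self.frame.groupby("otu_id")["effect"].agg(lambda s: s.abs().max())

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class SelectionResult:
    """OTUs selected as explanatory, with the rule(s) that kept each."""

    frame: pd.DataFrame  # columns: otu_id, reason in {effect, rho, both}
    effect_cut: float
    rho_cut: float

    @property
    def otu_ids(self) -> list[str]:
        return list(self.frame["otu_id"])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def _labels_array(mc: McInstances, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        missing = [s for s in mc.sample_ids if s not in labels.index]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        return labels.loc[mc.sample_ids].to_numpy()
    arr = np.asarray(labels)
    if len(arr) != mc.n_samples:
        raise ValueError("labels length does not match sample count")
    return arr


def _distinct_draws(rng: np.random.Generator, idx: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Two uniform with-replacement draws, distinct elementwise (no self-pairs)."""
    a = rng.choice(idx, size=m)
    b = rng.choice(idx, size=m)
    clash = a == b
    while clash.any():
        b[clash] = rng.choice(idx, size=int(clash.sum()))
        clash = a == b
    return a, b


def effect_size(
    mc: McInstances,
    labels,
    pair: tuple[str, str],
    seed: int = 0,
    n_draws: int | None = None,
) -> pd.DataFrame:
    """Effect-size rows for one ordered group pair (A, B); positive effect
    means the OTU is relatively more abundant in B.

    Group sizes are equalized by uniform resampling with replacement
    (``n_draws`` defaults to the larger group size); the random pairing is
    seeded on the unordered pair so swapping (A, B) exactly negates diff_btw
    and effect.
    """
    A, B = pair
    lab = _labels_array(mc, labels)
    for g in (A, B):
        if g not in lab:
            raise ValueError(f"unknown group label {g!r}")
    idx = {g: np.flatnonzero(lab == g) for g in (A, B)}
    for g, ix in idx.items():
        if len(ix) < 2:
            raise ValueError(f"group {g!r} has {len(ix)} samples; need >= 2")

    lo, hi = sorted((str(A), str(B)))
    pair_seed = np.random.SeedSequence([seed, _stable_hash(lo), _stable_hash(hi)])
    rng = np.random.default_rng(pair_seed)
    m = n_draws or max(len(idx[A]), len(idx[B]))
    sign = 1.0 if (str(A), str(B)) == (lo, hi) else -1.0
    glo = A if str(A) == lo else B
    ghi = B if glo == A else A

    D = mc.n_otus
    eff_acc = np.zeros(D)
    btw_acc = np.zeros(D)
    win_acc = np.zeros(D)
    for k in range(mc.K):
        X = mc.data[k]
        i1, i1b = _distinct_draws(rng, idx[glo], m)
        i2, i2b = _distinct_draws(rng, idx[ghi], m)
        z = X[i2] - X[i1]                       # x_hi - x_lo, draws x OTUs
        w = np.maximum(np.abs(X[i1] - X[i1b]), np.abs(X[i2] - X[i2b]))
        eff_acc += np.median(z / w, axis=0)
        btw_acc += np.median(z, axis=0)
        win_acc += np.median(w, axis=0)
    K = mc.K
    return pd.DataFrame(
        {
            "otu_id": mc.otu_ids,
            "group_a": A,
            "group_b": B,
            "diff_btw": sign * btw_acc / K,
            "diff_win": win_acc / K,
            "effect": sign * eff_acc / K,
        }
    )


def _stable_hash(s: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.blake2b(s.encode(), digest_size=4).digest(), "little")


def successive_pairs(order: Sequence[str]) -> list[tuple[str, str]]:
    return [(order[i], order[i + 1]) for i in range(len(order) - 1)]


def pairwise_effects(
    mc: McInstances,
    labels,
    pairs: str | Sequence[tuple[str, str]] = "all",
    cohort_order: Sequence[str] | None = None,
    seed: int = 0,
) -> EffectTable:
    """Effect table over many group pairs.

    ``pairs='all'`` uses every unordered pair; ``'successive'`` walks the
    declared cohort ordering (defaulting to order of first appearance in the
    labels); an explicit pair list is used verbatim.
    """
    lab = _labels_array(mc, labels)
    if cohort_order is None:
        cohort_order = list(pd.unique(pd.Series(lab)))
    else:
        unknown = set(cohort_order) - set(np.unique(lab).tolist())
        if unknown:
            raise ValueError(f"cohort_order names unknown groups: {sorted(unknown)}")
    if isinstance(pairs, str):
        if pairs == "all":
            pair_list = list(itertools.combinations(cohort_order, 2))
        elif pairs == "successive":
            pair_list = successive_pairs(cohort_order)
        else:
            raise ValueError(f"pairs must be 'all', 'successive' or a list, got {pairs!r}")
    else:
        pair_list = [tuple(p) for p in pairs]
    if not pair_list:
        raise ValueError("no group pairs to compare")
    frames = [effect_size(mc, labels, p, seed=seed) for p in pair_list]
    return EffectTable(pd.concat(frames, ignore_index=True))


def select_explanatory(
    eff: EffectTable,
    rho: RhoGraph,
    effect_cut: float = 1.0,
    rho_cut: float = 0.65,
) -> SelectionResult:
    """OTUs with |effect| >= effect_cut in any pair, or belonging to any
    OTU pair with E(rho) > rho_cut."""
    eff_otus = set(eff.otu_ids)
    rho_otus = set(rho.otu_ids)
    if eff_otus != rho_otus:
        raise ValueError(
            "effect table and rho graph cover different OTU sets "
            f"({len(eff_otus)} vs {len(rho_otus)} OTUs)"
        )
    by_effect = set(eff.max_abs_effect().pipe(lambda s: s[s >= effect_cut]).index)
    edges = rho.edges(rho_cut)
    by_rho = set(edges["otu_i"]) | set(edges["otu_j"])
    rows = []
    for otu in sorted(by_effect | by_rho):
        reason = (
            "both" if otu in by_effect and otu in by_rho
            else "effect" if otu in by_effect
            else "rho"
        )
        rows.append({"otu_id": otu, "reason": reason})
    return SelectionResult(
        frame=pd.DataFrame(rows, columns=["otu_id", "reason"]),
        effect_cut=effect_cut,
        rho_cut=rho_cut,
    )


def bin_by_taxon(
    eff: EffectTable,
    tax: TaxonomyTable,
    rank: str = "genus",
    effect_cut: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Annotate effect rows with a taxon bin and summarise per bin.

    OTUs unclassified at ``rank`` share one pooled bin.  Returns the
    annotated long frame and a per-(pair, bin) summary with member count,
    median effect and the count of members at |effect| >= effect_cut.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    lineage = tax.frame[rank] if len(tax.frame) else pd.Series(dtype=str)
    binned = eff.frame.copy()
    binned["taxon"] = [
        lineage.get(o, UNCLASSIFIED) for o in binned["otu_id"]
    ]
    binned["taxon"] = binned["taxon"].fillna(UNCLASSIFIED)
    summary = (
        binned.groupby(["group_a", "group_b", "taxon"], sort=True)
        .agg(
            n_otus=("otu_id", "nunique"),
            median_effect=("effect", "median"),
            n_above_cut=("effect", lambda s: int((s.abs() >= effect_cut).sum())),
        )
        .reset_index()
    )
    return binned, summary
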