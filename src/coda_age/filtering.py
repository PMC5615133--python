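"""Abundance/prevalence OTU filters.

Conventions (documented, not inferred from data):

* the minimum-abundance rule is strict (``>``), the prevalence rule is
  inclusive (``>=``);
* proportions are always computed against each sample's *original* depth,
  before any OTU removal, so the retained set is independent of the order in
  which filters are applied;
* prevalence counts strictly positive cells.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .table_io import CountTable, CountTableError

__all__ = ["FilterSpec", "FilterReport", "filter_otus", "drop_singletons"]


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """Thresholds for :func:`filter_otus`.

    min_prop_any
        Retain OTU only if its relative abundance exceeds this in >=1 sample.
    min_prevalence
        Retain OTU only if present (count>0) in at least this fraction of
        samples.
    max_prop_any
        Optional band filter: drop OTUs exceeding this proportion in any
        sample (used to exclude dominant taxa).
    min_prop_any_strict
        Optional band filter: a stricter minimum-abundance threshold (used to
        exclude rare taxa).
    """

    min_prop_any: float = 0.001
    min_prevalence: float = 0.2
    max_prop_any: float | None = None
    min_prop_any_strict: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_prop_any", "min_prevalence", "max_prop_any",
                     "min_prop_any_strict"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        lo = self.min_prop_any
        if self.min_prop_any_strict is not None:
            lo = max(lo, self.min_prop_any_strict)
        if self.max_prop_any is not None and lo >= self.max_prop_any:
            raise ValueError("minimum proportion threshold >= max_prop_any")


@dataclasses.dataclass
class FilterReport:
    """Removed OTUs with one reason each (first failing rule wins)."""

    removed: pd.DataFrame  # columns: otu_id, reason

    def to_tsv(self, path) -> None:
        self.removed.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.removed)


def filter_otus(table: CountTable, spec: FilterSpec) -> tuple[CountTable, FilterReport]:
    """Apply abundance and prevalence thresholds to the OTU set.

    Retains OTU j iff ``max_s count[s,j]/depth[s] > min_prop_any`` and the
    fraction of samples with a positive count is ``>= min_prevalence``; the
    optional band thresholds are applied afterwards.  Samples are untouched.
    """
    depths = table.depth.to_numpy()
    if np.any(depths <= 0):
        raise CountTableError("cannot filter: zero-depth samples present")
    counts = table.counts.to_numpy()
    props = counts / depths[:, None]
    max_prop = props.max(axis=0)
    prevalence = (counts > 0).mean(axis=0)

    reasons: dict[str, str] = {}
    otus = np.asarray(table.otu_ids)
    keep = np.ones(len(otus), dtype=bool)

    fail = max_prop <= spec.min_prop_any
    for o in otus[fail & keep]:
        reasons[o] = "min_prop_any"
    keep &= ~fail

    fail = prevalence < spec.min_prevalence
    for o in otus[fail & keep]:
        reasons[o] = "min_prevalence"
    keep &= ~fail

    if spec.min_prop_any_strict is not None:
        fail = max_prop <= spec.min_prop_any_strict
        for o in otus[fail & keep]:
            reasons[o] = "min_prop_any_strict"
        keep &= ~fail
    if spec.max_prop_any is not None:
        fail = max_prop > spec.max_prop_any
        for o in otus[fail & keep]:
            reasons[o] = "max_prop_any"
        keep &= ~fail

    report = FilterReport(
        pd.DataFrame(
            {"otu_id": list(reasons), "reason": list(reasons.values())}
        )
    )
    if keep.sum() < 2:
        raise CountTableError(
            f"filter retains {int(keep.sum())} OTUs (<2); "
            f"{len(report)} removed — loosen the thresholds"
        )
    filtered = CountTable(
        table.counts.loc[:, otus[keep]], table.metadata, table.taxonomy
    )
    return filtered, report


def drop_singletons(table: CountTable) -> CountTable:
    """Remove OTUs whose total count across all samples is <= 1."""
    totals = table.counts.sum(axis=0)
    keep = totals[totals > 1].index
    return CountTable(table.counts[keep], table.metadata, table.taxonomy)
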