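"""Reading, writing and validation of OTU count tables, taxonomy and metadata.

The canonical on-disk layout is tab-separated text with OTU ids in the first
column and sample ids in the header row (classic QIIME orientation); the
transposed layout is accepted via the ``orientation`` flag.  Taxonomy may be
embedded as a trailing ``taxonomy`` column of the count table or supplied as a
separate two-column TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "TaxonomyTable",
    "CountTableError",
    "RANKS",
    "UNCLASSIFIED",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "join_metadata",
    "parse_lineage",
    "read_taxonomy",
]

#: Fixed rank order used throughout; genus is the finest rank retained.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"

_RANK_PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")


class CountTableError(ValueError):
    """Raised for malformed count tables, metadata or taxonomy inputs."""


@dataclasses.dataclass
class CountTable:
    """Validated samples x OTUs integer count matrix with optional annotations.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers; index = sample ids, columns = OTU ids.
    metadata : pandas.DataFrame, optional
        Indexed by sample id; joined via :func:`join_metadata`.
    taxonomy : TaxonomyTable, optional
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    taxonomy: "TaxonomyTable | None" = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape[0] < 2 or c.shape[1] < 2:
            raise CountTableError(
                f"need at least 2 samples and 2 OTUs, got {c.shape}"
            )
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample ids: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate OTU ids: {dups}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = _first_bad_cell(c, lambda v: not _is_number(v))
            raise CountTableError(f"non-numeric count at {bad}")
        if np.any(arr < 0):
            bad = _first_bad_cell(c, lambda v: v < 0)
            raise CountTableError(f"negative count at {bad}")
        if not np.allclose(arr, np.round(arr)):
            bad = _first_bad_cell(c, lambda v: float(v) != round(float(v)))
            raise CountTableError(f"non-integer count at {bad}")
        self.counts = c.astype(np.int64)

    # -- derived quantities -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depth(self) -> pd.Series:
        """Per-sample total read count (row sums)."""
        return self.counts.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def proportions(self) -> pd.DataFrame:
        """Counts closed to relative abundances against each sample's depth."""
        d = self.depth
        if (d == 0).any():
            zero = d.index[d == 0].tolist()
            raise CountTableError(f"zero-depth samples: {zero}")
        return self.counts.div(d, axis=0)

    # -- subsetting ---------------------------------------------------------

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise CountTableError(f"unknown sample ids: {missing}")
        meta = None
        if self.metadata is not None:
            meta = self.metadata.loc[[s for s in sample_ids]]
        return CountTable(self.counts.loc[list(sample_ids)], meta, self.taxonomy)

    def select_otus(self, otu_ids: Sequence[str]) -> "CountTable":
        missing = [o for o in otu_ids if o not in self.counts.columns]
        if missing:
            raise CountTableError(f"unknown OTU ids: {missing}")
        return CountTable(self.counts[list(otu_ids)], self.metadata, self.taxonomy)

    def groups(self, column: str = "cohort") -> pd.Series:
        if self.metadata is None or column not in self.metadata.columns:
            raise CountTableError(f"no metadata column {column!r}; join metadata first")
        return self.metadata.loc[self.counts.index, column]


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def _first_bad_cell(df: pd.DataFrame, pred) -> str:
    for s in df.index:
        for o in df.columns:
            try:
                if pred(df.at[s, o]):
                    return f"sample {s!r} / OTU {o!r}"
            except TypeError:
                return f"sample {s!r} / OTU {o!r}"
    return "<unknown>"


# ---------------------------------------------------------------------------
# taxonomy


class TaxonomyTable:
    """Per-OTU ranked lineage with explicit ``unclassified`` placeholders."""

    def __init__(self, frame: pd.DataFrame):
        missing = [r for r in RANKS if r not in frame.columns]
        if missing:
            raise CountTableError(f"taxonomy missing ranks: {missing}")
        self.frame = frame[list(RANKS)].copy()

    def rank(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise CountTableError(f"unknown rank {rank!r}; choose from {RANKS}")
        return self.frame[rank]

    def genus(self, otu_id: str) -> str:
        if otu_id not in self.frame.index:
            return UNCLASSIFIED
        return self.frame.at[otu_id, "genus"]

    def genus_of(self, otu_ids: Iterable[str]) -> pd.Series:
        """Genus label per OTU; OTUs absent from the table are unclassified."""
        return pd.Series(
            {o: self.genus(o) for o in otu_ids}, name="genus"
        )

    def __len__(self) -> int:
        return len(self.frame)


def parse_lineage(
    lineages: Mapping[str, str] | pd.Series,
    delimiter: str = ";",
    strip_prefixes: bool = True,
) -> TaxonomyTable:
    """Parse ``otu_id -> delimited lineage string`` into a ranked table.

    Lenient: malformed or empty strings yield fully unclassified rows.  Rank
    assignment is positional (domain, phylum, ..., genus); tokens equal to
    common null markers become ``unclassified``.
    """
    if isinstance(lineages, pd.Series):
        lineages = lineages.to_dict()
    rows = {}
    for otu, s in lineages.items():
        tokens: list[str] = []
        if isinstance(s, str) and s.strip():
            for tok in s.split(delimiter):
                tok = tok.strip()
                if strip_prefixes:
                    for p in _RANK_PREFIXES:
                        if tok.startswith(p):
                            tok = tok[len(p):]
                            break
                if tok.lower() in ("", "na", "none", "unknown", "unclassified"):
                    tok = UNCLASSIFIED
                tokens.append(tok)
        row = {}
        for i, rank in enumerate(RANKS):
            row[rank] = tokens[i] if i < len(tokens) else UNCLASSIFIED
        rows[otu] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "otu_id"
    return TaxonomyTable(frame if len(frame) else _empty_taxonomy())


def _empty_taxonomy() -> pd.DataFrame:
    return pd.DataFrame(columns=list(RANKS)).rename_axis("otu_id")


def read_taxonomy(path: str | Path, delimiter: str = ";") -> TaxonomyTable:
    """Read a two-column TSV (otu_id, lineage) into a :class:`TaxonomyTable`."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise CountTableError(f"{path}: expected two columns (otu_id, lineage)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return parse_lineage(mapping, delimiter=delimiter)


# ---------------------------------------------------------------------------
# count table I/O


def read_count_table(
    path: str | Path,
    orientation: str = "otus_in_rows",
    taxonomy_column: str = "taxonomy",
) -> CountTable:
    """Read a TSV count table, normalising to samples x OTUs.

    ``orientation`` declares the on-disk layout: ``otus_in_rows`` (canonical;
    OTU ids in the first column, sample ids in the header) or
    ``samples_in_rows``.  A trailing ``taxonomy`` column, if present, is
    parsed into the returned table's taxonomy.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("samples_in_rows", "otus_in_rows"):
        raise CountTableError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None

    taxonomy = None
    if orientation == "otus_in_rows":
        if taxonomy_column in df.columns:
            taxonomy = parse_lineage(df[taxonomy_column].astype(str))
            df = df.drop(columns=[taxonomy_column])
        df = df.T
        df.index.name = None
        df.columns.name = None
    else:
        # taxonomy cannot be embedded row-wise in this layout
        pass
    try:
        return CountTable(df, taxonomy=taxonomy)
    except CountTableError as e:
        raise CountTableError(f"{path}: {e}") from e


def write_count_table(
    table: CountTable,
    path: str | Path,
    orientation: str = "otus_in_rows",
    header_comment: str | None = None,
) -> None:
    """Write a count table as TSV in the requested orientation."""
    if orientation not in ("samples_in_rows", "otus_in_rows"):
        raise CountTableError(f"unknown orientation {orientation!r}")
    df = table.counts if orientation == "samples_in_rows" else table.counts.T
    df = df.rename_axis("id")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV indexed by its first column (sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype={0: str})
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise CountTableError(f"{path}: duplicate sample ids {dups}")
    if "age" in df.columns:
        ages = pd.to_numeric(df["age"], errors="raise")
        if (ages < 0).any():
            raise CountTableError(f"{path}: negative ages present")
        df["age"] = ages
    return df


def join_metadata(
    table: CountTable,
    meta: pd.DataFrame,
    policy: str = "strict",
) -> tuple[CountTable, list[str]]:
    """Attach sample metadata to a count table.

    policy ``strict``: every table sample must have a metadata row (error
    otherwise).  policy ``intersect``: keep only samples present in both,
    returning the dropped sample ids alongside the annotated table.
    """
    if policy not in ("strict", "intersect"):
        raise CountTableError(f"unknown join policy {policy!r}")
    if meta.index.has_duplicates:
        raise CountTableError("metadata has duplicate sample ids")
    table_ids = table.counts.index
    have = table_ids.isin(meta.index)
    if policy == "strict":
        if not have.all():
            missing = table_ids[~have].tolist()
            raise CountTableError(f"samples missing from metadata: {missing}")
        kept = table_ids
        dropped: list[str] = []
    else:
        kept = table_ids[have]
        dropped = table_ids[~have].tolist()
        if len(kept) < 2:
            raise CountTableError("metadata intersection leaves <2 samples")
    annotated = CountTable(
        table.counts.loc[kept],
        metadata=meta.loc[kept],
        taxonomy=table.taxonomy,
    )
    return annotated, dropped
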