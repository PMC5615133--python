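"""Dirichlet-multinomial OTU-table simulation with known ground truth.

Each sample's expected log2 abundance vector is the shared base composition
plus (i) its group's sparse shift vector, (ii) one latent value per
proportional block (shared by block members up to a small jitter), and
(iii) independent per-OTU noise.  The vector is closed to a probability
composition, optionally perturbed by a Dirichlet draw (overdispersion
precision ``theta``; ``theta = inf`` degenerates to pure multinomial), and
counted by a multinomial draw at a log-normally distributed depth.

Group shifts are specified in log2 clr-like units so recovery targets are in
the same currency the differential module reports.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .table_io import CountTable, TaxonomyTable, parse_lineage

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_table", "make_fixture",
           "FIXTURES"]

# age ranges loosely mirroring an eight-cohort, childhood-to-centenarian design
_DEFAULT_AGE_RANGES = [
    (3, 6), (8, 12), (13, 14), (19, 24), (19, 24), (30, 50), (60, 79), (95, 106),
]
_COHORT_LABELS = ["3-6", "8-12", "13-14", "19-24", "19-24S", "30-50", "60-79", ">94"]

_GENUS_POOL = [
    "Prevotella", "Bacteroides", "Bifidobacterium", "Faecalibacterium",
    "Blautia", "Dorea", "Roseburia", "Clostridium", "Ruminococcus",
    "Anaerostipes", "Marvinbryantia", "Lachnospira",
]


@dataclasses.dataclass
class SyntheticSpec:
    """Generator parameters; see the module docstring for the model."""

    n_groups: int = 2
    samples_per_group: int | Sequence[int] = 50
    n_otus: int = 100
    base_log_composition: np.ndarray | None = None  # log2 units; drawn if None
    base_sigma: float = 2.0
    group_shifts: dict[tuple[int, int], float] = dataclasses.field(default_factory=dict)
    proportional_blocks: list[list[int]] = dataclasses.field(default_factory=list)
    block_sigma: float = 0.1
    latent_sigma: float = 1.0
    noise_sigma: float = 0.5
    overdispersion: float = math.inf  # Dirichlet precision theta
    depth_mean: float = 1e4          # median of the log-normal depth law
    depth_sigma: float = 0.25        # sd of log(depth)
    seed: int = 0
    group_names: list[str] | None = None
    age_ranges: list[tuple[int, int]] | None = None
    fraction_unclassified: float = 0.15

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_otus < 2:
            raise ValueError("need n_groups >= 1 and n_otus >= 2")
        sizes = self.sizes
        if min(sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        seen: set[int] = set()
        for block in self.proportional_blocks:
            bset = set(block)
            if len(bset) != len(block):
                raise ValueError(f"block has repeated members: {block}")
            if bset & seen:
                raise ValueError("proportional blocks must be disjoint")
            if any(j < 0 or j >= self.n_otus for j in block):
                raise ValueError(f"block index out of range: {block}")
            seen |= bset
        for (g, j), v in self.group_shifts.items():
            if not (0 <= g < self.n_groups and 0 <= j < self.n_otus):
                raise ValueError(f"shift key out of range: {(g, j)}")
            if not math.isfinite(v):
                raise ValueError(f"non-finite shift for {(g, j)}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")

    @property
    def sizes(self) -> list[int]:
        if isinstance(self.samples_per_group, int):
            return [self.samples_per_group] * self.n_groups
        sizes = list(self.samples_per_group)
        if len(sizes) != self.n_groups:
            raise ValueError("samples_per_group length != n_groups")
        return sizes

    @property
    def labels(self) -> list[str]:
        if self.group_names is not None:
            if len(self.group_names) != self.n_groups:
                raise ValueError("group_names length != n_groups")
            return list(self.group_names)
        return [f"g{i + 1}" for i in range(self.n_groups)]


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated table."""

    expected_compositions: pd.DataFrame   # samples x OTUs probabilities
    spiked: pd.DataFrame                  # columns: group, otu_id, shift_log2
    blocks: list[list[str]]               # OTU ids per proportional block
    seed: int

    @property
    def spiked_otus(self) -> list[str]:
        return sorted(set(self.spiked["otu_id"]))

    @property
    def block_otus(self) -> list[str]:
        return sorted({o for b in self.blocks for o in b})

    @property
    def true_otus(self) -> list[str]:
        """All OTUs carrying planted structure (spiked or block members)."""
        return sorted(set(self.spiked_otus) | set(self.block_otus))

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.spiked.to_csv(out / "truth_spiked.tsv", sep="\t", index=False)
        rows = [
            {"block_id": i, "otu_id": o}
            for i, members in enumerate(self.blocks)
            for o in members
        ]
        pd.DataFrame(rows, columns=["block_id", "otu_id"]).to_csv(
            out / "truth_blocks.tsv", sep="\t", index=False
        )
        self.expected_compositions.rename_axis("sample_id").to_csv(
            out / "truth_compositions.tsv", sep="\t"
        )
        (out / "truth_meta.json").write_text(json.dumps({"seed": self.seed}))

    @classmethod
    def read(cls, in_dir: str | Path) -> "SyntheticTruth":
        src = Path(in_dir)
        spiked = pd.read_csv(src / "truth_spiked.tsv", sep="\t").fillna("")
        blocks_frame = pd.read_csv(src / "truth_blocks.tsv", sep="\t")
        blocks = [
            sorted(g["otu_id"].astype(str))
            for _, g in blocks_frame.groupby("block_id")
        ]
        comps = pd.read_csv(src / "truth_compositions.tsv", sep="\t", index_col=0)
        meta = json.loads((src / "truth_meta.json").read_text())
        spiked["otu_id"] = spiked["otu_id"].astype(str)
        return cls(
            expected_compositions=comps,
            spiked=spiked,
            blocks=blocks,
            seed=int(meta["seed"]),
        )


def _make_taxonomy(otu_ids: list[str], frac_unclassified: float,
                   rng: np.random.Generator) -> TaxonomyTable:
    lineages = {}
    for o in otu_ids:
        if rng.random() < frac_unclassified:
            lineages[o] = ""
        else:
            genus = _GENUS_POOL[int(rng.integers(len(_GENUS_POOL)))]
            lineages[o] = (
                f"Bacteria;SomePhylum;SomeClass;SomeOrder;SomeFamily;{genus}"
            )
    return parse_lineage(lineages)


def generate_table(spec: SyntheticSpec) -> tuple[CountTable, SyntheticTruth]:
    """Draw one count table (with metadata and taxonomy) plus its truth."""
    rng = np.random.default_rng(spec.seed)
    D = spec.n_otus
    base = (
        np.asarray(spec.base_log_composition, dtype=float)
        if spec.base_log_composition is not None
        else rng.normal(0.0, spec.base_sigma, size=D)
    )
    if base.shape != (D,):
        raise ValueError("base_log_composition has wrong length")

    sizes = spec.sizes
    labels = spec.labels
    n_total = sum(sizes)
    otu_ids = [f"OTU{j:04d}" for j in range(D)]
    sample_ids: list[str] = []
    in_block = np.zeros(D, dtype=bool)
    for block in spec.proportional_blocks:
        in_block[list(block)] = True

    age_ranges = spec.age_ranges or [
        _DEFAULT_AGE_RANGES[i % len(_DEFAULT_AGE_RANGES)]
        for i in range(spec.n_groups)
    ]

    counts = np.zeros((n_total, D), dtype=np.int64)
    expected = np.zeros((n_total, D))
    meta_rows = []
    row = 0
    for g, (label, n_g) in enumerate(zip(labels, sizes)):
        shift = np.zeros(D)
        for (gs, j), v in spec.group_shifts.items():
            if gs == g:
                shift[j] = v
        lo_age, hi_age = age_ranges[g]
        for i in range(n_g):
            lam = base + shift
            for block in spec.proportional_blocks:
                u = rng.normal(0.0, spec.latent_sigma)
                jitter = rng.normal(0.0, spec.block_sigma, size=len(block))
                lam[list(block)] += u + jitter
            lam[~in_block] += rng.normal(0.0, spec.noise_sigma, size=int((~in_block).sum()))
            p = np.exp2(lam - lam.max())
            p /= p.sum()
            expected[row] = p
            if math.isfinite(spec.overdispersion):
                p = rng.dirichlet(spec.overdispersion * p)
            depth = max(
                D,
                int(round(rng.lognormal(np.log(spec.depth_mean), spec.depth_sigma))),
            )
            counts[row] = rng.multinomial(depth, p)
            sid = f"{label}_s{i:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "age": int(rng.integers(lo_age, hi_age + 1)),
                    "cohort": label,
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "site": f"site{g % 3 + 1}",
                }
            )
            row += 1

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    taxonomy = _make_taxonomy(otu_ids, spec.fraction_unclassified, rng)
    table = CountTable(
        pd.DataFrame(counts, index=sample_ids, columns=otu_ids),
        metadata=meta,
        taxonomy=taxonomy,
    )
    spiked = pd.DataFrame(
        [
            {"group": labels[g], "otu_id": otu_ids[j], "shift_log2": v}
            for (g, j), v in sorted(spec.group_shifts.items())
        ],
        columns=["group", "otu_id", "shift_log2"],
    )
    truth = SyntheticTruth(
        expected_compositions=pd.DataFrame(
            expected, index=sample_ids, columns=otu_ids
        ),
        spiked=spiked,
        blocks=[sorted(otu_ids[j] for j in b) for b in spec.proportional_blocks],
        seed=spec.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# canned fixtures


def _fixture_spec(name: str, seed: int) -> SyntheticSpec:
    if name == "tiny":
        return SyntheticSpec(
            n_groups=2, samples_per_group=6, n_otus=20,
            depth_mean=2e3, seed=seed,
        )
    if name == "null":
        return SyntheticSpec(
            n_groups=2, samples_per_group=50, n_otus=100,
            depth_mean=1e4, seed=seed,
        )
    if name == "spiked":
        shifts = {(1, j): 3.0 for j in range(5)}
        return SyntheticSpec(
            n_groups=2, samples_per_group=50, n_otus=100,
            group_shifts=shifts, depth_mean=1e4, seed=seed,
        )
    if name == "blocks":
        blocks = [[0, 1, 2, 3], [10, 11, 12], [20, 21, 22, 23, 24]]
        return SyntheticSpec(
            n_groups=1, samples_per_group=400, n_otus=60,
            proportional_blocks=blocks, block_sigma=0.1, latent_sigma=1.5,
            depth_mean=2e4, seed=seed,
        )
    if name == "spiked_blocks":
        # 10 spiked + 6 block members = 16 planted OTUs; spiked OTUs get an
        # abundant baseline so a downward shift cannot vanish below depth
        shifts = {(1, j): 3.0 if j % 2 == 0 else -3.0 for j in range(10)}
        blocks = [[20, 21, 22], [30, 31, 32]]
        base = np.random.default_rng(seed + 17).normal(0.0, 2.0, size=80)
        base[:10] = np.maximum(base[:10], 1.5)
        return SyntheticSpec(
            n_groups=2, samples_per_group=100, n_otus=80,
            base_log_composition=base,
            group_shifts=shifts, proportional_blocks=blocks,
            block_sigma=0.1, latent_sigma=1.5, noise_sigma=0.5,
            depth_mean=1e4, seed=seed,
        )
    if name == "cohort_like":
        # eight cohorts shaped like the study, scaled down for CI
        rng = np.random.default_rng(seed + 1)
        shifts: dict[tuple[int, int], float] = {}
        for g in range(8):
            for j in rng.choice(120, size=6, replace=False):
                shifts[(g, int(j))] = float(rng.choice([-2.5, 2.5]))
        return SyntheticSpec(
            n_groups=8,
            samples_per_group=[24, 30, 24, 28, 40, 20, 20, 30],
            n_otus=120,
            group_shifts=shifts,
            proportional_blocks=[[100, 101, 102], [110, 111, 112, 113]],
            block_sigma=0.1, latent_sigma=1.2,
            depth_mean=5e3, seed=seed,
            group_names=list(_COHORT_LABELS),
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")


FIXTURES = ("tiny", "null", "spiked", "blocks", "spiked_blocks", "cohort_like")


def make_fixture(
    name: str,
    out_dir: str | Path | None = None,
    seed: int = 2017,
) -> tuple[CountTable, SyntheticTruth]:
    """Generate a named fixture; optionally write its TSV bundle to disk.

    The bundle contains counts.tsv (canonical orientation), metadata.tsv,
    taxonomy.tsv and the truth TSVs; regeneration with the same seed is
    byte-identical.
    """
    spec = _fixture_spec(name, seed)
    table, truth = generate_table(spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .table_io import write_count_table

        write_count_table(table, out / "counts.tsv")
        table.metadata.rename_axis("sample_id").to_csv(out / "metadata.tsv", sep="\t")
        tax_rows = []
        assert table.taxonomy is not None
        for o in table.otu_ids:
            lineage = ";".join(table.taxonomy.frame.loc[o])
            tax_rows.append({"otu_id": o, "lineage": lineage})
        pd.DataFrame(tax_rows).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        truth.write(out)
    return table, truth
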