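"""One-command orchestration: filter -> clr -> MC -> effects/rho -> stats.

Every stochastic stage draws its seed deterministically from the single
pipeline seed and the stage name, so the whole report bundle is reproducible
bit-for-bit from (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import expected_rho, pair_diagnostics, rho_clusters
from .coda_core import (
    aitchison_distance,
    clr_from_counts,
    dirichlet_instances,
)
from .community_stats import (
    depth_diversity_check,
    group_dispersion,
    pairwise_permanova,
    permanova,
    shannon_diversity,
    smooth_age_trend,
)
from .differential import pairwise_effects, select_explanatory
from .filtering import FilterSpec, filter_otus
from .ordination import compositional_pca
from .table_io import (
    CountTable,
    read_count_table,
    read_metadata,
    read_taxonomy,
    join_metadata,
)

log = logging.getLogger("coda_age")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "stage_seed",
            "ConfigError"]


class ConfigError(ValueError):
    """Aggregated, human-readable configuration problems."""


@dataclasses.dataclass
class PipelineConfig:
    counts: str = ""
    metadata: str = ""
    taxonomy: str | None = None
    out_dir: str = "coda_age_out"
    orientation: str = "otus_in_rows"
    join_policy: str = "intersect"
    group_column: str = "cohort"
    cohort_order: list[str] | None = None
    min_prop_any: float = 0.001
    min_prevalence: float = 0.2
    max_prop_any: float | None = None
    K: int = 128
    prior_mass: float = 0.5
    log_base: str = "2"
    effect_cut: float = 1.0
    rho_cut: float = 0.65
    cluster_min_size: int = 3
    n_permutations: int = 999
    rho_max_zero_fraction: float = 0.95
    seed: int = 0
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the pipeline seed."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2 ** 32)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a flat YAML mapping into a PipelineConfig, checking invariants.

    All problems are collected and reported together.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key: value mapping")
    errors: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})

    for name in ("effect_cut", "rho_cut", "prior_mass"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive, got {getattr(cfg, name)}")
    if cfg.K < 2:
        errors.append(f"K must be >= 2, got {cfg.K}")
    if cfg.cluster_min_size < 1:
        errors.append(f"cluster_min_size must be >= 1, got {cfg.cluster_min_size}")
    if cfg.n_permutations < 1:
        errors.append(f"n_permutations must be >= 1, got {cfg.n_permutations}")
    if not (0 <= cfg.min_prop_any <= 1) or not (0 <= cfg.min_prevalence <= 1):
        errors.append("filter fractions must lie in [0, 1]")
    if str(cfg.log_base) not in ("2", "e"):
        errors.append(f"log_base must be 2 or e, got {cfg.log_base!r}")
    if not cfg.counts:
        errors.append("counts path is required")
    if not cfg.metadata:
        errors.append("metadata path is required")
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    cfg.log_base = str(cfg.log_base)
    return cfg


def _check_cohort_order(cfg: PipelineConfig, labels: pd.Series) -> list[str]:
    observed = list(pd.unique(labels))
    if cfg.cohort_order is None:
        return sorted(observed)
    unknown = [c for c in cfg.cohort_order if c not in observed]
    if unknown:
        raise ConfigError(f"cohort_order names unknown cohorts: {unknown}")
    missing = [c for c in observed if c not in cfg.cohort_order]
    if missing:
        raise ConfigError(f"cohort_order omits observed cohorts: {missing}")
    return list(cfg.cohort_order)


def _stage(name: str):
    """Log a stage with elapsed time; re-raise errors tagged with the stage."""
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.time() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.1fs (%s)", name, dt, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Ctx()


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle to cfg.out_dir.

    Returns a dict of the principal in-memory results (also all written as
    TSV under the output directory).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    comment = f"coda-age {__version__} config={cfg.config_hash()} seed={cfg.seed}"

    with _stage("read"):
        table = read_count_table(cfg.counts, orientation=cfg.orientation)
        meta = read_metadata(cfg.metadata)
        table, dropped = join_metadata(table, meta, policy=cfg.join_policy)
        if cfg.taxonomy:
            table = CountTable(table.counts, table.metadata, read_taxonomy(cfg.taxonomy))
        if dropped:
            log.info("dropped %d samples without metadata", len(dropped))
        if cfg.group_column not in table.metadata.columns:
            raise ConfigError(f"metadata lacks group column {cfg.group_column!r}")

    with _stage("filter"):
        spec = FilterSpec(
            min_prop_any=cfg.min_prop_any,
            min_prevalence=cfg.min_prevalence,
            max_prop_any=cfg.max_prop_any,
        )
        table, report = filter_otus(table, spec)
        report.to_tsv(out / "filter_report.tsv")
        results["table"] = table

    labels = table.groups(cfg.group_column)
    order = _check_cohort_order(cfg, labels)

    with _stage("clr"):
        clr = clr_from_counts(table, prior_mass=cfg.prior_mass, log_base=cfg.log_base)
        dist = aitchison_distance(clr)

    with _stage("pca_all"):
        pca_all = compositional_pca(clr)
        _write_ordination(pca_all, out, "pca_all", comment)
        results["pca_all"] = pca_all

    with _stage("mc"):
        mc = dirichlet_instances(
            table, K=cfg.K, prior_mass=cfg.prior_mass,
            seed=stage_seed(cfg.seed, "mc"), log_base=cfg.log_base,
        )

    with _stage("effects"):
        eff = pairwise_effects(
            mc, labels, pairs="all", cohort_order=order,
            seed=stage_seed(cfg.seed, "effects"),
        )
        eff.to_tsv(out / "effects_all_pairs.tsv")
        eff_succ = pairwise_effects(
            mc, labels, pairs="successive", cohort_order=order,
            seed=stage_seed(cfg.seed, "effects"),
        )
        eff_succ.to_tsv(out / "effects_successive.tsv")
        results["effects"] = eff
        results["effects_successive"] = eff_succ

    with _stage("rho"):
        zero_frac = (table.counts == 0).mean(axis=0)
        excluded = list(zero_frac[zero_frac > cfg.rho_max_zero_fraction].index)
        if excluded:
            log.info("excluding %d near-all-zero OTUs from the rho graph", len(excluded))
        rho = expected_rho(mc, exclude_otus=excluded)
        edges = rho.edges(cfg.rho_cut)
        diag = []
        for r in edges.itertuples(index=False):
            d = pair_diagnostics(clr, r.otu_i, r.otu_j)
            diag.append({**r._asdict(), **d})
        pd.DataFrame(diag, columns=["otu_i", "otu_j", "rho", "slope", "corr"]).to_csv(
            out / "rho_pairs.tsv", sep="\t", index=False
        )
        clusters = rho_clusters(
            rho, cutoff=cfg.rho_cut, min_size=cfg.cluster_min_size,
            taxonomy=table.taxonomy,
        )
        clusters.to_tsv(out / "rho_clusters.tsv")
        results["rho"] = rho
        results["clusters"] = clusters

    with _stage("selection"):
        selection = select_explanatory(
            eff, rho, effect_cut=cfg.effect_cut, rho_cut=cfg.rho_cut
        )
        selection.to_tsv(out / "selection.tsv")
        results["selection"] = selection

    with _stage("pca_selected"):
        if len(selection.otu_ids) >= 2:
            # subset-reclosure: re-close the composition to the selected OTUs
            sub = table.select_otus(selection.otu_ids)
            clr_sub = clr_from_counts(sub, cfg.prior_mass, cfg.log_base)
            pca_sel = compositional_pca(clr_sub)
            _write_ordination(pca_sel, out, "pca_selected", comment)
            results["pca_selected"] = pca_sel
        else:
            log.info("selection too small for a subset PCA; skipped")
            results["pca_selected"] = None

    with _stage("permanova"):
        overall = permanova(
            dist, labels, n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "permanova"),
        )
        pairwise = pairwise_permanova(
            dist, labels, pairs="all", n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "permanova"),
        )
        disp = group_dispersion(clr, labels)
        _write_permanova_table(overall, pairwise, disp, out / "permanova_dispersion.tsv")
        results["permanova"] = overall
        results["pairwise_permanova"] = pairwise
        results["dispersion"] = disp

    with _stage("diversity"):
        profile = shannon_diversity(table)
        profile.to_tsv(out / "diversity.tsv")
        check = depth_diversity_check(
            profile, n_permutations=cfg.n_permutations,
            seed=stage_seed(cfg.seed, "diversity"),
        )
        results["diversity"] = profile
        results["depth_check"] = check
        if "age" in table.metadata.columns:
            trend = smooth_age_trend(
                profile.frame["shannon"].to_numpy(),
                table.metadata["age"].to_numpy(dtype=float),
            )
            trend.to_csv(out / "diversity_age_trend.tsv", sep="\t", index=False)

    # labels TSV so plots can be regenerated from disk alone
    pd.DataFrame({"sample_id": labels.index, "group": labels.to_numpy()}).to_csv(
        out / "sample_groups.tsv", sep="\t", index=False
    )

    if cfg.make_plots:
        with _stage("plots"):
            from . import plots

            plots.render_all(out, group_column=cfg.group_column)

    with _stage("provenance"):
        prov = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": dataclasses.asdict(cfg),
            "stage_seeds": {
                s: stage_seed(cfg.seed, s) for s in ("mc", "effects", "permanova", "diversity")
            },
            "n_samples": table.n_samples,
            "n_otus": table.n_otus,
            "depth_check": dataclasses.asdict(check),
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, default=str))

    return results


def _write_ordination(res, out: Path, prefix: str, comment: str) -> None:
    with open(out / f"{prefix}_scores.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        res.scores.rename_axis("sample_id").to_csv(fh, sep="\t")
    with open(out / f"{prefix}_loadings.tsv", "w") as fh:
        fh.write(f"# {comment}\n")
        res.loadings.rename_axis("otu_id").to_csv(fh, sep="\t")
    pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(res.n_components)],
            "variance_fraction": res.variance_fraction,
        }
    ).to_csv(out / f"{prefix}_variance.tsv", sep="\t", index=False)


def _write_permanova_table(overall, pairwise, disp, path) -> None:
    """Emit the pairwise F/R2/P rows merged with per-group dispersion."""
    disp_map = disp.frame.set_index("group")
    rows = []
    for r in pairwise:
        a, b = r.groups
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "F": r.pseudo_F,
                "R2": r.R2,
                "P": r.p_value,
                "mcd_a": disp_map.at[a, "mcd"],
                "iqr_a": disp_map.at[a, "iqr"],
            }
        )
    frame = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(
            f"# overall: F={overall.pseudo_F:.4f} R2={overall.R2:.4f} "
            f"P={overall.p_value:.4g} permutations={overall.n_permutations}\n"
        )
        frame.to_csv(fh, sep="\t", index=False)
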