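# coda-age

Compositional data-analysis pipeline for comparing gut-microbiota OTU count
tables across age cohorts. One framework covers the whole analysis:

- **table_io** — TSV count tables (both orientations), taxonomy lineages,
  sample metadata, validated and joined into one object.
- **filtering** — abundance (`> 0.1%` in any sample) and prevalence
  (`>= 20%` of samples) OTU filters, plus band filters and singleton removal.
- **coda_core** — count-zero-multiplicative replacement, clr transform,
  Dirichlet Monte-Carlo posterior instances (default K=128, prior 0.5),
  Aitchison distance.
- **ordination** — compositional PCA (form and covariance biplots) and
  Ward clustering.
- **differential** — expected standardized effect sizes per group pair
  (median between-group clr difference over max within-group dispersion,
  averaged over Monte-Carlo instances), explanatory-OTU selection
  (|effect| >= 1 or E(rho) > 0.65), genus binning.
- **association** — symmetric proportionality rho
  (`1 - var(x_i - x_j)/(var x_i + var x_j)`) as an expectation over
  instances, pair diagnostics (major-axis slope, Pearson correlation),
  threshold-graph clusters.
- **community_stats** — PERMANOVA (Monte-Carlo or exact enumeration) on the
  Aitchison distance, per-group dispersion (median/IQR of centroid
  distances), Shannon diversity, depth-confounding check, loess age trends.
- **synthetic_data** — Dirichlet-multinomial table generator with planted
  group shifts and proportional OTU blocks, plus named fixtures.
- **cli_report** — YAML-configured one-command pipeline with TSV/figure
  outputs and full provenance.

## CLI

```sh
# simulate a fixture, then run the full pipeline on it
coda-age simulate --fixture spiked_blocks --out fx/
cat > cfg.yaml <<EOF
counts: fx/counts.tsv
metadata: fx/metadata.tsv
taxonomy: fx/taxonomy.tsv
out_dir: report/
seed: 1
EOF
coda-age -v run --config cfg.yaml
```

Stage subcommands (`coda-age filter|effects|rho|permanova`) run individual
steps; see `coda-age <cmd> --help`. The report bundle contains the filter
report, PCA scores/loadings/variance (all OTUs and the re-closed explanatory
subset), the pairwise effect table, the rho pair/cluster tables, the
PERMANOVA + dispersion table, diversity profiles, figures, and
`provenance.json` (seeds, config hash, versions). Outputs are bit-for-bit
reproducible from (inputs, config, seed).

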