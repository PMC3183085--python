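# teflank

Comparative epigenomics of transposable-element (TE) insertions: quantify
spreading of repressive chromatin (e.g. H3K9me3, MeDIP) from TE bodies into
flanking DNA by comparing the *full site* (strain carrying the insertion)
with the *empty site* (strain lacking it) at insertionally polymorphic
copies.

The package implements, as tested reusable components:

- **`teflank.genome_io`** — plain-text I/O (element tables with per-strain
  presence codes, BED6+mapq reads, minimal SAM, bedGraph / fixedStep
  wiggle, BED/GTF genes, chromosome sizes, expression counts), coordinate
  normalization (internal 0-based half-open), and element-length
  classification (full-length ≥ 4 kb, solo-LTR 320 bp ± 20 %).
- **`teflank.coverage`** — read filtering (mapq ≥ 7, unique alignments,
  positional deduplication), directional 150 bp fragment extension,
  element-body read masking, per-base coverage tracks, strand-aware 5′/3′
  flank profiles, and copy-count + library-size normalized metaprofiles.
- **`teflank.asymmetry`** — the core statistics: RPKM
  (`n / (L_kb × N_millions)` with fractional read assignment), RPKM
  asymmetry `(RPKM_A − RPKM_B)/(RPKM_A + RPKM_B + ε)` bounded in [−1, +1],
  adjusted Fisher–Pearson skewness, per-copy windowed asymmetry at
  configurable distance bands (default <1 kb / 1–2.5 kb / 2.5–5 kb),
  tie-corrected Kruskal–Wallis + Dunn post-hoc tests, and a genome-wide
  sliding-window differential scan for unannotated insertions.
- **`teflank.heatmap`** — per-copy flank coverage matrices ordered by
  full-site flank coverage, with the identical row permutation applied to
  the empty-site matrix.
- **`teflank.mappability`** — mean alignability scoring of bodies/flanks
  from a [0, 1] mappability track, with partitioning filters.
- **`teflank.gene_impact`** — the multi-step filter for genes plausibly
  silenced by insertion-induced heterochromatin: TSS proximity (≤ 5 kb),
  copy-body + promoter enrichment in the full-site line only (fold over
  genome-median window RPKM), and reduced expression in the
  insertion-carrying line.
- **`teflank.simulate`** — a seeded two-strain cohort generator with known
  ground truth: common and polymorphic copies, Poisson background,
  body/flank enrichment with a step or exponential spreading kernel,
  mappability holes inside bodies, configurable library depths, and
  planted promoter-proximal silenced genes.  Deterministic fixture bundles
  are written as plain-text files readable by `genome_io`.

## CLI

```sh
teflank simulate --seed 7 --outdir out/bundle \
    --set n_polymorphic_copies=50 --planted-gene 368 4.0
teflank profile     --bundle out/bundle --outdir out/profile
teflank asymmetry   --bundle out/bundle --outdir out/asym
teflank spreading   --bundle out/bundle --outdir out/spread --png
teflank scan        --bundle out/bundle --outdir out/scan
teflank gene-impact --bundle out/bundle --outdir out/gi
teflank all --seed 7 --outdir out/pipeline --planted-gene 368 4.0
```

Analysis parameters come from `--set key=value` flags and/or a flat
`key = value` config file via `--config` (precedence: CLI > file >
defaults).  Every subcommand writes a JSON run log with the parameters and
library sizes that produced its numbers.

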