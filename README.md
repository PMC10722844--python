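# dslst

Layer-stratified marine community analysis for ASV count tables: alpha and
beta diversity, zone-enrichment odds ratios, seasonal indicator species, and
per-profile source partitioning of deep-scattering-layer (DSL) diversity —
plus a synthetic stratified-community generator with planted ground truth so
the whole pipeline is testable without external sequence data.

## What it does

Given an ASV × sample count table, a taxonomy table and sample metadata
(station / season / layer / profile / depth / environmental covariates):

- **community_io** (`dslst.community`) — validated readers/writers for
  tab-separated count, taxonomy and metadata tables (plus a triples
  dialect); lineage-based taxon filtering (keep Bacteria/Archaea, drop
  organelles), dataset-wide singleton removal, seeded rarefaction without
  replacement, relative abundance, rank aggregation.
- **diversity_stats** (`dslst.diversity`) — Shannon H (nats), richness,
  Pielou J; Bray–Curtis dissimilarity; PCoA (negative eigenvalues excluded,
  uncorrected); one-way PERMANOVA and pairwise PERMANOVA with
  Bonferroni/Holm/BH adjustment; ordination-axis vs scaled-covariate Pearson
  correlations; the BIX fluorescence ratio (emission 380/430 nm at 310 nm
  excitation, bilinear interpolation).
- **clade_enrichment** (`dslst.enrichment`) — per-clade mesopelagic vs
  epipelagic log odds ratios (natural log, Haldane–Anscombe correction for
  zero cells) with two-sided Fisher exact p-values; top-k panels with
  optional phylum-to-class splitting.
- **indicator_species** (`dslst.indicators`) — Dufrêne–Legendre IndVal
  (mean-abundance specificity × occurrence fidelity) with seeded permutation
  p-values, the strict `p < 0.05 & indval > 0.5` selection rule, and
  per-group summaries with order-level breakdowns.
- **source_partitioning** (`dslst.partition`) — the core procedure: per
  vertical profile, every DSL ASV is classified into
  `EPI_shared / unique_DSL / MS_only_shared / MD_only_shared /
  all_meso_shared` (epipelagic precedence), DSL-enriched ASVs are flagged by
  ANOVA + Tukey HSD across mesopelagic layers, and results are summarized
  per profile, averaged across profiles, pooled over profiles, and crossed
  with season (3-way overlap regions).
- **synthetic_data** (`dslst.simulate`) — layer/season-stratified
  Dirichlet-multinomial community generator with planted surface
  specialists, mesopelagic generalists, DSL-unique, DSL-enriched, seasonal
  indicator and cosmopolitan taxa (hard structural zeros), matching
  environmental covariates and synthetic EEMs with an exact planted BIX.

## CLI

Everything is under a single `dslst` entry point; all inputs and outputs are
plain TSV/JSON.

```bash
# generate a synthetic dataset with ground truth
dslst simulate --out data/ --seed 7

# validate, filter, rarefy
dslst io validate --counts data/counts.tsv --taxonomy data/taxonomy.tsv --metadata data/metadata.tsv
dslst io filter --counts data/counts.tsv --taxonomy data/taxonomy.tsv --min-total 2 --out filtered.tsv
dslst io rarefy --counts filtered.tsv --depth 20000 --seed 1 --out rarefied.tsv

# diversity
dslst alpha --counts rarefied.tsv
dslst beta --counts rarefied.tsv --metric braycurtis
dslst pcoa --counts rarefied.tsv --axes 3
dslst permanova --counts rarefied.tsv --metadata data/metadata.tsv --group layer --perms 999 --seed 0 --pairwise --adjust bonferroni
dslst envfit --counts rarefied.tsv --metadata data/metadata.tsv --axes 1,2

# enrichment, indicators, partitioning
dslst zone-odds --counts rarefied.tsv --taxonomy data/taxonomy.tsv --metadata data/metadata.tsv --rank phylum --top 10 --split-proteobacteria-classes
dslst indval --counts rarefied.tsv --metadata data/metadata.tsv --group season --subset layer=DSL --perms 999 --seed 0
dslst partition --counts rarefied.tsv --metadata data/metadata.tsv --season spring --pooled
dslst seasonal-venn --counts rarefied.tsv --metadata data/metadata.tsv --layer DSL
```

`dslst simulate` also accepts a YAML spec (`--spec spec.yaml`) with any
`CommunitySpec` field (category sizes, per-season layer availability,
enrichment/indicator fold-changes, overdispersion, depth, seed).

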