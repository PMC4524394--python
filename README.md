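# ssrkit

A toolkit for SSR (microsatellite) marker development and codominant-marker
population-genetic analysis:

- **`ssrkit.mining`** — Class I SSR detection in reads (di ≥ 11, tri ≥ 7,
  tetra ≥ 6 repeats, tract ≥ 21 bp), compound-locus merging (≤ 100 bp
  interruption), flank assessment, catalog summaries.
- **`ssrkit.design`** — primer-pair selection in SSR flanks (product
  100–250 bp, ΔTm ≤ 1 °C, length 18–24, GC 40–60 %), nearest-neighbor Tm,
  and working / putatively-polymorphic / failed validation verdicts
  (unique amplicon, Ta ≥ 50 °C, ΔTm ≤ 3 °C).
- **`ssrkit.vpcr`** — virtual PCR: 3′-anchored 9-mer binding-site search on
  both strands, amplicon prediction (≤ 2000 bp, Ta window 30–80 °C), and
  cross-genome transferability rates with tandem-motif verification.
- **`ssrkit.diversity`** — allele frequencies, Na/Ne/Ho/He(GD)/PIC/Shannon I,
  frequency classes, PPL, private alleles, exact hypergeometric rarefied
  allelic richness and Kalinowski-style private rarefied richness.
- **`ssrkit.amova`** — distance-based AMOVA (PhiPT) with permutation and
  exact-enumeration p-values; shared-allele (default) and squared
  allele-count (Smouse–Peakall-style) genotypic distances; pairwise PhiPT.
- **`ssrkit.phylo`** — Nei genetic distances (standard 1972 and DA 1983)
  and deterministic UPGMA with Newick export.
- **`ssrkit.dapc`** — allele-count coding, PCA, sequential K-means with BIC
  model selection (K = 2..20), discriminant analysis of principal
  components with membership posteriors, and a-score PC retention.
- **`ssrkit.simulate`** — synthetic reads with planted SSRs and SSR-free
  background, template-genome pairs differing in repeat copy number, and
  Balding–Nichols structured diploid genotype matrices — all with ground
  truth for end-to-end scoring.
- **`ssrkit.io` / `ssrkit.cli` / `ssrkit.pipeline`** — FASTA/FASTQ and
  GenAlEx-style genotype CSV, configuration, and orchestration.

The package also ships a transcribed 34-marker reference panel
(`ssrkit/data/marker_panel.tsv`, `ssrkit/data/marker_diversity.tsv`) used
by the `accept` command and the acceptance report.

## CLI

```bash
ssrkit run --seed 1 --out out/              # full synthetic pipeline
ssrkit simulate-reads --seed 1 --out sim/   # reads + truth table
ssrkit mine sim/reads.fasta --out catalog.tsv
ssrkit diversity genotypes.csv --out div/
ssrkit amova genotypes.csv --n-perm 1000 --seed 1 --out amova.json
ssrkit tree genotypes.csv --out pops.nwk
ssrkit accept                               # panel summaries vs reference
```

All stage parameters are overridable through a JSON config
(`--config cfg.json`, see `ssrkit.config.PipelineConfig`); every output
file is stamped with the config hash and seed, and reruns with the same
config are byte-identical.

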