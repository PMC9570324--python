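# methyloscan

A toolkit for bacterial SMRT methylome analysis:

- **Motif scanning** — IUPAC (degenerate and bipartite) motifs scanned
  strand-aware over linear or circular genomes, with partner-motif
  (reverse-complement) detection.
- **Kinetic calling** — a simplified Welch's-t-test caller over inter-pulse
  durations against an in-silico reference, Phred-scaled modification QVs,
  and the QV ≥ 30 / adenine-or-cytosine call filter.
- **Methylome summaries** — per-motif fraction, nDetected/nGenome, mean
  score / IPD ratio / coverage and an objective score; unmethylated-site
  lists; greedy de-novo motif discovery from call contexts.
- **Genomic context** — promoter (<100 bp upstream of a start codon) /
  gene-body / intergenic classification and Fisher's exact test for
  promoter enrichment of unmethylated sites.
- **In-silico MSRE-PCR** — MboI / DpnI / Bsp143I digestion logic over GATC
  duplex methylation states and amplicon presence prediction.
- **MTase repertoire** — presence/absence profiling from ortholog identity
  tables (strict >70% identity), persistent-MTase detection, Jaccard
  distances, UPGMA and neighbor-joining trees, single-linkage species
  clustering (distance ≤ 0.06).
- **Synthetic data** — genomes, ORF annotations, and methylomes with full
  ground truth (methylation fraction f, promoter-unmethylation odds weight
  θ), so the whole pipeline is testable offline.

Formats: FASTA, GFF3, the PacBio `modifications.gff` dialect (plus an
equivalent CSV), BED6, newick, and CSV summaries. Internal coordinates are
0-based half-open everywhere; conversion happens only in `io_formats`.

## CLI

```bash
methyloscan simulate --seed 1 --genome-length 200000 --out fixtures/
methyloscan scan --genome fixtures/genome.fasta --motif GATC:1:m6A
methyloscan summarize --genome fixtures/genome.fasta \
    --mods fixtures/modifications.gff --motif GATC:1:m6A --out summary.csv
methyloscan unmethylated --genome fixtures/genome.fasta \
    --mods fixtures/modifications.gff --motif GATC:1:m6A --out unmet.bed
methyloscan enrich --genome fixtures/genome.fasta --gff fixtures/annotations.gff3 \
    --mods fixtures/modifications.gff --motif GATC:1:m6A
methyloscan discover --genome fixtures/genome.fasta --mods fixtures/modifications.gff
methyloscan msre --states states.csv --fwd-end 50 --rev-start 250
methyloscan repertoire --hits hits.csv --out-dir rep/
methyloscan tree --dist d.csv --method nj
```

Motif syntax is `IUPAC:methylOffset:modType` (0-based offset of the
methylated base, modType `m6A` or `m4C`), e.g. `GATC:1:m6A`.

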