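# morphlocus

Tools for locating and characterizing a **female colour-morph supergene
locus** from short-read resequencing data, of the kind found in damselflies
where a male-mimicking morph (A), an intermediate morph (I) and an ancestral
morph (O) are controlled by one genomic region under a dominance hierarchy
A > I > o. The package is aimed at population-genomics researchers who want a
reference-free route to a trait locus whose causal variation may be *content*
(insertions present in one morph and absent in another) rather than
*sequence* (SNPs), plus the downstream analyses that characterize it.

The toolkit implements, as one reproducible pipeline:

* **Reference-free k-mer GWAS** — canonical 31-mer presence/absence per
  sample; minor-allele-count and canonization filters; per-k-mer 1-df Pearson
  chi-square χ² = N·(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); family-wise 5%
  significance from a max-statistic phenotype-permutation null (threshold =
  ⌈0.95·(m+1)⌉-th smallest of m permutation maxima); exact full-length
  mapping of significant k-mers to morph assemblies and a content-vs-sequence
  verdict.
* **Read-depth content genotyping** — unique-seed read placement, 500 bp
  windows, >10% repeat-content exclusion, per-sample standardization by a
  neutral background region; standardized depth ≈ 1 / 0.5 / 0 for
  homozygous-present / heterozygous / absent content; pool-seq contrasts.
* **Population-genetic scans** — missing-data-aware π (ratio of sums over
  callable sites, invariant sites included), Hudson's FST (ratio of sums:
  Σ(d_xy − (π₁+π₂)/2)/Σd_xy), Tajima's D with the canonical constants,
  genome-wide 5th–95th percentile envelopes, composite-genotype r² LD decay,
  and an allelic chi-square SNP GWAS with MQ/GQ/MAF/depth/repeat filters.
* **Architecture reconciliation** — per-window content classes (A-unique,
  AI-shared, all-shared, O-only) from per-morph majority calls, merged
  intervals and spans, and a translocation-offset estimate from k-mer hits
  clustered on two assemblies.
* **A ground-truthed simulator** (`morphlocus.synthio`) — forges the
  three-haplotype architecture (tandem inverted duplication, two A-unique
  insertions, an AI-shared block translocated ~3.5 mb in I, a deeply
  divergent region under balancing selection) at a configurable scale, with
  diploid cohorts, uniform error-bearing reads and truth side-channels, so
  the whole pipeline is testable offline.

## Worked example

Simulate a small cohort and run the k-mer association end to end:

```python
import numpy as np
from morphlocus import synthio, kmer_assoc
from morphlocus.cli_io import RunConfig

cfg = RunConfig(seed=1, error_rate=0.0)          # 1:10 scale, 19 per morph, 15x
cohort = synthio.simulate_population(cfg)
reads = synthio.cohort_reads(cohort)

phen = cohort.phenotype_labels()
samples = [s for s in cohort.samples if phen[s] in "AO"]
labels = np.array([phen[s] == "A" for s in samples])

sets = [kmer_assoc.count_kmers(reads[s], k=31) for s in samples]
table = kmer_assoc.build_table(sets)              # MAC >= 5, canonized >= 20%
assoc = kmer_assoc.test_association(table, labels)
null = kmer_assoc.permutation_threshold(table, labels, 100, seed=1)
sig = assoc.kmers[null.significant(assoc.statistic)]

hits = kmer_assoc.map_kmers(sig, cohort.alleles["A"].seq, 31, "A")
lo, hi = synthio.locus_interval(cohort.alleles["A"])
inside = ((hits["pos"] >= lo) & (hits["pos"] < hi)).mean()
print(f"threshold={null.threshold_5pct:.1f} significant={len(sig)} "
      f"inside_locus={100 * inside:.2f}%")
```

Typical output (seed 1):

```
threshold=18.6 significant=120480 inside_locus=99.91%
```

Read it as: the permutation family-wise threshold sits at χ² ≈ 18.6, far
below the χ² = 38 of a perfectly morph-separating k-mer; ~120k k-mers are
significantly associated with the A-vs-O contrast; and 99.9% of those that
map to the A assembly fall inside the single truth morph-locus interval —
the content-GWAS behaviour the method is designed to show.

The same pipeline is available from the shell:

```bash
morphlocus run --seed 1 --outdir out/          # simulate -> kmer -> depth ->
                                               # popgen -> architecture
morphlocus simulate --seed 1 --outdir sim/     # cohort + truth files only
```

`out/locus_report.txt` summarizes the locus span, per-class content totals,
the translocation estimate and the windows exceeding the Tajima's D
95th-percentile envelope; `out/manifest.json` records a checksum, stage,
parameters and seed for every file written.

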