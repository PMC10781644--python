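# Methods

`morphlocus` implements the integrative genomic analysis used to locate and
characterize a supergene-like colour-morph locus in damselflies: a
reference-free k-mer association scan, read-depth copy-number genotyping
against morph-specific assemblies, windowed population-genetic statistics,
linkage-disequilibrium decay, and the reconciliation of all of these into a
structural model of the locus. A ground-truthed simulator generates the
three-haplotype architecture so that every stage is testable without any
external data. This note records the models, the parameters that matter, the
numerical conventions, and the places where a design was genuinely open.

## The simulated system

Three haplotype classes segregate at one locus in females:

* **o** — the ancestral arrangement: a single backbone sequence.
* **A** — the derived male-mimicry arrangement: the backbone plus
  (i) a ~20 kb tandem inverted duplication of backbone sequence,
  (ii) a ~150 kb block of novel content that is shared with I,
  (iii) two windows of novel A-unique content (~400 kb and ~500 kb), and
  (iv) deep class-specific divergence in a backbone region shared by all
  morphs (the balancing-selection signature).
* **I** — the backbone plus a copy of the shared ~150 kb block only,
  translocated so that its I-assembly coordinate sits exactly
  `translocation_offset` (~3.5 mb) downstream of its A-assembly coordinate.

All sizes are the full-scale values divided by `scale_factor`; the packaged
desk profile uses 1:10 (backbone 2 mb, locus ~146 kb, offset 350 kb).
At `scale_factor=1` the configured sizes equal the full-scale ones exactly.
Morph phenotype follows the dominance hierarchy A > I > o: one A allele gives
morph A, otherwise one I allele gives morph I, otherwise morph O. Default
allele frequencies are (A, I, o) = (0.3, 0.2, 0.5) — a convention, chosen so
all six genotypes are sampled at realistic rates; cohorts are drawn until
`n_per_morph` individuals of each phenotype exist (default 19 per morph, a
typical wild-caught resequencing design).

Coordinates are 0-based half-open everywhere (BED-native), including in every
file the package writes.

### Mutation model

Two processes generate sequence variation:

* **Class divergence** (`d_between`, default 0.02/site): substitutions planted
  on every A-class copy within the divergent backbone region. All A copies
  share them, so they segregate at the sampled A-haplotype frequency — an
  old, deeply diverged balanced haplotype class.
* **Within-population diversity** (`theta_within`, default 0.002/site):
  unlinked neutral polymorphisms drawn per content space. Site counts follow
  the Watterson density `theta * a1(n)` and derived-allele counts the neutral
  frequency spectrum (P(i) ∝ 1/i over the n copies carrying that content),
  so expected pairwise diversity per site equals `theta_within` and windowed
  Tajima's D is centred near zero away from the locus. The expected pairwise
  difference between an A-class and an o-class copy of the divergent region
  is `d_between + theta_within`.

A per-copy "private singleton" model was considered and rejected: it makes
every genome-wide window singleton-only, pushing baseline Tajima's D to ≈ −2
and leaving the locus barely distinguishable from the envelope. The neutral
SFS baseline makes the balanced divergent region the outlier, which is the
phenomenon the scan exists to detect. Because sites are unlinked (no shared
genealogies), between-window variance of D is smaller than under a coalescent
with linkage; the 95th-percentile envelope is correspondingly tight. Passing
tests therefore demonstrate correct statistical machinery and the intended
qualitative signature, not calibration against coalescent simulations.

### Read model

Single-end, fixed-length (default 100 bp; 150 bp in the depth-calibration
analyses), substitution-only errors at `error_rate` (default 0.002/base),
uniform starts, random strand. Each haplotype contributes
`round(coverage × length / (2 × read_length))` reads, so expected depth at a
position present on both copies equals `coverage` (default 15×). True read
origins are kept in a side-channel truth table, never in the FASTQ.
Indel errors, quality-score variation and paired ends are deliberately out of
scope; none of the downstream computations consume them.

### Repeats

~10% of the backbone is overwritten with tandem tracts (one random 100 bp
unit tiled over ~2 kb at desk scale), and the simulator writes the repeat BED
itself. The tracts are genuinely repetitive, so the mapper's
ambiguity-discard rule is exercised for real, and windows overlapping them
exceed the 10% repeat-content exclusion threshold.

## k-mer association

Per sample, canonical k-mers (k = 31; odd k only, so no self-palindromes) are
collected as presence/absence — packed 2 bits/base into `uint64`, which keeps
canonicalization and set operations pure integer-array work (k ≤ 31 on this
path; larger odd k up to 63 is reserved and currently not implemented).
Listing-stage filters: k-mers present in fewer than
5 samples are dropped, as are k-mers whose "canonized fraction" — the share
of containing samples that observed the k-mer in *both* orientations — is
below 20%. At the testing stage a minor-allele-frequency filter (≥ 5%, plus
absence in ≥ 5 samples) removes monomorphic and near-monomorphic k-mers.

Association per k-mer is the 1-df Pearson chi-square (no continuity
correction) on the 2×2 presence × phenotype table; a perfectly separating
k-mer attains χ² = N (the sample count). Family-wise error is controlled with
a max-statistic permutation null: labels are shuffled preserving class sizes,
the maximum χ² across all tested k-mers is recorded per permutation, and the
threshold is the ⌈(1−α)(m+1)⌉-th smallest of the m maxima (m = 100 default).
The threshold indexes m+1 rather than m: with small cohorts a permutation
occasionally reproduces the observed labelling, and the m-indexed ceiling
quantile would then declare nothing.

Because the chi-square has discrete support, the observed maximum frequently
*ties* the threshold order statistic, and a strict-inequality rule alone is
badly conservative (measured family-wise error ≈ 1.5% at nominal 5% in
20-sample null cohorts). The significance call therefore uses the canonical
randomized exact tie rule: with U ~ Uniform(0,1) drawn once per analysis from
the seeded permutation stream, the randomized permutation p-value
(1 + #{perm > M} + U·#{perm = M}) / (m+1) of the observed maximum M is itself
Uniform(0,1) under exchangeability, so rejecting at p ≤ α attains the nominal
family-wise level exactly and never exceeds it. When the observed maximum is
strictly above the threshold — every strong-signal analysis — the rule
reduces to the plain "χ² above threshold" cut.

A linear-mixed-model association (with a k-mer kinship matrix) is
intentionally not implemented: simulated cohorts are unstructured, and the
permutation threshold carries the error-control burden.

**Sample-size floor.** The max-statistic null saturates when the tested
k-mers cover all possible case/control presence patterns: with 6 samples per
morph (12 per contrast) the ~10⁴ distinct polymorphism patterns exhaust the
C(12,6) = 924 possibilities, every permutation contains a perfect separator,
and the threshold equals the maximal χ² — no k-mer can ever be declared
significant. The default cohort size of 19 per morph (C(38,19) ≈ 1.7×10¹⁰
patterns) avoids this; it is a statistical requirement of the method at desk
scale, not a tuning choice.

Significant k-mers are mapped to assemblies by exact full-length match on
either strand (100% identity by construction). The content-vs-sequence
verdict then follows the contrast logic: if divergence is novel *content*,
the vast majority of significant k-mers map exclusively to one assembly
(default majority 0.90); if it is *sequence* divergence, each morph
contributes its own allele-specific k-mers, so exclusive hits appear on both
assemblies ("sequence" when both exclusive shares exceed 1 − majority;
"mixed" otherwise; "none" without significant k-mers).

## Read-depth genotyping

Reads are placed by unique-exact-seed voting: every 31-mer occurring exactly
once in the assembly (either strand) is an anchor; seeds are taken across the
read at stride 7, each seed hit votes for an implied (start, orientation),
and the majority wins. Reads with no unique seeds or a tied top vote are
discarded — the stand-in for a mapping-quality filter, suppressing repeat
placements. Depth is averaged in non-overlapping 500 bp windows (the final
partial window is dropped); windows with > 10% repeat-annotated content are
excluded. Each sample's window means are divided by that sample's mean depth
over the non-repetitive windows of a large neutral background region
(≥ 100 usable windows required), giving standardized depths near 1.0
(content on both haplotypes), 0.5 (one haplotype) and 0 (absent). Calls use
the midpoint thresholds 0.25 / 0.75, which are a convention made explicit
here — depth plots are normally read at the same three levels without any
named cutoff. Pool-seq contrasts treat each pool as one
high-coverage sample; a pool carrying an insertion at frequency p has
expected standardized depth ≈ p over it, and the locus is flagged when the
median candidate-window depth difference between pools exceeds the
genome-wide 99th percentile of per-window differences.

## Population genetics

All statistics run on a variant table carrying biallelic SNP genotypes with
per-haplotype missingness plus interval-level callability, so invariant-site
denominators are honest. In the packaged pipeline the table comes from
simulator truth (standing in for read mapping + variant calling, which the
pipeline does not re-derive); mapping-quality, genotype-quality and combined
depth annotations are simulated so the standard site filters have teeth
(repeat sites get low MQ and ~3× depth; 2% of sites get low GQ).

* **π** per window = Σ differing pairs / Σ comparable pairs over callable
  sites (ratio of sums; invariant callable sites add pairs to the
  denominator only). Windows with zero comparable pairs are missing.
* **Hudson FST** per window = Σ(dxy − (π₁+π₂)/2) / Σ dxy over sites with ≥ 2
  called haplotypes per population (ratio of sums; unbiased within-population
  π). Raw values are preserved; clamping negatives to zero is applied only in
  a separate plotting column. Fixed differences with no within-population
  variation give exactly 1.
* **Tajima's D** per window uses the canonical a₁…e₂ constants; sites with
  under 50% of haplotypes called are dropped, the effective n is the minimum
  per-site called count over the window's segregating sites, and S = 0
  windows are missing, never zero.
* **Envelopes** are genome-wide 5th/95th percentiles (linear interpolation);
  for FST only non-zero plotted values enter, so that rare strongly
  differentiated windows are not buried under the mass of zeros.
* **LD**: composite r² on genotype dosages (squared Pearson correlation; no
  phasing assumed; missing dosages mean-imputed per site), variants thinned
  to every 100th, pairs recorded when r² > 0.05 within 15 mb (scaled) or
  ≤ 10,000 intervening variants. Monomorphic sites are skipped.
* **SNP association**: allelic 1-df chi-square on allele counts (genotypic
  2-df variant behind a flag), after MQ > 20, GQ > 30, MAF > 0.02, repeat
  exclusion, and a combined-depth cap defaulting to
  1.5 × n_samples × mean coverage — the generalization of the cohort-specific
  absolute cap used at full scale. Output is unadjusted −log₁₀ P.
* **TE windowing**: per-family interval union, then covered fraction per
  1.5 mb (scaled) window.

Popgen windows are coordinate-tiled with the final partial window kept (with
its true callable extent); depth windows drop the partial window. The
difference is deliberate and documented.

## Architecture reconciliation

Per-window content classes come from per-morph majority calls (≥ 80% of a
morph's samples agreeing): A-unique (present in A, absent in I and O),
AI-shared (present in A and I, absent in O), all-shared, O-only; windows
outside the candidate region are background, everything else is ambiguous and
never silently dropped. The 80% majority tolerates up to 3 discordant
samples of 19 — enough to absorb a single anomalous individual carrying the
shared block, a failure mode real cohorts do produce. Contiguous same-class
windows merge into intervals; class totals are the recovered content sizes.

The translocation offset is estimated from significant derived-vs-ancestral
k-mers that hit both the A and I assemblies: hit positions are clustered 1-D
(gap threshold 10 kb), each assembly's main cluster must hold ≥ 90% of hits
(otherwise an ambiguous-translocation error with per-cluster diagnostics),
and the offset is the absolute difference of cluster centroids. The ~20 kb
inverted duplication exists only as simulator ground truth; inferring it
from short reads would need split-read/SV machinery that is out of scope.

## Reproducibility and problem sizes

Every stochastic step draws from a named child stream of the master seed
(`numpy` `SeedSequence` spawn keys), so identical configs give byte-identical
FASTA/FASTQ/BED/TSV outputs. The pipeline writes a JSON manifest with a
SHA-256 checksum, producing stage, parameters and seed for every file; re-runs
skip stages whose parameter hash and outputs are unchanged, and changing a
parameter invalidates exactly its downstream stages.

Analyses in the test-suite and acceptance script run at these sizes, chosen
as the package's desk-scale defaults: 1:10 architecture (2 mb backbone),
19 samples per morph at 15×, 100-bp error-free reads for the k-mer
localization analyses; 50 kb insertion genotyping at 20× / 150 bp / 0.002
errors; 200 replicate 20-sample 50 kb cohorts for the family-wise error
calibration; 30 kb-equivalent (3 kb) windows for the scans.

## Known limitations

* Sites are unlinked within class; LD decay with distance inside the
  collinear backbone is therefore flat, and the LD module's decay summary is
  exercised by construction rather than by a recombination gradient.
* The mapper is exact-seed based: at divergence ≫ 3% between read and
  reference, placement rates fall faster than for a banded aligner.
* Genotype r² uses mean-imputation for missing dosages; with heavy
  missingness a pairwise-complete implementation would differ.
* The simulator's diploids are unstructured (no kinship, no inbreeding), so
  the chi-square association is exact by design; real cohorts would need the
  mixed-model machinery this package intentionally omits.
* k > 31 is not implemented on the packed path.
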