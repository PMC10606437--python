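# Methods

`circulome` characterizes plant extrachromosomal circular DNA (eccDNA)
inventories — "circulomes" — across herbicide-resistant (HR) and
herbicide-sensitive (HS) blackgrass (*Alopecurus myosuroides*) populations.
The package implements the analysis stages downstream of circle detection:
redundancy collapse, inventory summaries, genomic origin mapping,
density-enrichment testing, protein-domain set comparisons, QTL overlap,
and candidate-gene homology, together with a fully seeded synthetic
generator that plants known structure so every stage is testable without
the (multi-gigabase) real data.

## Coordinate conventions

All in-memory coordinates are 0-based half-open (BED convention). GFF3
(1-based closed) is converted at the reader boundary; that reader and the
GFF3 writer are the only places ±1 arithmetic occurs. Strand is recorded
but ignored by all counting operations: no stage of the analysis is
strand-aware. Multi-mapping circles keep all primary alignments and each
placement contributes to window counts independently; a flag retains
secondary alignments (`tp:A` PAF tag) when wanted.

## Redundancy collapse (clustering)

Circle detections are collapsed into non-redundant representatives the way
CD-hit does it: records sorted longest-first (ties by id), each record
joins the **first** existing cluster whose representative it matches at
identity ≥ the threshold (default 0.9), else founds a new cluster. A
best-hit mode (join the highest-identity qualifying representative) is
available behind a flag. Identity is the number of identical aligned
positions in the best local alignment divided by the length of the shorter
sequence (CD-hit's denominator). Scoring: match +1, mismatch −1, gap
open −2, gap extend −1 (the first gap position costs −2, each further −1).
Because the molecules are circular, the shorter sequence is additionally
aligned against the representative concatenated to itself (doubling
trick), and the better identity is used, making the collapse
rotation-invariant. Alignment runs through biopython's `PairwiseAligner`;
the test suite checks it against an independent hand-written Gotoh DP.

Greedy first-fit makes two properties hold by construction and the tests
assert them: re-clustering the representatives yields only singletons
(every representative failed to reach threshold against all earlier ones),
and shuffling the input order never changes the representative set.

**Prefilter.** Exact scoring of every pair is quadratic and, at ~7 kb
circle lengths, expensive (~10⁸ DP cells per pair). Three screens run
before the exact scorer, each conservative by design and all validated
against the exhaustive no-prefilter oracle in the tests:

1. shared 11-mer requirement (a pair with no common 11-mer is skipped);
2. a k-mer *evidence* screen: a pair at ≥ 0.9 identity shares on the order
   of 0.9¹¹ ≈ 0.31 k-mers per position of the shorter sequence, while an
   unrelated 7-kb pair shares a background handful (~10); pairs sharing
   fewer than 5% of the possible k-mers are skipped;
3. a banded infix edit-distance screen (edlib) allowing an extra 0.08
   identity slack below the threshold before skipping, which also locates
   the matching region so the exact aligner only scores a padded slice of
   the doubled representative.

Screens 2–3 are heuristics with a deliberate margin, not proofs; the
oracle-equivalence test (50 sequences incl. rotations and mutated copies)
is the evidence they do not drop true pairs at these parameters.

One behaviour worth knowing: circles excised from *overlapping genomic
loci* are genuinely similar (the shorter can be near-contained in the
longer), so on a small dense genome the collapse merges some non-duplicate
circles, and a planted duplicate can fail to join its parent when the
parent was itself absorbed into an overlapping cluster first. Both are
faithful consequences of first-fit greedy semantics, not defects.

## Inventory summaries

Per-sample rows: circle count, mean/min/max length, circles with ≥1
predicted gene, circles with predicted tRNA, and percent with coding
sequence = 100 × n_with_gene / n_ecc rounded **half-up** to 2 decimals
(half-up reproduces every printed value of the published seven-population
inventory bundled in `circulome.reference`). Cohort aggregation takes
cross-sample means rounded half-up to integers; on the published counts it
gives 1079 gene-carrying circles and 4885 circles per sample (the source
text prints 4886; the bundled counts average to 4885.3, and the package
reports the computed value). Length histograms use half-open bins
[k·w, (k+1)·w).

## Genome windows and hotspots

Chromosomes are tiled exactly with non-overlapping windows (default
500 kb; terminal windows may be short and are kept, not merged). An
eccDNA placement increments **every** window it overlaps by ≥1 bp
(BEDtools-intersect semantics; midpoint assignment behind a flag), so the
window-count total exceeds the placement count exactly by the number of
boundary spanners. Placements on chromosomes outside the genome index
(unanchored contigs) are tallied separately as a mapping-rate statistic.
Phenotype totals sum per-sample counts over the HR and HS groups.

Hotspots are formalized as windows whose grand count is ≥ k standard
deviations (population SD, default k = 3) above the genome-wide mean; a
top-quantile mode is also provided. Note the arithmetic constraint: with N
windows the population z-score cannot exceed √(N−1), so k = 3 is
unreachable on grids of ≤10 windows — recovery experiments therefore use a
200-kb grid (25 windows on the 5-Mb toy genome), where a planted 50×
hotspot scores z ≈ 5 and is recalled in 100% of seeded runs.

## Flank-density permutation test

Units are annotated genes (default) or grid windows. For each unit the
flank is [start−f, end+f) minus the unit itself (f = 200 kb, clipped at
chromosome ends); flank gene/TE counts use any-overlap and exclude the
unit's own feature; a unit is *eccDNA-present* when its own interval
overlaps ≥1 mapped circle of the group under test (HR and HS are tested
separately over their pooled placements). The statistic is
mean(present) − mean(absent). The null is built by permuting the
present/absent labels with group sizes fixed: exact enumeration of all
C(n, n₁) labelings when that number is ≤ 20,000 (p = fraction of labelings
at least as extreme; the identity labeling makes p > 0), otherwise n_perm
sampled labelings (default 10,000) with the add-one estimator
p = (1 + #extreme)/(1 + n_perm), which requires a seed. Two-sided by
absolute value by default; one-sided "greater" available.

**Validity and the generator's null.** Label permutation assumes the
presence labels are exchangeable against the flank values under the null.
That fails when one circle can cover several gene units (labels become
spatially clustered while flank values are spatially autocorrelated), and
the test then over-rejects even with no planted coupling — we measured
~9% at α = 0.05 with freely placed, overlapping genes. The calibration
experiments therefore use the generator's spaced-gene mode
(`min_gene_gap` larger than the circle length cap: no circle spans two
units), under which the measured type-I rate over 500 seeded null
replicates is ~0.05, inside the binomial 99% CI. This is a statement about
the *test's assumptions*, and it carries over to real data: gene-level
permutation p-values should be treated as approximate wherever single
circles span multiple genes.

Calibration runs use n_perm = 499 so that (1 + n_perm)·α = 25 exactly at
α = 0.05. Power: with planted coupling strong enough to shift mean
flank-gene counts by ≥ 0.5 SD (the planted β = 0.15 produces ≈ 0.65 SD),
the rejection rate over 25 seeded replicates is ≥ 0.96.

## Domain set algebra

Per-sample catalogs map PFAM accessions to the number of distinct circles
carrying them. The partition takes the HR core (intersection over HR
samples) and HS core; their intersection is the all-sample core, and the
set differences are the group-specific cores, so |HR core| = |core| +
|HR-specific| identically. Per-sample unique accessions are those in
exactly one sample across both groups (an in-group-only mode is flagged);
pairwise sharing is reported per same-group pair, optionally excluding
accessions carried by any other sample of the group. Counts are ignored by
the set algebra. Term enrichment is a plain hypergeometric upper tail with
Benjamini–Hochberg correction — a deliberate simplification that does not
model annotation-length bias.

## QTL overlap and candidate homology

A circle (or a CDS predicted on one) matches a QTL by any ≥1 bp overlap;
each QTL is classified by its CDS content as HR-only / HS-only / both /
none (exhaustive and exclusive). Phenotype totals count unique circle ids
by default (a per-QTL-sum mode is flagged). HR-exclusive windows are grid
windows overlapping a QTL with circles from ≥ m HR samples (default 3)
and none from any HS sample; relaxing m is monotone.

Protein homology uses local alignment under BLOSUM62 (X scored 0) with
affine gaps: a gap of length L costs 11 + L. Identity uses the
alignment-column denominator. Bit scores and E-values follow
Karlin–Altschul, bit = (λS − ln K)/ln 2 and E = m·n·2^(−bit), with the
published gapped-BLOSUM62 constants λ = 0.267, K = 0.041 (configurable; n
is the total residue count of the candidate set). The default reporting
threshold E ≤ 1e−10 is configurable.

## The synthetic generator

What it emulates: 7 samples (4 HR, 3 HS); circle counts per sample
(default 500, configurable to the low thousands); a truncated log-normal
length law on [31, 29081] bp whose location parameter is solved
numerically so the truncated mean is exactly 6,900 bp (σ = 1; rejection
sampling; infeasible targets are a hard error); ~8.5% of circles on
unanchored contigs and ~1.5% unmapped; planted hotspot windows
(multiplicative origin-intensity factors on the grid); origin probability
∝ hotspot factor × exp(β × genes within ±200 kb), so gene-density
enrichment is a single knob; redundant detections (default 10% of circles
re-emitted rotated with 2% point substitutions — identity ≈ 0.98, above
the 0.9 collapse threshold); per-sample domain vocabularies built from a
69-accession shared core (including a dominant gypsy-transposon-like
accession planted as the abundance leader), 11 HR-only and 22 HS-only core
accessions, plus disjoint per-sample unique accessions, with every
vocabulary accession guaranteed ≥1 carrier circle; and QTL intervals
planted by construction into known CDS-content classes (default 7 both /
4 HS-only / 1 HR-only / 3 none plus 2 HR-exclusive full windows) by
reserving segments from random origin sampling and forcing designated
circles into them.

Reproducibility: one global seed fans out to fixed-index substreams
(genome, annotations, QTL layout, one per sample), so adding samples never
perturbs existing ones, and identical seeds give byte-identical output
files.

What it does **not** emulate: concatemeric reads or CCS error models; tRNA
genes (per-circle tRNA flags are drawn, not derived); strand effects;
sequence composition (uniform random genome — no repeats, GC structure or
gene models, so clustering results reflect positional overlap and planted
duplication only); and realistic chromosome counts or sizes. Two toy-scale
artifacts matter when reading results: (1) on a 5-Mb genome the planted
hotspot windows and QTL reservations hold a visible fraction of all
circles, which can swamp a weak gene-density coupling and flip the sign of
the flank statistic on the all-features default dataset — the enrichment
analyses therefore isolate the coupling (hotspots/QTL off); (2) flank
clipping near chromosome ends couples any origin-density gradient to both
gene and TE flank counts, so toy-scale TE "enrichment" is an edge
artifact, and passing tests say nothing about TE enrichment in real data.

## Problem sizes used by the shipped experiments

Chosen so replicated experiments stay cheap: calibration/power replicates
run sequence-free on a 1-Mb, 2-chromosome genome with 60 circles/sample
(mean 400 bp, cap 2 kb) and 120 spaced genes, n_perm = 499; hotspot
recovery on the 5-Mb genome with a 200-kb grid; full-sequence clustering
demonstrations use 40 circles/sample at the full ~6.9-kb length law
(pairwise alignment at 7 kb costs seconds per pair). The acceptance script
prints each quantity with the problem size it used.

## Known limitations

- The collapse reproduces CD-hit's greedy *semantics*, not its short-word
  statistics; clusterings can differ from CD-hit's on borderline pairs.
- E-values use fixed Karlin–Altschul constants rather than
  sequence-composition-adjusted ones; they are comparable within a run,
  not to BLAST output.
- The permutation test inherits the exchangeability caveat above.
- The hypergeometric term enrichment ignores length bias.
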