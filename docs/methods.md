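# Methods

`mirdiffreg` implements a genome-wide small-RNA differential-regulation
analysis for a two-line, two-condition, replicate-pool design: two
genetically similar rat lines with contrasting neuropathic-pain phenotype
(high-autotomy HA, low-autotomy LA), each profiled by small RNA-seq in
sham-operated and nerve-injured (SNL, spinal nerve ligation) dorsal root
ganglia, with three biological replicate pools per line x condition group
(12 pools). The scientific question is not which elements respond to
injury — thousands do — but which respond *differently* in the two lines,
making them candidate determinants of the pain phenotype rather than of
injury per se.

## Pipeline model

### Read editing

Raw reads are insert + 3' sequencing adapter. Adapter detection slides the
adapter prefix along the read and requires at least 10 visible adapter
nucleotides, of which the first 10 must match with at most one
substitution; the leftmost detection wins, and reads without a detectable
adapter are discarded. Matching is substitution-only (no indels): the
tolerance models sequencing error and rare RNA editing, not structural
variation. Trimmed inserts outside 16–41 nt are removed; survivors are
collapsed to unique sequences with per-pool counts ("reads level"
matrix). T is mapped to U on ingest; all internal sequences are RNA.
Quality scores are ignored (no quality model is part of the analysis).

### Annotation by hierarchical seed alignment

Each unique sequence is aligned to an ordered hierarchy of reference
libraries (known rat miRNAs, then all-species miRNAs, then other sncRNA
classes such as tRNA/rRNA/repeats/piRNA). Alignment is sense-strand,
ungapped and restricted to the first 20 nt of the read (the *seed*);
mismatches beyond the seed are ignored, so 3' non-templated additions
(NTA, post-transcriptional A/U tailing) never block assignment. Mismatch
budgets are per library (1 for known rat miRNAs, 2 for cross-species
homology, configurable elsewhere). The seed may start within ±2 nt of the
consensus 5' end by default (isomiR 5' fluctuation); `max_offset=None`
allows any internal offset. A sequence is assigned at the first library
with a hit and removed from the input of later libraries, so counts are
never double-assigned; unassigned sequences stay in the reads-level
matrix unnamed. All unique-sequence variants assigned to one canonical
identifier (its *isomiRs*) have their counts summed at the identifier
level. Within a library, ties go to the lowest mismatch count, then to
the lexicographically first identifier — an arbitrary but deterministic
rule.

Novel-miRNA candidacy implements only the genomic read-cluster thresholds:
reads clustering within a ±2 nt start window; most frequent read with
count ≥ 10 and length 20–23 nt; 5' fluctuation ≤ 2 nt; and, for
candidates with no homolog in any species, both hairpin arms present with
perfect 2-nt 3' overhangs (evaluated under an idealized duplex pairing
`i ↔ L−1−i` on the hairpin). Hairpin folding and machine-learning
classification are out of scope.

### Quantification

Counts are converted to reads per million (RPM) per pool, in two modes:
*reads-level* (denominator = all reads in the pool; columns sum to 10^6
exactly) and *within-library* (denominator = reads assigned to the same
reference library, making identifiers comparable within a library's
scope). RPM is kept in floating point; no rounding occurs before
filtering. The abundance filter keeps elements with RPM ≥ 10 in at least
3 of the 12 pools (both configurable) and is applied after normalization.

### Pool consistency and outlier exclusion

Replicate pools within a group should resemble each other more than pools
across groups. The report computes: pairwise Pearson correlation of raw
RPM profiles (no log transform), average-linkage (UPGMA) clustering on
d = 1 − r, and per-group mean coefficient of variation (per element:
sample SD / mean across replicates, zero-mean elements skipped; group
value: mean over elements).

A pool is flagged as an outlier only when all three hold:

1. **Topology** — in the dendrogram the pool merges outside its group
   before its group-mates have merged together (formalized as: the pool is
   absent from the smallest dendrogram node containing all of its
   group-mates).
2. **CV reduction** — dropping the pool reduces its group's mean CV by at
   least a factor `cv_ratio_threshold` (default 1.2) after c4(n)
   debiasing. The debiasing matters: the sample SD of n normal replicates
   underestimates σ by the factor c4(n) (c4(2) ≈ 0.798, c4(3) ≈ 0.886),
   so an uncorrected 2-replicate CV is ~10% below a 3-replicate one and
   *every* pool drop looks like an improvement. The default 1.2 was chosen
   from simulation as the midpoint between the clean-data ratio
   distribution (99th percentile ≈ 1.14) and the injected-outlier
   distribution (5th percentile ≈ 1.31).
3. **Context** — the reduced CV is at most the mean CV of the other
   groups (a group that stays noisier than its peers after the drop has a
   problem the drop does not fix).

Flags are advisory. Exclusion is an explicit configuration action and is a
pure column drop; no other pool's values change. The pipeline reports
regulation statistics both with and without excluded pools.

Known limitation: with Pearson distance on raw RPM, the profile
correlation is dominated by the handful of most abundant elements. A
compositional distortion that happens to spare those elements is invisible
to the dendrogram, which caps the detection rate of the conjunctive rule
at ~85% for the synthetic outlier model below (see Calibration).

### Regulation statistics

Per line, injury regulation (*SNL-reg*) of an element with group means
`SNL` and `sham` is measured two ways:

* **subtraction metric** `(SNL − sham) / ((SNL + sham)/2)`, dimensionless,
  bounded in (−2, 2), antisymmetric under swapping the conditions;
* **fold change** `SNL/sham` for up-regulation and `−(sham/SNL)` for
  down-regulation (no change → +1), with `log2(SNL/sham)` used wherever
  fold changes enter arithmetic.

Both metrics are reported for every element. The per-element test is a
one-tailed two-sample Welch t-test of the SNL pools against the sham
pools, in the direction of the observed change.

Differential regulation (*diff-reg*) contrasts the lines. For each line,
SNL-reg is estimated from every (SNL pool, sham pool) pair — k×k = 9
estimates per line at the default design — and `diff` is the difference of
the two line means (HA − LA). The two estimate sets are compared with a
two-tailed Welch t-test. An optional permutation null re-splits either the
pooled pairwise estimates (`permutation_mode="estimates"`, the default) or
the line labels of whole pools within condition (`"pools"`); small
instances are enumerated exhaustively (p = exact tail fraction), sampled
runs use the add-one correction `(1 + hits)/(runs + 1)` so p is never 0.
The default is 10^5 runs, configurable up to 10^7.

Multiple testing uses Benjamini–Hochberg q-values per matrix, alongside
the *FDR limit* — the largest ordered p with `p_(i) ≤ i·α/m` — so the
rejection rule "uncorrected p ≤ FDR limit" is exactly the BH rejection
set at α. A baseline contrast (HA_sham vs LA_sham fold ratio with a
two-tailed Welch test) checks that the two lines hardly differ before
injury.

Zero handling: the subtraction metric tolerates a zero in one condition
and is undefined only when both means are zero (element skipped and
logged); ratio metrics apply an RPM floor (default 0.5) inside the
ratio only. Degenerate variance: if both groups are constant, p = 1 for
equal means and p = 0 otherwise; variance below (10^-12 × data scale)^2
is float noise from demeaning constants and is treated as zero.

### Calibration caveats (measured by the acceptance tests)

The pairwise-estimate design is the field's procedure and is implemented
faithfully, but its t-test is *anticonservative*: the 9 estimates per line
share 3 + 3 pools, so treating them as independent samples understates the
standard error of the line mean by a factor of ~2 (with per-pool relative
variance v, the true variance of the HA−LA mean difference is 4v/3 while
the estimator's expectation is v/3). On null synthetic data the measured
rate of nominal p < 0.05 is ≈ 0.32, and on spiked data the BH discovery
list at q ≤ 0.05 carries a large false-discovery proportion (≈ 0.8 under
the recovery conditions below) even though sensitivity is high (≈ 0.96).
Ranking by q remains informative — spiked elements dominate the top of the
list — but the q-values must not be read as calibrated error rates. The
pool-label permutation mode does not share observations across the two
sides of the test and is the calibrated alternative. Similarly, choosing
the one-tailed direction from the observed sign makes the per-element
SNL-reg null rate structurally 2α (measured ≈ 0.074 at α = 0.05 on
negative-binomial counts, below 2α because the skewed counts make the
t-test conservative at n = 3).

## Synthetic data generator

No sequencing data are bundled; the generator produces data with the
statistical structure the analysis assumes, plus ground truth, so every
stage is testable and parameter recovery can be measured.

* **Abundance law** — element mean abundances are log-normal
  (default σ_log = 2.0), rescaled to a 10^6 RPM budget, reproducing the
  strong right skew of real small-RNA profiles (a few elements at 10^4–10^5
  RPM, most near the bottom of the range).
* **Replicate noise** — counts are negative binomial around the group
  mean, parameterized by a target coefficient of variation (default
  CV = 0.2, matching replicate-pool variability of real data); sampling
  never goes below the Poisson floor, so low-abundance elements are
  noisier than the target, as in real libraries. `noise="poisson"` and
  `"none"` give the dispersion→0 and variance-free limits for tests.
* **Spike-ins** — a configurable set of elements receives a multiplicative
  injury effect in the SNL condition of one line (the ground-truth
  differential set). `make_study_config` places 5% spike-ins with folds
  1.5–3× (inverted to down-regulation with probability 1/2) on elements
  with baseline RPM ≥ 1000, where measurement is precise.
* **Outlier pool** — one pool can be compositionally distorted: a random
  30% of elements multiplied by i.i.d. log-uniform factors in
  [1/inflation, inflation] (default inflation 3), emulating a pool with a
  shifted RNA-class composition without modelling its cause.
* **Read emission** — FASTQ reads are insert + adapter with constant
  quality, with configurable fractions of 1–2 nt 3' A/U non-templated
  additions, adapter truncation below the 10-nt detection minimum, and
  single-substitution adapter corruption. At zero corruption the editing
  stage reproduces the source count matrix exactly (round-trip property).
* **Scale** — default 2×10^6 reads per pool and a few hundred elements;
  the generative structure (skew, CV, effect sizes) is scale-free, so
  conclusions about the statistics do not depend on emulating full library
  depth, and per-pool totals are approximate because the dominant
  elements' own noise moves the column sums.

Everything derives from a single seed; identical configurations are
bit-identical. What the generator does *not* emulate: sequencing error
inside the insert, genome coordinates and strand, compositional coupling
between elements beyond the RPM budget, and abundance-dependent biological
dispersion. Passing recovery tests therefore demonstrate correctness of
the statistical machinery under the stated model, not performance on real
libraries.

## Numerical and design choices

* Welch (unequal-variance) t-tests throughout; the pooled-variance variant
  is not offered.
* BH q-values come from `statsmodels.stats.multitest`; the FDR limit is
  computed in-package and its rejection set is verified against the
  q-value rule.
* UPGMA clustering uses `scipy.cluster.hierarchy.linkage(method="average")`
  on condensed 1 − r distances; exact distance ties merge deterministically
  in index order.
* Permutation enumeration switches to exact mode when the split count is
  ≤ 20 000; observed-tail comparisons use a 10^-12 relative tolerance so
  ties are counted as hits on both sides.
* Reads shorter than 20 nt use their full length as the seed; seed
  positions overhanging the consensus count as mismatches.
* The reads-level matrix is analysed with the same statistics as the
  identifier-level matrix (no separate count-model route).
* Figures are not rendered; the dendrogram is exported as Newick and the
  volcano data (diff, −log10 q, both always finite) as TSV.
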