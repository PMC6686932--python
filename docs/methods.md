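# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic-data generators do and do not emulate, and the
numerical details a user re-running or extending the analyses should know.

## Coordinates and interval conventions

All internal coordinates are 0-based half-open (BED convention); readers for
1-based formats (variant tables) convert on input and writers convert back.
"Shares at least one base" always means `bp_overlap >= 1`; book-ended
intervals ([0,5) + [5,9)) merge during union operations.  Chromosome names
are compared by exact string match — there is deliberately no "chr"
aliasing, so mixed naming surfaces as an explicit unknown-chromosome error
rather than a silent empty overlap.

## Representative peaks

Two consolidation modes reflect two study designs.  With technical
replicates, peaks called on pooled reads are retained when they overlap
replicate peaks from at least `min_support` (default 2) distinct replicates;
pooled coordinates are kept unchanged.  Across individuals (no technical
replicates), the union of per-individual peaks is merged into disjoint
regions; each region records every contributing sample and that sample's
best score.

Top-K selection is by peak score (−log10 p) for replicate-supported sets.
For union sets it is by the mean of per-individual ranks: within each
individual, peaks are ranked by score (1 = most significant); a union region
takes the rank of the individual's most significant overlapping peak, or
(peak count + 1) when the individual has no peak there.  The penalty keeps
regions missing from some individuals in the ranking without letting a
single individual's outlier p-values dominate.  When an individual
contributes several overlapping peaks to one region, the best-ranked peak
represents it — the natural choice given that the region exists because at
least one strong peak is there.  Ties in score or mean rank break by
(chromosome, start), making selection deterministic.

## Counts and PCA

Counts-in-peaks matrices use half-open containment of single-base insertion
positions.  Normalization is median-of-ratios size factors followed by
log2(count / sf + 1) — a fully specified stand-in for regularized-log
variance stabilization that preserves its purpose (library-size control and
damping of low-count variance).  When no peak has positive counts in every
sample (possible when sample groups occupy disjoint peak sets), size factors
fall back to total-count ratios normalized to geometric mean 1.  PCA is
centered, on the `top_variable` (default 5000) most variable transformed
rows, via full SVD; components are ordered by explained variance.

## Genic and chromatin-state annotation

The four genic categories use strand-aware windows: TSS-proximal spans 5 kb
upstream to 1 kb downstream of any TSS; downstream spans 5 kb past any TTS.
Precedence is TSS-proximal > intragenic > downstream > distal, applied per
peak with ≥ 1 bp overlap (not midpoint) deciding membership, so every peak
receives exactly one category.  Gene models must carry strand; unstranded
records are rejected at the reader.

The 18 chromatin-state mnemonics merge into five combined labels: promoter
(1_TssA, 2_TssFlnk, 3_TssFlnkU, 4_TssFlnkD, 14_TssBiv), transcribed (5_Tx,
6_TxWk), enhancer (7_EnhG1, 8_EnhG2, 9_EnhA1, 10_EnhA2, 11_EnhWk, 15_EnhBiv),
polycomb-repressed (16_ReprPC, 17_ReprPCWk), other (12_ZNF/Rpts, 13_Het,
18_Quies).  State overlap counts distinct peak bases (the peak set is merged
first), and tables report both raw bp and the fraction of total peak bases —
partially unlabeled peaks are neither excluded nor imputed.  Epigenome
ranking uses competition ranking (ties share the better rank).

## Motif scanning and enrichment

JASPAR / MEME-minimal count matrices become probability matrices with a
0.25-per-cell pseudocount; log-odds are log2 against a uniform background by
default (overridable with observed genome frequencies).  Scanning is a plain
threshold scan: every window on either strand scoring at or above the
threshold is an occurrence; windows containing N are skipped.  The default
threshold is 80 % of the motif's maximum attainable log-odds — the
downstream logic needs occurrence sets, not per-site p-values, so no p-value
machinery is attached to sites.  When the same motif occurs at identical
coordinates and strand on two haplotypes, the higher-scoring copy survives
(haplotype 1 on ties).

Backgrounds for enrichment are Altschul–Erickson dinucleotide-preserving
shuffles: a random last-exit edge per symbol that forms a spanning
arborescence into the final symbol, random permutation of the remaining
exits, then an Eulerian walk.  The shuffle provably preserves the exact
dinucleotide count multiset and the first and last symbol, and is
deterministic per seed.  Enrichment is a one-sided Fisher exact test on the
per-sequence "has ≥ 1 occurrence" 2×2 table; E = p × number of motifs
tested, with significance at E < 1e-100 by convention (configurable).  The
odds ratio applies a Haldane–Anscombe +0.5 only when a cell is zero; the
p-value is always exact.

## Footprints

Windows are the motif plus 100 bp flanks, dropped when less than 90 % of
bases are uniquely mappable, when they touch a blacklist region, or when
they exceed chromosome bounds (counted and logged).  Transposition matrices
count insertion events per strand-oriented window position; minus-strand
rows are column-reversed so motif position 1 is always leftmost — flipping
every strand and mirroring the insertion coordinates reproduces the same
matrix, which the tests verify.

Bound/unbound classification takes posterior binding probabilities, either
supplied externally (2-column TSV) or from the built-in EM stand-in: a
two-component mixture in which the bound component has free per-position
Poisson rates (it can learn both a higher overall insertion level and a
motif-depleted shape) and the unbound component one flat rate, with the
prior probability of being bound a logistic function of the standardized
motif score.  The logistic prior is refit each M-step by a guarded Newton
update (skipped when it would not improve), so each iteration is a
generalized EM step and the objective is non-decreasing.  Initialization is
deterministic (median split on total counts); non-convergence after
`max_iter` returns the last iterate with a warning.  This mixture is a
deliberate simplification of hierarchical footprint-mixture models
(negative-binomial counts, multi-resolution profiles); supplying externally
computed posteriors bypasses it entirely.

Aggregate profiles sum counts per column within each group (bound; the
top 10,000 unbound sites by motif score — the ordering criterion is a
package choice) and normalize to probability vectors.  Sum-then-normalize is
the default rather than per-site-normalize-then-average because it is robust
to low-count sites; a +1-per-column Laplace smoothing keeps the ratio finite
and can be disabled for exact oracle checks.  TPR is the per-position ratio
bound/unbound; mTPR averages the motif positions, fTPR all 200 flank
positions (no exclusion zone next to the motif edge); mTPR < fTPR calls an
aggregate footprint.  On null simulations the call is a fair coin, and the
statistic is invariant to scaling all counts.

## GWAS variant enrichment

Clumping iterates leads by ascending p and drops any lead with r² > 0.2 to a
retained lead within 1 Mb (first-seen kept on exact p ties).  Loci are the
lead plus all variants with r² > 0.8 within 1 Mb.  Controls are drawn from
pool variants in the same matching cell as the lead: proxy-count bins
{0, 1, 2, 3–5, 6–10, >10}, MAF bins of width 0.02, TSS-distance bins at pool
deciles.  These bin definitions are fixed, documented choices (matched-
control enrichment tools do not publish theirs); an empty cell widens the
MAF bin once to its immediate neighbors before raising an unmatchable-locus
error.

Per-locus overlap probabilities p_i are Monte-Carlo estimates over
`n_control_sets` (default 500) matched controls drawn without replacement
(capped at cell size), each expanded to its own locus.  The test statistic
is the number of GWAS loci with any member variant inside a peak; the
p-value is the exact upper tail of the Poisson-binomial distribution of
Σ Bernoulli(p_i), computed by convolution dynamic programming (exact for
thousands of loci); z = (observed − Σp_i) / sqrt(Σ p_i (1 − p_i)).  The
upper tail only is reported (enrichment direction); Bonferroni significance
is p < α / n_traits with α = 0.05 and 11 trait groups by default.  Each
locus uses a generator derived from the base seed and a stable hash of its
lead id, so results are invariant to locus order and reproducible per seed.

## Allelic imbalance

Input counts are assumed to come from pileups at genotyped heterozygous
sites with base quality already thresholded upstream (Phred ≥ 30 is the
conventional pileup filter); the module's own filters drop sites with any
non-genotyped base, fewer than 10 total counts, or an unseen allele.  The
null is BetaBinomial(n, π, ρ) with α = π(1−ρ)/ρ, β = (1−π)(1−ρ)/ρ; ρ = 0 is
the binomial limit, handled analytically (and numerically: ρ below 1e-10
switches branches, with continuity verified).  Fitting maximizes the exact
log-likelihood with L-BFGS-B within π ∈ [1e-4, 1−1e-4], ρ ∈ [1e-8, 0.99]
from four fixed starts, keeps the best optimum, and explicitly compares
against the ρ = 0 boundary.  Fewer than 50 sites triggers a warning.

The two-tailed p is twice the smaller exact tail, capped at 1 — an explicit
convention, switchable to the "sum of outcomes no more likely than observed"
alternative, since two-tailed definitions differ between packages.  The
doubled-tail test is conservative under the discrete null: at π = 0.5,
ρ = 0.05 and realistic coverage the nominal rate at α = 0.05 stays below
0.05.  Overdispersion monotonically inflates p for fixed counts, which is
the reason a beta-binomial p at strongly imbalanced counts exceeds the
corresponding exact binomial p.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (config, seed) built on numpy Generators;
all acceptance-scale runs use two 10-Mb toy chromosomes (the GWAS
calibration experiments use two 100-Mb chromosomes purely to host ~5000 LD
blocks), chosen so each experiment finishes in seconds at the sample sizes
the statistical checks need.

- Peak sets emulate a design of 3 individuals or 2–3 technical replicates:
  shared regions appear per sample with probability `share_fraction` (0.9),
  boundaries jittered ±50 bp, scores correlated around a per-region base
  score; private noise peaks are sample-specific; a pooled peak list mimics
  peak calling on pooled reads.
- Insertions are Poisson: background 2e-5 events/bp, peaks 0.02 events/bp;
  bound motif windows get a 3× accessibility boost and their motif cores are
  thinned with the depletion probability (default 0.3) — protein occupancy
  as a thinned point process.
- LD is assigned at the block level (within-block pairs drawn proxy-grade,
  moderate, or weak; cross-block r² = 0), not simulated from a coalescent —
  sufficient for clumping/proxy/matching logic and orders of magnitude
  faster.  MAFs are uniform on [0.05, 0.5].
- Allele counts follow the beta-binomial data-generating process exactly,
  with an optional truly imbalanced fraction at a shifted π and an optional
  global reference bias.
- Sequences are i.i.d. uniform with the consensus planted at a configurable
  rate.

None of this reproduces real-data complications: fragment-length structure,
Tn5 sequence bias, copy-number and mappability artifacts, genuine LD decay,
correlated multi-trait GWAS architecture, or alignment reference bias.
Passing tests therefore demonstrate the correctness and calibration of the
*procedures* under their stated models, not performance on any particular
real dataset; headline counts from any real study (peak totals, enrichment
z-scores, imbalanced-site counts) depend on restricted-access data and are
out of scope.

## Numerical details and degenerate inputs

- Poisson-binomial: convolution DP, O(n²), exact; tail clipped to [0, 1].
  sd = 0 means every p_i ∈ {0,1}: z is 0 when observed equals expected,
  ±∞ otherwise, p degenerate.
- PWM log-odds clip probabilities at 1e-9 to keep zero entries finite.
- Beta-binomial p-values use exact tail summation via the distribution's
  cdf/sf; the vectorized scan path and the scalar path agree.
- EM: rates floored at 1e-8; priors clipped away from {0,1};
  all-identical-window inputs yield equal posteriors by symmetry.
- Empty peak collections, empty samples, k larger than a collection, and
  missing chromosomes all take defined paths (empty outputs, zero columns,
  whole collection, empty overlap) rather than raising, except where a
  result would be meaningless (all-zero sample in size factors, no bound
  sites in profile aggregation, unmatchable loci).
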