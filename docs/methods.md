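# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `uvsig`, in the order data flow through the pipeline.

## Consensus calling and event collapsing

A variant enters the analysis only if every supplied caller reports the
identical (sample, chrom, pos, ref, alt) key and the key is absent from
the exclusion list (a dbSNP/Ensembl-variation export supplied as a file;
keys may be site-level or sample-qualified). Multi-allelic VCF records
are split into biallelic calls at read time. Coordinates are 1-based in
VCF/GFF3 and 0-based half-open everywhere internally; conversions happen
only at I/O boundaries.

Adjacent same-sample SNV pairs merge into one `dinucleotide` event.
UVB photochemistry produces cyclobutane pyrimidine dimers whose
signature product is a CC>TT doublet — two base calls, one lesion — so
a pair counts once in total burden. Runs of three or more adjacent SNVs
merge left-to-right greedily into pairs (doublets are the only species
with a physical interpretation here; longer runs are vanishingly rare
and would otherwise make collapsing order-dependent). Indels pass
through unmodified and do not interact with collapsing. Dinucleotide
events are *excluded* from the SBS96 catalog and the 6-class tallies but
count (as one) toward total burden and are reported on their own axis.

## Classification and spectra

Each SNV is reported on its pyrimidine-bearing strand: a purine
reference base maps through the reverse complement, giving 6 classes
(C>A, C>G, C>T, T>A, T>C, T>G) x 16 flank combinations = 96 channels in
the frozen COSMIC order (classes as above, contexts alphabetical within
class). `at_cpg` is true iff the mutated cytosine is immediately 5' of a
guanine on that strand. Events whose trinucleotide context contains an N
are logged and dropped from context analyses.

Spectrum normalization counts the 32 pyrimidine-centric trinucleotides
in a user-supplied region set (both strands via complementation; windows
centered on region-edge bases are included) and reports
count x 10^6 / occurrences per channel — mutations per million available
sites. Whether the regions are the capture design or the whole exome is
the caller's choice; the denominator is explicit input, never inferred.

## Strand assignment and the strand-bias test

For a gene on strand s, the template (transcribed) strand is the
complement of s. An SNV whose pyrimidine lies on the coding strand is
`untranscribed`, on the template strand `transcribed`; intergenic events
and events under genes annotated on both strands are `unknown` and are
excluded from tallies (reported as an excluded count so totals remain
auditable).

The per-class test conditions on the total event count n: under strand
symmetry the transcribed count is Binomial(n, 1/2), and the two-sided
p-value sums all outcomes with likelihood no greater than the observed
one (minimum-likelihood rule; `scipy.stats.binomtest`). This is exactly
the classical exact comparison of two Poisson rates with equal exposure.
Two properties worth knowing:

- the test is *conservative at discrete n*: at n = 100 the attainable
  size at nominal alpha = 0.05 is 0.0352, and simulated null rejection
  rates match that enumerated size, not 0.05;
- reported log2 ratios add 0.5 to both counts only when one is zero;
  raw counts are always retained alongside.

Tests aggregate events per experimental group by default (pooled across
tumors); per-sample testing is available by calling the test on
per-sample tallies.

## Signature extraction

One in-house multiplicative-update NMF serves all extraction roles,
with the generalized Kullback-Leibler divergence (default; the natural
objective for count data) or squared Frobenius error. Updates run until
the relative objective improvement over a 10-iteration window falls
below `tol` (1e-6) or `max_iter` (2000); the objective trace is
returned and is non-increasing by construction. Factors are rescaled on
exit so signatures are column-stochastic and exposures carry the counts.
Cross-extractor robustness (the published three-tool comparison) is
reproduced by varying the objective and resampling scheme of this one
implementation rather than porting three codebases; `cross_method_
correlation` compares the resulting signature sets by Pearson
correlation.

**Stability.** For each candidate rank K: every sample's counts are
resampled by a multinomial bootstrap of its own mutations (n_bootstrap
= 50 by default); each replicate is factorized from a fresh random
start; the pooled replicate signatures (n_bootstrap x K profiles) are
partitioned into K clusters by k-medoids on cosine distance (10
restarts, seeded); stability is the mean silhouette width of that
partition. At K = 1 the silhouette is undefined and stability is the
mean cosine of replicates to their centroid. Consensus signatures are
normalized cluster centroids.

**Rank selection.** Stability alone cannot penalize underfitting — a
single cluster of rank-1 bootstrap fits is trivially stable — so an
error guard excludes underfit ranks. For count data the expected
squared Frobenius residual from sampling noise alone equals the total
mutation count N (Poisson variance = mean), so a rank whose
reconstruction error on the unresampled catalog exceeds
`noise_factor x sqrt(N)` (noise_factor = 1.3) is still missing real
structure and is inadmissible. Threshold-free alternatives based on the
shape of the error curve were tried and rejected: extra ranks absorb
noise worth up to ~30% of total error on catalogs of this size, which
overlaps any fixed "relative improvement" slack. If overdispersed data
leave no rank under the floor, ranks within 1.3x of the best achieved
error are admitted instead. Among admissible ranks the smallest within
0.02 of the maximal stability is selected (parsimony). The per-rank
reference fits are warm-started from the previous rank's solution
augmented with one small random component, plus two cold restarts,
keeping the error-vs-rank curve monotone despite local optima.
Reported per-rank diagnostics include explained variance, residual sum
of squares, Hoyer sparseness, and consensus-clustering dispersion/
cophenetic summaries.

**Activities.** Each sample's 96-vector is regressed on the signature
profiles by non-negative least squares. Counts are then allocated
channel-by-channel in proportion to the posterior probability of each
signature given the channel (lambda_ck = W_ck h_k normalized over k);
channels where no signature reaches the `posterior_threshold` (0.5)
contribute their counts to `unassigned`, so activities + unassigned
equal the sample total exactly. The thresholded-posterior rule is this
package's interpretation of "uncategorized" mutations — the quantity is
reported in the source literature without a defining rule — and with
K = 2 the maximum posterior can drop below 0.5 only at exact ties, so
unassigned fractions are near zero here; raw NNLS coefficients are kept
alongside for users who prefer them.

## Signature comparison

Cosine similarity is scale-invariant and lies in [0, 1] for
non-negative spectra. Empirical p-values permute the entries of the
*second* vector (the reference profile; which vector the cited
convention shuffles is ambiguous, so the choice is explicit and
flaggable): p = (1 + #{permuted cosine >= observed}) / (n + 1), never
zero, with n = 10^6 by default. For vectors of length <= 7 (7! = 5040)
enumeration replaces sampling and the exact tail fraction is returned.
Reference catalogs are user-supplied files in the COSMIC tabular layout;
the channel ordering is validated against the canonical labels and
mismatches are errors, never silently reindexed.

## Copy number

Segments (e.g. CNVkit `.cns`) are validated for within-sample
non-overlap, then filtered to |log2 ratio| >= 0.2 with >= 5 supporting
bins. The threshold is inclusive ("surpassing" is read as >=): boundary
segments are reported. The altered-genome fraction is the altered
footprint over the total segmented footprint, per sample; it is
invariant to splitting segments and lies in [0, 1]. Sex chromosomes are
included by default (flag to exclude); zero-footprint samples report
NaN rather than a silent zero.

## Group and survival statistics

"Nonparametric ANOVA with BH correction" is implemented as
Kruskal-Wallis omnibus followed by all pairwise Mann-Whitney tests with
Benjamini-Hochberg adjustment — the standard reading of that phrase.
Mann-Whitney uses the exact null distribution for combined n <= 20 and
the tie-corrected normal approximation otherwise. The t-test family
uses Welch tests with Holm's step-down adjustment. ANOVA post hocs are
Tukey's HSD (studentized range) or Fisher's LSD (pooled-variance
pairwise t, unadjusted, to be read only after a significant omnibus F).
Kaplan-Meier estimation and the Gehan-Breslow-Wilcoxon test (log-rank
weighted by the number at risk, emphasizing early separation) are
delegated to lifelines; survival comparisons default to each group
versus a designated control.

## Dosimetry

The erythema action spectrum is 1 for lambda <= 298 nm,
10^(0.094(298-lambda)) for 298-328 nm, and 10^(0.015(C-lambda)) for
328-400 nm. C = 140 (default) gives the continuous modern form; C = 139
reproduces the original 1987 tabulation and leaves a ~1.035x step at
328 nm (documented, selectable). Effective dose integrates
weight x spectrum over the lamp's native wavelength grid by trapezoid;
grids coarser than 5 nm are linearly resampled to 1 nm first so the
exponential weight is adequately sampled. Conversions: 1 kJ/m^2 =
100 mJ/cm^2; 1 SED = 10 mJ/cm^2 erythemally weighted. The
tanning-session equivalence halves the session's erythemal energy
(the UVB component of tanning lamps carries roughly half the erythemal
effect) and divides by the comparison lamp's EEE. Minimal-erythema-dose
phototype tables are out of scope.

## The synthetic cohort generator

The generator exists so every stage has a ground truth. It emulates:

- a random reference (default 200 kb, GC 0.42 — mouse-like) with
  non-overlapping genes alternating strands over ~half the sequence,
  and the whole sequence as the capture region;
- a UVB-like signature (C>T concentrated at dipyrimidines with the
  5'-T preference TCT > TCC > TCA > TCG, minor mass elsewhere) and a
  flat background, or arbitrary custom profiles;
- per-sample activities: Gamma(shape 4, CV 0.5) around configured means
  *within exposure groups*. The default cohort is one third each
  "no_uv" / "uva" / "uvb" with UVB-signature multipliers 0.05 / 0.05 /
  2.9 (mean 1, so configured means are cohort-wide expectations) and a
  uniform background. This mirrors the defining feature of a
  mixed-exposure tumor cohort — order-of-magnitude differences in
  UV-signature activity between groups — and that spread is precisely
  what makes de novo extraction identifiable: if every sample had the
  same mixture proportions the catalog would be numerically rank 1 and
  no extractor could separate the processes;
- placement: each mutation's channel is drawn from its signature and
  assigned a uniformly chosen reference site with the matching
  trinucleotide context (collisions redrawn). Genic C>T events are
  thinned on the template strand to odds 1:rho (untranscribed:
  transcribed), emulating transcription-coupled repair. A configured
  fraction of C>T events is emitted as CC>TT pairs at CC/GG sites;
- per-caller call sets: each true variant independently missing from
  each caller with the dropout probability, plus caller-private false
  positives (which three-way consensus removes);
- clinical data: exponential survival per group with right-censoring at
  a fixed horizon, and CNA segments tiled evenly with a planted altered
  fraction that the analysis recovers exactly by construction.

Everything is deterministic under the seed.

What the generator does *not* emulate — and hence what passing recovery
tests cannot claim about real data: alignment and calling artifacts with
positional structure, mutation hotspots and chromatin-dependent rates,
subclonality and purity, overdispersion beyond Gamma-Poisson, indel
spectra, and realistic genome-scale context frequencies (a 200 kb i.i.d.
reference stands in for the mouse exome). Recovery results demonstrate
correctness of the inference machinery under the model's own
assumptions, not field performance.

## Problem sizes and reproducibility

Default experiment sizes were chosen so the full test suite and the
acceptance script each complete in well under a minute of CPU while
leaving comfortable statistical margins: 30-50 samples with a few
hundred mutations each for recovery experiments, 50 bootstrap replicates
over ranks 1-5 for selection, 10^4 simulated tests for calibration,
10^5 Monte-Carlo permutations against exhaustive enumeration. All
stochastic stages take explicit seeds; the pipeline stamps outputs with
the configuration hash and seed, and identical configurations reproduce
identical summaries byte for byte.
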