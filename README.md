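# uvsig

Post-variant-calling genomic analysis of UV-accelerated melanoma mouse
models: from ensemble somatic call sets to mutation burden, trinucleotide
spectra, transcriptional strand bias, de novo mutational-signature
extraction, signature-catalog matching, copy-number burden, survival
statistics, and erythemal UV dosimetry.

## Who this is for

Groups studying UV mutagenesis in genetically engineered mouse models (or
comparable exome cohorts) who have already run alignment, variant calling
with multiple callers, and copy-number segmentation, and need the
downstream analysis: which mutations are real and recurrent, what the
mutational spectrum looks like, whether the UVB photoproduct footprint
(C>T at dipyrimidines, CC>TT doublets, transcribed-strand depletion) is
present, how many mutational processes shaped each tumor, and how the
delivered UV doses translate into erythemally weighted units. A
synthetic-data generator emulates every input, so the entire pipeline is
testable without any sequencing data.

## The model in brief

**Events.** Variants reported by all callers and absent from a
known-variant list form the consensus; adjacent same-sample SNV pairs
collapse into single dinucleotide events (one pyrimidine-dimer lesion,
one event). SNVs are classified into the 6 pyrimidine-centric classes x
16 flanking contexts of the SBS96 scheme; purine-reference sites map
through the reverse complement.

**Spectra and strand bias.** Catalogs are samples x 96 count matrices in
the fixed COSMIC channel order. Rates normalize counts to trinucleotide
availability (count x 10^6 / occurrences in the region set). Each genic
SNV is labeled by whether its pyrimidine lies on the template
(transcribed) or coding (untranscribed) strand; asymmetry per class is
tested with the exact conditional binomial test (transcribed count ~
Binomial(n, 1/2) under the null, two-sided minimum-likelihood rule —
the standard exact two-Poisson-rate comparison).

**Signatures.** The catalog V (96 x n) is factorized V ~ WH with
multiplicative updates under a KL or Frobenius objective; W's columns
are signatures (non-negative, summing to 1), H holds exposures in
mutation counts. For each candidate rank K, per-sample multinomial
bootstraps are refactorized, the pooled replicate signatures are
clustered (k-medoids, cosine distance) into K groups, and stability is
the mean silhouette. Ranks whose reconstruction error exceeds 1.3x the
Poisson noise floor sqrt(total mutations) are still underfitting and are
excluded; among the rest, the smallest rank within 0.02 of the maximal
stability is selected. Activities are refit per sample by non-negative
least squares; mutations in channels where no signature reaches a 0.5
posterior are reported as unassigned.

**Comparison.** Cosine similarity against reference catalogs (e.g.
COSMIC SBS), with empirical p-values from permuting one profile's
entries (exhaustive for short vectors, up to 10^6 Monte-Carlo draws
otherwise).

**CNA, statistics, dosimetry.** Copy-number burden is the footprint of
segments with |log2 ratio| >= 0.2 supported by >= 5 bins, divided by the
total segmented footprint. Group comparisons use Mann-Whitney U,
Kruskal-Wallis + pairwise Mann-Whitney with Benjamini-Hochberg
correction, t-tests with Holm adjustment, or ANOVA with Tukey HSD /
Fisher LSD post hocs; survival uses Kaplan-Meier curves and the
Gehan-Breslow-Wilcoxon weighted log-rank test. UV doses are weighted by
the McKinlay-Diffey erythema action spectrum (1 below 298 nm,
10^(0.094(298-l)) to 328 nm, 10^(0.015(140-l)) to 400 nm) and expressed
as erythemally effective energy (EEE) or standard erythema doses
(1 SED = 10 mJ/cm^2 weighted).

## Worked example

`examples/01_simulate_and_extract.py` simulates 20 tumors in three
exposure groups (unexposed / UVA / UVB) from a UVB-like + flat-background
signature mixture, runs consensus calling through signature extraction,
and prints:

```
rank selection (stability = mean bootstrap silhouette; a rank is
admissible when its error reaches the Poisson noise floor):
      stability  reconstruction_error
rank
1         1.000               216.148
2         0.940                79.811
3         0.730                72.339
4         0.741                71.038
selected rank: 2
Signature 1: cosine 0.999 to planted 'uvb_like' profile
Signature 2: cosine 0.950 to planted 'flat' profile

per-group mean activity (mutations attributed per signature):
       Signature 1  Signature 2  unassigned
group
no_uv         12.0        104.4         0.0
uva           16.3         81.4         0.0
uvb         1286.7         66.9         0.0
```

Rank 1 is perfectly "stable" (one cluster of bootstrap fits is trivially
reproducible) but its reconstruction error sits far above the noise
floor, so it is rejected; rank 2 reaches the floor with a 0.94
silhouette and is selected. The recovered profiles match the planted
ones (cosine 0.999 / 0.950), and the attributed activities reproduce the
experimental design: UVB-signature mutations are ~100x enriched in the
UVB-exposed group while the background process is uniform.

The other examples demonstrate strand-bias testing (a planted 1:3
transcribed:untranscribed odds for C>T returns log2 ratio -1.61 vs the
true -1.58, p < 10^-4, with all other classes null), survival/CNA
analysis, and dosimetry (`examples/04_dosimetry.py` weights a synthetic
312 nm lamp line: a 4.5 kJ/m^2 exposure yields 67.5 mJ/cm^2 EEE = 6.75
SED, and the tanning-session arithmetic 4.5 SED -> 45 -> 22.5 mJ/cm^2
UVA-attributable -> 1.58x a 70 kJ/m^2 lamp exposure).

A thin CLI mirrors the stages (`uvsig run|variants|spectrum|extract|
compare|cna|stats|survival|dose|simulate`); `uvsig run --config
analysis.yaml` drives the full pipeline from one YAML file.

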