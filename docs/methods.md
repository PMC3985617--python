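# Methods

This note records the models implemented in `dualmark`, their assumptions,
the defaults and numerical choices, and what the synthetic-data generators do
and do not emulate.

## Allele-conversion cycling model

Each lineage is a binary vector over L target loci (L = 10 by default, the
usual 10-plex oligo pool size). One engineering cycle draws a conversion
event for every lineage independently and ORs it onto the genotype;
conversions are irreversible. Cycles are i.i.d.: no fitness differences among
genotypes, no escape-mutation process, and no oligo- or locus-specific
conversion variance are modelled.

Three per-cycle distributions are supported:

* **empirical_pattern** — resample whole observed conversion patterns from a
  genotyped single-cycle population, preserving any positional structure in
  the input data;
* **empirical_count** — resample only the conversion-count histogram and
  place the k conversions uniformly without replacement among the L loci
  (no positional dependence); this is the default reading when only count
  summaries are trusted;
* **parametric_zib** — a zero-inflated binomial ZIB(π, p): with probability π
  the cycle converts nothing, otherwise K ~ Binomial(L, p). The zero-inflated
  family is the minimal two-parameter way to reconcile a reported mean with a
  reported zero fraction, because single-cycle recombineering data are
  over-dispersed at zero relative to a plain binomial (a sub-population
  misses recombination entirely, e.g. cells that escaped co-selection).
  Only the mean and P(K = 0) are matched; the upper tail of K is whatever the
  ZIB implies and is a documented approximation.

**Calibration.** `fit_conversion_model(m, P₀, L)` eliminates p through the
mean constraint p = m / ((1 − π)L) and bisects on π until
|π + (1 − π)(1 − p)^L − P₀| < 1e-8. Feasibility requires
(1 − m/L)^L ≤ P₀ ≤ 1 − m/L; infeasible pairs raise an error naming the
violated bound (plain-binomial floor or all-or-none ceiling). The degenerate
pair (m = 0, P₀ = 1) returns π = 1, p = 0.

**Bottlenecks.** Counter-selection inocula are modelled as uniform
subsampling without replacement (hypergeometric), which leaves the expected
conversion-count histogram unchanged but collapses genotype diversity at
small sizes — small inocula frequently reduce a mixed population to a single
genotype.

All stochastic operations take explicit integer seeds; there is no global
random state. `numpy.random.Generator` (PCG64) drives every draw.

## Growth-curve selection statistics

Threshold time is the first time OD₆₀₀ ≥ 0.4, linearly interpolated between
the bracketing samples (plate readers sample every few minutes; interpolation
recovers off-grid crossing times). A curve that never crosses is censored at
its last sample time. No smoothing is applied by default; an optional
moving-median (window 3) is available for spike removal.

NSA = 1 − [t^RS · (t^CNS/t^RNS)] / t^CS is a ratio of ratios: the
recombinant-vs-control ratio in selection, normalized by the same ratio in
nonselective media to cancel inoculum disparities. It is invariant to
rescaling all four times and is ≤ 1. Censored times enter the formula at the
horizon and set a flag: the reported NSA is then a conservative lower bound.
Censored nonselective controls make the statistic uninterpretable and raise.

Normalized Culture Time is the affine normalization
(t_oligo − t_positive) / (t_mock − t_positive): 0 when the oligo culture
behaves like the marker-knockout positive control (the encoded mutation
confers escape), 1 when it behaves like the mock recombination. Values
slightly outside [0, 1] are legitimate (faster than the knockout, or slower
than mock) and are preserved. Scores below 0.6 are called causal and
[0.6, 1.0) borderline; these cutoffs are conventions carried in
`CultureTimeResult` and do not affect the numeric score.

## Escape-frequency estimation

Single platings use the exact binomial (Clopper–Pearson) 95% interval from
beta quantiles. Escape frequencies reach 1e-11 with 0–1 colonies observed, a
regime where Wald-type intervals are meaningless; with zero colonies the
point estimate is 0 and the upper bound is ≈ 3.69/N. Replicated platings are
summarised as the mean ± SEM of per-replicate frequencies (the reporting
convention for plate-count experiments); a single replicate has no defined
SEM and falls back to the exact interval. Fold reductions are plain frequency
ratios; when the improved condition observed zero colonies the ratio is
reported against its interval upper bound, i.e. as a lower bound. An optional
interval on the ratio uses the delta method on log frequencies. Reported
frequencies are rounded to 2 significant figures by `round_sig`.

Two mechanistically independent counter-selection agents should multiply:
predicted joint escape = p₁·p₂, with the observed/predicted factor as the
deviation measure. No Luria–Delbrück fluctuation analysis is attempted —
platings measure frequencies, not mutation rates.

## Multi-clone mutation analysis

Coordinates are 1-based inclusive at every interface (VCF convention);
internal arithmetic is half-open 0-based; genome bins are half-open
[k·size, (k+1)·size) from 0.

**Classification** rebuilds the gene's reference region with the edit applied,
orients both to the coding strand (reverse complement for minus-strand
genes), and classifies by precedence: start_lost (first codon changed) >
frameshift (net length change ≢ 0 mod 3) > in-frame indel > stop_gained >
stop_lost > nonsynonymous > synonymous, using NCBI translation table 11.
Variants not fully inside a gene are intergenic. Indels are left-aligned
before keying so identical events from different callers merge;
`merge_callsets` keeps calls present in ≥ min_callers callsets per clone.
A premature stop in the first quarter of a CDS can be rescued by downstream
in-frame ATG codons; classification does not model this, but such variants
carry a caveat flag in the tallies.

**Ancestral filter.** A variant carried by more than half the clones (default
threshold 0.5, configurable) predates the independent escape events and is
strain background; it is excluded from causal tallies and reported
separately. The 0.5 default treats a variant present in ~55% of clones as
background, matching how majority variants behave in practice.

**Recurrence and enrichment.** Per gene: distinct variant keys, total =
Σ per-variant incidence, genomes hit, and the LoF fraction of distinct
mutations (start-lost + frameshift + stop-gained). Under the null that
mutations land uniformly per coding bp, a gene's expected share of the
scope's mutations is its coding length over the scope's total coding length;
the one-sided exact binomial p-value is P(X ≥ observed) with
X ~ Binomial(n_scope, expected share). Genes are ranked by distinct, then
total, then LoF fraction. An exact test was chosen over an informal count
ranking so the null is explicit and calibratable; genome-wide scopes are
Benjamini–Hochberg corrected because thousands of genes are tested at once.

**Duplication sites.** Duplicating the causal operon protects the
counter-selection, but identical copies invite recA-mediated single-crossover
loop-out. A candidate insertion site is accepted only if each of the two
circular arcs between the candidate and the wild-type operon contains at
least one essential gene entirely within it, so either loop-out deletes an
essential gene and is purged by selection. Candidates inside annotated genes
are rejected with a reason.

## Synthetic data: what it emulates and what it does not

The generators produce inputs whose *statistical structure* matches what the
analyses assume, so that calibration and recovery are meaningfully testable:

* **Reference genomes** are random ORFs (ATG…stop, no internal stops) on
  alternating strands with random spacers — no codon bias, operon structure,
  GC skew or repeats.
* **Escape cohorts** default to 96 clones, causal hit probability 0.93
  (~89/96 clones carrying a causal-gene mutation), LoF bias 0.75 among causal
  mutations, ~30 passenger SNVs per clone placed uniformly per bp
  genome-wide, and 21 ancestral variants shared by every clone. The
  passenger burden reflects a mismatch-repair-deficient (mutS⁻) background
  (≈ 34 mutations/clone in comparable data sets); Poisson placement is an
  assumption — real hypermutator spectra may be over-dispersed and
  context-biased. Uniform-per-bp placement is exactly the null the
  enrichment test assumes, which is what makes the null-calibration test
  meaningful. Frameshifts are generated as 1-bp deletions, premature stops
  as single-base changes to TAA/TAG/TGA, start losses as start-codon SNVs.
* **Growth quartets** grow exponentially after a lag with OD capped at
  carrying capacity; the control selective culture grows from
  n0 × resistant_fraction (counter-selection leakiness) and a sub-single-cell
  resistant inoculum does not grow at all. Defaults: n0 = 1e6 cells (typical
  well inoculum), doubling time 30 min, lag 60 min, OD conversion 1e-8/cell,
  48 h horizon. No death phase, no stochastic single-cell lag.
* **Platings** draw colonies ~ Poisson(f·N): at N up to 1e10 with tiny f the
  Poisson and binomial laws coincide and Poisson is cheap.

Passing tests on these inputs demonstrate internal consistency, correct
calibration under the stated models, and recovery of planted signal; they do
not demonstrate robustness to alignment artifacts, caller-specific error
modes, context-dependent mutation spectra, or growth phenotypes outside the
exponential-with-lag family.

## Problem sizes and tolerances

Monte-Carlo checks use 10⁴ lineages for cycling summaries (3-standard-error
bands), 2 × 10³ replicate platings per frequency decade for interval
coverage, 10⁴ random variants for classifier/oracle agreement, 20 seeds for
planted-causal recovery, and a 1000-gene genome with ~150 expected mutations
per gene for the p-value uniformity check (large per-gene counts make the
discrete exact p-values effectively continuous; gene lengths are varied so
p-value supports differ across genes). These sizes give stable checks at
interactive run times on a single CPU.

## Known limitations

* The ZIB per-cycle model constrains only the mean and zero fraction; the
  full conversion-count distribution (and hence multi-edit tail behaviour)
  is approximate.
* Whether real cycling data resample patterns or counts is data-dependent;
  both modes are provided and neither is asserted to be the mechanism.
* NCT is one reasonable affine normalization between the two controls; other
  monotone normalizations would rank oligos identically but scale
  differently.
* The classifier handles single-ALT SNVs and small indels; structural
  variants, multi-nucleotide substitutions spanning codon boundaries are
  handled generically via CDS reconstruction but complex overlapping events
  within one clone are not composed.
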