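# Methods

This note documents the models, numerical choices and limitations behind
`consangcnv`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Coordinate and unit conventions

All internal coordinates are 0-based half-open `[start, end)`; 1-based
coordinates appear only in human-readable report writers. Genetic distance
is used for all homozygosity calculations; physical distance only for
interval geometry (CNVs, peaks, mappable genome). Rates are fractions
internally and percentages in reports.

## Gene-dropping model

Meioses place crossovers as a Poisson process with rate 1 per Morgan on the
genetic map — no crossover interference, no sex-specific maps. Chromosomes
assort independently; this is implemented by laying the autosomes end to
end on a single centimorgan axis and re-randomizing meiotic phase at every
chromosome start, which lets one Poisson draw cover the genome. Founder
haplotypes carry unique integer labels; autozygosity is the set of regions
where an individual's two haplotype mosaics carry the same founder label,
so simulated truth is exact rather than inferred. Physical coordinates of
segments come from inverting the (piecewise-linear) genetic map.

The default synthetic genome has 22 autosomes with genetic lengths
proportional to the human sex-averaged map, totalling ≈ 3,538 cM, at a
uniform 1 Mb per cM. A 2-chromosome toy variant keeps tests fast. Checks
that rely on the inbreeding coefficient use pedigree expectations: F = 1/16
for first-cousin offspring, 1/64 for second cousins, each verified within
3 Monte-Carlo standard errors.

## Deep-founder IBD segment lengths

For descent of both alleles from a single founder g generations back, the
autozygosity loop comprises k = 2g meioses. A literal unconditional
gene-drop through such a loop leaves ~2^-k of the genome autozygous —
at g = 16 effectively nothing in any feasible number of replicates — while
the quantity of interest is the *length distribution of segments
conditional on descent*. `simulate_founder_ibd` therefore simulates the
standard conditional model: segment boundaries are set by the nearest
crossover in any of the loop's k meioses, i.e. by the superposition of the
k crossover processes (Poisson at k/100 per cM), truncated at chromosome
ends. Interior segment lengths are exponential with mean 100/k cM (verified
by a Kolmogorov–Smirnov test on interior segments of a long chromosome;
interior segments of *short* chromosomes are length-biased low by end
censoring, which is why the distribution checks use a long-chromosome toy).

Length-weighted closed forms under this model,
fraction of length below x = 1 − e^(−x/μ)(1 + x/μ) with μ = 100/k:

* second-cousin loop (k = 8, μ = 12.5 cM): 93.8% of segment length is ≥ 5 cM;
* 16-generation founder (k = 32, μ = 3.125 cM): 47.5% of length is < 5 cM.

The calibration claims about the 5 cM filter are interpreted as these
**length-weighted** fractions: that reading reproduces both printed
calibration figures simultaneously, whereas a segment-count-weighted
reading does not. Simulated values on the finite genome land at ≈ 93.1%
and ≈ 48.5% (chromosome-end censoring shortens segments slightly relative
to the infinite-genome closed form).

## ROH calling

Window qualification excludes missing genotypes from both numerator and
denominator of the homozygous fraction (a window with no non-missing calls
never qualifies); counting missing calls as homozygous would let
missingness masquerade as autozygosity. Run boundaries are the outermost
run-supporting markers, not window edges — marker-level support is the
natural union of qualifying windows and is what the brute-force
window-enumeration oracle computes. The window steps 1 marker; chromosomes
shorter than the window are skipped with a warning, not padded. All
threshold comparisons (≥ 98%, ≥ 5 cM, ≥ 2.5%) are inclusive; the 98%
comparison is made as `hom + 1e-9 ≥ frac × non-missing` to keep the
inclusive boundary exact despite the binary representation of 0.98.

Recovery behaviour: a run needs at least one full window inside it, so at
marker density d (markers/cM) segments shorter than ~window/d cM are
undetectable; called boundaries overshoot truth by up to the window extent.
Recovery tests therefore use ≥ 30 markers/cM, where called runs match true
segments with mean Jaccard > 0.95.

## Consensus CNVs, rarity, burden

Caller concordance is geometric: per sample and copy-number class, each
caller's calls are unioned, the per-base count of distinct supporting
callers is swept, and maximal regions with depth ≥ k become consensus
events (boundary events at identical positions are netted before the
threshold test, so abutting calls do not split a region). Classes are never
pooled. The consensus probe count is the minimum probe count among
overlapping supporting calls; biallelic-deletion selection requires ≥ 3 of
4 algorithms and ≥ 5 probes.

Rarity against the control catalog matches copy-number class as well as
locus: an event is common only if **more than 50%** of the *query* length
overlaps a single same-class catalog entry. Query-relative overlap is the
conservative choice for small query events; a locus seen in controls only
as a single-copy loss never makes a biallelic deletion common.

De-novo flagging is deliberately asymmetric: child events are
consensus-grade, while *any* single-caller parental call of the same
gain/loss direction overlapping by ≥ 1 bp marks the event inherited. The
leniency suppresses false de-novo calls caused by parental boundary jitter
or reduced parental sensitivity. CN 3 and CN 4 pool as "gain" for direction
only; they remain distinct classes for rarity matching.

Burden is carrier-based (individuals with ≥ 1 qualifying event), tested
with the exact one-sided hypergeometric tail (scipy's hypergeometric
survival function; cross-checked in tests against an explicit
binomial-coefficient enumeration).

## Monte-Carlo coincidence test

The mappable genome is the union of inter-marker intervals ≤ 100 kb, minus
exclusion regions, autosomes only. Placements preserve CNV lengths and lie
**wholly within one mappable interval**: a mappable interval is chosen with
probability proportional to its number of valid starts for that length,
then a start is drawn uniformly — making every feasible placement equally
likely (verified by chi-square against uniform over all feasible starts at
n = 10^6). Spanning placements across low-density gaps are disallowed so
that placed length on the mappable genome is preserved exactly.

Affected and unaffected sets are re-placed independently within each
replicate (no biological coupling between the groups is modelled). All
p-values use the add-one estimator (1 + #more-extreme)/(n + 1), which is
never zero and is slightly conservative. The joint p counts replicates that
are simultaneously at least as enriched (affected) and at least as depleted
(unaffected) as observed; by construction p_joint ≥ 1/(n+1) and
p_joint ≤ min(marginal p). Null calibration (observed sets drawn from the
same sampler) is checked by KS tests on the marginal p-values over 500
simulated cohorts; those calibration cohorts use 250 CNVs so that the
coincidence count is near-continuous — with few CNVs the count's discrete
atoms dominate the KS distance regardless of sampler correctness.

Intensity tracks are dense per-25-bp-bin scores; peaks are maximal runs of
bins ≥ threshold (default 20, with a sweep mode over 20–40 for robustness
reporting). bedGraph records not aligned to the bin grid are resampled by
per-bin maximum — the conservative direction for peak calling. Chromatin
states are per-200-bp-bin labels from a closed 15-state alphabet; state
coincidence means intersecting ≥ 1 bin whose state is in the tested subset.
The enhancer subset defaults to the two enhancer states (genic enhancers +
enhancers) and is configurable. Per-epigenome and per-tissue-union tests
are reported without multiple-testing correction: tissues overlap and are
highly correlated, so the effective number of tests is not well defined and
all marginal/joint p-values are reported as-is. The noncoding filter
removes CNVs intersecting any coding exon of a coding gene before testing.

## Gene context

Gene "distance" is the bp gap to the gene's **coding span** (0 when
overlapping), because the neighbor window is anchored on the nearest coding
region; ties report all tied genes. Additional neighbors are coding genes
whose coding span lies within 150 kb of the nearest gene's coding region
(gene-to-gene), capped at 1 Mb + 150 kb from the CNV. Reports carry signed
distance and an overlap class (exonic/intronic/left/right) rather than
free-text position labels.

TAD boundary regions are the gaps between consecutive TADs of a profile;
abutting TADs contribute a 1-bp point boundary so strict containment stays
decidable. *Strict* disruption requires an entire boundary region inside
the deletion; *permissive* requires removal of a TAD start or stop site
(the first or last base of a TAD); strict implies permissive by
construction. TAD profiles are kept as raw interval lists, not merged
interval sets, precisely so abutting TADs survive.

## Synthetic cohorts: what they do and do not show

The generator reproduces the statistical structure the analysis relies on:
pedigree-driven autozygosity with exact truth, allele-frequency-driven
genotypes with symmetric allele-flip error (a truly homozygous site is
mis-read as heterozygous at ≈ the configured error rate) and missingness,
independent per-caller detection with Gaussian boundary jitter and
Poisson false calls, peak tracks with controllable coverage, and case CNV
sets with a controllable fraction forced to overlap peaks (placed uniformly
among peak-overlapping placements by rejection). Deletion lengths default
to a lognormal with ~20 kb median and a long right tail, clipped to
2–900 kb, matching the size range of validated biallelic deletions.

Not modelled: linkage disequilibrium among founder haplotypes, crossover
interference, array intensity artefacts, batch effects, population
structure, and caller error correlated between algorithms. Passing tests
therefore demonstrate correctness of the *statistical machinery* under the
stated generative assumptions, not robustness to every real-data pathology.

## Problem sizes used in checks

Calibration targets use 5,000 gene-drop replicates each (the three
percentages move by < 1 point across seeds at that size). Oracle
equivalence uses random panels up to 5,000 markers and random 4-caller call
sets; Fisher equivalence uses 1,000 random tables; null-calibration uses
500 cohorts × 2,000 replicates; the power check uses 100 cohorts × 10,000
replicates on a 100 Mb 2-chromosome toy at 7% peak coverage, where a
planted 0.8 overlap bias in 28 case deletions is detected (joint p < 0.01)
in ≥ 90 of 100 cohorts.

## Known limitations

* The genetic map is piecewise linear and the default synthetic map is
  uniform (1 Mb/cM); real recombination-rate heterogeneity will change
  physical (not genetic) segment lengths.
* Consensus probe counts take the minimum over supporting calls overlapping
  the region; callers reporting probe counts on different scales should be
  harmonized upstream.
* The placement sampler treats starts as integer bp; for mappable intervals
  much shorter than a CNV the feasible-start weighting is exact, but CNVs
  longer than every mappable interval are a hard error by design.
* Vendor-specific chip metrics (console QC, MAPD) are consumed as
  precomputed columns, never recomputed.
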