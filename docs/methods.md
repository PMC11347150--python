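# Methods

This note documents the models, estimators and numerical choices behind
`selexa`, in the spirit of a statistical-methods appendix: what is computed,
under what assumptions, and what a passing test does and does not establish.

## The simulated world

The synthetic-data module states one world and keeps it fixed.

**Doped library.** A reference strand of 105 nt — an 85-nt catalytic region
followed by a 20-nt 3′ primer-binding site — is mutagenized at μ = 0.21 per
position inside the region; a mutated position takes one of the three
alternative bases uniformly. Substitutions only: doped chemical synthesis is
substitution-dominated, and fixed-length molecules keep alignment columns
trivially defined. Defaults: N = 10⁵ molecules and 10⁵ reads per round.
These are desk-scale surrogates — a real selection starts from ~10¹⁴
molecules — chosen so the full pipeline runs in seconds; consequences of the
gap are discussed under *Selection stringency* below.

**Fitness.** A `FitnessModel` plants conserved-base constraints and
Watson–Crick pair constraints (A·T, T·A, G·C, C·G; G·T wobbles are *not*
Watson–Crick here, since in DNA covariation a G·T column pattern is treated
as noncanonical). Fitness is the product over constraints of 1 (satisfied)
or a `mismatch_penalty` (default 0.05) per violation; the reference has
fitness exactly 1. The multiplicative form makes compensatory rescue
expressible: disrupting one partner of a pair costs a factor, restoring the
pair recovers it fully, which is exactly the double-mutant-cycle logic the
covariation module measures.

**Selection.** Per round, each molecule survives independently with
probability `capture × fitness` (capture default 0.5, a free knob — capture
efficiencies per round are never published), then survivors are resampled
with replacement back to N (error-free amplification; PCR bias, chimeras
and indels are out of scope). Implementation detail: molecules are collapsed
to unique sequences once, survival is binomial thinning per unique sequence
and resampling is one multinomial draw — distributionally identical to the
per-molecule description and orders of magnitude faster. All randomness
flows from integer seeds through `numpy` `SeedSequence` spawning; every
stochastic operation is bit-reproducible.

**Selection stringency at desk scale.** The shipped fixture plants the four
pairs 11–47, 12–46, 17–40, 26–30 (1-based) and the conserved blocks 1–10
and 43–79. With all ~45 conserved positions constrained at penalty 0.05, a
doped molecule carries ~9.5 violations on average, the expected number of
round-1 survivors in a 10⁵ pool is below one, and `run_selection` raises its
extinction error — a faithful consequence of compressing a 10¹⁴-molecule
experiment into 10⁵. Structure-recovery experiments therefore plant the pair
constraints only (`aurora_fitness_model(include_conserved=False)`), which is
also what the recovery claim is about; conservation-logo experiments keep
the full constraint set but soften the penalty to 0.5 so the pool survives.
A green recovery test therefore establishes that the MI machinery finds
planted pairs in a surviving, diverse pool — not that a desk-scale
simulation can reproduce the stringency of the real selection.

**Reads.** Sequencing is a multinomial sample of molecules (a census when
the requested depth equals the pool total, so noiseless reads reproduce
molecule frequencies exactly), with layout `5′ tag + molecule` (125 nt for
the fixture), independent per-base substitution errors at a uniform rate,
and a constant Phred-30 quality — quality realism is omitted because nothing
downstream consumes it.

**Plates and curves.** Screen plates draw negative controls from
Normal(μₙ, σₙ), positive controls from Normal(μₚ, σₚ) and each compound well
from Normal(μₙ + (1−inhibition)(μₚ−μₙ), σₚ). Saturation curves evaluate
`V0 = Vmax·Sⁿ/(Kⁿ + Sⁿ)` plus optional Gaussian noise. Neither models plate
spatial artifacts, drift, or heteroscedastic detector noise; green screen
tests certify the statistics, not robustness to those artifacts.

## Preprocessing

Primer matching is Hamming distance at fixed offsets (default tolerance 1
mismatch per primer), testing the read and its reverse complement; the
clipped insert is kept only when its length equals the design's strand
length (105 nt for the fixture). This is deliberately not a general
adapter trimmer: amplicon reads have a fixed layout, and the simplification
makes the filter exactly auditable (kept + rejected = input, with per-reason
tallies). Reads containing N are rejected (`ambiguous_base`) rather than
imputed. Count tables are written as TSV with a `# round=k seed=s` header
and deterministic ordering (count descending, then lexicographic).

## Library statistics

Mutational distances are Hamming distances over the doped region only — the
primer site is fixed by design and would only dilute the spectrum. Read
weighting is the default and one-per-unique weighting is available, because
published distance histograms rarely state which was used. Logo information
content is `2 + Σ_b f_b log₂ f_b` bits against the uniform DNA background,
with an additive pseudocount (default 0.5 per cell) instead of a
small-sample correction. Enrichment is the difference of log₂ frequencies
with the same pseudocount. Shell coverage is closed-form:
`q_r = (μ/3)^r (1−μ)^{L−r}`, shell size `C(L,r)·3^r`, and
`p_present = 1−(1−q_r)^N` computed via `log1p`/`expm1` to keep precision
when `q_r·N` is tiny; at μ = 0.21, L = 85 and study-scale N every shell out
to r ≈ 4 is saturated, which is the design rationale for a 21% doping rate.

## Covariation

MI is estimated in bits from read-weighted joint base frequencies with an
additive pseudocount of 0.5 per joint cell; marginals are row/column sums of
the smoothed joint so the estimate is internally consistent. Sequence
weights are capped at the 99th-percentile count, preventing a single jackpot
clone from dominating the columns. The average-product correction
(`score = MI_ij − MI_i·MI_·j / MI_mean`) removes the shared-background
component before thresholding, as is standard in covariation/contact
analysis. The whole L×L computation is one one-hot Gram product, so 10⁵
reads over 85 columns take seconds.

Pair calling is greedy: candidates with score above a threshold (default:
mean + 5 SD of the off-diagonal score distribution — a plug-in outlier rule,
exposed as a flag because published MI significance criteria vary) are
visited in deterministic order (score descending, then position), accepted
when position-disjoint and separated by at least 4 nt (admitting a 3-nt
loop), and classified `pair` when the Watson–Crick fraction is ≥ 0.9, else
`correlated`. Greedy rather than optimal matching: deterministic,
explainable, and exact at the scale of a hairpin.

The test suite validates the MI engine against a literal 16-cell double-loop
oracle on random instances, and validates calling on a column-permutation
null (independently shuffling each alignment column, which preserves
marginals and destroys joint structure). A count-shuffle null — permuting
read counts across unique sequences — does *not* silence the scores in this
simulator and is not used: selection writes most of its signal into *which*
sequences survive, not into their counts.

Double-mutant-cycle coupling is `log₁₀[(a11·a00)/(a10·a01)]` with activities
floored (default 10⁻³) before the logarithm; the flooring is flagged in the
result. Zero means multiplicative (independent) effects; strongly positive
means compensatory rescue.

## Kinetics

Initial rates: ordinary least squares through the time points with fraction
reacted ≤ 0.15 (the "linear phase"; the cutoff is a flag, since published
descriptions rarely quantify it), slope × [E] giving V0 in μM·min⁻¹.
Saturation fits: `scipy.optimize.curve_fit` with positivity bounds,
initialized at vmax = max observed rate, k_half = S nearest half of it,
n = 1. Unweighted residuals match the conventional Prism-style fit. The
Hill model is provided because substrate titrations of this deoxyribozyme
family show mild cooperativity; the hyperbolic model is the default, and
whether a published "half-maximal" constant is a Km or a Hill K is left to
the caller — both fits report `k_half`. Noiseless round trips recover
parameters to better than 4 significant digits across a (vmax, k_half) log
grid.

## Screening statistics

Z-factor uses sample SDs (n−1); it is affine-invariant and may be negative.
Percent activity anchors the negative-control mean at 0% and positive at
100%. Hit calling is quadrant-based with explicit thresholds (defaults:
screen ≤ 50% and counterscreen ≥ 80% → `target_inhibitor`; both ≤ 50% →
`enzyme_false_positive`), since published scatter-plot classifications print
no cutoffs; compounds lacking a counterscreen value are flagged
`unresolved`, never dropped. The limit of detection is the lowest tested
concentration opening a run in which every higher concentration also exceeds
mean(background) + 3 SD — the run requirement guards against isolated noise
excursions that the bare minimal-concentration definition would accept. IC50
is a 4-parameter logistic fit on log₁₀ concentration (bottom ≥ 0,
top ≤ 120%), reported on the linear scale. Brightness is ε × Φ.

## Known limitations

- No indels, chimeras, PCR bias, quality modeling or paired-end merging;
  inputs are merged/single fixed-layout reads.
- Desk-scale populations understate selection stringency (see above);
  absolute enrichment factors are not comparable to a real experiment.
- The MI threshold is a plug-in outlier rule, not a calibrated significance
  test; with few informative columns the 5-SD rule is conservative.
- The greedy pair caller does not search pseudoknots and resolves conflicts
  locally; it is not a folding algorithm.
- The shipped fixture's reference sequence is a synthetic stand-in with the
  planted pairs made complementary; only its layout parameters mirror the
  published design.
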