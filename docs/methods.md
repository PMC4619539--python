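# Methods

## Scope and data model

The pipeline starts from *segmented* copy-number profiles: per-sample
tables of (chromosome, start, end, mean log2 ratio). Probe-level array
processing, normalization and segmentation are upstream concerns and out of
scope; the segment table is the contract. All coordinates are 1-based and
fully inclusive, in memory and on disk; interval length is
`end − start + 1` (so chr1:156826196–157106439 measures 280,244 bp). BED
input is converted from 0-based half-open on read; GFF3 is native.
Chromosome names normalize to `chrN`. Within one sample and chromosome,
overlapping segments are a hard error, as are duplicated qPCR wells —
malformed input is rejected, never silently repaired.

## Minimal common regions

Amplified intervals per sample are segments classified AMPLIFICATION
(fold change 2^log2 > 1.75 by default), with abutting intervals merged
(`merge_gap`, default 0: only directly adjacent segments merge). GAIN
segments do not contribute support by default — recurrent *amplification*
is the target — but `include_gain=True` relaxes this, and `target_state`
can be repointed at deletions.

The support profile is a sweep line over interval endpoints: between
consecutive breakpoints the set of covering samples is constant, and a
sample counts once per position no matter how many of its intervals
overlap. Within each maximal run of support ≥ `min_support` (default 3),
hotspots are the plateaus of *locally maximal* depth, with adjacent
equal-depth plateaus merged. The rationale: a deeper sub-region is shared
by more samples, and the region shared by the largest supporting set is
exactly the minimal common overlap of that set. Hotspots longer than
`max_length` (default 2.5 Mb) are discarded; the length constraint applies
to the final hotspot, not to the contributing amplicons.

Two subtleties are worth recording. First, `support` is the plateau depth;
`supporting_samples` is the intersection of the covering sets across the
plateau's elementary intervals. They coincide except in the measure-zero
case where two equal-depth plateaus with different covering sets are
merged; the containment invariant (hotspot ⊆ every supporting sample's
amplified region) is asserted on `supporting_samples` and holds exactly.
Second, correctness is established not by inspection but by equivalence
with a brute-force oracle that counts distinct samples at every base of a
toy chromosome and re-derives the plateaus per base; the test suite runs
this equivalence on over a hundred random cohorts.

## qPCR quantification

Replicate aggregation is mean-within-experiment, then mean-across-
experiments, matching a design of independent experiments each containing
internal replicates; experiments whose internal-replicate SD exceeds
`qc_sd_cutoff` (default 0.5 cycles) are flagged, not dropped. Standard
curves regress mean Ct on log10(dilution); efficiency is E = 10^(−1/slope),
required to exceed 1 (negative slope) and flagged above 2.1 rather than
rejected, since super-efficient assays occur in practice. The
efficiency-corrected ratio follows the Pfaffl form; ΔΔCt is exposed
separately and is exactly the E = 2 special case (property-tested).

Two independent experiments can be combined in two inequivalent ways:
compute one ratio from the fully aggregated Cts (default,
`mode="ratio_of_means"`), or one ratio per experiment and then average
(`mode="mean_of_ratios"`). The default was chosen because it uses every
well symmetrically in a single estimator; both modes agree exactly in the
noise-free limit, and the option keeps the alternative reading available
for sensitivity analysis.

Classification boundaries (0.5 / 0.75 / 1.25 / 1.75) assign boundary
values to the non-diploid state — deletions and gain include their outer
bound; amplification is strictly above 1.75. Boundaries are measure-zero
for continuous ratios, so the choice matters only for constructed inputs,
but it is fixed and tested. Segment log2 ratios classify through the same
bins via 2^log2 with independently configurable thresholds.

## Association and survival

Mann–Whitney U contrasts a covariate (Breslow thickness, mm) between
copy-state groups: exact null distribution when both groups have ≤ 8
observations and no ties, normal approximation with tie correction
otherwise; two-sided by default. Empty groups yield flagged,
not-computable results instead of exceptions, since sparse states are
routine in small cohorts.

Direction concordance calls each platform's sign with a dead zone:
|log2| ≤ ε counts as "no change", and zero matches zero only. The strict
default ε = 0 reproduces a literal sign comparison; setting
ε = log2(1.25) treats within-diploid-band wobble as no change, which is
the convention the acceptance script reports.

Kaplan–Meier estimation uses the product-limit estimator (via lifelines).
The log-rank statistic and the hazard ratio are computed from the pooled
risk-set table: at each distinct event time, observed and expected events
per group under the hypergeometric model, with the standard tie-corrected
variance; χ² = (O₁ − E₁)²/V on 1 df. The HR is the Mantel–Haenszel ratio
(O₁/E₁)/(O₂/E₂) with CI exp(ln HR ± 1.96·√(1/E₁ + 1/E₂)) — the estimator
commonly printed by graphing statistics packages, which makes published
values directly comparable; a one-covariate Cox fit is available as a
sensitivity option. The log-rank χ² is cross-checked against lifelines'
independent implementation in the tests. A group with zero observed or
expected events flags the HR not-computable. The default survival grouping
contrasts AMPLIFICATION against DIPLOID, excluding gains, because the
biological question is whether full amplification marks outcome.

## The synthetic cohort generator

The generator emulates four features of the motivating data and is
explicit about what it does not model.

*Recurrent amplicons.* Each planted hotspot assigns states by exact quota
(round(fraction × n) after a seeded shuffle) so that small cohorts are
deterministic; Bernoulli sampling is a flag for power studies. Amplified
samples carry an amplicon containing the planted interval, extended per
side by 0–20 whole probe spacings; per side, the minimum extension over
the amplified set is forced to zero, so the minimal common overlap equals
the planted interval exactly and boundary recovery can be asserted to
within one probe spacing (in practice: exactly). Default probe spacing is
50 kb, the approximate resolution of an 8×60K CGH array.

*Passengers.* Poisson(5.7) amplicons per genome with log-normal lengths
(log-mean ln 350 kb, log-sd 0.8, mean ≈ 0.47 Mb), matching the scale
reported for primary melanoma genomes. Passengers are placed uniformly
(chromosome chosen proportionally to length) but kept clear of planted
loci and of each other within a sample, so planted truth stays
unambiguous — a deliberate simplification; real passengers can of course
collide with driver loci.

*Log2 ratios.* Drawn uniformly on the log2 scale inside the fold-change
band of the assigned state, shrunk by a guard margin (default 0.05 in
ratio units) at every boundary, so noise-free classification is exact by
construction. Diploid background segments wobble inside the diploid band
rather than sitting at 0.

*Thickness and survival.* Log-normal thickness (log-sd 0.35) with additive
log-shifts per state; defaults (base median 2.3 mm, gain ≈ 3.0 mm,
amplified ≈ 4.7 mm) reproduce the *ordering* of published group medians,
which is all the source material constrains. Event times are exponential
with hazard baseline_rate × hr_amp^(amplified), administratively censored
at `censor_time` (no competing risks); defaults are baseline 0.01
events/month, hr_amp = 1/0.30 (amplified patients progress earlier, so
that the diploid-over-amplified ratio lands near the published 0.30), and
120-month censoring. Overall survival reuses the same structure at half
the baseline rate (`os_rate_scale = 0.5`) — a pragmatic choice that makes
the OS endpoint exercisable without modeling a second disease process.

*qPCR.* Ct = Ct_base − log_E(quantity) + N(0, ct_sd), with quantity the
true copy ratio (samples), 1 (calibrator) or the dilution factor (standard
curve wells); default design is 2 experiments × 3 internal replicates,
efficiencies 1.95/2.0, ct_sd 0.15 cycles, and a four-point 10-fold
dilution series. With ct_sd = 0 the full calling chain inverts the
generator to machine precision — the pipeline-identity tests rely on this.

All randomness fans out from a single seed through
`numpy.random.SeedSequence.spawn`, so identical configurations produce
byte-identical output files.

What passing these tests does *not* show: the generator has no tumor
purity or ploidy, no clonal heterogeneity, no probe-level noise, no
spatially correlated segmentation error, and planted states are cleanly
separated from the thresholds. Performance on real cohorts — where
fold-change distributions straddle the 1.75 boundary and segmentation
boundaries blur — is bounded by those idealizations.

## Problem sizes and numerics

The test suite and the acceptance script run at sizes chosen as adequate
for the statistics they check: oracle equivalence on 100+ random 100-kb
cohorts of 10 samples; hazard-ratio calibration on 100 replicate cohorts
of n = 400 with a planted hr of 0.3, asserting ≥ 90% CI coverage;
the headline cohort at n = 64 on a full-length chromosome 1. Ties in the
Mann–Whitney switch the implementation to the tie-corrected normal
approximation; ties in event times use the standard hypergeometric
variance. Degenerate inputs — empty groups, zero-event arms, single-well
aggregates, headers-only tables — return flagged results or typed errors,
as specified per function.

## Known limitations

Hotspot detection reports recurrence, not significance: there is no
background model of passenger recurrence (GISTIC-style inference is out of
scope), so hotspot support should be read descriptively. The qPCR caller
assumes a single reference gene and a diploid calibrator; multi-reference
normalization and purity correction are not implemented. Survival analysis
is two-group and univariable by design.
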