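# Methods

This note records the models, parameter choices and numerical decisions
behind `panelval`, and what the synthetic material does and does not
establish about real sequencing data.

## Variant model and truth matching

A variant is a normalized `(chrom, pos, ref, alt)` substitution,
insertion or deletion with its allele fraction (VAF) and read support.
Normalization is the standard parsimony/left-alignment procedure:
shared trailing bases are trimmed (re-anchoring on the preceding
reference base whenever an allele would empty), then shared leading
bases are trimmed; indels therefore migrate to the left edge of
homopolymer runs. SNVs are returned unchanged and multi-nucleotide
substitutions are kept as single indel-class records rather than
decomposed, because clinically a duplication or MNV is reported as one
event. Truth matching is exact on the normalized key — no fuzzy indel
window — on the grounds that missed indels in panel validations are
explained by masking and coverage, not representation distance; both
calls and truth records pass through the same normalizer first.

Two footprints matter. The capture design pads every exon by 5 bp; the
reporting rule only emits variants within ±2 bp of the coding sequence.
Calls are therefore restricted to the ±2 bp reportable mask while truth
records are kept over the full ±5 bp capture footprint, so a truth
indel anchored 3–5 bp into the intron counts as a structural false
negative: the assay captures it but the pipeline never reports it.
This choice (rather than masking truth records too) is deliberate — it
is the only reading under which intronic-fringe indels appear in the
sensitivity denominator, which is how a validation would experience
them.

Call filtering keeps a variant iff VAF ≥ 5% **and** alt reads ≥ 10
(both configurable). Filtering is idempotent and order-preserving.

## Accuracy statistics

Sensitivity, specificity, PPV and NPV are binomial proportions.
Intervals are Wilson by default (better behaved at proportions of 0 or
1 and small denominators) with Clopper–Pearson as the alternative; both
delegate to `statsmodels.proportion_confint` and are cross-checked in
the tests against an independent closed-form Wilson implementation and
an exact interval obtained by root-finding on binomial tail
probabilities. True-negative material exists only for SNV sites (a
wild-type position in one blend where another blend is mutant), so
indel specificity is reported as unknown rather than zero-denominator.

VAF correlations use Pearson r on raw fractions; the 95% interval is
computed on the r scale via the Fisher z transform (SE `1/√(n−3)`) and
the endpoints squared, with the lower endpoint floored at 0 when the
r-interval straddles zero. Degenerate cases (n = 3, |r| = 1, zero
variance) collapse or raise explicitly. Repeatability correlates
blends within a run over shared background variants; intermediate
precision correlates the same blend across runs and also pools all
between-run pairs into an overall estimate.

The limit of detection stratifies cancer-variant detection by expected
VAF (default strata 4–5%, 5–10%, ≥10%) and reports the lowest stratum
with 100% detection; with no fully detected stratum the LoD is "not
reached". VAF spectra are binned at 20% and 50% with lower-closed bins
(the boundary belongs to the upper bin). Reported percentages use
half-up rounding at the report's precision (integers for bins, one
decimal elsewhere).

## Region QC

A region underperforms when `log2(d) < mean(log2 d) − 2·SD(log2 d)`.
The SD is the sample SD (n−1): cohorts here are small (a handful of
blends and FFPE samples), where the distinction is material. The rule
is applied by default to per-region depths averaged over the cohort's
samples; a per-sample mode flags the union of per-sample failures
instead (both readings of "assessed across the cohort" are supported).
Zero-depth regions fail unconditionally and are excluded from the
moments so the log is always defined. Under a pure log-normal depth
model the rule flags the one-sided 2-SD tail, ≈2.3% of regions; with
GC suppression active the flagged set concentrates almost entirely in
the top GC decile.

## Copy number

Depths are GC-normalized by dividing by the median depth of the
region's GC bin (width 0.05, linearly interpolated between occupied bin
centres, flat beyond the outermost bins) and rescaling the cohort
median to 1. Binned medians were chosen over LOESS because they are
robust and tuning-free at ~900 regions. The tumour/control ratio is
labelled deletion below 0.65 and amplification above 2.4 (config
defaults, not constants); zero-control regions are uncallable, never
labelled. Genes take a label when more than half their callable
regions agree; chromosome/arm losses are read off the gene summary of
the genes on that chromosome — no segmentation is attempted at panel
scale. Ratios are recentred by the cohort median only; no per-pair
purity recentring is applied.

For an event of copy number CN at purity p the expected ratio is
`(p·CN + 2(1−p))/2`, so CN ∈ {0, 1} → deletion and CN ∈ {8, 30} →
amplification are recovered at full purity, a 30-copy amplification
survives dilution down to ~30% purity (ratio 6.2), and a one-copy arm
loss at 80% purity sits at 0.6, just under the deletion threshold.
CN = 4 at full purity lands at ratio 2.0, below the 2.4 amplification
threshold: it is intentionally not asserted anywhere, and a validation
using these thresholds should expect 4-copy gains to read as neutral.

## Synthetic material

The generators emulate the study design the pipeline is meant to
validate, and their defaults are those design conditions: a 901-region
/ 78-gene / ~311 kb panel; four cell blends sharing 163 background SNVs
and 34 background indels (VAFs from a Beta mixture of low-fraction,
heterozygous and near-homozygous components) plus 61 cancer SNVs and 17
cancer indels unique to single blends at expected VAFs of 5–30%; 87
true-negative sites sampled from the 183 cross-blend cancer-SNV
positions; 15 FFPE/FF pairs; cohort mean depths of 700 (blends), 785
(FFPE) and 977 (FF).

Two deliberate defaults differ from a fully faithful re-creation.
First, cancer expected VAFs start at 5% so that the default run is
self-consistent with the pipeline's own 5% floor; the `reference`
preset lowers the floor to 4% and places 33 SNVs in the 4–5% stratum,
where binomial sampling at depth ~700 gives each roughly an 8–50%
chance of surviving the filters — sub-threshold dropout is then
expected by construction, and the LoD analysis reports it. Second, 10%
of truth indels are anchored 4 bp into the intron to exercise the
reportable-mask miss mode described above.

Region depths are log-normal (σ = 0.25, mean-preserving) multiplied by
a GC suppression factor that declines linearly from 1 at GC 0.72 to a
floor of 0.02 at GC 0.85 — a stylised version of hybridization loss in
GC-rich targets. Observed variant support is Binomial(region depth,
true VAF); a call is emitted only if it passes the filters. For every
truth record the generator also computes its exact filter-survival
probability `P(Bin(d, v) ≥ max(⌈0.05·d⌉, 10))` (zero for records
outside the reportable mask), which gives the pipeline a
Poisson-binomial envelope to be tested against.

The paired cohort draws, per pair, 433 shared variants (FFPE VAF =
FF VAF + N(0, 0.02)), 371 FF-only variants with VAF strata sampled at
(78.1%, 17.6%, 4.3%) across (<5%, 5–10%, ≥10%), and 72 FFPE-only
artefact calls at (50.8%, 33.2%, 16.0%), 80% of them C>T/G>A to mimic
deamination. A deterministic `exact_counts_table()` fixture carries the
same discordance profile as fixed counts (13,146-row union) for
arithmetic checks. The CNV cohort shares region capture efficiency
between tumour and control (residual per-sample σ = 0.05), which is the
premise of ratio-based calling; depth-ratio noise would otherwise be
dominated by independent capture variation that real paired libraries
do not exhibit.

All generators draw from independent, seed-derived streams, so outputs
are byte-identical under a fixed seed and adding one generator call
does not perturb the others.

### What the synthetic runs do not show

The generators operate at the region/variant level: there are no reads,
no alignment or duplicate-marking artefacts, no mappability structure,
no sequence-context error model beyond the C>T artefact fraction, and
no tumour heterogeneity beyond a single purity scalar. Passing tests
therefore demonstrate that the analysis — filtering, masking, matching,
statistics, normalization, thresholds — behaves correctly under its own
stated model, not that any particular wet-lab assay meets these
numbers. Cohort-level quantities that depend on real specimens
(absolute duplicate rates, insert sizes, clinical concordance rates)
are emulated only as orderings or bands, never as point values.

## Problem sizes

The default test suite runs the full design scale (901 regions) for the
generators and statistics, a scaled-down 80-region configuration for
end-to-end orchestration, 10,000 regions for the underperformance tail
property, 200 random (x, n) pairs for CI oracle equivalence, 500 random
indels for normalizer oracle equivalence, and 1,000 replicates for CI
coverage. The acceptance script runs one full design-scale pipeline per
invocation; everything completes in seconds on one CPU.

## Known limitations

* Exact-key matching will count a caller's unnormalized or decomposed
  representations as misses unless they pass through the same
  normalizer; MNV decomposition is out of scope.
* The GC trend estimator needs ≥20 regions and occupied bins across the
  GC range; very small panels should disable suppression instead.
* Arm-level losses at purity ≲70% approach the 0.65 threshold and
  become majority-vote coin flips per gene; the gene median ratio is
  reported alongside the label for exactly this case.
* The FFPE artefact model asserts only the existence and VAF profile of
  artefacts, not their sequence spectrum beyond the C>T fraction.
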