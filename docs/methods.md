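# Methods

## The assay model

Each well of the bioassay yields a luminescence time series; the agonist
(8-Br-cGMP) is injected at a known time on the same clock. Two metrics
summarise a well:

* **AUC** — trapezoid integral of the signal over
  `[injection + offset, injection + offset + length]` with defaults
  offset = 14 s and length = 279 s. Window endpoints falling between
  samples are linearly interpolated, making the integral bit-reproducible
  on any grid. A window extending beyond the recorded trace is an error
  unless partial coverage is explicitly allowed.
* **Latency** — time from measurement onset (`times[0]`, not the
  injection) to the maximal signal; argmax ties break to the earliest
  time, the conservative (shorter) latency.

Technical replicates must share a time grid and are averaged pointwise;
metrics are computed on the averaged trace, never averaged from per-well
metrics. Per plate, every variant's AUC and latency are divided by the
mean wild-type value of that plate (so the wild type is 1 by
construction and plate-level sensitivity drift cancels). Biological
replicates (independent transfections) are then aggregated as mean and
SD with the n−1 denominator; fewer than three replicates produces a
warning column, not a failure, so small fixtures remain runnable.

**No-response detection.** A well with no agonist response is flagged
when the post-/pre-injection mean-signal ratio falls below a fold-change
threshold (default 1.5; the pre-injection mean is floored at 1e-9 RLU so
a dark baseline cannot divide by zero). A `manual_override` column
reproduces curator revision. Independently, any variant whose normalized
AUC is strictly below 0.02 has its latency forced to 0 with SD 0 — the
peak position of a near-flat trace is noise, not kinetics. The boundary
is strict: exactly 0.02 keeps its latency.

Out of scope by design: injection-artifact correction, baseline
subtraction, well-position effects and kinetic curve fitting.

## Tri-category classification

Control variants (presumed-benign population variants plus
homology-swap controls) calibrate per-parameter z-score bands
`mean_control ± z·SD_control` with z = 2.56 exactly as used in the assay
protocol (not the conventional 2.576); z is config-exposed. A variant
parameter is judged by its interval `[mean − SD, mean + SD]`:

* *outside* — entirely below or above the band;
* *inside* — strictly within the open band;
* *overlap* — anything touching a band edge (a variant that "hits the
  threshold" is never inside or outside).

Any parameter outside ⇒ **abnormal**; both inside ⇒ **normal**;
otherwise **uncertain**. One parameter outside with the other
overlapping is abnormal (the abnormal clause is a disjunction). A
non-functional variant's forced latency of 0 gives the degenerate
interval [0, 0], which lies below any positive band and therefore makes
the abnormal call structural.

For 10,000 point-interval variants drawn from the control distribution,
the non-normal fraction matches the two-parameter nominal level implied
by z = 2.56 (≈ 2.1%) within a 99% binomial band; the acceptance suite
checks this.

## Functional score

Within a cohort (by default all assayed variants excluding dedicated
control constructs; a config flag includes them):

* `AUCₙ = (AUC − AUC_min) / (AUC_max − AUC_min)`
* `Lₙ = (L − L_min)/(1 − L_min)` for `L_min ≤ L ≤ 1` and
  `Lₙ = (L − 1)/(L_max − 1)` for `1 < L ≤ L_max`
* `FC = 0.5·AUCₙ + 0.5·Lₙ` (equal weights).

The latency map is deliberately implemented exactly as specified and is
therefore **discontinuous at L = 1**: a latency marginally above 1 maps
near 0 while L = 1 maps to 1. Users correlating FC with predictors
should be aware of this; cohorts with all latencies at or below 1 are
unaffected. Degenerate cohorts (no AUC spread, or values above 1 with
`L_max ≤ 1`) raise an error rather than dividing by zero.

## OddsPath calibration

With P₁ the prior proportion of pathogenic variants among all controls
and P₂ the proportion among variants sharing a readout,
`OddsPath = [P₂/(1−P₂)] / [P₁/(1−P₁)]`. An empty readout cell receives a
single opposite-class pseudo-count (policy `add_one_opposite_if_empty`,
config-exposed); with the validation design of 30 pathogenic-direction
and 20 benign-direction controls, 28 pathogenic and 0 benign variants in
the abnormal readout give P₂ = 28/29 and OddsPath 18.7, and a normal
readout of 2 pathogenic-labelled plus 19 benign variants gives 0.07.
The normal-readout composition (19 + 2 with the full 30:20 prior) is the
unique simple counting convention consistent with both ratios and is
config-driven, not hard-coded.

Strength bands follow the published OddsPath calibration (pathogenic
≥ 2.1 supporting, ≥ 4.3 moderate, ≥ 18.7 strong, ≥ 350 very strong;
benign mirrored at reciprocals). Band comparisons use a 0.5% relative
tolerance so a ratio is judged at the precision at which such ratios are
reported (18.67, printed 18.7, earns the ≥ 18.7 band). The benign
direction carries a conservative cap (default: supporting) — a
homomeric surrogate assay should not single-handedly drive a benign
classification — so 0.07 yields BS3_supporting despite sitting in the
moderate band; the cap is config-exposed.

**Maximum credible allele frequency** (the BS1 gate): for a recessive
disease, `AF_max = allelic_het · √(prevalence · genetic_het /
penetrance)`; dominant, `prevalence · genetic_het · allelic_het /
(2 · penetrance)`. The default disease model (prevalence 1/4000,
genetic heterogeneity 0.08, allelic heterogeneity 0.63, penetrance 0.9)
gives 0.00297.

## ACMG/AMP engine

Evidence items carry an explicit strength so strength-modified criteria
count in the tier of their applied strength. Gates (all config):
BA1 at grpmax filtering AF > 5%; BS1 at > 0.00297 (BA1 absent); BS2 at
> 2 population homozygotes; PM2 at supporting strength when the variant
is absent from population data or rarer than 0.0022% (PM2's strength and
rarity bound are modern-practice defaults, config-exposed); PM3 below a
PopMax AF of 0.0022%, at moderate strength with a documented in-trans LP
allele and at supporting strength on the frequency gate alone (an
optional strict mode requires the trans observation); PP3 at the REVEL
band strength (0.644/0.773/0.932 for supporting/moderate/strong) or at
supporting from SpliceAI ≥ 0.2, never stacked — one item at the maximum
triggered strength; BP4 only when SpliceAI ≤ 0.1 **and** REVEL ≤ 0.29.
PP5/BP6 are not implemented. PS3/BS3 apply at the OddsPath-calibrated
strengths only to variants with definitive readouts outside the CLZ
assembly domain, where a homomeric surrogate assay is uninformative;
incomplete-missplicing minigene results contribute no evidence.

The combiner collapses duplicate criteria to maximum strength, counts
items per direction and tier, and applies the standard five-tier
combining table; simultaneous satisfaction of pathogenic and benign
combinations returns VUS (conflict rule), and BA1 alone is stand-alone
benign. The table is verified against a literal rule-table oracle over
every evidence multiset of size ≤ 6. Initial (no functional data) and
final classifications feed a reclassification report with a full 5×5
transition matrix.

## Predictor concordance

Spearman rho uses average ranks; the two-sided p-value uses the
t-approximation for n > 9 and exact permutation enumeration for n ≤ 9.
Predictor scores band into B-like (< lb_max), P-like (> lp_min) and
uncertain calls. The ROC threshold for unbanded predictors scans
midpoints between consecutive distinct scores and returns the Youden-J
optimum (ties to the lower threshold), so separable cohorts get a cut
strictly between the class ranges; the ROC area is cross-checked against
exhaustive Mann–Whitney pair counting in the tests. Concordance tables
exclude functionally uncertain and CLZ-domain variants up front and use
complete cases per predictor; correct/discordant/uncertain-call
fractions sum to 1 by construction.

## Synthetic data

The generator emulates what the analysis assumes about real data:
plate-structured long-format traces, per-plate wild-type controls,
biological × technical replicate nesting, and variant-effect archetypes
(wild-type-like, non-functional, reduced amplitude, delayed, combined,
hyperfunctional). The transient is a log-normal-shaped pulse after
injection — only the derived metrics matter, so any shape with a
controllable integral and peak position serves — with multiplicative
log-normal noise at three levels: per construct (`sample_cv`, default
0.08; distinct variants of one archetype have genuinely different
means, which is what spreads a control group wider than any single
variant's replicate scatter), per transfection (`bio_cv`, 0.05) and per
well (`noise_cv`, 0.05), plus a per-plate factor (SD 0.1) that the
normalization cancels by design. Background luminescence defaults to 0
(a dark pre-injection baseline is what the no-response detector keys
on). Defaults mirror the assay protocol: three biological × three
technical replicates, a 20-variant control group (3 population-benign +
17 homology controls), injection at 30 s with a 330-s measurement at 2-s
sampling that covers the standard AUC window.

Archetype allocation uses deterministic largest-remainder rounding plus
a seeded shuffle, so a 50/50 mix of 40 variants is exactly 20/20 under
every seed. Annotation tables draw predictor scores as the archetype's
true severity plus Gaussian noise clipped to each score's documented
range, mostly-rare allele frequencies with a few common alleles to
exercise BA1/BS1/BS2, and a configurable CLZ-flag fraction. Everything
is deterministic given the seed.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: injection artifacts, baseline drift,
well-position effects, photon-counting statistics, non-log-normal
outliers, and any correlation structure between predictors beyond their
common dependence on true severity.

The packaged transcript model and domain map are synthetic stand-ins
(so named in their files and accessors): exon labels, CDS layout,
protein length (686 aa) and the frame-relevant exon lengths (108-nt
coding exon 9, non-triplet exon 10) match the published *CNGA1*
structure, while the remaining exon lengths and domain intervals are
plausible inventions. Real GenBank mRNA records parse through
`TranscriptModel.from_genbank`.

## Validation fixture and problem sizes

`validation_split()` encodes the assay-validation design — 20 controls
(19 with both intervals inside, 1 overlapping) and 30 likely-pathogenic
variants (23 non-responders, 4 reduced-AUC, 1 reduced-AUC with slow
latency, 1 normal-appearing, 1 threshold-hitting) — as normalized
mean ± SD values against fixed bands, giving 95.0% normal controls and
93.3% abnormal LP variants by direct categorization.

Test problem sizes are chosen for tight statistical checks at
interactive runtimes: 100-trace metric oracles, 10,000-variant coverage
simulation, 8–10 biological replicates for amplitude-ratio recovery
(within 3 standard errors at ratios 0, 0.25, 0.5, 1.0), and full
enumeration of ≤ 6-item evidence multisets and ≤ 20-count OddsPath
tables.

## Known limitations

* The assay is homomeric (CNGA1 alone, and the wild-type reference is a
  CNGA3 channel); CLZ-domain readouts are structurally unreliable and
  are excluded from evidence application and concordance, not fixed.
* The latency min–max map's discontinuity at L = 1 is reproduced as
  specified, not smoothed.
* Initial classifications in practice involve curator judgement; the
  engine exposes explicit evidence items and per-variant overrides
  rather than attempting to model manual steps.
* The tri-category rule treats the mean ± SD interval as the unit of
  evidence; it is not a formal hypothesis test and inherits the
  replicate count through the SD only.
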