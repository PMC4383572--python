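# Methods

This note documents the models, defaults and design choices behind
`estroscreen`, in the order the pipeline runs them.

## Study model and synthetic data

The screen targets a multi-treatment uterine time-course design: an
ovariectomized-rodent study with vehicle plus several estrogenic
treatments, expression profiled 2 h and 24 h after dosing, processed in
batches that each contain vehicle controls, and a parallel set of
animal-level bioassay endpoints at 24 h and 72 h.

The generator simulates log₂-scale expression as

```
value(probe, sample) = baseline(probe)
                     + template(archetype; class, time) · effect
                     + batch_shift(probe, batch)
                     + ε,       ε ~ N(0, noise_sd²)
```

with per-probe baselines `N(8, 2²)` (typical log-intensity scale),
i.i.d. Gaussian noise (`noise_sd = 0.25` by default; within-group
variability of the real arrays is not published, so this is an exposed
free parameter) and an additive per-batch, per-probe shift
(`batch_shift_sd = 0.3`). Four replicates per treatment × time cell are
assigned round-robin to two batches, mirroring the group sizes (3–8) of
the real studies.

### Response archetypes

Seven archetypes span the response shapes the screen exploits, expressed
as mean log₂ deviation from vehicle per (treatment class, time) cell.
The intermediate class is always the arithmetic midpoint of the short-
and long-acting cells; vehicle cells are 0.

| archetype | short 2 h | long 2 h | short 24 h | long 24 h |
|---|---|---|---|---|
| transient_up / _down | ±1.0 | ±1.0 | 0 | 0 |
| sustained_up / _down | ±0.7 | ±0.7 | 0 | ±1.0 |
| late_up/_down_long_only | 0 | 0 | 0 | ±1.3 |
| long_selective_up | 0 | +1.5 | 0 | +0.5 |

Only two amplitudes are semantically pinned (unit transient 2-h response;
unit sustained long-acting 24-h response). The remaining amplitudes were
chosen once to *decorrelate* the archetypes: the maximum pairwise |r|
between archetype profiles over the class × time cells is 0.58, safely
below the pattern-merging threshold, so correlation-seeded extraction can
in principle separate all seven. `long_selective_up` is modeled as
selective for the long-acting class at both timepoints (strong early,
weaker late); this keeps it distinguishable from `late_up_long_only`,
which is the identical *shape* if both respond only at 24 h (correlation
is scale-invariant).

### Test compounds and phenotypes

A test compound of class *c* follows the archetype templates' class-*c*
column scaled by `potency`, with every 24-h component additionally scaled
by `persistence ∈ [0, 1]`; `non_estrogenic` zeroes all templates. Setting
`persistence = 1, potency = 1` reproduces the matching reference arm's
generative distribution.

Phenotypes are drawn per endpoint around class-specific means (defaults
below), additive Gaussian noise for measured quantities and multiplicative
log-normal noise for fold-change endpoints (strictly positive,
right-skewed); percentages are clipped to [0, 100]. The defaults encode
the screen's qualitative scheme — long-acting compounds drive strong 72-h
growth with no apoptosis; short-acting ones a moderate 24-h proliferative
response, attenuated growth and elevated TUNEL:

| endpoint | unit | vehicle | short | long | noise |
|---|---|---|---|---|---|
| weight_24h | mg | 25 | 32 | 45 | 3.5 |
| weight_72h | mg | 25 | 42 | 105 | 8 |
| edu_pct_24h | % | 7 | 40 | 65 | 3 |
| tunel_pct_72h | % | 1 | 7 | 0.5 | 0.6 |
| leh_72h | µm | 10 | 16 | 35 | 2.5 |
| birc1a_fold_72h | fold | 1 | 2 | 8 | 0.25 (log) |
| ltf_fold_72h | fold | 1 | 5 | 50 | 0.30 (log) |

Six animals per group by default (the real studies use 3–10).

**What the generator does not emulate:** probe-level platform artifacts
(dye effects, spatial gradients, feature extraction), correlated noise
between probes beyond the planted archetypes, dose–response structure,
missing values, or outlier animals. Passing tests therefore demonstrate
that the pipeline's logic is correct under its stated statistical
assumptions, not that the thresholds transfer unchanged to any particular
real platform.

## Preprocessing

Batch correction subtracts, per probe and batch, the mean of that batch's
vehicle samples. Every supported design has vehicle controls in every
batch; the correction removes any additive per-batch offset exactly,
preserves treatment-vs-vehicle contrasts, and is idempotent. It is the
package's declared stand-in where a published batch-correction recipe is
unavailable, and is deliberately the simplest method consistent with the
additive batch model above.

Count-style data (digital-count platforms) are normalized by the
housekeeping-probe convention: each sample is scaled so its geometric mean
over the housekeeping probes matches the global geometric mean. Relative
expression is invariant to per-sample rescaling (the global target itself
moves by a single overall constant, which is immaterial after the log₂
transform). Missing values are rejected at load; no imputation policy is
offered.

## Pattern extraction

Per probe, over treatment × time groups (batches must be corrected first):

* `SNR = (max group mean − min group mean) / pooled within-group SD`,
  with 0 for a flat profile and a finite cap (10⁶) when the pooled SD is
  exactly 0 but means differ;
* `magnitude = max over non-vehicle groups of |group mean − vehicle mean|`,
  computed within each timepoint.

Probes with `SNR ≥ 3` and `magnitude ≥ 0.585` (1.5-fold) are eligible.
Patterns grow greedily: the unassigned probe with the largest unassigned
correlation neighborhood (r ≥ `r_min`; ties broken toward the
lexicographically smallest probe id) seeds a pattern; its neighborhood
becomes the membership, the profile is the member mean, and remaining
unassigned probes correlating ≥ `r_min` with the profile are absorbed.
The loop stops when the best neighborhood is smaller than `min_cluster`
(10); profiles are re-fitted once at the end (no convergence iteration —
keeps the algorithm deterministic and O(n²)). Patterns are labeled with
the archetype whose template best correlates (r ≥ 0.8) with their
class × time means, else `unclassified`.

`r_min` defaults to **0.75**. This was calibrated once against
planted-archetype recovery at the generator's defaults: sampling noise at
n = 32 samples attenuates same-archetype correlations to ~0.64–0.79 while
pushing cross-archetype correlations (template r up to 0.58) over a 0.70
threshold often enough to bridge patterns (~91–95% recovery); at 0.75
recovery is ≥ 97% and the noiseless design is recovered exactly. The
threshold is a config knob (`PatternParams`), as are all filter values.

## Panel derivation

For a panel spec (timepoint, contrast sides A/B, k = 50, α = 0.05):

1. candidates = members of patterns whose archetype labels can carry the
   contrast (2-h panel: transient + sustained; 24-h panel: sustained +
   late + long-selective); without patterns, all probes;
2. probe-wise one-way ANOVA across the contrast classes,
   Benjamini–Hochberg adjusted, keep adj-p < α;
3. PCA of the row-standardized candidate submatrix (correlation scale, so
   high-variance probes don't dominate); select the component whose
   sample scores correlate most with the contrast indicator; rank
   candidates by |loading| (ties by probe id);
4. take the top k greedily, skipping probes correlating |r| > 0.95 with an
   already-selected probe.

The panel stores per-probe directions (sign of mean B − mean A), the two
contrast centroids as mean log₂ deviations from vehicle, and the unit
discriminant axis from centroid A to B. Loadings from a single component
are used; pre-filtering by fold change is implicitly provided by the
pattern-magnitude filter upstream.

Validation clusters the contrast samples on the panel probes
(average linkage, 1 − Pearson r distance, each probe centered across the
selected samples), cuts the tree into the two contrast sides and reports
the adjusted Rand index. Per-probe centering matters: after
vehicle-anchored batch correction, vehicle samples carry no shared signal
on panel probes, and without centering their mutual correlation is ~0, so
single vehicle samples split off at the 2-cut even for a perfect panel.

For the panel-purity property (50 selected probes ⊂ 150 planted among
5,000 at effect = 2 × noise SD), the study condition is 20 samples per
group. With thousands of null probes, a few are by chance both strongly
significant *and* low-variance, and on correlation-scale loadings such
nulls rank alongside weak planted probes; 20 samples per group pins
per-probe variances well enough that this essentially never happens.

## Endpoint statistics and ordinal calls

Tukey's HSD uses the studentized-range distribution on the pooled ANOVA
MSE (Tukey–Kramer form for unequal group sizes); Fisher's LSD performs
the unadjusted pairwise t tests on the same MSE. Degenerate inputs
(zero pooled variance) yield p = 1 for equal means and p = 0 otherwise.
Studentized-range probabilities come from scipy's numerical integration;
a Monte-Carlo simulation of the null maximum-statistic serves as an
independent check in the test suite.

An endpoint call compares the treated-vs-vehicle effect to a *reference
effect* measured on the reference study: `ratio = |Δ| / Δ_ref`, and

* **strong** if significant and ratio ≥ 0.75,
* **moderate** if significant and ratio ≥ 0.25,
* **inconsistent** if significance and effect size disagree,
* **none** otherwise.

Δ_ref is the long-acting reference arm's effect for every endpoint except
TUNEL, where long-acting estrogens show no response and the short-acting
arm anchors the ratio. Calls are direction-agnostic (absolute effects);
expected directions live in the classification template. The cut points
(0.25 / 0.75) operationalize the conventional −/−/+/+/++ notation and are
config-exposed.

## Classification

Transcriptional scores:

* `estrogenicity ∈ [−1, 1]`: Pearson correlation between the candidate's
  2-h panel deviations and the panel's estrogen centroid direction;
* `longevity`: projection of the 24-h deviations onto the panel axis,
  affinely calibrated so the short-acting centroid maps to 0 and the
  long-acting centroid to 1.

Both are the package's own scoring choices — simple, monotone, and
unit-calibrated against the references.

The expectation template encodes, per class and endpoint slot, the
expected call; "−/+" cells are wildcards matching none/inconsistent/
moderate. The RNA slots are derived from the scores (2-h: moderate iff
estrogenicity ≥ τ_e; 24-h: the calibrated longevity plays the effect
ratio's role with the same 0.25/0.75 cuts).

Decision, with τ_e = 0.5 and longevity bands (< 0.35 short, > 0.65 long):

1. estrogenicity below τ_e **and** no endpoint call above "inconsistent"
   → non-estrogenic. (Requiring literally every call to equal "none"
   would misroute ~30% of truly inert compounds, since seven endpoints
   tested at α = 0.05 yield spurious sub-threshold significances at the
   expected type-I rate; gating on moderate-or-strong calls keeps the
   null path at its nominal error rate.)
2. otherwise count mismatches against the short- and long-acting template
   rows (wildcards free, unavailable slots skipped);
3. longevity in the long (short) band with no worse a mismatch count than
   the other row → long-acting (short-acting);
4. anything else — middle band, missing longevity, or score/template
   disagreement — → intermediate.

The explicit middle band exists because the screen must be able to return
an intermediate verdict for partial agonists whose biology genuinely sits
between the reference classes. When transcript scores and endpoint calls
conflict, the mismatch-count comparison in step 3 is the declared
precedence rule. Missing modalities reduce evidence and are logged, never
fatal; a compound with high 2-h estrogenicity but no 24-h data can never
be called non-estrogenic.

## Determinism and numerics

Every stage is a pure function of (inputs, seed); the pipeline fans a
single seed out to stages by fixed offsets, and all artifacts are plain
text with sorted keys and full float precision, so fixed-seed reruns are
byte-identical. Ties are broken lexicographically (pattern seeding,
loading ranks) or toward the smallest id (pattern assignment). PCA signs
follow the largest-|loading|-positive convention. Correlations against
constant vectors raise instead of returning NaN.

## Problem sizes

The shipped defaults — 10,000 probes with 7 × 300 planted, 32-sample
reference design, 40 simulated test compounds, 10,000-replicate null
calibrations — run the full acceptance battery in well under a minute on
one CPU; they were chosen as the package's standard demonstration scale
and match the order of magnitude of the real studies (4 × 44K arrays
collapse to ~10–20k informative probes).

## Known limitations

* The pattern extractor re-implements the correlation-seeded idea behind
  the EPIG family of tools, with its own calibrated defaults; it is not a
  port of any particular tool's parameterization.
* The batch-correction and panel-selection recipes are deliberately
  simple, defensible choices; both are isolated behind config so
  alternatives are drop-in.
* Ordinal-call cut points and longevity bands are calibrated on the
  synthetic references; real deployments should re-anchor them on their
  own reference compounds.
* Equal-variance ANOVA machinery is used throughout; fold-change
  endpoints are simulated heteroscedastic, which the significance gate
  tolerates but a fastidious analysis might log-transform first.
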