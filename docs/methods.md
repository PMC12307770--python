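# Methods

This note documents the models and procedures implemented in `swimassay`,
the choices made where a published convention does not pin one down, and
what the synthetic generator does and does not emulate.

## Arenas and event extraction

Arenas are flat (top-view) collections of named zones — rectangles,
circles, annuli, polygons — in millimetres with the origin at the lower
left, plus an adjacency graph and a role label per zone. Six presets match
the standard apparatus dimensions: the 12-chamber slalom maze
(20 × 85 mm), the 4-chamber show-jump maze (20 × 42 mm), the swimming
plus-maze (8 × 8 mm center, 8 × 10 mm arms; the two shallow arms carry the
aversive label — depth is encoded purely as a label, no 3-D geometry), the
open tank (35 mm diameter well whose central circle covers exactly 80% of
the area, radius ratio √0.8), the three-arm Y-maze (7.5 × 30 mm arms at
120°), and the U-shaped sociability arena (stimulus / no-stimulus arms
joined by the starting intersection).

**Zone membership** is decided by the animal's center point; a point on a
shared boundary belongs to the zone declared first, making shared edges
half-open. The tracker convention (center vs head point) is not
standardised across laboratories; the center point is used and stated
here. Samples outside all zones are labelled `none`.

**Visit extraction** compresses per-sample labels into runs, absorbs
`none` runs into the preceding visit, and de-bounces: runs shorter than
`min_dwell` merge into their flanking visits (coalescing when both flanks
are the same zone, otherwise joining the preceding visit). The default
`min_dwell` of **0.2 s** suppresses single-frame flicker at the 30 fps
tracking convention; it is configurable and 0 disables merging. Increasing
`min_dwell` can only reduce the visit count (a tested invariant).

**Session metrics.** Per zone: occupancy time (summing to the session
length to 1e-9 s), entry count, and first-entry latency — censored at the
session length, with a flag, for zones never entered (entry count 0 ⇔
censored latency, also a tested invariant). Mean velocity is path length
over elapsed time for the whole session including immobile periods (the
alternative — excluding immobile frames — is not used; whole-session is
the stated convention here). An immobile episode is a maximal run with
speed below **1 mm/s** sustained for at least **1 s**; both parameters are
configurable, as "immobility" has no universal definition at this body
size.

## Population-scaled endpoints

Min-max scaling across "the investigated population" is interpreted as
scaling within the analysis batch actually passed in — typically one
species × experiment group; cross-species analyses can pool batches by
passing them together, and which choice was made is visible in the call.
A constant column scales to **0** for every subject (not NaN), so
downstream averages of censored-only populations remain defined.

* **Mean transition latency (MTL)**: per chamber (2..12), first-entry
  latencies (censored at session length) are min-max scaled across the
  population; a subject's MTL is the mean of its scaled chamber values,
  in [0, 1]. At least two subjects are required, since scaling across a
  single subject is undefined.
* **Success rate**: percent of subjects with at least one visit to the
  final chamber.
* **Anxiety score**: `scaled(latency) − scaled(time)` for the aversive
  (shallow-arm) zone, i.e. (scaled time − scaled latency) · (−1), in
  [−1, 1]. The subtraction order is fixed by the requirement that the
  score correlate *positively* with avoidance: an avoider has long latency
  and little time in the aversive zone, hence a positive score.
* **Zone preference**: time% and entry counts aggregated by zone role
  (e.g. both shallow arms summed).

## Y-maze action classification

Arm visits are reduced from zone visits by absorbing the center zone
(crossing the center does not end an arm visit; only arrival at a
different arm does) and collapsing the repeats that absorption exposes.
Every overlapping window of three consecutive arm visits gets exactly one
label with precedence **direct > alternation > indirect**: a window
containing an immediate repeat (x = y or y = z) is a direct revisit; else
three distinct arms are an alternation; else the window is an indirect
revisit (x = z ≠ y). The precedence is needed because immediate repeats
are defined on pairs while the reported distribution is over length-3
windows; pair-level repeat counts are exported separately for
transparency. Alternation% uses the window count (visits − 2) as
denominator, the rodent-literature convention in which uniform random
no-stay choice gives 50% and perfect alternation 100%. Over all 27
triples the label partition is 15 direct / 6 alternation / 6 indirect,
verified in tests against a brute-force enumeration oracle.

## Repeatability

Repeatability is the intraclass correlation

R = σ²_between-subject / (σ²_between-subject + σ²_within-subject).

Published descriptions of this decomposition sometimes swap the
"within/between test" vocabulary depending on whether the unit is the test
or the individual; this package follows the standard animal-personality
usage in which the numerator is the stable between-*subject* variance.

**Estimator**: one-way random-effects ANOVA method of moments —
σ²_within = MS_within (pooled within-subject mean square), σ²_between =
max(0, (MS_between − MS_within)/k₀) with the usual unbalanced-design
coefficient k₀ = (N − Σkᵢ²/N)/(n − 1). Closed-form and hand-checkable; on
balanced Gaussian data it coincides with the REML mixed-model estimator
(tested against statsmodels MixedLM). Negative between-subject estimates
are truncated at zero before forming R. Subjects with fewer than two
observations are excluded — they carry no within-subject information.
Covariate-adjusted ("adjusted") repeatability is not implemented; the
variance decomposition is an extension point for it.

**Uncertainty**: parametric bootstrap with **1000** replicates by default —
data are redrawn from the fitted normal random-intercept model on the same
design, R is re-estimated per replicate, and the 2.5/97.5 percentiles form
the 95% CI (percentile intervals; no bias correction). An estimate whose
CI excludes 0 is flagged significant. Identical seeds give bit-identical
intervals. The degenerate all-constant case defines R = 0 with CI [0, 0]
and a warning.

**Summaries**: SiM is the first session's value (which session a
single-measure analysis should take is otherwise arbitrary; the first is
used); SuM is the mean over available sessions. Inter-test correlations
are Pearson or Spearman on complete subject pairs (≥ 3), via scipy.

## Modality

1-D Gaussian mixtures with K components are fitted by EM: initial means at
spread quantiles of the data (the first restart exact, later restarts at
random quantile positions), equal initial weights, pooled-variance
initialisation, and a variance floor of 1e-6 × sample variance that keeps
the likelihood finite on repeated values. Defaults: **10** restarts,
tolerance **1e-8** on the log-likelihood gain, **500** iterations maximum.
The per-iteration log-likelihood trace of the chosen restart is exposed
and asserted non-decreasing in tests. K = 1 uses the closed-form Gaussian
ML fit. Components are reported sorted by mean. When no restart converges
(typical when K exceeds the true number of modes and EM drifts slowly
along a flat ridge) the best fit is returned flagged, with a warning.

Model selection fits K = 1..3 and picks the K with the highest
BIC = 2·logL − p·ln n, oriented so that *higher is better* — the
orientation under which a "highest BIC" decision rule is coherent — with
p = 3K − 1 free parameters (free component variances; an equal-variance
flag with p = 2K is provided). BIC values are min-max scaled to [0, 1]
over the K grid per variable, so plots show the winner at 1. All EM fits
are restart-seeded and deterministic under a fixed seed; scikit-learn's
GaussianMixture serves as an independent cross-check oracle in the tests,
never as the implementation.

## Effect sizes

d = |mean(a) − mean(b)| / SD(a ∪ b), the SD of the two groups pooled into
one sample with n − 1 denominator ("total standard deviation"). This is
deliberately *not* Cohen's pooled-within-groups SD — the total-SD reading
matches the summary the pipeline reconstructs — but the Cohen variant is
available via `sd_mode="pooled_within"`. Effects are reported as absolute
values; composite effects (one manipulation summarised over several
endpoints) are unweighted means of component d values. Zero pooled SD
yields a missing value with a warning, and per-comparison pooled samples
are used throughout (no across-comparison SD sharing).

## Synthetic generator

The generator produces data with the statistical structure the analysis
assumes, for testing and calibration — not biomechanically realistic
swimming, and no coupled social dynamics (a companion condition can only
be emulated as a rate shift).

* **Zone walks**: a continuous-time Markov chain on the arena adjacency
  graph — exponential dwell with per-zone mean (default **5 s**), next
  zone proportional to edge weights. The avoidance parameter a ≥ 0
  multiplies aversive-zone dwell and aversive-zone entry weight by
  e^(−a), mimicking an anxiety-like construct: a = 0 is indifference,
  a ≈ 5 near-total avoidance. A log-normal per-subject multiplier on
  rates (SD on the log scale) induces stable individual differences and
  hence repeatability; an explorer-type mixture over rate multipliers
  induces multimodal endpoint distributions. Rendering to a 30 Hz track
  adds within-zone jitter (a mean-reverting walk around a per-visit
  anchor, clamped 0.5 mm inside the zone) and hazard-driven immobile
  episodes. Visits shorter than one frame interval cannot appear in a
  rendered track; the event-level output is the primary representation
  and endpoint tests consume it directly.
* **Y-maze policy**: first two visits uniform distinct; then with
  probability p_direct repeat the current arm, otherwise with probability
  p_alt complete an alternation, else return to the previous arm.
  p_alt = 0.5, p_direct = 0 is exactly the uniform no-stay random walk,
  whose expected alternation percentage is 50 — the random-choice
  reference recomputed by `scripts/acceptance.py`.
* **Repeated measures**: y_ij = μ + b_i + e_ij with known true
  R = σ_b²/(σ_b² + σ_e²) attached as metadata.
* **Population values**: i.i.d. draws from a stated Gaussian mixture.

Determinism: one mandatory seed per run; per-subject streams are split by
`SeedSequence.spawn`, so a subject's data is independent of how many other
subjects follow it, and identical configurations reproduce outputs
byte-identically (serialised with 17 significant digits).

Passing tests on this generator demonstrate correctness of the estimators
under their own model assumptions (Markov dwell, Gaussian random
intercepts, Gaussian mixture components). Real tracking data departs from
these in known ways — non-exponential dwell, drift within sessions,
tracking noise and lost frames — so the tests validate the arithmetic and
the statistical calibration, not biological conclusions.

## Problem sizes and numerical choices

Simulation-based checks use: 32 subjects × 200 visits for the Y-maze
random-choice null (tolerance ±2 percentage points, the Monte-Carlo error
at that size); a repeatability recovery grid over true R ∈ {0.1, …, 0.9}
with n = 100 subjects, k = 3 sessions, 200 replicates (mean R̂ within
±0.05 of truth); 50 seeded runs of n = 300 for each modality scenario
(≥ 95% correct K). Bootstrap and EM are fully vectorised (replicates and
restarts as batch axes), which keeps the full test suite under two
minutes on one core.

Tie-breaks and degenerate inputs: boundary points go to the first-declared
zone; constant scaling columns map to 0; equal BICs resolve to the smaller
K; negative variance components truncate to 0; zero-window Y-maze
sequences and zero-variance correlations return missing values with
warnings rather than raising.

## Known limitations

* The ANOVA method-of-moments estimator is an approximation to
  likelihood-based mixed-model repeatability on unbalanced designs (they
  coincide when balanced); no covariate adjustment.
* Only the standard 95% percentile bootstrap CI is offered.
* Min-max scaled endpoints depend on the composition of the scaling
  batch; comparing MTL or anxiety scores across separately scaled batches
  is not meaningful.
* The modality decision is restricted to univariate Gaussian components,
  K ≤ 3 by default; it is a model-selection heuristic, not a hypothesis
  test for multimodality.
* The sociability U-shape, plus-maze, and Y-maze geometries are idealised
  rectilinear/polygonal layouts at the printed dimensions; real apparatus
  corners and wall curvature are not modelled.
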