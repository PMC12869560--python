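# Methods

`ehrsynth` generates analysis-ready synthetic longitudinal EHR data in three
stages — tokenize, generate, reconstruct — and ships the evaluation battery
and ground-truth simulator needed to test every stage without access to real
clinical data. This note documents the models, the parameters that matter,
the numerical choices, and the limitations.

## Data model and tokenization

A cohort is three linked tables (`patients`, `visits`, `diagnoses`) sharing
`patient_id` keys, described by a declarative `CohortSchema`: static fields
(categorical, continuous, or binary condition labels), visit fields
(categorical or continuous with band definitions), one or more diagnosis-code
systems, an inter-visit gap variable, and a visit cap. Visits are sorted
chronologically and capped at the first `max_visits` visits (earliest-first
preserves trajectory onset).

Because the generator is a discrete-token model, continuous variables are
discretized into bands. Band edges default to per-variable quantiles
(20 bands) computed on the training split, which bounds per-band probability
mass; explicit edges can be declared in the schema. The inter-visit gap uses
a hybrid grid — one band per day up to 7 days, one per week beyond — so that
gap bands line up with the three timestamp-reconstruction tiers, plus a
dedicated `[-2, 0)` day overlap band: in admission/discharge data a new
admission can begin before the previous discharge (overlapping ED/inpatient
episodes), and the gap there is measured from the previous *discharge*. In
visit-date-only schemas the gap is between consecutive start times and is
nonnegative.

Missingness is informative in clinical data, so a missing value is
represented by the *absence* of a band token, never by an explicit missing
token; the generator learns missingness rates jointly with everything else,
and reconstruction leaves missing values missing.

Rare diagnosis codes (fewer than `min_count = 50` occurrences cohort-wide)
are collapsed to the longest prefix (default candidates: 3 then 2
characters) whose aggregated count reaches the threshold, falling back to
the shortest candidate. The empirical distribution of full codes within each
aggregated category, stratified by gender (with a pooled fallback), is
stored and used to re-expand codes in the synthetic output, restoring the
original code spectrum.

The flat token vocabulary is ordered: special tokens, binary condition
labels, static levels/bands, visit categorical levels, visit bands, gap
bands, codes. Label tokens come first deliberately — they are the clamping
targets for conditional generation, and the within-visit head (below) lets
earlier tokens inform later draws, so a clamped condition label influences
the demographic tokens drawn after it.

## The generator

The engine is a small causal transformer over *visit positions*: each
sequence position holds one multi-hot token vector (position 0 a
start-of-record marker, position 1 the static/label vector, then one
position per visit, terminated by an end-of-record vector). Pre-layer-norm
blocks with learned positional embeddings, GELU feed-forward, causal masks
built at runtime for the actual sequence length, and raw-logit outputs
scored with a numerically stable binary cross-entropy. Forward and backward
passes are written directly in numpy (gradient-checked against numerical
differentiation), optimized with Adam under global-norm clipping.

Three architectural details matter for fidelity at desk scale:

- **Within-visit autoregressive head.** With one position per visit, token
  draws within a visit would be conditionally independent given history,
  which destroys within-visit co-occurrence structure (and any correlation
  between banded variable pairs). A masked V×V coupling matrix adds each
  already-drawn token's contribution to the logits of tokens later in the
  vocabulary order; during training it is teacher-forced with the target
  vector, making the per-position likelihood a proper autoregressive
  factorization over the token order.
- **Persistent static context.** The static/label vector is OR-ed into the
  *input* at every visit position (targets untouched), so demographics and
  condition labels condition each step directly rather than only through
  attention to position 1.
- **Calibration anchoring and averaging.** The output bias is initialized at
  the empirical marginal logits of the training data, and parameters are
  Polyak-averaged (EMA, decay 0.995); validation loss each epoch and the
  best-validation checkpoint both use the averaged weights. Both choices
  reduce the seed-to-seed variance of generation calibration considerably.

Defaults (the desk-scale study configuration): 2 layers, 4 heads, 64-dim
embeddings, batch 16, learning rate 1.5e-3, at most 20 epochs with early
stopping (patience 5) on validation loss. Production-scale settings
(4–12 layers, 256–768 dims) are reachable through the same config. Training
is deterministic for a fixed seed and thread configuration; mixed precision
is exposed as a flag but is a no-op (float32 throughout).

### Sampling and constraints

Generation proceeds position by position; within a position, tokens are
drawn in vocabulary order as independent Bernoullis from the (sigmoid)
probabilities, with the within-visit head updating later logits after each
draw. Two kinds of masking are applied in the same pass:

- The end-of-visit marker is preset before any draw (it is structurally
  certain), so its learned coupling conditions the whole visit exactly as in
  teacher forcing; the within-visit coupling matrix is masked *inside*
  structural groups, whose exclusivity the sampler enforces directly.
- **User rules** (declarative constraints): `forbid-token` forces a probability to
  0 everywhere; `forbid-co-occurrence` zeroes either side of a pattern once
  the other side is active in the partial visit (sound under sequential
  drawing regardless of order); `require-if` forces consequents to 1 once
  the antecedent set is active, with a closure pass for antecedents
  completed late. Contradictory rules raise an error. Generated cohorts are
  checked post hoc by exhaustive scan.
- **Structural rules**: a variable's level/band tokens are mutually
  exclusive, so their predicted Bernoulli marginals are treated as a
  multinomial — always-present fields (static and visit categoricals, the
  gap beyond the first visit) normalize and draw exactly one level, while
  band groups keep the leftover mass 1 − Σp as the probability of
  missingness, preserving informative missingness. These keep every
  generated vector a structurally valid visit, so detokenization never
  trips the one-band-per-variable invariant.

Conditional generation clamps the requested label tokens active before the
static vector is drawn. Unconditioned generation draws the label vector
first, then visits. An end-of-record Bernoulli is evaluated before each
visit (always "continue" at the first visit), and generation stops at the
visit cap.

## Reconstruction (dequantization)

**Continuous variables.** For each variable, the empirical distribution is
estimated per stratum with a Gaussian-kernel KDE; bandwidths come from
statsmodels `KDEMultivariate` (normal-reference rule) and the CDF is
evaluated on a discretised grid in closed form (Φ sums, vectorised). Visit
variables are stratified by gender × event type, static variables by
gender; strata under 30 observations fall back to the pooled estimate
(flagged). Grid resolution defaults to one natural unit (1 year of age,
1 hour of stay), capped in point count for very wide ranges. A banded value
is regenerated by two-stage sampling: a grid subinterval inside the band is
chosen proportionally to its KDE mass, then a value is drawn uniformly
inside the subinterval — so every reconstructed value lies inside its source
band, and the within-band shape follows the empirical distribution rather
than being flat. A zero-mass band falls back to a uniform draw (flagged).

**Correlated pairs.** For a configured pair (by default total and treatment
length of stay), a joint KDE CDF is evaluated on a product grid (the
Gaussian product-kernel CDF factorizes, so the grid evaluation is one matrix
product; fits subsample to 5,000 points per stratum). Rectangle masses come
from the inclusion–exclusion identity F(b,d) − F(a,d) − F(b,c) + F(a,c);
tiny negative numerical residues are clipped to zero and the cell masses
renormalized. Sampling picks a joint cell inside the band rectangle by mass,
then uniforms within the cell. On the shared grid, unclipped cell masses
telescope exactly (to float precision) to the joint-implied marginal
interval masses.

**Timestamps.** Patients are stratified by total visit count (capped at 8,
pooled fallback) and a start week is sampled from a KDE-derived probability
grid over first-visit week indices; day of week and hour of day come from
empirical tables. The calendar lookup maps (week index, day) to dates,
indexed from the Monday of the study start; weeks outside the window clamp
to the edge (flagged). For visit-date-only schemas, visit `i`'s week is the
start week plus the cumulative sum of gap-week values — an exact identity.
For admission/discharge schemas, discharge times follow a three-tier logic
by length of stay: up to 24 h (inclusive), discharge = admission + LOS
exactly; 1–7 days, the LOS is rounded half-up to whole days and the time of
day set from a sampled end hour; over 7 days, the LOS is converted to weeks
and the discharge date comes from the (end week, end day) calendar lookup
with a sampled end hour. Discharge never precedes admission. Subsequent
admissions mirror the same tiers using the inter-visit interval from the
previous discharge; a negative (overlap-band) interval places the admission
before the previous discharge, and a stable sort restores start-time order
afterwards (diagnoses travel with their visits). End hours/days are sampled
from training empirical distributions when the schema does not carry them as
banded variables.

**Codes.** Aggregated categories are re-expanded by sampling the stored
per-stratum empirical table (gender stratum, pooled fallback); codes never
aggregated pass through unchanged.

All fitted reconstruction state (KDE grids, calendar maps, empirical tables,
aggregation map) serializes to a single versioned JSON sidecar written at
fit time and required at generation time.

## The ground-truth simulator

The simulator plants known statistical structure so that every metric has a
recoverable truth. Defaults define the study conditions used throughout the
tests:

- 2,000 patients over a 2018–2020 window; age truncated-normal (50, 18) on
  [18, 90]; 50% female.
- Visit counts 1 + Poisson(2.5), capped at 10; visit dates drawn from
  (week, day) cells weighted by a seasonal factor 1 + 0.3·sin(2πw/52) and
  day-of-week weights (2,2,2,2,2,1,1) — a 2:1 weekday:weekend intensity
  ratio; daytime-weighted start hours. Two event types (ED 60%, inpatient
  40%) with log-normal lengths of stay (ED: meanlog 1.2, sdlog 0.7;
  inpatient: meanlog 3.2, sdlog 1.0, in hours).
- Total and treatment length of stay form a bivariate log-normal pair whose
  log-scale copula correlation is solved numerically so the value-scale
  Pearson correlation is 0.7.
- 18 ICD-10-shaped synthetic codes with per-visit base prevalences
  0.002–0.10; some have logistic age effects (e.g. a dementia-like code with
  strong positive age slope, an asthma-like code with negative slope) or a
  gender odds multiplier; one within-visit co-occurrence lift (chest-pain →
  myocardial-infarction-like, lift 3); six deliberately rare codes exercise
  prefix aggregation.
- A progression rule: diabetes-family index codes lead to a
  hypoglycaemia-like outcome code in a strictly later visit with
  probability 0.6. Index codes are planted only in non-final visits, so the
  conditional-occurrence estimand equals 0.6 exactly; the outcome code has
  no base prevalence.
- Informative missingness: treatment LOS is missing 2.5× more often when the
  dementia-like code is present.
- A 2% overlap mixture pulls an admission up to 2 days (bounded by the
  previous stay's duration) before the previous discharge, producing the
  negative gap band.
- Binary condition labels derive from code-family prefixes (diabetes,
  heart disease).

`truth_check` re-estimates every configured parameter (gender proportion,
age moments, a plain code's prevalence, the progression probability, the
pair correlation in the inpatient stratum, the weekday:weekend ratio, the
seasonal amplitude via a sinusoid fit to weekly counts) against ~3-standard-
error Monte-Carlo tolerances at the realized sample sizes.

What the simulator does *not* emulate: real ICD semantics, multi-morbidity
beyond one co-occurrence lift and one progression rule, facility/provider
structure, secular trends, or measurement error in continuous values.
Passing tests therefore demonstrate that the pipeline's machinery preserves
the planted structures, not that it captures every property of real EHRs.

## Evaluation battery

- **Summary and correlation fidelity**: per-variable descriptive statistics
  (Table-style side-by-side), pairwise Pearson correlations on visit rows
  with the difference matrix and its largest absolute entry.
- **Code-frequency R² and retention**: relative per-code frequencies on a
  log10 scale (floored at half of one occurrence), over codes present in
  the real cohort; absent-in-synthetic codes enter at the floor. All
  fidelity R² values are *agreement* R² against the identity line
  (1 − SS_res/SS_tot with the synthetic vector predicting the real one,
  floored at 0): self-comparison gives exactly 1 and disjoint-support
  cohorts give 0, which a squared correlation would not.
- **Bigram R²**: within-visit (unordered code pairs per visit, normalized
  by visit count) and sequential (ordered pairs across consecutive visits,
  normalized by consecutive-pair count), on the union support; verified
  against an exhaustive enumeration oracle on small cohorts.
- **Conditional occurrence**: P(outcome code in any strictly later visit |
  index code) versus P(outcome ever | no index).
- **TSTR**: gradient-boosted classifiers (xgboost, depth 4, 200 trees,
  learning rate 0.1, fixed seed) trained on real, synthetic and combined
  data, all scored on a held-out real test set (precision/recall/F1 at
  threshold 0.5, PR-AUC, ROC-AUC). Three built-in tasks: next-visit target
  diagnosis among previously undiagnosed patients, in-visit death flag from
  admission-time features, and 30-day revisit.
- **Attribution agreement**: per-feature mean |Shapley| attributions from
  xgboost's exact tree-path algorithm (`pred_contribs`), compared between
  the real- and synthetic-trained models by top-10 overlap and Spearman
  rank correlation; the test oracle is exhaustive Shapley coalition
  enumeration on ≤ 8 features.
- **Equal opportunity**: max − min true-positive rate across subgroup
  levels at threshold 0.5 (difference convention; groups without positive
  cases are excluded with a warning).
- **Coefficient comparison**: the same regression specification (OLS, GLM
  binomial, or linear mixed model with one random intercept) fitted to both
  cohorts; paired estimates with 95% intervals, sign-agreement flags, and a
  per-factor flag for preserved ordering of level estimates. Binomial
  models with a grouping factor fall back to a plain GLM (no frequentist
  GLMM in the stack).
- **Prevalence curves**: patient-level condition prevalence by gender and
  age through a binned logistic smoother (binomial GLM on age-bin midpoint,
  linear + quadratic), with the maximum absolute between-cohort gap per
  condition. This is a deliberate simplification of a full additive model.
- **Temporal fidelity**: daily event counts per cohort (zero-filled over
  each cohort's span), sample ACF and PACF (Durbin–Levinson) to a
  configurable lag, and the lag-7 contrast. This is where the pipeline is
  *expected* to fall short: the engine models individual trajectories, and
  timestamp reconstruction restores format, not aggregate calendar
  structure, so the weekly lag-7 peak present in the ground truth is
  strongly attenuated in synthetic data. The package reproduces this
  limitation by design and the acceptance checks assert it.

## Problem sizes and determinism

The standard desk-scale study used by the tests and the acceptance script:
2,000 simulated patients (vocabulary ≈ 230 after aggregation), 80/10/10
patient-level split, 2-layer engine for at most 20 epochs, 6,000 generated
patients for distributional comparisons (a larger synthetic sample keeps
estimator noise in the fidelity metrics well below model error — the pure
Monte-Carlo ceiling of within-visit bigram R² at 2,000-vs-2,000 is ≈ 0.88),
10,000 for the constraint-soundness scan, 2,000 for conditional cohorts,
and 20,000 values for the KDE reconstruction checks. Everything is driven
by explicit seeds; repeated runs with the same configuration produce
identical outputs in single-threaded mode.

## Known limitations

- Within-visit dependence is modelled only through the token-order
  autoregressive head; cross-variable correlation in *generated* cohorts
  (e.g. the total/treatment LOS pair) is attenuated relative to the real
  data even though the reconstruction step preserves whatever dependence the
  band pairs carry. A token-level hierarchical generator would capture more.
- Tier-2/3 timestamps are intentionally coarse (day/week resolution plus a
  sampled end hour), so discharge − admission equals the LOS exactly only
  in tier 1.
- Aggregate temporal structure (weekly/seasonal intensity) is not preserved;
  synthetic data from this pipeline is unsuitable for forecasting or
  seasonality analyses.
- The coefficient-comparison harness supports one random intercept (linear
  family); random slopes and binomial mixed models are out of scope.
- No privacy or membership-inference evaluation is included.
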