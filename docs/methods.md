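# Methods

`playdyn` implements a nonlinear process analysis of psychodynamic
play-therapy sessions.  The unit of observation is one coded play segment;
the unit of analysis is the discrete "play state" occupied by a patient's
longest play segment in each session.  This note documents the models,
conventions and numerical choices, and what the synthetic test bed does and
does not show.

## Profile scoring

Each play segment is rated on CPTI items (1–5 Likert: 1 = no evidence,
5 = most characteristic).  The five composite profiles — Adaptive (12
items), Inhibited (9), Impulsive (10), Disorganized (9) and Play Engagement
(5) — are arithmetic means of their item scores.  No standardisation is
applied: every item already lives on the same 1–5 metric, so composites are
directly comparable.  Items may belong to several profiles (Facilitation of
Play counts toward Adaptive and Engagement; Inhibition of Play toward the
three non-adaptive profiles); each profile counts its items once.

Reliability helpers: Cronbach's alpha per profile is computed over segments
pooled across patients (one estimate per profile, matching how such
instruments are usually reported; `alpha_grouping='per_patient'` is the
sensitivity option).  Inter-rater agreement uses ICC(2,1) — two-way random
effects, absolute agreement, single rater — because the design is two fixed
independent raters rating every segment; other variants are exposed through
the `variant` argument.  Both return NaN with a logged warning on
degenerate (zero-variance) tables.

Longest-play-segment selection: "longest" is operationalised as the
greatest value of the optional per-segment `duration` field (transcript
lines, seconds — any consistent unit).  Segments without a duration count
as ties, and all ties resolve to the earliest segment, logged.  Sessions
with no play segment are flagged and excluded.

## State clustering

Before pooling patients, the correlation structure of the five profile
series is checked per patient: Engagement–Disorganized and
Engagement–Inhibited negative, Disorganized–Impulsive–Inhibited pairwise
positive, Adaptive–Engagement positive.  When every patient shows the same
sign pattern the descriptors can be treated as carrying the same meaning
across patients, and segments are clustered jointly.

States are K-means clusters over the five profile scores **only**,
unstandardised.  The published cluster table also lists modal narrative and
relational theme codes per cluster, but unordered categorical codes have no
defensible place in a Euclidean K-means; themes are therefore attached post
hoc as per-cluster modes (smallest code on ties).  This is the largest
interpretive decision in the package and is surfaced in the API
(`attach_modal_themes` is a separate, explicit step).

K selection follows the first peak or plateau of the explained-variance
curve (between-cluster SS / total SS over a contiguous scan range, default
2–12): the smallest K whose gain to K+1 is negative or at most a
stationarity tolerance (default 0.01 absolute).  A curve that keeps rising
above tolerance returns the maximal K with a warning.  K-means runs 25
restarts with best inertia under a fixed seed; fitted labels are re-indexed
1..K by descending cluster size so state names are reproducible.  New
segments are assigned to the nearest center; exact ties go to the
lower-indexed state, logged.

## Markov dynamics

Transitions are single steps between consecutive sessions' states, pooled
over patients, **never across a patient boundary** (the total is exactly
Σ(len−1) = 160 on the bundled data; this convention reproduces the
reproducible rows of the published matrix cell-for-cell).  Percentages are
row-normalised counts × 100; a never-left state yields an all-NaN row,
flagged.  The "attractor" is the unordered state pair maximising the
reciprocal count N_ab + N_ba, with ties returned in full.

The ergodicity diagnostic builds one row per ordered off-diagonal state
pair (include-diagonal flag available): transition count N_ij, marginal
frequencies f_i and f_j computed over all pooled state occurrences (163 in
the bundled data), their composite c_ij, and the Euclidean distance d_ij
between cluster centers in the five-dimensional profile space (themes
excluded, matching the clustering space).  The composite defaults to the
product f_i·f_j — the expected share of transitions under independence,
which is the natural null for "transition counts scale with state
frequency" — with a `sum` option for sensitivity; the source material never
defines its composite, so this remains a documented ambiguity.  Reported
statistics are the Pearson r of N_ij against c_ij and the first-order
partial correlation removing d_ij.  High r with r_partial ≈ r means
transitions follow state frequency regardless of how far apart states lie:
every state remains reachable, the loose dynamical sense in which the
therapy system is called ergodic.  On the bundled case study this yields
r = 0.91 and partial r = 0.85 over the 42 pairs.

## Recurrence quantification

State trajectories are binarised into a change series: 0 when the next
segment keeps the state, 1 when it changes.  Patients are concatenated in
fixture order; the default **includes** the two pairs straddling patient
boundaries (length 163 − 1 = 162), because this convention reproduces the
published recurrence rate (0.626; exclusion gives 0.623).  The flag
preserves the alternative.

Recurrence is symbolic and exact-match: embedding dimension 1, radius 0,
main diagonal (Theiler window 1) excluded from numerator and denominator.
RR = Σ_s n_s(n_s−1) / (N(N−1)) over symbol counts — equivalently the
fraction of off-diagonal index pairs holding equal symbols.  RR depends
only on the symbol multiset and is therefore exactly invariant under the
shuffled surrogates (the published identical real/shuffled value of 0.626
is a mathematical identity, not an empirical finding).  DET is the fraction
of recurrent points on diagonal lines of length ≥ lmin (default 2),
computed diagonal-by-diagonal with run-length encoding; an O(N²)
recurrence-plot oracle verifies it in the tests.  Edge effect worth
knowing: a constant series of length N has DET = 1 − 2/(N(N−1)), not 1,
because the two corner cells of the plot sit on length-1 diagonals.

The published determinism values (real 0.462, shuffled 0.503) are **not**
reproducible under any standard convention on the published sequences (the
lmin = 2 convention gives ≈0.85 for both); the line-length convention used
there is unstated, so those numbers are not treated as reproduction
targets.  DET is validated against the brute-force oracle instead, and the
surrogate ensemble (default 30 uniform permutations of the binary series,
seeded) reports its mean ± sd for comparison.

## Phase comparison and reliable change

Each series is split into treatment halves with the floor rule: the first
half takes floor(N/2) elements (47 → 23 + 24; validated against the
published per-cluster ratios).  Per-category occurrence is compared by the
**ratio of relative frequencies** (n₁/N₁)/(n₂/N₂).  The source tables label
these "odds ratios", but the printed values follow the frequency-ratio
rule — e.g. (8/23)/(4/24) = 2.09 — so that is the default; a true odds
ratio with optional Haldane 0.5 correction is available.  A ratio is
undefined ("n.d.") whenever either half-count is zero, which reproduces the
published pattern of undefined cells exactly.  Activity-type ratios use
session-count denominators (segments of a type per session, compared across
halves), so 6 vs 2 interruptions over equal 20-session halves gives exactly
3.0.  Summary means/SDs cover defined ratios only.

Reliable change: RCI = (pre − post)/SE_diff for symptom scales (decrease is
improvement) and (post − pre)/SE_diff for functioning scales; change is
reliable when RCI > 1.96.  Clinical cutoffs (CBCL Internalizing 64, Anxiety
70, configurable) determine whether a patient crossed from the clinical to
the non-clinical range.  The bundled outcome fixture recovers the
per-instrument SE_diff from the published score differences and RCIs,
rounded to two decimals (Anxiety 1.20, Internalizing 2.80, CGAS 5.16); one
published row implies a slightly different SE (2.98) and is carried as a
documented inconsistency rather than resolved.

## Synthetic data

The generator is the package's ground-truth test bed.  Its defaults are the
study conditions: 3 patients × 55 sessions (the study's mean treatment
length), K = 7 states, the planted transition matrix equal to the published
pooled percentage matrix renormalised row-stochastic, planted centers equal
to the published cluster centers, and profile emission noise sd 0.15 per
coordinate (clipped to [1, 5]).  Each patient starts from the stationary
distribution of the planted matrix and follows a first-order chain; each
session draws 4–7 segments (matching the reported segmentation, M = 5)
with half-specific activity rates — interruptions halve in the second half,
the direction of change the study reports — and at least one play segment;
the longest play segment carries the state emission.  Item-level mode emits
integer item scores as round(clip(item target + segment-level shared factor
+ item noise)): the shared "halo" factor (sd 0.5) plants the inter-item
correlation that gives the composites their internal consistency, and the
item target of a multi-profile item is the mean of its profiles' center
coordinates.  Outcomes are drawn per instrument around configurable
pre/post means (individual sd 3 score points) with the study's SE_diff
values.

A separate lightweight generator produces profile-score series with the
planted correlation-sign structure via a two-factor model (an adaptive
factor loading on Adaptive and Engagement; a dysfunction factor loading on
the three non-adaptive profiles and negatively on Engagement).  Its series
are unclipped by default so degenerate settings (zero noise, single factor)
give exact ±1 correlations.

What the synthetic bed does **not** show: real CPTI ratings are ordinal,
rater-dependent and serially dependent within sessions; emitted noise here
is iid Gaussian and raters are not modelled.  Passing recovery tests
demonstrates the estimators are correctly implemented, not that the
clinical coding process is this clean.

### Known limits of recovery at the study's own scale

Two recovery properties are *not* attainable under the study-sized default
conditions, and the package reports them honestly rather than relaxing the
conditions:

* **Transition recovery at 3 × 55 sessions.**  Two of the seven states
  hold only ~4% of the stationary mass (~6 visits in 162 transitions), so
  their estimated rows carry sampling errors of ±0.2–0.4; the median
  max-abs error across seeds is ≈0.33.  Accurate recovery of the full
  matrix needs orders of magnitude more data (a 10⁵-step chain recovers it
  within 0.014).
* **State recovery by clustering at noise sd 0.15.**  The planted centers
  lie as close as 0.19 apart in profile space while the emission noise
  vector has norm ≈0.34 in five dimensions, so even the Bayes-optimal
  nearest-true-center rule recovers only ≈65% of labels (K-means ≈55%).
  Recovery ≥90% requires center separation of at least ~5 noise sd, which
  the package's property tests verify with well-separated synthetic
  centers.

## Problem sizes and determinism

All stochastic tests and the acceptance script derive their generators from
explicit seeds; identical seeds give byte-identical outputs (JSON reports
are written with sorted keys).  Simulation sizes used by the test suite:
10⁵ steps for estimator-consistency checks, 10⁴ for attractor/ergodicity
brute-force comparisons, 4 × 10³ for the iid-determinism closed-form check,
and ≤ 10³ segments for correlation-structure checks — small enough that the
full suite runs in well under a minute on one CPU.
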