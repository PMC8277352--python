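# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the procedure was genuinely
open.

## Data model and cleaning

A cohort is a subject × region matrix of c-Fos⁺ cell counts (averaged over
replicate 250 × 250 µm ROIs, hence continuous), one condition label per
subject from the nine-condition design (two helping-test conditions, four
social controls, chocolate, trapped, home-cage baseline), and an explicit
missing mask.

**Outlier rule.** A value is removed iff it is more than 2 group standard
deviations from its (condition, region) mean *and* lies strictly outside the
observed [min, max] of that region pooled over all *other* conditions. The
"other conditions" reading is deliberate: an extreme value trivially extends
its own condition's range, which would make the literal pooled-range clause
vacuous. The rule is single-pass with statistics computed on the original
data. It is *not* idempotent in the strict sense — removing a value shrinks
the other conditions' pooled range and can put a previously interior value
outside it on a re-run — so the contract tested is purity plus per-entry
validity of both clauses, not fixed-pointness. Group cells with fewer than 2
values have no SD and are never flagged (they are logged as skipped).
A single extreme value can only be flagged in a group of ≥ 6, since the
z-score of one point among n is bounded by (n−1)/√n.

**Imputation.** Methods that need complete data (PLS, eigen regions) receive
per-(condition, region) mean imputation; all summaries that can be
missing-aware (totals, correlations) ignore missing values instead.
Imputation preserves the condition means of observed data exactly.

## Synthetic cohorts

Counts follow a log-normal–Poisson mixture: for subject *i* (condition *c*)
and region *r* with latent module *m(r)*,

  log µ = log(baseline) + σ·(√λ·z_{i,m(r)} + √(1−λ)·ε_{ir}) − σ²/2 + log(effect(r, c)),

counts = mean of two Poisson(µ) replicate ROIs. λ (module loading) is the
log-scale within-module correlation; σ (dispersion, default 0.4 ≈ a 40%
between-animal CV) controls overdispersion; the −σ²/2 term keeps E[count] =
baseline × effect. Group sizes default to the study design: 8+8 helping-test,
8+7 brief, 8+7 two-free (the six social conditions sum to 46, giving the
F(5, 40) one-way ANOVA), chocolate 8, trapped 9, baseline 9 (brief + two-free
+ trapped + baseline = 48, the broad reference pool). The study-shaped
default plants a global helping-test elevation (ingroup ×1.5, outgroup
×1.25) plus ingroup-specific accumbens effects (shell ×1.8, core ×1.6),
mirroring the qualitative structure of the real cohort: broad task
activation, stronger for the ingroup, with selective accumbens recruitment.

Behavioral cohorts: a fixed fraction of rats (default 6/8) acquire
door-opening on a uniform random day in [2, 6] and then open every day with
latency decaying exponentially (τ = 2.5 days) from 1800 s toward a 120 s
floor, capped at the 2400 s half-way point; non-openers never open. Tracks
are heading-persistent random walks with reflecting walls, optional bias
toward the restrainer zone, mean speed 5.4 cm/s, and an optional teleport
artifact rate for exercising the velocity filter.

Photometry: both channels share a slow exponential drift and a smoothed
motion artifact; the 470 nm channel adds event-locked double-exponential
transients (rise 0.2 s, decay 1.5 s) and independent noise. Ground truth
(event times, amplitude, expected ΔF/F peak) is returned alongside.

What the generator does *not* emulate: biophysical GCaMP kinetics,
hemodynamic-like slow confounds, spatially structured ROI noise, non-random
missingness, or inter-day behavioral correlation beyond the acquisition
model. Passing recovery tests therefore demonstrates that the algorithms
recover the planted statistical structure at study sample sizes, not that
they are robust to every failure mode of real histology or photometry.

## Statistics

Cochran's Q and Friedman's test are computed from their closed forms;
Friedman applies the tie correction (capped latencies tie heavily by
construction — non-opening days are encoded at the 2400 s cap). Degenerate
inputs (all rows constant) return statistic 0, p = 1, flagged. The unpaired
t-test uses pooled variance (Student's: the reported df of 14 at 8 + 8
implies pooled, not Welch). Wilcoxon signed-rank uses the exact null for
n ≤ 25 and the continuity-corrected normal approximation above. Pearson
correlations are uncorrected for multiplicity by design (the study's
explicit choice for the 45-region correlation analyses); Bonferroni and
Šidák corrections are available where ANOVAs need post-hoc tables.
`opener_power` enumerates all (k₁, k₂) binomial outcomes and applies a
one-sided Fisher exact test — direction is pre-specified by the hypothesis
that ingroup-tested rats open more — giving exact design power
(≈ 94% at n = 8, p₁ = 0.7, p₂ = 0, α = 0.05).

## Task PLS

Row *c* of the analysis matrix is the mean region profile of condition *c*;
columns are centered by the unweighted grand mean of condition means
(conditions have unequal n, and the contrast is over conditions, so each
condition counts equally). Permutation reassigns subjects to conditions
without replacement keeping group sizes; p = (#{s_perm ≥ s_obs} + 1)/(n_perm
+ 1), so p is never 0 and its minimum is 1/(n_perm + 1). The bootstrap
resamples subjects with replacement within condition; a resample that leaves
fewer than two distinct subjects in a condition (when the pool allows two) is
redrawn and logged. Because SVD signs and near-degenerate LV orders are
arbitrary, each bootstrap solution (V·S) is aligned to the observed one by an
orthogonal Procrustes rotation before the SE is taken; the bootstrap ratio is
observed salience / bootstrap SE, thresholded at 2.57 — the 99% two-sided
normal quantile Φ⁻¹(0.995) = 2.5758 truncated to two decimals.

## Co-activation networks

Correlations are pairwise-complete; any pair with fewer than 3 shared
subjects is invalid and excluded from ranking. Edges are the top
`threshold_frac` of valid pairs ranked by |r| — magnitude ranking keeps
negative co-activations as (dashed-line) edges, with the sign stored as an
attribute; ties at the cutoff are all retained and the realized fraction
logged. Retained edges are binarized for all graph metrics (degree,
betweenness, clustering, path length).

The scale-free topology index bins positive degrees into up to 10
equal-occupancy bins over distinct degree values (84-node graphs have sparse
degree histograms), converts bin frequencies to densities by the
midpoint-edge widths, and regresses log₁₀ density on log₁₀ mean degree:
index = R² × sign(−slope), positive for decaying distributions. Graphs with
fewer than 3 occupied bins report the index as undefined with a reason —
never as 0. A deliberate caveat: for a *symmetric* (binomial) degree
distribution the log–log slope is genuinely near zero, so the index hovers
around 0 with either sign; the index separates scale-free from dense-random
graphs by magnitude, not reliably by sign.

Percent connectivity is the percentage of non-isolated nodes (network
density is computed separately, so the two quantities stay distinct).
Small-worldness follows the standard random-reference normalization:
σ = (C/C_rand)/(L/L_rand) on the largest connected component, with C_rand
and L_rand averaged over 100 Erdős–Rényi G(n, m) graphs matched in node and
edge count (largest-component convention for disconnected instances,
logged). The threshold sweep recommends the smallest fraction with a
defined, positive scale-free index and percent connectivity at or above a
configurable floor (default 50%).

Hubs are the intersection of the top-⌈0.2·N⌉ regions by degree and by
betweenness, with boundary ties included and logged. Louvain runs with an
explicit seed; an edgeless graph degenerates to singleton communities.

## Ensemble eigen-region procedure

The default grid is the full factorial 5 thresholds {5, 10, 15, 20, 25%} ×
2 clusterings × 2 weightings × 2 references = 40 configurations. Clustering
operates on counts pooled over the compared and reference conditions — the
partition must be condition-agnostic because every subject needs a cluster
score. Under binary weighting retained pairs carry weight 1; under soft
power they carry |r|^β, with auto-β the smallest integer in [1, 20] whose
weighted-connectivity profile reaches a scale-free fit of 0.8 (fallback 6,
logged). The threshold applies to both clusterings: for the dendrogram path
the similarity of non-retained pairs is zeroed before the dissimilarity
1 − S is built, so the factorial grid stays meaningful for hierarchical
clustering too.

The dynamic tree cut is a simplified dynamic-hybrid variant implemented on
scipy average-linkage dendrograms: a static cut at 99% of the maximum merge
height, then minimum-cluster-size enforcement (size 3) — members of
undersized branches join the nearest surviving cluster when their mean
dissimilarity to it is within the cut height, otherwise they fall into an
"unclustered" pseudo-cluster excluded from regression. Louvain communities
below size 3 are treated the same way.

Eigen regions: regions are z-scored across subjects and each cluster's first
principal component score is taken per subject, with the sign fixed so the
score correlates positively with the cluster's mean z profile; singleton
clusters pass their z-scores through, zero-variance regions are dropped with
a warning. Note that z-scoring across *all* pooled subjects compresses a
planted condition shift by the between-class variance it adds to the
denominator — a real property of the procedure, visible in the recovery
tests.

Each cluster's eigen region enters its own 3-class multinomial logistic
regression (intercept + score; reference class = reference group), fit by
Newton iterations with a ridge stabilizer λ = 1e−4 against separation —
small enough to perturb finite coefficients well under 0.1%. One regression
per cluster rather than a joint fit: with 23–64 subjects and potentially
more than ten clusters a joint multinomial would be ill-posed.

**Inference choice.** Per-contrast p-values default to the profile
likelihood-ratio test, with Wald p-values reported alongside and selectable.
The reason is the Hauck–Donner effect: at the baseline-reference group sizes
(8/8/9) the Wald z statistic *never* exceeds ≈ 2.3 no matter how large the
true effect is — as separation approaches, the coefficient grows but its
estimated SE grows faster — so after the Bonferroni correction over clusters
× 2 contrasts half of the configuration grid would have zero power at any
effect size. The LRT does not collapse (power 0.85–0.96 at standardized
effects of 2–2.5 under the same correction) and its null rejection at the
corrected threshold stays at or below nominal. Bonferroni uses m = clusters
× 2 contrasts within each configuration. Non-converged clusters count as
"none"; so do unclustered regions.

Tallying: each region inherits its cluster's category per configuration;
the four per-region counts always sum to the number of configurations, and
the tally is invariant to configuration order.

## Photometry

ΔF/F = (s470 − OLS fit of s405 → s470)/median(s470), with the fit over the
whole session (one session, one fit). The OLS residual property makes the
*mean* of the corrected trace zero — the median of ΔF/F is not guaranteed
zero and is not asserted. The correction passes the control channel's noise
through with the fitted gain, so the corrected noise floor is
noise_sd·√(1 + gain²), and with dense event trains the mean transient level
is absorbed into the fit — PSTH amplitudes are referenced to the session
mean, which matters only when events occupy a non-negligible fraction of the
session. A constant control cannot carry artifact information: the fit
degenerates to mean subtraction with a warning. Zone entries are 0→1
transitions of the in-zone flag (a configurable minimum re-entry gap defaults
to 0); events whose ±10 s window leaves the session are dropped, not padded.
The pre/post test averages ΔF/F over [−1, 0) and (0, +1] per event and runs
Wilcoxon signed-rank across events — the per-event pooling mode is the
default (a per-session mode is available), matching a pooled n of ~83
entries. The in-zone/out-of-zone comparison is the two-level
repeated-measures case, computed as a paired t with F = t² reported.

## Behavior

Openers are rats that opened on *all* of the final three testing days (a
latched final c-Fos day is marked and skipped); the strict reading of
"consistently" is adopted. Latency on non-opening sessions is the 2400 s
half-way cap, applied uniformly, which is also why Friedman's tie correction
is mandatory. The velocity filter removes samples whose speed from the last
*retained* sample exceeds 30 cm/s, walking the track sequentially so a
single teleporting sample removes exactly itself and gaps are differenced
across, never interpolated; the reported velocity measure uses central
differences on the filtered track. Zone containment is half-open
([x₀,x₁)×[y₀,y₁)) so adjacent zones partition the arena; starting inside the
zone is not an entry; time-in-zone attributes each inter-sample interval to
its starting sample, making time-in + time-out equal the session duration
exactly. Per-day/per-minute tidy tables are exported for external
mixed-model tooling; mixed models themselves are out of scope.

## Tracing

Co-label percentages are 100 × colabel/FG per (rat, region); FG = 0 rows are
excluded (logged), not reported as 0%. The opener vs non-opener comparison
uses a cell-means two-way layout: the group main effect is tested against
the within-(group × region) residual with F(1, N − 2g) (unweighted marginal
means, harmonic-mean cell size for unbalanced data), and per-region
contrasts are pooled t-tests with Šidák correction. With one region the main
effect reduces exactly to F = t².

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from one global seed via a stable CRC of the stage name, so
stages stay reproducible under grid changes. The test suite runs its
simulation-based checks at deliberately chosen sizes: null calibrations at
500–800 replicates, recovery suites at 10–30 seeds with study-scale group
sizes, the ensemble recovery at 30 regions, and the exhaustive oracles
(sign-flip enumeration, all-shortest-path betweenness) at n ≤ 10 nodes or
events where enumeration is exact. The acceptance script runs the full
84-region, 9-condition pipeline with 500 permutations and 500 bootstraps.

## Known limitations

- The 40-configuration grid is a reconstruction of the factorial the study
  describes (its exact parameter file is not public); the grid is fully
  overridable.
- The dynamic tree cut is a simplified variant, not a port of the reference
  hybrid algorithm; on well-separated modules the two agree (the recovery
  tests assert ARI > 0.7), but borderline branch assignments can differ.
- The scale-free index's sign is uninformative for symmetric degree
  distributions (see above).
- Printed-statistic reproduction on the study's deposited tables requires
  those tables; the package computes every headline statistic from any
  counts CSV in the documented layout, and the acceptance script reports the
  synthetic-cohort analogues.
- With fewer than ~6 subjects per condition the bootstrap and the ensemble
  regressions are fragile; errors and redraw logging make this visible
  rather than silent.
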