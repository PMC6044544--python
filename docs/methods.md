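# Methods

## The analysis model

The pipeline quantifies the strength of individual memory representations
as the *neural representation score*: the mean Pearson correlation between
a memory's trial patterns across different scanning sessions, minus the
mean correlation between that memory's trials and the trials of the other
memories of the same 8-memory set (all pairs cross-session).  Splitting the
16 memories into two sets — one memory per age in each — keeps the
between-memory baseline within a set and leaves the identically aged
memory of the other set available as a *matched-age* baseline variant.
Per-memory scores are averaged over the two memories at each age, giving
one subject × age score table for group inference.

Two deliberate fidelity choices: raw correlations are averaged without
Fisher z-transformation (a `fisher` switch exists), and memory-level
similarity is the mean over cross-session trial pairs, not the correlation
of session-averaged patterns.

### Trial patterns and noise normalisation

Trial betas come from session GLMs with boxcar regressors over the
12-second recall window convolved with the canonical double-gamma HRF
(via nilearn's regressor builder).  The default estimator is
least-squares-separate (one GLM per trial with a single regressor for all
other trials), which tolerates overlapping responses; least-squares-all is
available and always supplies the residuals.  Residuals from each session
are centred, their covariances averaged with equal weights (sessions are
equal length), and shrunk toward the diagonal,
Σ̂ = (1−λ)S + λ·diag(S).  λ defaults to the analytic
(Schafer–Strimmer-style) intensity — the ratio of summed sampling
variances of the off-diagonal entries to their summed squares — and is
floored at 0.9 when the pooled residual row count is at most a tenth of
the voxel count.  Patterns are whitened by the symmetric inverse square
root of Σ̂ (eigenvalues floored at 1e−10 × max for invertibility).
The scoring stage also accepts precomputed patterns directly, since the
scientific core starts at whitening.

### Group statistics

Repeated-measures ANOVAs use the full within-subject sums-of-squares
decomposition, matching classical statistical-package output.  Mauchly's
test (first-order chi-square approximation) gates the Greenhouse–Geisser
correction at p < .05; when it rejects, both degrees of freedom are
multiplied by ε̂ from the covariance of orthonormal condition contrasts.
In the two-way (experiment × age) ANOVA with a 2-level first factor, the
age effect's ε comes from the level-averaged table and the interaction's
from the level difference.  An effect sum of squares below 1e−12 of the
total is treated as exactly zero (F = 0, p = 1) to keep identical-input
edge cases exact.  ICC(2,1) — two-way random effects, absolute agreement,
single measure — is computed from the mean squares.  Cousineau
normalisation (cell − subject mean + grand mean) underlies the
within-subject error bars.

### Prediction shift

The follow-up scan happens 8 months after the first, i.e. two positions
along the sampled age grid (0.5, 4, 8, …, 24, 60 months).  The predicted
follow-up profile shifts the first-scan group means two grid positions
forward; ages shifted past the penultimate sampled age (28 and 32 months)
saturate at the 24-month level, and the most remote age is assumed
unchanged at 68 months.  Each original age receives a directional
hypothesis from the sign of (predicted − original); by default only exact
ties (the saturated boundary ages, or deliberately equal profile values)
count as "no change" — a tolerance argument widens that band.  Hypotheses
are tested with paired t tests, one-tailed for hypothesised changes;
"no change" is operationalised as failure to reject at α = .05 (a TOST
equivalence option was considered and left out of scope; the two-sided
non-rejection rule is what the narrative logic of the design uses).

### Searchlight and cluster inference

Regions grow around every ROI voxel by taking the `target` (default 160)
nearest ROI voxels in Euclidean distance, ties broken by ascending linear
index (0-based, x-fastest) so growth is deterministic and hits the target
exactly; ROIs smaller than the target return whole and flagged.  Within a
region the memory RSM is built per set (8 × 8) exactly as in the whole-ROI
analysis, its lower triangle *including the diagonal* is rank-correlated
(Spearman) with the identity model RSM — the model's informative entries
are its ones on the diagonal — and the two sets' correlations averaged.
Each voxel's map value is the mean over all regions containing it.
Group inference sign-flips whole subject maps: clusters are 26-connected
components of voxels with one-sample t ≥ 3, the null is the distribution
of maximum cluster size over random sign assignments (identity included,
so corrected p ≥ 1/n_perm), and cluster p is the proportion of null maxima
at least as large.

A property worth knowing: under pure noise the model-RSM Spearman score
has a small *negative* expectation (here roughly −0.02 to −0.09, growing
as effective dimensionality falls).  It is not an implementation bias —
with independent RSM entries the expectation is zero — but a consequence
of RSM entries sharing trials, which couples the ranks of diagonal and
off-diagonal cells.  Because group inference is by sign-flip permutation
on the empirical maps, a common negative offset under the null makes
positive-effect inference conservative rather than invalid.

## The synthetic cohort

The generator emulates the study conditions: 30 subjects (16 at
follow-up), 16 memories = 2 sets × 8 ages, 6 repetitions across 12
sessions of 8 trials, alternating set-A-only and set-B-only sessions —
the simplest layout satisfying "no memory twice per session" and
"same-age memories never together".  A trial pattern is

    amplitude(age) · memory_signature + w_shared · common_vector + noise,

with unit-norm signatures drawn once per memory (reused at follow-up, so
the second scan measures the same representations), a common retrieval
component (default weight 0.3) shared by every trial, and Gaussian noise
smoothed along the voxel axis (σ = 1.5 voxels, rescaled to marginal SD
1.0) so the covariance is non-diagonal and the whitening stage has
structure to exploit.  Session residuals are drawn from the same noise
process.  Vividness ratings are i.i.d. with P(5)=.55, P(4)=.35, P(3)=.06,
P(2)=.03, P(1)=.01, which under the default exclusion threshold (ratings
< 3 dropped) retains about 5.4 of 6 trials per memory, matching the
5.2–5.6 retained in the design this emulates.  The default amplitude
profile (0, .6, .7, .9, .3, .1, 1.0, .9) encodes the hypothesised
nonmonotonic consolidation time course — undetectable at 0.5 months,
rising over the first year, dipping at 16–20 months, strong at 24–60 —
as a simulation input, not an empirical claim.

What the generator does *not* emulate: haemodynamic realism beyond the
boxcar+HRF option, physiological or motion artefacts, temporal
autocorrelation, between-session signal drift, and anatomical structure.
Passing recovery tests therefore show the pipeline's statistical machinery
is correct and calibrated under its own assumptions; they cannot certify
behaviour under real-scanner artefacts.

One interaction deserves note: with a nonzero shared component and
heterogeneous amplitudes, a zero-amplitude memory acquires a slightly
positive expected score at low noise, because other memories' signal
variance dilutes their shared-component correlations more than its own.
At the default noise level (SD 1.0, the regime the README example uses)
the effect is far below detection threshold; null-calibration tests set
the shared weight to zero so the null is exact.

## Simulation sizes and tolerances

Calibration and recovery suites run at sizes chosen to give tight
Monte-Carlo error while keeping the default test run short: the null
calibration of the detectability t test uses 1,000 simulated groups of 8
subjects × 24 voxels (rate asserted at 0.05 ± 0.02); cluster FWE
calibration uses 500 null datasets of 12 smoothed-noise maps on an 8×8×8
ROI with 1,000 permutations each; profile recovery uses 20 cohorts of 10
subjects; the prediction-shift power check uses 20 two-experiment cohorts
of 16 subjects.  "High SNR" in recovery suites means noise SD 0.25 with
120 voxels — chosen by a power analysis as the regime in which the
design's effects are reliably detectable at the study's sample sizes.
Oracle-equivalence tests compare against brute-force enumeration (pairwise
similarity, rank formulas, complete sign-pattern enumeration) or against
pingouin/statsmodels at 1e−10; Mauchly p values are compared only to 0.01
because pingouin uses a higher-order chi-square correction.

## Known limitations

- Mauchly's test is undefined for n − 1 < k − 1 subjects; the code then
  reports W = NaN and conservatively applies the GG correction.
- The searchlight recomputes region membership per centre (O(V²) sorting);
  fine for partial-volume ROIs at this scale, not tuned for whole-brain.
- The LSS estimator refits one model per trial; for very long sessions the
  LSA mode is the practical choice.
- Scores are means of correlations; no variance weighting across pairs is
  attempted, matching the method being implemented.
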