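# Methods

This note documents the models, conventions and numerical choices behind
`nirsprune`, and what the synthetic cohorts can and cannot say about real
infant fNIRS data.

## Quality metrics

**Conventions.** All standard deviations are *population* (ddof = 0) unless
noted; the statistical stage's z-scoring (see below) uses the sample sd
(ddof = 1), matching the usual definition of a standardised regression
variable. Analysis windows are 0-based, half-open, non-overlapping sample
ranges of `round(window_s × fs)` samples starting at sample 0; a trailing
partial window is discarded. Default window length is 3 s.

**CV** is `σ/|μ|` of the raw intensity; a zero-mean signal returns `inf`.
**SNR** is `20·log₁₀(μ/σ)` dB and requires a positive-mean intensity
signal; `σ = 0` returns `inf`.

**Cardiac bandpass.** A 3rd-order Butterworth bandpass (default
1.3–3.2 Hz, the infant resting heart-rate band) applied forward-backward
(`sosfiltfilt`, zero phase). The filter is pinned by its contract, not its
name: ≤1 dB loss at band centre, ≥20 dB attenuation one octave outside
either edge — the tests measure both.

**SCI** is the zero-lag cross-correlation of the two wavelengths'
bandpassed, per-window normalized signals, i.e. the Pearson correlation of
the filtered window pair. It is symmetric in wavelength order and invariant
to positive rescaling.

**PSP.** The biased cross-correlation sequence of the two normalized
window signals (`ρ[k] = (1/n) Σ x̄λ1[t]·x̄λ2[t+k]`, lags −(n−1)…n−1) is
Hamming-windowed; its discrete amplitude spectrum is scaled so that a
perfectly coherent unit-variance sinusoid pair has a unit-amplitude cosine
cross-correlation, and PSP is the *peak power* `A²/2` of that spectrum:
0.5 for perfect coherence at a bin frequency, ~0.01 (median) for white
noise at n = 30. The peak search runs over the full discrete spectrum —
the input is already cardiac-bandpassed, so restricting the search to the
band changes little; this definition is this package's contract, fixed by
an independent brute-force oracle (explicit lag-by-lag cross-correlation
plus a direct DFT) that the implementation must match to 1e-9. On this
scale the conventional threshold grid 0.005–0.1 spans the transition from
incoherent to clearly cardiac content.

**Degenerate windows** (zero variance, e.g. saturated flat-lined data)
count as *failing* windows in the good-window fraction, not as missing:
flat data is bad data. A threshold of exactly 0 disables that test — this
is precisely how the SCI-only pruning variant is defined (PSP threshold
forced to 0), and it keeps the vacuous-threshold limit well defined for
SCI, which can be negative.

## Motion detection and clean windows

Detection operates on optical-density change `dOD(t) = −ln(I(t)/mean(I))`
per wavelength; the conversion is isolated in one function so the working
space could be toggled. A sample is flagged when any sliding window of
`tMotion` = 1 s covering it has a range (max − min) exceeding
`AMPthresh` = 0.4 *or* `STDEVthresh` = 15 × the whole-series standard
deviation of the sample-to-sample differences. Flags are dilated by
`tMask` = 1 s on each side, truncated at the recording edges; a flag on
either wavelength flags the channel, and a 3-s window is clean only if it
contains no flagged sample at either wavelength. The whole-series (not
windowed) σ anchors the variance criterion. The implementation is pinned
against an exhaustive brute-force scan; note that under this rule a short
rectangular excursion is flagged over roughly its own extent plus the
detection-window reach (~1 s) plus the mask on each side.

**PoM** (percentage of motion) is the mean over acceptable (non-CSE)
channels of the percentage of windows containing motion.

## Pruning procedures

- **CSE** ("channels with signal extrema"): a channel whose minimum raw
  intensity over samples and wavelengths is strictly below 3e-4 is
  excluded before any analysis; independent of motion masks, idempotent.
- **CV pruning**: per non-CSE channel, CV per wavelength on the
  *concatenated clean windows* (the closest reading of "computed on
  motion-free data"); pruned when the absolute difference strictly exceeds
  0.2. The strict boundary is deliberate and toggleable (`inclusive=True`)
  because descriptions of this rule vary between "exceeds" and "20% or
  more"; the boundary case is pinned by a test.
- **SCI/PSP pruning**: retained iff the fraction of clean windows passing
  both thresholds is ≥ `q_threshold` (default 0.75). Channels with zero
  clean windows are pruned with their own status code — a channel with no
  evaluable data cannot be certified.

## Sweep, matching, trade-off

The sweep grid defaults to sci 0.05–0.90 (step 0.05) × psp 0.005–0.100
(step 0.005), 360 combinations, plus SCI-only rows (psp = 0) and one CV
row per participant. Per-window SCI/PSP are computed once per channel and
re-thresholded across the grid. Participants are flagged excluded when CR
falls below 60% of their acceptable channels — a descriptive cut exposed
as configuration, since no canonical exclusion rule exists.

Retention matching ranks grid points by |mean CR − mean CR_CV| and by
|#excluded − #excluded_CV|, averages ties within each ranking, sums the
two ranks, and selects the minimum; remaining ties resolve toward lower
(sci, psp), consistent with recommending the least aggressive thresholds.
Rank-sum is a deliberate choice where the aggregation was genuinely open.

The trade-off tool reduces grid points to group means, fits an isotonic
(monotone) trend of mean TRC SNR against mean CR — monotonicity is the
contract; no particular smoother is claimed — and recommends the points
with the largest positive residual, ties preferring higher retention.

## Statistical stage

One row per participant × method at the retention-matched parameters
feeds the method model `outcome ~ method + (1|participant)`; each pairwise
contrast is estimated on its two-method subset and Wald p-values are
Bonferroni-multiplied by the number of contrasts (default family m = 3 per
cell; the family size is configurable since a study-wide family is equally
defensible). The full model's fixed effects are
`SCI*PSP + Age*SCI + Age*PSP + SCI*PoM + PSP*PoM + Age*PoM + Task +
Cohort + CSE` with random intercepts for participant and for the
SCI×Cohort and PSP×Cohort groupings, expressed as variance components
within the participant grouping (statsmodels' MixedLM supports only
nested components; the bootstrap inference does not rest on the exact
random-effects covariance). Age enters as a scaled numeric predictor by
default, with a categorical option. All numeric variables including the
outcome are z-scored (`(x − x̄)/s_x`, sample sd); a recovered coefficient
therefore lives on the scaled-outcome scale, β_scaled ≈ β_raw·s_x/s_y.
Degenerate variables (no variation in the data at hand, e.g. a single-task
cell or a cohort with no CSE channels) are dropped from the formula
together with the terms containing them rather than fitted as singular
columns.

Model residuals on data of this kind are non-normal, so the primary
inference is a percentile bootstrap over rows (resampled with replacement,
fixed seed; default n_boot = 1000, reducible): estimate = bootstrap mean,
CI = 2.5/97.5 percentiles, SE = bootstrap sd. Model-based Wald p-values
are carried as diagnostics only. Identifiability caveat: between-participant
predictors (age, cohort, PoM, CSE) need clearly more participants than
between-participant terms; with very small cohorts those estimates are
noisy even when finite.

## Synthetic cohorts

Each channel's intensity per wavelength is
`baseline · exp(−artifact_dOD) · instability · (1 + a(c)·cardiac + response
+ drift + noise)` with:

- **cardiac**: sinusoid plus a 20% second harmonic (so the PSP peak is not
  trivially the only spectral line), unit variance, frequency drawn from
  the interior of the infant band per recording; modulation depth
  `a(c) = 0.015·(0.2 + 0.8c)` of baseline, linear in the coupling quality
  c ∈ [0, 1]. Wavelength 2 receives `c·cardiac + (1−c)·independent`
  band-limited noise, so cross-wavelength coherence — hence SCI/PSP — is
  controlled by c, and c = 1 with zero noise gives SCI = 1 exactly.
- **instability**: multiplicative low-frequency (<0.5 Hz) fluctuation with
  amplitude `0.4·(1−c)²·U(0.3, 1)`, drawn independently per wavelength.
  This is the mechanism that ties coupling quality to intensity-domain SNR
  and gives CV-difference pruning something to bind on: badly coupled
  optodes wander, differently per wavelength.
- **drift**: <0.1 Hz sinusoid, ≤1% of baseline — keeps the CV of clean,
  well-coupled channels small and stable.
- **motion**: `round(rate·minutes)` events (deterministic count, so event
  counts are exactly controllable; onsets, kinds and amplitudes random) of
  two kinds, Gaussian spikes and box-car baseline steps, applied in dOD
  space with amplitudes defaulting to 0.3–1.2 dOD. The artifact taxonomy
  of real infant motion is not established; spikes and steps are a
  modelling choice.
- **CSE channels**: baseline 2e-4, below the 3e-4 floor.
- **evoked response**: canonical-shaped gamma HRF on a 30-s block design
  (10 s on) in the designated task-relevant channels, default 1% of
  baseline.

Cohorts draw a per-participant mean coupling (logit scale, scatter 0.6)
and motion rate (log scale, scatter 0.5), carrying injectable
age/cohort/task/motion effects recorded in the ground truth; channel
couplings scatter around the participant mean (Beta, concentration 8).
Per-participant random streams derive deterministically from the master
seed and the participant's design cell, so cohorts are reproducible under
subsetting. Default conditions mirror the study design: 34 channels, 10 Hz,
780/850 nm, ages {5, 8, 12, 18, 24} months, cohorts {Gambia, UK}, tasks
{HaND, SNS}.

For validating the statistical stage in isolation there is additionally a
*row-level* generator (`simulate_analysis_table`) that draws analysis rows
directly from the linear model with known coefficients, participant
intercepts and threshold-by-cohort components — the signal-level generator
cannot inject an exact coefficient on a derived outcome like TRC SNR.

**What passing tests do not show.** The generator emulates the statistical
structure the pruning analysis assumes — coherence governed by coupling,
motion that degrades quality, wavelength-asymmetric instability — not the
optics of a real instrument or real infant behaviour: no optode-geometry
forward model, no physiological systemic components (respiration, Mayer
waves), no heart-rate variability within a recording, and a stylised
artifact taxonomy. Results on synthetic cohorts validate the machinery and
the directional behaviour of the methods, not empirical threshold values
for any particular instrument or population.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: recordings of
60–120 s (a real session is ~20 min), cohorts of 6–12 participants,
replicate counts of 10–20, and bootstrap n_boot 100–200 (the package
default is 1000). The quantities involved — window metrics, retention
counts, rank matching — are unaffected by duration beyond sampling noise,
and every stochastic test fixes its seeds.
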