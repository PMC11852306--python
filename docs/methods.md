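# Methods

This note documents the models and procedures implemented in `bpci`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions a maintainer would want written down.

## Signal model and preprocessing

Input records carry three synchronized channels — PPG, ECG and invasive
arterial pressure (ABP) — at a common sampling rate (125 Hz by default).
Analysis uses one 20 s window per record, cut after a 60 s settling offset
(the offset is configurable; nothing in the method depends on its exact
value). Reference labels with SBP ≥ 200, SBP ≤ 70, DBP ≥ 150 or
DBP ≤ 40 mmHg are excluded as outliers before any model sees them.

**Stage 1 (denoising).** Each channel is decomposed with an undecimated
(maximal-overlap) db8 wavelet transform to level 10, via PyWavelets' SWT
with per-level normalization and reflection padding to a multiple of
2^10. Detail levels d7–d10 and the approximation a10 — everything below
roughly 0.5 Hz at 125 Hz — are zeroed; details d1–d6 are shrunk by
empirical-Bayes posterior-median thresholding under a quasi-Cauchy
spike-and-slab prior. The mixing weight per level is found by marginal
maximum likelihood; the posterior median is solved by vectorized bisection
on the closed-form zero function. The noise scale is estimated from the
MAD of d1 (the finest level is essentially noise for these band-limited
signals) and propagated to deeper levels as σ_j = σ_1·2^(−(j−1)/2), the
white-noise decay of the normalized undecimated transform. A zero-phase
Butterworth high-pass at 0.5 Hz follows; its order is mapped linearly from
a "steepness" parameter S ∈ [0.5, 1] to 4–12 (S = 0.5 → order 4). Zero-phase
(forward–backward) application is the default so fiducial timing is not
shifted; a one-pass causal mode exists behind a flag.

*Caveat:* the level discard plus high-pass is a linear band cut whose
transition spans roughly 0.5–1 Hz. Pulse fundamentals near 1 Hz
(heart rates at or below ~60 bpm) are partially attenuated, and each
re-application attenuates them again, so the chain is only approximately
idempotent for slow rhythms. Morphology features ride on the harmonics and
are unaffected in practice.

**Stage 2 (landmarking).** R peaks are detected on a sym4 level-4
reconstruction keeping only d2+d3 (an ~80 ms QRS concentrates there at
125 Hz), with a three-point local-maximum test against an adaptive
threshold — 0.5 × the 98th percentile of the rectified reconstruction per
2 s block — and a 0.3 s refractory period that keeps the larger of two
competing candidates. Neither the threshold fraction nor the block length
is critical; both are configurable. PPG pulse feet are first located as
minima between systolic peaks and then refined by walking back from the
maximum-slope point to the start of the upstroke, which is sharper than a
wide diastolic valley and insensitive to heart rate. The dicrotic
inflection is the first smoothed second-difference sign change on the
falling limb (curvature below 10⁻⁶ of the pulse amplitude counts as flat);
a pulse without one falls back to the 66 %-decay point and is flagged.
Trusted windows are cut into beat-anchored segments of round(1.4 × fs)
samples, one per pulse foot, capped at 13; fewer than 10 viable segments
rejects the window (as a recorded reason, not an exception).

## Signal-quality index

Three rhythm rules are checked on both channels' peak trains and both must
pass: extrapolated heart rate (beat count scaled to 60 s) within
40–180 bpm; no inter-peak interval above 3 s; max/min interval ratio below
2.2 (the ratio is unitless). Any failure short-circuits. Otherwise each
beat — a window of width equal to the median beat interval centered on its
peak, edge-truncated beats excluded — is correlated with the average-beat
template, and the window is `trusted` iff the mean of the PPG-pulse and
QRS correlation means reaches the threshold.

The correlation threshold (default **0.8**) is the single largest constant
the quality-index recipe leaves open; it is exposed prominently in the
config. Note a structural property of template matching: it measures
*regularity*, not correctness — a window whose every pulse is identically
inverted self-matches perfectly and passes. Only heterogeneous corruption
(a minority of deviant beats, broadband noise, rhythm breaks) is caught,
which is the intended scope of the check.

## Features and dataset

Each accepted segment yields 47 features (timing: ST, DT, CT, IBI, HR,
PAT1–3; shape: PIR, LASI, AUI, PPGk, MXAP, MIAP, MEU, FHR, first/second
derivative landmarks; areas A1–A4, IPAR, SA, DA, areaPPG; widths SW/DW at
10/25/33/50/66/75 % of pulse amplitude; spectral/statistical MPSD, MCORR,
skewness, kurtosis, entropy). Amplitude features are computed on pulses
shifted so their minimum is zero, with intensity ratios (PIR, MXAP, MIAP)
referenced to the window-level baseline, which makes every feature
invariant to adding a constant to the PPG. Width features read the stated
fractions as amplitude fractions (horizontal cuts through the pulse), on
the rising limb for SW and falling limb for DW.

Decisions where the definitions were genuinely open:

- **PTT** is operationalized as PAT2 minus a configurable pre-ejection
  constant (default 0). A cuff-less system has no aortic-valve signal, so
  the R peak stands in for ejection; PAT1–3 are the measurable transit-time
  proxies and PTT is exposed as a derived quantity, not a 48th column.
- **MEU** ("blood viscosity") is implemented as the log-amplitude decay
  rate from the systolic peak to the dicrotic inflection, and **FHR** as
  the dominant periodogram frequency of the pulse. Both are provisional
  operationalizations of under-specified quantities.
- **Entropy** is Shannon entropy of a 16-bin amplitude histogram of the
  normalized pulse.
- **MCORR** (max normalized PPG–ABP cross-correlation) needs the reference
  channel and therefore exists only at training time; at inference it is
  imputed by the training median. Because it touches the label source it
  is leakage-sensitive and can be dropped entirely (`drop_mcorr`).

Reference SBP/DBP per segment are the means of per-beat ABP maxima and
inter-beat minima. Rows are split 80/10/10 into train/validation/test,
either per-row or keeping each subject's rows together; the split is
deterministic in the seed.

## Feature selection (MRMR + WFD)

Mutual information is estimated by a plug-in estimate on an equal-frequency
10 × 10 contingency table (rank-based binning: deterministic, fast, and
invariant to monotone rescaling; the bin count is exposed). Zero tests on
estimated MI use a 10⁻¹² tolerance. The MRMR ranking proceeds in phases:
most-relevant feature first; then any relevant features with zero
redundancy to the selected set, by relevance; then remaining relevant
features by the quotient MIQ = relevance / mean redundancy; zero-relevance
features are appended in ascending index (a seeded shuffle restores a
randomized order where exact fidelity to a randomized step matters).

The weighted feature decision scores every prefix of the ranking (sizes
p down to 1) by 5-fold cross-validated gradient-boosting MSE and selects
the prefix with the smallest mean CV error, ties to the smaller size. One
CV partition is shared across all sizes — re-partitioning per size adds
comparison variance without benefit — with per-size repartitioning
available behind a flag. Selection runs independently for SBP and DBP.

## Gradient boosting (GBA)

Squared-error stagewise boosting, written from first principles: F0 is the
target mean; each of M = 50 stages fits a depth-2 regression tree to the
residuals. The split criterion is the weighted two-sided SSE over
midpoints of sorted unique feature values, with leaf values the weighted
means of each side; the exact line-search step for squared loss with mean
leaves is 1, applied with shrinkage ν (default 0.1). Ties between
equal-SSE splits break toward the smallest feature index, then the
smallest threshold, so fits are bit-reproducible. A leaf also forms when a
side would fall below the minimum leaf size (5) or all feature values
coincide. No row or feature subsampling is used; the seed argument is
threaded but unused in the default configuration.

## Gaussian-process regression

Exact GPR with the exponential kernel by default
(k = σ_f² exp(−‖x−x′‖/η)); the squared-exponential is available. The
signal variance σ_f² is a hyperparameter separate from the noise variance
σ² — conflating them degenerates the marginal likelihood. The length scale
is isotropic. Inputs are standardized per column; with no explicit basis
the targets are centered internally and the mean added back at prediction
(numerically equivalent to a constant basis with fixed weight, and it
keeps a zero-mean prior sensible for ~120 mmHg targets). With a constant
or linear basis the weights w are profiled in closed form (generalized
least squares) at every objective evaluation.

Fitting maximizes the profiled log marginal likelihood over
(log η, log σ², log σ_f²) by L-BFGS-B with analytic gradients (valid at
the profiled ŵ by the envelope theorem), from data-driven starts
(η₀ = median pairwise distance, σ²₀ = 0.1·var y, σ_f²₀ = var y) plus
seeded perturbed restarts (default 5 in the library, 3 in the pipeline).
All solves go through a Cholesky factorization with jitter escalation;
no explicit inverses. Predictions return the posterior mean
β(x*)ᵀw + Σ φᵢ k(x*, xᵢ) and variance k(x*,x*) + σ² − k*ᵀ(K+σ²I)⁻¹k*.
The MAE-optimal point prediction is the posterior median, which for this
Gaussian predictive equals the mean — implemented as stated, coincidence
documented here.

A known identifiability note: with the exponential kernel, η → 0 makes K
approach σ_f²·I, so on structureless data the split between σ² and σ_f²
is arbitrary (the smooth kernel does not have this degeneracy). This is a
property of the model, not the optimizer.

## Per-subject uncertainty

Each subject contributes ~10–13 segment-level estimates from one window.
Four interval constructions are built per subject and target:

- **gpr** — mean ± z·(mean predictive SD), the model's own interval;
- **boot** — parametric bootstrap: Gaussian MLE (μ̂, σ̂ with n
  denominator), an n×B matrix of redraws μ̂ + σ̂·z, column means sorted,
  percentile (α, 1−α) interval. B defaults to 1000 and α to 0.025; the
  per-column statistic is deliberately the column mean, making this a CI
  for the subject mean;
- **uncer** — expanded uncertainty U = K·u_c, u_c = √(u_α²+u_β²+u_γ²),
  with u_α = σ̂/√n (Type A), u_β = 0 at deployment (estimated as the mean
  calibration bias when a reference is supplied), u_γ = 1 mmHg (the
  maximum allowable error of a mercury column) and K = 2 (≈95 %). The
  u_γ floor means this interval is never narrower than 4 mmHg. An
  alternative reading u_α = σ̂ is available behind a flag; neither reading
  is asserted as canonical;
- **monte** — the central-limit interval μ̂ ± Ψ⁻¹((1+γ)/2)·s/√n.

The cohort summary reports the mean width and mean bounds across subjects
(labelled as means of per-subject quantities, since pooled and averaged
aggregation differ). Width-sanity expectations (≈7–10 mmHg SBP, 3–6 mmHg
DBP for a deployable monitor) are a reporting concern, not an error
condition.

## Evaluation

ME, SD (n−1 denominator around ME) and MAE; AAMI/ESH pass iff |ME| ≤ 5 and
SD ≤ 8 mmHg, inclusive. BHS grades use inclusive ≤5/≤10/≤15 mmHg
cumulative percentages against tiers A (60/85/95), B (50/75/90),
C (40/65/85); **all three tiers of a grade must hold**, and a row meeting
no full tier grades D. Bland–Altman limits are ME ± 2·SD exactly (not
1.96·SD). Tabulated verdicts from published baseline models are kept as
test fixtures; one of them prints a grade inconsistent with its own
percentage triple under the all-tiers rule, and the fixtures assert the
rule, not the misprint.

## The synthetic-data generator

`bpci.synth` emulates the study conditions so every stage is testable
offline. Per subject: beat intervals 60/HR plus Gaussian jitter; an ECG of
Ricker-wavelet QRS complexes (~80 ms) at the R times; a PPG whose foot
trails each R peak by that beat's pulse transit time, with a two-bump
(systolic + dicrotic) pulse whose bump timing is fixed in absolute time
(~0.15 s and ~0.34 s after the foot) — systole does not scale with the
beat interval, which both matches physiology and keeps the upstroke onset
sharp at any heart rate; an ABP oscillating beat-wise between that beat's
DBP and SBP, normalized per beat so the extrema match the recorded truth
exactly, with the waveform pinned to DBP at the foot itself. Per-beat SBP
satisfies SBP = a − b·PTT exactly; variability enters through PTT jitter,
so b × ptt_jitter is the SD of the SBP sequence (the 50-subject study
cohort uses 2 mmHg). DBP is SBP minus a subject pulse pressure with mild
per-beat noise, and the PPG amplitude scales with the beat's pulse
pressure (a stroke-volume proxy) so diastolic pressure has an observable
correlate. Cohorts share one coupling (a, b) = (250, 500 mmHg/s) with
baseline SBP uniform over 100–160 mmHg — subject identity is expressed
through transit time, as the model assumes.

Injectable artifacts: channel white noise, baseline wander, motion spikes,
dropped beats (removed from both the signals and the truth), inverted
pulses. What the generator does **not** emulate: respiratory modulation,
baroreflex dynamics, drift in the PTT↔BP coupling, sensor saturation,
pulse-morphology disease variants, or inter-channel clock skew. Passing
tests therefore demonstrate that the pipeline recovers the structure this
generator encodes — transit-time-coded pressure with realistic rhythm and
morphology — not clinical accuracy on hospital data.

## Problem sizes and runtime

The default test suite and the acceptance script use desk-scale sizes
chosen to exercise every code path: 50-subject cohorts (≈630 beat
segments), 20-seed recovery studies at n = 200–400, 10⁴-replication
coverage simulations. The full suite runs in about four minutes on one
CPU; the acceptance script in about four more.

## Known limitations

- The SQI passes self-consistent corruption (see above) and its
  correlation threshold is a package convention, not a published value.
- Reference DBP from short segments credits the inter-peak minimum to the
  segment even when it physiologically belongs to the neighboring beat;
  with ±2 mmHg beat-to-beat variation this contributes sub-mmHg label
  noise.
- Exact GPR is O(n³); only a row-subsampling switch is provided, not a
  sparse approximation.
- The bootstrap and central-limit intervals are intervals for the *mean*
  of a subject's estimates; they say nothing about single-beat error.
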