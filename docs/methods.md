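# Methods

This note documents the models and procedures implemented in `dawnchorus`,
the design choices made where the design was genuinely open, and what the
synthetic scenes do and do not establish about real recordings.

## Band-level substrate

Audio is reduced to 1-second, 1/3-octave-band SPL matrices
(`dawnchorus.bandspl`). Frames are non-overlapping 1-s rectangles; the
power of each FFT bin (Parseval-normalised to mean-square units) is
assigned to the base-10 nominal band whose passband
[fc·10^(−1/20), fc·10^(+1/20)) contains the bin frequency. This is
deterministic, exactly energy-preserving within the covered range, and
sidesteps IIR filter-design ambiguity; an ANSI-style filter bank would be
a drop-in alternative behind the same contract. Bands whose upper edge
exceeds Nyquist are dropped with a warning.

Levels are dB relative to digital full scale plus a user calibration
offset (default 0 = uncalibrated); the hardware calibration chain is
deliberately abstracted into that single number. Zero-power cells are
floored at −120 dB rather than −∞. A-weighting uses the IEC 61672
analytic response evaluated at band centres. The per-second broadband
A-weighted level is the energy sum across bands; its hourly median is the
L50 used to confirm that sound energy concentrates around sunrise.

The exact integration time/weighting used by field SPL loggers is not
standardised across deployments; 1-s rectangular frames are assumed
throughout.

## Solar geometry and the dawn window

Sunrise (`dawnchorus.solar`) uses the NOAA solar-calculator equations —
Julian-century polynomial expansions of the solar mean longitude and
anomaly, apparent longitude with nutation/aberration corrections,
obliquity, declination and the equation of time — solved iteratively for
the upper-limb zenith of 90.833°. Agreement with an independent
Julian-date sunrise-equation implementation is within ±0.5 min over the
spring dates tested; no network almanac is consulted. (An earlier
candidate, the classic low-accuracy fractional-year Fourier fit, carries
a ~0.26° declination bias worth ~2 min of sunrise at latitude 58° and was
rejected.) Timestamps carry explicit fixed UTC offsets supplied by the
user; no daylight-saving database is consulted. Latitudes poleward of
66.5° may have no sunrise; that condition raises an explicit
`NoSunriseError` rather than returning a number.

The analysis window is sunrise − 0.5 h to sunrise + 2.5 h, a fixed 3-h
span; window extraction is idempotent and tolerates partial coverage with
a warning.

## Quality screening

Wind, rain and vessel noise concentrate energy at low frequencies, so
obscured seconds are flagged when the energy-summed level over bands with
centres ≤ 800 Hz exceeds the day's baseline by ≥ 10 dB (both
configurable). The baseline is the whole-window median of that series:
robust to events occupying up to half the window. A centred rolling
median is available via `baseline_window_s`, but is *not* the default
because any event longer than the rolling window fills it, drags the
median up to the event level, and silences the flag exactly when it
matters. The consequence of a median baseline, documented and tested: a
uniformly elevated (chronically windy) day yields no flags — the rule
targets transient obscuration, not loud sites. Because flagging is
baseline-relative, the exclusion decision is invariant to calibration
offset.

A day is excluded when strictly more than 25 % of its window seconds are
flagged (a day at exactly 25 % is retained). No attempt is made to
classify the noise source; wind, rain and anthropogenic noise are treated
identically by the low-band proxy.

## The Acoustic Complexity Index

The coarse index is evaluated directly on dB SPL values, per band:
summed absolute adjacent-second differences divided by the band's summed
SPL, with per-band values over the 8 retained thirds (1250–6300 Hz)
summed into the daily ACI_tot. Three consequences are load-bearing and
tested:

* **Scale invariance, offset sensitivity.** Multiplying the series by k
  leaves ACI unchanged; adding a dB offset changes only the denominator,
  so ACI strictly decreases. Calibrated absolute levels are therefore
  required for cross-site or cross-year comparison.
* **Order sensitivity.** Sorting a series minimises the numerator; the
  index measures temporal intermittency, not level.
* **Adjacent differences number n−1.** The summation runs over the n−1
  defined adjacent pairs. Missing seconds (gaps) break the difference
  chain rather than juxtaposing non-adjacent seconds.

The denominator is the sum of dB values as printed in the coarse-index
convention for calibrated band-level data; a linear-power evaluation can
be obtained by converting the matrix before the call, but is not the
default. The fine-resolution variant computes the classic ACI on STFT
magnitudes (hop 0.01 s, bin width ≈ 86.1 Hz, i.e. nperseg = sr/86.1)
normalised per bin over the whole signal, summed over bins in
1250–6300 Hz.

## Bayesian change-point model

Daily ACI values x₁…xₙ (excluded days dropped, series compressed — the
model assumes a sequence, and imputation would fabricate structure) are
modelled with the Barry–Hartigan normal product-partition model:
contiguous blocks share a mean, observations are N(μ_block, σ²), block
means draw from a common normal prior, and each of the n−1 positions is
independently a change point with probability p. With uniform priors
p ~ U(0, p₀), w ~ U(0, w₀) — w = σ²/(σ²+σ₀²) the within/total variance
ratio — and flat priors on the grand mean and log σ², the partition
marginal is

g(ρ) = ∫₀^{p₀} p^k (1−p)^{n−1−k} dp · ∫₀^{w₀} w^{k/2} (W + wB)^{−(n−1)/2} dw

for k change points, within-block sum of squares W and between-block sum
of squares B. Hyperparameter caps default to p₀ = w₀ = 0.2, the
convention of the established implementation lineage of this model;
both are exposed in the API and config.

Two independent routes compute the posterior probability of a change at
each position:

* **Gibbs sampling** over the change indicators (default 10,000 sweeps
  after 5,000 burn-in), with the conditional odds derived from g. The
  p-integral is an incomplete beta function; the w-integral has no closed
  form and uses 64-point midpoint quadrature, evaluated in log space.
  Uniform variates are pre-drawn from a seeded generator, so a fixed seed
  reproduces the fit exactly. The per-day posterior mean averages the
  blockwise shrinkage estimate ŵ·x̄ + (1−ŵ)·x̄_block across sweeps.
* **Exact enumeration** of all 2ⁿ⁻¹ partitions (n ≤ 16), same priors and
  quadrature — the calibration oracle. Tests additionally validate the
  weight definition itself against adaptive quadrature
  (`scipy.integrate.quad`) with no shared code path.

Sampler-vs-enumeration agreement on mixed small-n fixtures is ~0.01 in
absolute probability, within the ±0.03 calibration requirement. The odds
are invariant to location and scale changes of the series (tested to
MCMC tolerance).

The spring transition is the earliest strict local maximum of the
posterior change probability exceeding 0.5 (plateaus resolve to their
earliest index; a peak at the first position has no baseline and is not
eligible). Its fold-change is the ACI on the transition day divided by
the mean ACI of all preceding retained days (optionally a trailing
window). "All preceding days" is the default because the baseline period
is otherwise unbounded in the definition; the window is configurable.

## Call detection and count correction

The band-limited energy detector integrates STFT power (Hann window,
default 23 ms, 50 % overlap) over the configured frequency band, tracks
background with a running median of the same in-band level over 60 s, and
emits events for contiguous supra-threshold runs after merging gaps
shorter than `min_gap` and applying duration limits. Because the
background is a median of the level being thresholded, detection is
invariant to global gain, and raising the SNR threshold can only remove
detections.

Evaluation against ground truth uses greedy one-to-one matching: truth
events in onset order claim the nearest unmatched detection within the
onset tolerance whose band overlaps, ties resolving to the earliest
detection, making the score independent of detection order. Daily counts
are corrected by inverse sensitivity, count/(1 − FNR) — the standard
estimator when a detector's miss rate is measured on a review subset —
rejected above FNR = 0.95 where the correction is unstable.

## Diversity and association

Shannon diversity is reported in nats and Simpson as the Gini–Simpson
probability 1 − Σp²; both are the most common defaults when the index
family is named without a base or variant, and both are
label-permutation- and total-count-invariant. Pseudo-species (consistent
but unidentified vocalization types) are ordinary labels.

The ACI–predictor association is identity-link OLS with optional
within-group centering, reporting slope ± SE and R². A mixed model with
an inverse link would be a package-specific choice whose coefficients are
not comparable across implementations; the scientific claim carried by
this module — and the only one tested — is the sign and strength of the
association, e.g. daily ACI regresses positively on true call counts with
R² > 0.3 on synthetic seasons (in practice ≈ 0.999, since the scenes
contain no confounders).

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the structure the analyses assume, with defaults
set to the study conditions of a subarctic spring deployment:

* Site at (58.456°, −135.866°), UTC−8; 60-day season 2012-03-17 to
  2012-05-15; arrival day 2012-04-16 (day 30).
* Three species templates: tonal whistler 2500–5850 Hz (0.8-s single
  syllable, +25 dB), fast FM singer 3–9 kHz (18 × 0.1-s chirp syllables,
  +20 dB), phrase singer 2700–6000 Hz (6-syllable two-note motif,
  +22 dB).
* A homogeneous Poisson song process per species per day: 2 songs/h
  before arrival, 40 songs/h on and after. Real dawn choruses have
  within-morning rate structure (a decay after sunrise); no published
  characterization was available to copy, so the process is homogeneous
  within the window and this is a stated simplification, not a claim.
* Ambient floor: audio path −50 dB RMS re full scale (white); band path
  30 dB SPL per band with 0.3 dB per-cell Gaussian jitter. The jitter
  magnitude is the calibration that realises the intended post/pre ACI
  contrast of ≥ 1.8× at the default rates (measured ≈ 2.3×); quieter
  jitter raises the contrast, louder jitter buries it.
* Weather events: additive band-limited pink-noise bursts (audio path)
  or flat in-band power elevations (band path) over a configurable
  frequency extent, emulating broadband wind/rain masking.
* Daily covariates: a linear −2→10 °C temperature ramp with sd-1.5 noise
  and optional arrival coupling; wind elevated on storm days.

Determinism: every draw derives from (seed, day index, stream) via
`numpy.random.SeedSequence`, so scenes are bit-reproducible and any day
can be regenerated in isolation. Ground truth is exhaustive: every
rendered song appears in the call log with exact onset, duration, and
frequency extent, and ≥ 90 % of each song's energy lies within its
template band (tested per song type).

Two render paths share the event sampler. The audio path renders
waveforms (used by the band-SPL, detector and fine-ACI tests); the band
path constructs the 1-s band-SPL matrix directly and is what
season-scale analyses consume — 60 days of 3-h windows as audio would be
~24 GB of samples for no additional information, since the coarse index
only sees the band-level substrate.

What passing tests therefore show: the chain recovers a known arrival
step under realistic sparsity, noise and screening losses. What they do
not show: robustness to overlapping continuous songs, varying source
distance/propagation, diel rate structure, or species mimicry — real
recordings contain all of these, and detector thresholds and screening
defaults should be re-tuned on annotated field data before operational
use.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` use: full-length (10,800-s)
band-SPL windows for season analyses over 60 days; 20 replicate seasons
for arrival recovery; 10 × 300-s audio windows (~115 songs) for detector
scoring; change-point fits at the conventional 10,000/5,000 iterations;
exact enumeration up to n = 10. These sizes make the whole suite run in a
few minutes on one CPU while keeping every statistic at its operating
settings.

## Known limitations

* The coarse ACI on dB values is calibration-dependent by construction;
  uncalibrated recorders yield index values that are not comparable
  across gain settings.
* The change-point model assumes within-block normality and a single
  variance; heavy-tailed daily ACI noise (e.g. residual storm days that
  evaded screening) can inflate change probabilities at outliers.
* The screening proxy cannot separate wind from vessels, and a day of
  continuous wind is retained (with elevated but flat low-band levels)
  by design.
* The detector is single-band per species; overlapping same-band songs
  merge into one detection, which is the main recall loss in dense
  choruses.
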