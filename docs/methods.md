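# Methods

## Overview

`leadsync` implements an analysis linking interpersonal synchrony of motion
energy in dyadic interaction videos to the impressions observers form of one
of the interactants (the "green" target; their partner is "white").  The
chain is: motion-energy extraction from video → preprocessing and windowed
lagged cross-correlation → lead–lag decomposition → pseudosynchrony
validation → composite impression scoring → a Bayesian linear mixed model
with directional hypothesis tests → webcam-gaze quality control and group
comparisons.  A synthetic-data generator produces every input with the
statistical structure the analysis assumes, so the whole chain is testable
without any recordings.

## Motion energy

Motion energy for a region of interest (ROI) is, per frame transition, the
count of pixels whose absolute greyscale intensity change exceeds a noise
threshold (default 10 of 255).  A sum-of-absolute-differences mode is
available behind a flag; the count is the conventional MEA statistic and the
default.  Colour frames are converted to grey with Rec. 601 luma weights.
ROIs are fixed axis-aligned rectangles (head regions in the source
recordings); there is no person tracking.  Motion energy is invariant to
constant intensity offsets and, for motion fully contained in an ROI, to
enlarging that ROI.

Anonymized stimuli are produced by Gaussian-blurring each frame
(σ = 2.0 px by default; a σ = 2.5 dialect is supported), taking the Sobel
gradient magnitude, and binarizing with a per-frame Otsu threshold, leaving
only outlines; the target half of the frame is flagged for green
colourization on export.  Motion energy is computed on the original frames
by default (computing it on the edge maps is supported but not the default).

## Synchrony and leading

Per dyad, each motion-energy series is cleaned by replacing values larger
than 10 sample standard deviations with missing (a constant series, SD = 0,
is left untouched — a zero threshold would delete every positive value),
then divided by its SD.  Two 10-s excerpts are cut from each 5-minute
recording: 90–100 s (introduction) and 240–250 s (body of the
conversation).  All SDs use the sample convention (ddof = 1).

Within each excerpt, windowed lagged cross-correlations are computed: for
every window (default one 10-s window per excerpt) and every integer frame
lag ℓ in ±2 s at 25 fps, the Pearson correlation between green at *t* and
white at *t + ℓ* over pairwise non-missing samples.  The sign convention is
fixed throughout: **positive lag means green precedes, i.e. green leads**.
Absolute correlations are taken (synchrony regardless of direction of the
linear relation) and Fisher-z transformed after clamping |r| at 0.9999 so
perfect correlations stay finite.  Windows with fewer than 3 valid pairs or
a constant segment yield missing entries, not errors.

Leading scores collapse the window × lag matrix: green leading is the mean
(or, behind a flag, peak) of entries at positive lags, white leading at
negative lags, zero-lag synchrony at lag 0.  Both leading scores are
log-transformed as log(score + 1e-6); the epsilon guards exact zeros.
Window length, increment, maximum lag and the mean/peak choice are exposed
in the config — they are analysis parameters without uniquely correct
values, and the defaults (10 s window, 10 s increment, ±2 s lag, mean
aggregation) are the package's choices.

## Pseudosynchrony validation

Two checks establish that the synchrony statistic (mean Fisher-z |r| over
windows and lags) reflects genuine interaction:

1. **Time dependency**: surrogates pair a dyad's green stream with a
   segment-shuffled copy of its own white stream (contiguous segments
   re-ordered by a random non-identity permutation, preserving the value
   multiset while destroying shared temporal order).
2. **Section synchrony**: surrogates pair the green stream with white
   streams drawn from *other* dyads (1000 pairings per dyad by default),
   restricted to the same source study when possible because the two source
   studies differ systematically.

Each check reduces to per-dyad effects (genuine minus surrogate mean) and a
one-sample JZS Bayes factor against zero.  Sampling is with replacement by
default; a without-replacement mode (each other partner used exactly once)
makes the genuine statistic exactly exchangeable with its surrogates under
the null, which is what the rank-calibration tests use.

## JZS Bayes factor

The default Bayesian t-test places a Cauchy prior (scale r = √2/2) on the
standardized effect, equivalently an inverse-gamma(1/2, r²/2) prior on the
variance ratio g.  BF₁₀ is the one-dimensional integral over g of the
likelihood ratio at fixed g times the prior density, evaluated with adaptive
quadrature with the null density factored out for stability; the
implementation refuses to return when the quadrature error estimate exceeds
1 part in 10⁴.  One-sample/paired tests use N = n, ν = n − 1; independent
tests use N = n₁n₂/(n₁+n₂), ν = n₁+n₂−2.

## Composite impression and unidimensionality

The six 0–100 ratings (intelligent, awkward, likeable, trustworthy,
conversation, friends) are combined by reverse-coding awkwardness as
100 − x and averaging, so higher always means a more favourable
impression.  Whether one dimension underlies the six ratings is quantified
by a one-factor fit statistic: 1 − SS_offdiag(R − λλᵀ) / SS_offdiag(R),
with R the 6×6 Pearson correlation matrix (awkwardness reversed first) and
λ first-factor loadings from an iterated principal-factor fit started at
squared multiple correlations.  Noise-free rank-1 data give 1.0 exactly.
Note the null behaviour of this statistic: for independent columns a rank-1
fit still absorbs roughly half of a random 6×6 correlation matrix's
off-diagonal sum of squares, so "near 1" — not "near 0 under noise" — is
the meaningful benchmark.

Participant screening excludes, in order of precedence: participants who
flagged their data as not usable, verbal-IQ (WST) scores below 6 of 42, and
autism-trait (AQ-10) scores above 5 of 10; boundary scores (WST = 6,
AQ-10 = 5) are included.  Only the first matching reason is recorded.

## Bayesian linear mixed model

The confirmatory model regresses the composite score on diagnosis (treatment
coded, non-autistic reference), the two scaled log leading scores, all their
interactions up to the three-way, overall motion of both interactants, and
video source (study A reference), with random intercepts for participant and
stimulus and random participant slopes for diagnosis and source.  Continuous
predictors are z-scored across the modelling set.  Variants add a binarised
AQ-10 group (plus its interaction with diagnosis) or swap the outcome for a
single rating.

Inference is a blocked Gibbs sampler over the conjugate conditionals:

* all location parameters (fixed effects plus every random effect) are drawn
  jointly from one multivariate normal conditional — alternating β and u
  updates mix extremely slowly here because all substantive predictors vary
  only at the stimulus level, where they are confounded with the stimulus
  random intercept;
* each variance component and the residual variance from inverse-gamma
  conditionals.

Priors are weakly informative on the 0–100 outcome scale: β ∼ N(0, 50²),
variances ∼ inverse-gamma(0.01, 0.01).  Random-effect covariance is
diagonal (independent intercepts and slopes); this keeps every conditional
conjugate and is a deliberate simplification relative to an unstructured
covariance.  Default sampling is 4 chains × 10,000 iterations with 50%
warm-up; convergence is monitored by split-chain R-hat with a 1.05 warning
threshold.  Variance components of weakly identified slopes can show
elevated R-hat at short chain lengths; the location parameters, which carry
the hypotheses, converge quickly under the blocked update.

Hypotheses are evaluated one-sided in the direction of each posterior mean:
the posterior probability is the fraction of draws on that side of zero and
the evidence ratio its odds, capped at the number of draws when the fraction
is 1.  Effects are called credible above 0.975 (a two-sided 5% level remapped to
one-sided testing) or 0.95 for a priori directional hypotheses.

## Gaze preprocessing and metrics

Gaze is a 60-Hz stream of screen-half labels (target/other/missing) with a
face-tracking flag; a valid sample is tracked with a non-missing side.
Filters run in a fixed order: (1) drop trials with face-tracking accuracy of
50% or less; (2) invalidate fixation runs shorter than 50 ms (3 samples at
60 Hz; a fixation is a maximal run of same-side valid samples); (3) drop
trials with fewer than 400 valid samples; (4) drop participants with fewer
than 50% of their trials left (exactly 50% retained is kept).  The 50-ms
rule is applied before the 400-sample count (switchable).

Metrics per retained trial: the fraction of valid samples on the target half
and switches per 100 valid samples, where a switch is a side change between
consecutive valid samples — missing gaps neither create nor break switches
between same-side runs and count once between different sides.  Outliers in
metric vectors are removed by the 1.5 × IQR Tukey fences (linear-interpolated
quartiles, fence values kept).  Group comparisons use paired JZS t-tests on
per-participant condition means, plus a one-sample test of the target
proportion against 0.5.

## Synthetic data

The generator defines the conditions under which the pipeline is validated:

* **Motion**: each stream is a Poisson burst process (0.4 bursts/s,
  exponential amplitudes, 0.5-s exponential decay) plus truncated Gaussian
  noise — non-negative and spiky like real motion energy.  The white stream
  mixes its own bursts with the green stream delayed by τ frames (default
  12) weighted by a coupling c ∈ [0, 1): B = (1−c)·own + c·A(t−τ), floored
  at 0.  c = 0 gives independent streams; increasing c makes green lead.
  Recordings default to 5 minutes at 25 fps, matching the source videos.
* **Video**: two bouncing ellipses on opposite screen halves whose per-frame
  displacement follows a motion profile, closing the loop with the
  motion-energy extractor end to end.
* **Ratings**: the generative twin of the mixed model — outcome = Xβ +
  crossed random effects + residual noise, clipped to [0, 100] (clipping
  rate logged, <1% at defaults); the six observed ratings add item-level
  noise (SD 10 points) around the latent score with awkwardness
  reverse-coded, which yields high one-factor fits at large samples.
  Default true effects include a +4-point green-leading effect and a
  −6-point diagnosis × green-leading interaction per SD of predictor, with
  participant/stimulus SDs of 5, slope SDs of 2 and residual SD 15 —
  magnitudes on the scale of the rating instrument.
* **Gaze**: a two-state Markov chain with stationary target probability
  0.65 and a switch propensity chosen so that retained trials show about
  5–6 switches per 100 samples, with independent per-sample dropout.
* **Participants**: screening scores drawn to hit configured exclusion
  rates; the defaults reproduce the 247-collected / ≈196-included
  composition in expectation.

What the generator does **not** emulate: real body kinematics and their
autocorrelation structure beyond bursts, camera artefacts, rater response
styles (anchoring, scale use), correlated random slopes, or systematic
procedural differences between the two source studies beyond a label.
Passing tests therefore demonstrate that the pipeline recovers the
structures it assumes, at the stated sizes and noise levels — not that those
assumptions hold for any particular real recording.

## Numerical choices and problem sizes

* Fisher-z clamp 0.9999; log epsilon 1e-6; correlations need ≥3 valid pairs.
* The quadrature oracle in the tests integrates on a fixed log-spaced grid,
  independent of the adaptive implementation.
* Validation studies run at deliberately modest sizes chosen to give stable
  Monte-Carlo answers: 200 seeds per coupling level for lead-lag recovery,
  200–500 replicates for surrogate calibration, and a 50-participant ×
  44-stimulus, 4 × 2000-iteration, 20-replicate design for mixed-model
  parameter recovery.  The full study-scale configuration (196 participants,
  4 × 10,000 iterations) is the pipeline default.

## Known limitations

* The Gibbs sampler assumes Gaussian residuals and diagonal random-effect
  covariance; it is not a drop-in replacement for NUTS-based fits with
  unstructured covariances, and point estimates on real data should be
  expected to agree approximately, not exactly.
* The one-factor fit statistic is a defined quantity of this package; its
  scale is comparable across datasets analysed with this package but not
  numerically identical to other packages' unidimensionality indices.
* Head-ROI coordinates for real videos must be supplied in the config; no
  automatic person detection is attempted.
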