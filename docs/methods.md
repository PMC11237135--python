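# Methods

`infantspec` reimplements, as a tested pipeline with synthetic ground
truth, a spectral-analysis workflow for infant and toddler resting EEG:
multitaper power spectral densities, an infant-adapted aperiodic/periodic
spectral parameterization, band-peak and band-power feature extraction,
anesthesia-style frontal coherence, and nonlinear age-trajectory modelling.
This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Spectral estimation

Cleaned EEG is segmented into non-overlapping 2-s epochs (trailing
remainder dropped).  Each epoch's PSD is a discrete-prolate-spheroidal
(Slepian) multitaper estimate with K = 3 tapers.  The taper count is the
analysis convention; the time-bandwidth product is not separately
specified by it, so we use the standard companion NW = (K + 1)/2 = 2
(configurable).  The grid is the epoch's native resolution (0.5 Hz for 2-s
epochs at typical sampling rates); no zero padding by default.
Normalization is density-style: the integral of the one-sided PSD over
[0, fs/2] equals the signal variance up to taper bias (verified by the
white-noise Parseval test and the A²/2 sinusoid test, both within 5 %).
Averaging over epochs and electrodes is pointwise in linear power; the log
transform happens only at parameterization.  Because all weights are
equal, epoch-then-electrode averaging equals pooled averaging (tested).

## Spectral parameterization and the infant modification

The log10 power spectrum on 2.5-50 Hz is decomposed as

    log10 P(f) = b − χ·log10 f + Σ_k h_k · exp(−(f − c_k)² / 2σ_k²)

with the aperiodic component in fixed mode (no knee) and at most 7
Gaussian peaks; settings: peak_width_limits [0.5, 18.0] Hz, max_n_peaks 7,
peak_threshold 2.  The reported offset is the aperiodic power at 2.5 Hz
rather than the extrapolated 0 Hz intercept.  Fitting follows the
published algorithm: an initial least-squares power-law fit; a robust
refit on low-lying points of the flattened (log-minus-fit) spectrum;
iterative Gaussian extraction (global maximum, stop when its height fails
2× the sd of the current residual, half-height width guess, subtract,
merge overlapping guesses keeping the taller) followed by a bounded joint
refit; and a final aperiodic fit on the peak-removed spectrum.  R², mean
absolute error and per-frequency error are reported against the log
spectrum.

Spectra from roughly 2-7-month-olds carry a "trough": the 10-20 Hz
stretch, flanked by prominent alpha (~9.5 Hz) and high-beta (20-30 Hz)
peaks, falls below the initially estimated aperiodic component.  The
upstream robust fit zeroes these negative flattened values, which erases
the trough's depth ordering, and its percentile threshold then admits
every at-or-below-fit point — trough and all — into the refit.  The
infant modification implemented here changes two steps:

1. **Robust-fit baseline elevation.**  The flattened spectrum is shifted
   so its minimum is ≥ 0 instead of being clipped.  Because elevation
   removes the zero ties that make the upstream's tiny percentile constant
   act as a "keep everything at or below the fit" rule, the literal
   constant would keep only 2-3 grid points and make the refit fragile
   (this measurably breaks parameter recovery under noise).  The elevated
   flattened spectrum is therefore thresholded at its median: the refit
   keeps the same number of low-lying points as the upstream's effective
   selection, but ranked by true depth, so deep trough points anchor the
   refit and Gaussian-tail-contaminated fringe points are excluded.
2. **Pre-peak clipping.**  Negative values of the flattened spectrum are
   set to 0 before peak fitting, so the iterative Gaussian fits are not
   distorted by the trough.

Both the modified and unmodified paths are first-class and selectable;
the unmodified path reproduces the published behavior and is checked
against an independently written implementation (numpy.polyfit /
scipy.optimize.least_squares route) to 1e-3.

Measured properties of the modification on archetype banks: on 100
2-7-month archetypes (alpha + broad high-beta, per-bin log-power noise
0.01, the level of a heavily averaged PSD), the modified fit's 10-20 Hz
RMSE is ≤ the unmodified fit's in 100/100 replicates.  On trough-free
archetypes the modification is conservative in the typical case (median
aperiodic disagreement ~2e-5; exact agreement on pure power laws, where
the two selections provably coincide), but not uniformly below 1e-3: any
variant that changes behavior on trough spectra must also move the
selected point set on peaked trough-free spectra, and Gaussian-tail
leverage then shifts the fits by O(1e-3) for realistic peak heights.  A
selection keeping exactly the upstream's point count is provably identical
to the upstream fit, i.e. a no-op, so this residual disagreement is the
irreducible price of the modification.

Numerical details: bounded least squares with analytic initial guesses;
joint-refit center bounds at ±1.5 guessed sd; fitted peaks hugging a range
edge (within 1 sd) are dropped; candidate peaks below an absolute height
floor of 1e-6 log10 power are ignored (guards near-exact fits against
chasing numerical residue); optimizer failure is flagged on the fit object
(`converged`, `diagnostics`), never silently swallowed.

## Periodic features

The periodic spectrum (log spectrum minus fitted aperiodic component) is
resampled to a 0.1 Hz grid by cubic interpolation and smoothed with a
Savitzky-Golay filter (window 101 points ≈ 10 Hz, polyorder 8).  The
101-point window is printed convention; it exceeds the 96-point native
2.5-50 Hz grid, so the resampling step is what makes it feasible — a
declared choice, not an inference about the original pipeline.  The filter
itself is computed as a local least-squares polynomial projection on
window positions scaled to [-1, 1] and factorized by QR: at window 101 and
order 8 the conventional integer-position Vandermonde solve loses ~1e-3 of
accuracy to conditioning (even a constant input is then reproduced only to
~1e-3), whereas the scaled projection reproduces polynomials up to
degree 8 at machine precision; edge points take the nearest full window's
fitted values.  Peaks are
read off the smoothed residual rather than from the model Gaussians
because broad high-beta peaks are not reliably Gaussian: a band peak is
the highest strictly interior local maximum with positive amplitude within
theta 4-6.5, theta/alpha 4-12, low-beta 12-20, or high-beta 20-35 Hz; band
edges never count (a monotone residual has no peak).  Two-peak counting in
4-12 Hz merges maxima closer than 1 Hz (keeping the taller) — an invented
rule, configurable, needed because no separation criterion is printed.
Band power is the trapezoidal integral of the aperiodic or periodic curve
over theta 4-6, low-alpha 6-9, high-alpha 9-12, low-beta 12-20, high-beta
20-30, gamma 30-45 Hz, with band edges interpolated so integrals are
additive.  Peak prevalence per age bin (2-4, 4-6, 6-8, 8-11, 11-15, 18-20,
23-30, 35-44 months) is the binary mean with a Wilson 95 % interval.

## Coherence

Magnitude coherence between two frontal channels is |S_xy| / √(S_xx·S_yy)
with cross- and auto-spectra averaged over K = 5 tapers (TW = 3) and 6-s
non-overlapping windows before the ratio is formed; averaging per-window
coherences instead would be degenerate.  Cauchy-Schwarz bounds the
estimator in [0, 1] by construction; zero-power bins are reported as NaN,
never clamped.  Epoch selection: an epoch is kept iff its sd is ≤ 3× the
median epoch sd (the factor is unstated upstream; 3 is our documented
default), and is eligible iff the preceding 120 s of the anesthetic
concentration span ≤ 0.2 %.  The alpha band for the median summary
defaults to 8-12 Hz (also a documented choice).  The group comparison is a
one-way ANCOVA (value ~ group + anesthetic level) with an F test on the
group term, verified against hand-computed residual sums of squares and
calibrated for type-I error by simulation.

## Trajectories

Each feature is modelled over age in days as

    y = β₀ + β_sex·male + f(age) [+ f_Δ(age)·male] + u_subject + v_study + ε

where f is a natural cubic regression spline with basis dimension k = 4
and *fixed* degrees of freedom (no penalty), i.e. 3 estimable columns
after a centering constraint; sex enters as a single ordered-factor
contrast; u and v are random intercepts with subjects nested in studies.
Fitting is by maximum likelihood via statsmodels MixedLM (subject as a
variance component within study groups); with a single study the study
term is dropped with a warning.  The additive and interaction forms are
nested; the interaction is chosen when a likelihood-ratio test (df = the
number of interaction columns) is significant at α = 0.05.  This machinery
is verified against an mgcv fit of the same model form on a shared cohort
(curves agree after mean alignment to well under 10 % of the dynamic
range) and by simulation: interaction selection under a sex-null occurs at
≈ the nominal 5 % rate.

Predictions are made per sex on a 1-day grid with pointwise 95 % intervals
from the fixed-effect covariance.  Inflection ages are strict relative
extrema of the predicted curve within a ±100-day window
(scipy argrelextrema, order = 100); applying the search to the first
difference instead is exposed as an option, since either reading of
"inflection" is defensible.  The standardized rate of change is
(f(d+1) − f(d)) / sd(f) with the sd taken over the full age range; a
constant curve warns and returns zeros.  Recovery: ground-truth age curves
are built *inside* the spline family (a Gaussian bump projected onto the
basis, its center adjusted until the projected maximum sits at the target
day) because for an out-of-family truth curve the estimand is the
extremum of its best spline approximation, which can sit tens of days
away no matter the estimator.  With 200 subjects × 3 visits and realistic
random effects, the median absolute recovery error of a day-372 extremum
is well under 30 days.

The two-peak probability model is a logistic mixed model (linear age
effect, subject random intercept) fit by variational Bayes
(statsmodels BinomialBayesMixedGLM); no frequentist GLMM is available in
the installed stack, and the VB posterior mean/sd recover a simulated
−0.018 per-day log-odds slope with near-nominal interval coverage.
Benjamini-Hochberg FDR adjustment is applied within analysis groups (term
× region of interest) and matches a brute-force step-up oracle exactly.

## Synthetic data

The generator produces (a) spectra of the parameterization model form with
optional i.i.d. log-power noise; (b) Gaussian time series spectrally
shaped in the frequency domain so the expected PSD equals the model
spectrum (each 2-s epoch generated independently; DC zeroed; out-of-range
frequencies rolled off); (c) coherent channel pairs y₁ = s + n₁,
y₂ = s + n₂ from independent band-limited noises, with expected in-band
coherence σ_s²/(σ_s² + σ_n²); and (d) longitudinal cohorts with
deterministic feature-age curves plus subject/study random intercepts and
residual noise, uniform visit ages, and per-subject seed derivation so
subject i's data are invariant to cohort size.  Defaults emulate the study
design: ages 2-44 months (60-1340 days), ~3 visits per subject, several
study labels, offset rising steeply over the first year, exponent rising
gradually, a transient alpha peak waning after ~2-6 months, and high-beta
peak amplitude peaking near day 372.

What the generator does not emulate: EEG artifacts (blinks, muscle,
electrode pops), volume conduction and electrode geometry, non-Gaussian or
nonstationary signals, correlated (smooth) spectral noise, drop-out or
age-dependent visit schedules.  Passing tests therefore establish
correctness of the estimators and algorithms under the stated model, not
robustness to real-world artifacts — artifact removal is upstream of this
package by design.

## Problem sizes

The validation suite uses 100-replicate banks for parameter recovery and
A/B comparisons, 10-minute records for coherence closed-form checks, and
100 cohorts of 200 × 3 observations for trajectory recovery, chosen to
keep Monte-Carlo error comfortably below every tolerance tested.
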