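# Methods

This note documents the models, conventions and numerical choices behind
`optofmri`, and what the synthetic-data generator does and does not emulate.

## Block-design coherence analysis

**Pipeline order.** Voxel series are (1) converted to percent modulation
about the mean of the leading 30 s rest block, (2) boxcar-detrended with a
60 s centered moving-average window, and (3) Fourier-analyzed at the block
repetition frequency `f0 = 1/cycle_period` over the cycle-locked frames
(baseline frames stripped). The coherence is

    C = |X(f0)| / sqrt(Σ_{f>0} |X(f)|²),

the DFT amplitude at `f0` normalized by the root-sum-of-squares of all
positive-frequency amplitudes. The DC term is always excluded — with it the
statistic would depend on the series mean and would not be bounded by 1 —
and `n_exclude_low` optionally drops additional near-DC bins below `f0`
(residual drift); the default is 0, since boxcar detrending already empties
those bins. `f0` must fall exactly on the DFT grid (an integer number of
block periods); off-grid requests are rejected rather than interpolated.

**Detrending details.** The moving-average window is `window_s / TR` frames
(80 at the defaults), shrinking one-sidedly at the series edges. An
80-frame window spans exactly one 60 s block period, so the `f0` component
passes through the detrender untouched (the moving mean of a sinusoid over a
full period is zero) while linear drift is removed up to a half-frame
offset.

**Phase convention.** Phase is the *negated* argument of `X(f0)` mapped to
`[0, 2π)`, so it reads directly as temporal lag: a response delayed by `τ`
seconds has phase `2π f0 τ`. The fundamental of a 20 s-on/40 s-off boxcar
is centered 10 s into the train (phase π/3 ≈ lag 10 s); adding a ~3 s
hemodynamic lag leaves positive responders safely inside the positive
interval `[0, π/2] ∪ [3π/2, 2π)` (lags up to 15 s), while sign-flipped
(suppressed) responses land half a turn away. Both interval endpoints are
inclusive at π/2 and 3π/2. The convention is pinned by a round-trip test
against the generator.

**Significance.** `coherence_p_value` defaults to the correlation-statistic
transform `t = C·sqrt(df)/sqrt(1−C²)` with `df` degrees of freedom
(default 470 for a 480-frame series, configurable); at C = 0.35, df = 470
the Bonferroni-corrected p over 128×128×23 voxels evaluates to 9.0×10⁻¹⁰.
A second method, `white-noise-exact`, uses the exact null of white-noise
coherence, `C² ~ Beta(1, K−1)` for `K` positive-frequency bins. The two
agree that the threshold is astronomically conservative but differ in the
deep tail (≈2.4×10⁻¹⁵ vs ≈3×10⁻¹⁴ at the threshold); the Beta form is the
one the Monte-Carlo calibration test checks at moderate thresholds, because
it is exact for the simulated noise. Degenerate voxels (zero baseline mean)
are flagged NaN upstream and classified inactive.

**Group statistics.** Sessions are averaged within animal before averaging
across animals, weighting animals equally. Paired activation-volume
comparisons use one-sided Wilcoxon signed-rank tests; the family-wise
correction (Bonferroni by default, Holm optional) is applied across the
ROI × frequency-pair family whose size the caller supplies.

## Rank tests

Exact null distributions are used for samples of at most 25 per group.
Small samples whose ranks are perturbed by ties are handled by direct
enumeration — all 2ⁿ sign assignments for the signed-rank test (n ≤ 18),
all C(n₁+n₂, n₁) group assignments for the rank-sum test (pooled n ≤ 14) —
conditioning on the observed mid-ranks, because the closed-form exact null
does not. Larger samples use the normal approximation with continuity
correction. Zero differences are dropped (Wilcoxon's convention); an
all-zero sample is degenerate and returns p = 1 with a warning.

## Spindle-like-oscillation detection

The rule operates on the rectified 2 Hz high-pass-filtered trace. The
threshold `T = mean(|x|) + k·SD` (k = 6) is estimated per channel and trial
over the **whole trial** by default; the estimation window and the SD
definition are configurable. SD is taken as the standard deviation of
`|x|`, keeping the spread estimate in the same units as the mean-absolute
baseline; `sd_of='raw'` switches to the SD of the signed signal. "Magnitude"
is the rectified signal, not an analytic envelope. An onset requires no
threshold crossing in the preceding 500 ms and ≥2% occupancy in the
following 500 ms; at 1 kHz a single-sample artifact (1/500 = 0.2%) can
never qualify. Candidate onsets are restricted to the stimulation window,
but the quiet/occupancy windows may look outside it; an occupancy window
truncated by the trace end is evaluated over the available samples.
Because the threshold is data-derived, detection is invariant to overall
amplitude scaling, and raising k can only remove events.

## PSTHs and firing-rate tests

Pulse-aligned PSTHs bin spikes relative to every pulse onset in the train,
sum over pulses, and average across trials; the default window is one pulse
period and the default bin 5 ms. Baseline normalization divides each bin by
the count expected from the 20 s pre-stimulation rate (rate × bin width ×
number of alignment events), so 1 means "at baseline". Peak latency is the
bin with the maximum value. Rate-change tests compare per-trial rates in
consecutive 5 s stimulation bins against the per-trial 20 s pre-stimulation
rate, uncorrected across bins; sidedness is a parameter (one-sided increase
for thalamic/incertal presets, two-sided for cortex).

## EEG band power

Band power is integrated from a boxcar periodogram and normalized by total
power on `[0, fs/2]`. Band edges (not standardized in the source
conventions) default to delta 1–4, theta 4–8, alpha 8–12, beta 12–30 Hz,
half-open `[lo, hi)` with the Nyquist bin assigned to a band that reaches
it, so any partition's fractions sum to 1.

## Fiber light-cone model

Intensity below the tip combines conical geometric spread (half-angle
`θ = arcsin(NA/n)`, virtual apex `ρ = r/tanθ` behind the face) with
Kubelka-Munk scattering `1/(Sz+1)`. Defaults: tissue index n = 1.36 (which
maps NA 0.22 to a 9.31° half-angle) and S = 11.2 mm⁻¹ for mammalian brain,
applied at both 473 and 593 nm; neither is wavelength-resolved here, which
is the dominant uncertainty (a few percent on depth). The penetration depth
is found by bracketed root finding (Brent, xtol 10⁻⁶ mm ≪ the 10⁻⁴ mm
requirement) on the strictly decreasing profile; if the fiber face itself is
below threshold the depth is 0 with a warning. The excited volume is the
closed-form frustum, cross-checked against quadrature of `π R(z)²`.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes — no
more.

- **BOLD**: active voxels are `baseline × (1 + a/100 · (boxcar ⊛ h))` with
  `h` a causal gamma-variate kernel `((t/tp)^α e^{α(1−t/tp)})`, peak time
  3 s and FWHM 3 s by default (α from the Gaussian approximation
  FWHM ≈ 2.355·tp/√α), normalized so `a` is the peak percent modulation.
  All voxels get additive linear drift (0.3%/min default) and white Gaussian
  noise (0.5% of the 1000-unit baseline by default — the regime in which a
  1% responder still carries coherence ≈ 0.5 over six cycles). The 30 s
  rest baseline is prepended as extra frames by default; a flag folds it
  away for runs that start at cycle 1. Not emulated: spatial noise
  correlations, physiological (cardiac/respiratory) structure, motion, MR
  physics, HRF nonlinearity or variability across voxels of one ROI. Tests
  passing on these scenes therefore validate the *estimator logic and its
  calibration under the stated noise model*, not robustness to real-scanner
  artifacts.
- **LFP**: white Gaussian background (50 µV SD) plus injected SLOs — a
  10 Hz carrier under a Hann envelope (0.75 s default), peak amplitude
  expressed in background-SD units (10 SD default), onsets spaced
  `spacing_s ± jitter` (6.6 s default) inside the 20 s stimulation window.
  The count per train is exact; configurations whose events cannot fit the
  window are rejected. Real spindle waxing-waning irregularity and 1/f
  background are not modeled.
- **Spikes**: piecewise-homogeneous Poisson (baseline rate; per-bin gains
  across the stimulation window) plus an optional deterministic
  pulse-locked component (per-pulse fidelity, fixed latency, Gaussian
  jitter). Coincident samples merge to one spike to keep times strictly
  increasing.
- **EEG**: `spike_wave` is a 300 µV 10 Hz fundamental with 2nd/3rd
  harmonics over low noise (power concentrated in the alpha band);
  `low_voltage_fast` is 20 µV white noise. These are caricatures sufficient
  to exercise band-power code, not classifiers' training data.

Every generator takes one explicit seed (`numpy.random.default_rng`); no
global state. Identical seeds give bit-identical outputs.

## Problem sizes in the test suite

The suite favors the smallest sizes at which each property is sharp: 6–12
voxel grids for exactness checks, a 32×32×8 scene (8 192 voxels, 520
frames) for labeled-recovery accuracy, 100 trials for detector
sensitivity/specificity, 10⁵ noise draws for threshold calibration, and
full enumeration oracles only where ≤ 2¹⁸ cases exist. These choices make
the default run complete in well under a minute while keeping every
statistical tolerance at ≥3σ of its Monte-Carlo error.

## Known limitations

- The coherence p-value's t transform is an approximation whose accuracy
  depends on the chosen df convention; the exact Beta null is provided and
  preferred for calibration work.
- Registration, motion correction, spatial smoothing and atlas segmentation
  are out of scope: all volumes must share a grid already.
- The SLO detector reports onsets at the first supra-threshold sample, which
  trails the true envelope onset by the threshold-crossing time of the
  envelope (~0.1–0.2 s for the default spindle shape).
- Spike sorting is out of scope; spike times are inputs.
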