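# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `slowosc`, and what the synthetic-data validation does and does not
establish about real recordings.

## Slow-oscillation analysis

**Trace extraction.** A dF/F0 trace is the ROI-mean intensity per frame,
referenced to a scalar baseline F0 and reported in percent. The default
baseline (`min-frame`) is the ROI mean of the frame with the lowest mean
fluorescence *within the ROI* (earliest frame on ties). Two alternatives are
selectable: `min-frame-global` (the frame with the lowest whole-image mean —
equivalent for whole-field ROIs) and `sequence-mean` (the temporal mean).
The ROI-local minimum is the default because it makes per-ROI band power
invariant to phase offsets between ROIs: with a global minimum frame, a tile
whose trough does not coincide with the image-wide trough is referenced to a
larger F0 and its apparent power drops by up to (1−a)²/(1+a)² even though
its oscillation is unchanged. Note the min-frame baselines are slightly
amplitude-coupled (peak-to-trough reads 2a/(1−a) rather than 2a); the
sequence-mean baseline is amplitude-neutral and is what the amplitude-ladder
validation uses.

**Spectral estimator.** A single-taper (boxcar) periodogram of the
mean-subtracted trace per 50-s epoch, one-sided, density scaling. With this
normalization the integral of the spectral density over all frequencies
equals the trace variance exactly (Parseval; verified to 1e-9 relative),
so band power has the units of dF/F %². No Welch averaging is done within an
epoch — epoching itself provides averaging, and a 50-s window at 20 Hz gives
a 0.02-Hz grid that resolves the 0.6-Hz rhythm exactly. The DC bin is zero
after mean subtraction and excluded from band integrals.

**Band metrics.** Total slow power integrates 0 < f < 1 Hz. "Mean
frequency" is the power-weighted centroid over the analysis band; the peak
(argmax) frequency is also reported since the two differ for broad spectra.
A band whose power is numerically zero (≤ 1e-12 of total power, i.e. pure
spectral leakage) reports NaN rather than a leakage-driven centroid.

**Normalization.** Powers are normalized per stratum (e.g. age) to the mean
of an explicit reference (wildtype) subset, making the reference stratum
mean exactly 1. Strata are configuration, never inferred.

**Grid synchrony.** The field is tiled into 1-mm squares anchored at the
origin (row-major, 0-based; partial edge tiles discarded), one dF/F trace
per tile, pairwise Pearson correlations, and a synchrony index defined as
the mean off-diagonal correlation. Zero-variance tiles produce NaN
correlations that the index ignores.

**Binomial smoothing** (normalized binomial kernel, default order 4,
reflect-padded) is provided for display only; spectra are always computed on
raw traces because the kernel attenuates band power.

## Synthetic VSD movies

Each 1-mm tile follows F(t) = B·(1 + a·w(2πft + φ)), where w is a
sigmoid-edged square wave, `tanh(sin(θ)/0.15)`, mirroring the bistable
up/down membrane states; a pure sine is selectable for closed-form checks.
The square wave's harmonic content lies at odd multiples of f (1.8 Hz and
above for f = 0.6 Hz), outside the sub-1-Hz analysis band. Tile phases are
drawn von Mises with κ = 1/jitter² (jitter 0 → fully synchronized; jitter π
→ nearly uniform). An optional travelling-wave mode adds a linear phase lag
along columns. During a stimulus window every pixel is phase-locked to the
pulse train: a smoothed rectangular up state lasting the pulse width
(20-ms sigmoid edges) at each pulse onset — a phenomenological reset, not a
neural model. Noise is additive Gaussian per pixel. Generators refuse
oscillation or stimulus rates at or above Nyquist.

Defaults follow the recording conditions the analyses assume: 3×3 mm field,
50-ms frame interval, 50-s epochs, 0.6-Hz rhythm, 400-ms pulses at 1.2 Hz
for entrainment. The dF/F amplitude of slow waves has no published scale;
the default a = 0.05 is a generator choice (typical of wide-field VSD
signals) and all validations are either amplitude-relative or use known-a
ground truth. Noisy validations use a 1×1 mm field at 0.1-mm pixels with
per-pixel noise SD 100 on a baseline of 1000: after ROI averaging this
leaves a trace SNR near 5, a deliberately conservative operating point.

## Calcium ratiometry

Preprocessing subtracts, per channel, the modal intensity of the last
z-slice (histogram mode over integer-binned intensities, ties toward the
lower bin), clips at zero, and median-filters each slice with a disk of
radius 2. The ratio volume is voxelwise YFP/CFP with a CFP validity floor
(default 1 intensity unit); invalid voxels are NaN and excluded from ROI
means. ROIs are supplied as label volumes.

The Hill calibration [Ca²⁺] = K_d·((R−R_min)/(R_max−R))^(1/n) is strictly
increasing on (R_min, R_max); R ≤ R_min maps to 0 (underflow) and R ≥ R_max
to NaN (saturation — excluded from concentration summaries but still
classifiable as overloaded by ratio). The packaged constants
(R_min = 1.0, R_max = 2.58, K_d = 235 nM, n = 1) are deliberately pinned so
that the overload ratio threshold 1.79 is the midpoint of (R_min, R_max)
and therefore maps to exactly K_d = 235 nM, preserving the published
ratio↔concentration anchor; true in-situ constants live in external
calibration work and all four values are overridable.

The overload rule is reference mean + 2·SD (sample SD, n−1 denominator);
with no reference sample the packaged threshold is 1.79. Classification is
inclusive (ratio ≥ threshold), which makes ratio-threshold and
concentration-threshold classification provably identical under
monotonicity, boundary included. Overload fractions are reported per
(group, session) stratum in percent.

The synthetic generator draws neurites as ~3-px-thick line segments
(isotropically dilated so the radius-2 median filter preserves their core in
any orientation) with a 4-px exclusion margin so no median window mixes two
neurites; within a mask YFP = R·CFP exactly, a constant background is added,
and the last slice is background-only by construction — so the preprocessing
assumptions hold exactly and the noiseless round trip (generate → preprocess
→ ratio → Hill inverse) recovers the generating concentrations to machine
precision. Photon-like noise (Gaussian with SD ∝ √signal) yields median
concentration errors of a few percent at scale 1.

## Plaque morphometry

Counting operates on the maximum-intensity projection. The threshold is Otsu
by default (deterministic, parameter-free) with a fixed-threshold override;
components are 8-connected; components below 2 µm² are discarded. CAA
(vascular amyloid) is excluded by rule — components touching the image
border or with major/minor axis elongation above 5 — both configurable and
logged. Density divides the retained projected count by the full physical
stack volume (projected area × z extent), matching per-mm³ reporting from
projected counts; burden is the retained foreground fraction in percent.
Longitudinal change is (m₂−m₁)/m₁·100, computed on per-mm³ density for
counts (identical to raw-count change at equal volumes) and on burden
directly; a zero baseline reports NaN. Only integer-pixel rigid offset
correction is provided across sessions — the same field is assumed
re-imaged.

The generator places Poisson(density × volume) Gaussian blobs (σ = r/2)
uniformly in the volume, refusing expected volume fractions above 0.3.
Because placement is uniform, blobs can straddle the image border or overlap
in projection; density validations therefore disable the CAA border rule
(the synthetic volumes contain no vascular signal) and run at densities
where projection overlap is rare. On 0.105-mm³ volumes at 48.3 plaques/mm³
the recovered density is unbiased within 2 SEM over 50 seeds, and detection
recall/precision exceed 0.95. The optional CAA rim is a bright superficial
band along one image edge of the top z-slices, constructed to trigger the
border exclusion rule.

## Statistics

Each group is screened with Shapiro–Wilk at α = 0.05 (a constant group
counts as non-normal); all-normal data use Student's t (2 groups) or one-way
ANOVA (3+), otherwise Mann–Whitney or Kruskal–Wallis with Dunn's
multiple-comparison post-hoc (rank-based z statistics with tie correction,
Bonferroni-adjusted; implemented in-package and checked against a
hand-computed rank example). All tests are two-sided. Significance uses
α = 0.05 for two conditions and α = 0.025 for three or more. Summaries are
mean ± SEM (sample SD/√n; a single-value group reports NaN rather than 0).
Under a Gaussian null the adaptive two-group path rejects at 5% ± 1.5%
(1000 replicates, seeded).

## What synthetic validation does not show

The generators validate the estimators, not the biology: real VSD recordings
contain hemodynamic and photobleaching trends, spatially correlated noise,
and wave propagation; real YC3.6 stacks have bleed-through, depth-dependent
attenuation, and motion; real plaque fields have nonuniform background and
genuinely ambiguous CAA. Passing tests establish that the pipeline recovers
known ground truth under its stated noise models at the study's operating
points — they do not certify performance on data whose artifacts violate
those models.

## Problem sizes

Validation runs use desk-scale inputs chosen to exercise the estimators at
full statistical fidelity: 50-s, 20-Hz epochs (1000 frames); 100 seeded
runs for frequency recovery; 50 replicate 0.105-mm³ volumes for density;
1000 replicates for the type-I-error calibration; 200 replicates for the
Poisson goodness-of-fit check.
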