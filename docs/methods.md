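# Methods

This note documents the models behind `amciscreen`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical decisions a user should know before trusting a number.

## Synthetic study conditions

The pipeline is exercised on synthetic data because the clinical recordings
this class of analysis targets are private. The generators' defaults *are*
the study conditions:

* **Paradigm** — six photic-stimulation frequencies (3, 5, 10, 12, 15,
  20 Hz), 10 s stimulation alternating with 10 s rest, 120 s total;
  19-channel 10-20 EEG at 200 Hz.
* **Cohort** — two groups ("HC", "aMCI") of 24 subjects each. Feature
  marginals are moment-matched to the published group means/SDs of the six
  behavioral and eight significant neurological features.
* **Cross-modal structure** — the six reported significant behavioral ×
  neurological Pearson correlations (e.g. −0.40 between the 12 Hz
  fundamental lobe power ratio and hand movement speed) are planted through
  a Gaussian copula.

### EEG generator

During each stimulation block, addressed channels receive sinusoids at
f·n (random phase per channel and block) with per-lobe amplitudes;
harmonic amplitudes default to a 1/n rolloff, the typical SSVEP decay.
Background noise is pink (1/f amplitude) plus white Gaussian, 10 + 2 µV RMS
by default — no noise model is prescribed by the analysis itself; this
level leaves harmonic peaks clearly detectable in a 10 s block, which is
the regime the feature definitions presuppose. The generator does **not**
emulate volume conduction with a head model, electrode artifacts beyond
what the artifact-removal tests inject, or non-stationary background
rhythms; consequently, passing tests demonstrate correctness of the
*computations*, not robustness to every property of clinical EEG.

### VR session generator

A session log is constructed to *realize* requested feature targets: gaze
and hand streams are 3-D random walks whose cumulative lengths equal the
requested scanpath/hand distances, AOI labels are allocated so the
target/menu dwell ratio equals the requested fixation proportion, and the
six step-completion events (plus error events at random interior times)
close with the step-6 completion at the requested duration. Since the
extractor defines hand speed as distance / task time, the targets accept
any two of {time, distance, speed} and derive the third; an inconsistent
triple raises. Logs are sampled at 50 Hz — headset eye trackers log faster,
but all six features are sums or time-ratios over the session and are
insensitive to the logging rate; 50 Hz keeps 20 000-session runs cheap.
Saccade dynamics, tracker noise and blinks are not modeled (missing gaze
samples are supported by the extractor — dropped, never interpolated).

### Cohort sampler

Marginal families follow the shape of the published group statistics:
log-normal for strongly right-skewed magnitudes (scanpath length, hand
movement distance, time to completion — SD ≈ mean), negative binomial for
the overdispersed error count, zero-truncated Gaussian for roughly
symmetric positive quantities (fixation proportion, hand speed), Gaussian
for the eight neurological ratios. All families are moment-matched to the
published (mean, SD); truncation mass is negligible at these calibrations
(≥ 3 SD from the bound) so the match is effectively exact. The joint
distribution is a Gaussian copula: `cross_modal_corr` entries are *latent*
correlations, which coincide with the Pearson targets for the (near-)
Gaussian marginals involved in the planted pairs; for strongly non-Gaussian
marginals the realized Pearson r would be attenuated slightly. The
distributional forms are declared package choices — the original study
reports only means and SDs.

## Preprocessing

`zero_mean` subtracts each channel's mean. `remove_artifacts` is a
deliberately simple, documented wavelet eliminator exposed behind a stable
interface (a faithful third-party artifact-removal implementation can be
substituted): db4 decomposition to 5 levels in 1 s windows with 50%
overlap and Hann overlap-add reconstruction; per channel and per band the
threshold is θ = (β/0.1) · 1.5 · Q₀.₉₉₉(|coefficients|) pooled over all
windows of the recording, and coefficients above θ are zeroed
("elimination"). Pooling across the whole recording means a rare
large-amplitude transient cannot inflate its own threshold, while at the
default β = 0.1 the thresholds sit above the coefficient range of clean
bounded signals, which therefore pass nearly unchanged. Smaller β lowers
every threshold and removes more; this attenuation is monotone over the
artifact-targeting range (β ≳ 0.02). At extreme β the eliminator also
removes signal-band coefficients, and the residual error versus the clean
signal saturates at the spike's contribution to the surviving bands — a
regime outside the intended use. Whether artifact removal should run per
block or over the whole record is unspecified in the original study; this
implementation processes the whole record (thresholds pooled globally),
which is the more stable estimator.

## Spectral pathway

`time_frequency` is a sliding-window DPSS multitaper spectrogram: 500 ms
windows, 100 ms steps, 3 tapers at time–bandwidth product NW = 2 (8 Hz
full-width smoothing), FFT zero-padded to a 1 Hz grid over 1–50 Hz. The
method description also mentions a Hann-tapered FFT; `taper="hann"` runs
that single-taper reading, so both interpretations remain available.

**Calibration.** Window spectra are normalized so a sinusoid of amplitude
a, at a bin frequency, reads its mean-square power a²/2 (µV²): with
unit-energy tapers h_k the raw taper-averaged power at the sinusoid bin is
(a²/4)·C with C = mean_k |Σ_t h_k[t]|², so powers are divided by C/2. This
matters because the lobe power ratio is a ratio of *dB values*: an unknown
multiplicative power scale would shift both dB numbers by the same additive
constant and change the ratio. With this normalization, a planted
parietal/occipital dB ratio is recovered to ~1e-4 in noise-free simulation.

`harmonic_power` averages linear power over the block's window centers,
excluding 250 ms at each block edge (half a window) so smearing across the
block boundary does not dilute the estimate, then converts to dB with a
−120 dB floor replacing −∞ for zero power. `lobe_power` averages electrode
dB values directly — the dB conversion precedes channel averaging, the
only reading under which lobe ratios of 0.7–0.8 are meaningful — while
`average="linear"` averages linear power first instead.
`extract_power_features` emits `<f>PS-POR-<n>H` for every f in the schedule
and every harmonic with f·n < 50: 38 features for the full paradigm. (The
original study reports 17 lobe-power-ratio features without giving the
restriction that produces 17 from this domain; the package emits the full
rule-derived domain and leaves subsetting to the caller. Likewise the
stated count of 24 band connectivity ratio features cannot be reconciled
with TBR + ABR over six frequencies, which yields 12 — the package emits
those 12.)

## Connectivity pathway

wPLI is estimated per stimulation block as |E[Im S_ij]| / E[|Im S_ij|]
over 1 s Hann segments with 50% overlap (segment length configurable); the
per-bin wPLI is averaged over the integer-frequency bins inside the
half-open band intervals θ [4, 8), α [8, 12), β [12, 30), γ [30, 50) —
half-open so each edge frequency belongs to exactly one band. Entries whose
imaginary cross-spectrum is pure floating-point rounding of a real
cross-spectrum (zero-lag coupling) are set to 0 rather than left as noise
ratios. With ~19 segments per 10 s block the null wPLI bias is ≈ 0.2;
null-level checks therefore use longer blocks, where the estimator
converges toward 0.

The Onnela clustering coefficient is implemented with the cube root on the
triple product and normalization 1/(deg(e)(deg(e)−1)) over ordered neighbor
pairs — the standard reading of the printed formula. deg(e) counts
nonzero-weight neighbors; since wPLI graphs are effectively complete,
deg = N−1 unless the optional proportional-threshold sparsifier is applied.
C(e) is defined as 0 when deg(e) < 2 (the no-triangle limit), and weights
are *not* renormalized by the maximum weight by default (wPLI is already
bounded in [0, 1]); `normalize=True` restores Onnela's w̃ scaling.

## Statistics

The ladder uses a Lilliefors-corrected KS normality test (Gaussian with
sample-estimated mean/SD) at α = 0.05 on *either* group to enter the rank
branch; the rank test defaults to the Mann–Whitney rank-sum, which is the
valid test for two independent groups — the literal signed-rank variant
(pairing equal-n groups by sorted order) is available via
`rank_mode="signedrank"` for fidelity with the original report. Levene's
test uses the mean-centered variant at α = 0.05. BH correction is applied
within three separate families, matching how the analyses are reported:
the six behavioral tests, the neurological tests, and the correlation
grid. On 2000 null simulations (n = 24 per group) the ladder's empirical
type-I rate is ≈ 4–5% at nominal 5%.

## Classification

Standardization (train-fold z-scores), embedded selection and grid search
are all fit on the training fold only; reported SDs come from repeated
seeded stratified splits (default 30), the only mechanism consistent with
nonzero SDs on held-out metrics. The stratified split rounds per class
(round(0.7 · 24) = 17), giving exactly 34 train / 14 test on the 24 + 24
cohort. Embedded selection keeps features with |coefficient| strictly
above the mean importance (a feature exactly at the average counts as
below-average); if the rule selects nothing (identical features), the
benchmark falls back to the full set rather than fit on zero features.
Whether selection ran once globally or per split is unspecified in the
original study; the default here is per split (leakage-safe), with
`selection="global"` available. Default grids hold the single tuned
hyperparameter point per family; wider grids can be passed. AUC uses the
model's continuous scores (probability outputs where available). Note that
LOOCV on balanced classes is pessimistically biased under the null
(~41% rather than 50% on permuted labels) because the held-out subject's
class is always the training minority; this is a property of LOOCV, not a
defect of the implementation.

Problem sizes used by the shipped checks — 20 000 sessions/rows for
calibration recovery, 2000 simulations for the type-I rate, 30 benchmark
repeats — were chosen as the smallest sizes at which the quantities'
sampling error is well inside the stated tolerances.

## Known limitations

* The synthetic EEG contains no volume conduction, so wPLI graphs have no
  realistic spatial structure; connectivity features on synthetic cohorts
  are calibrated directly at the feature-table level instead.
* The 50 Hz VR logging rate and the random-walk gaze/hand geometry are
  sufficient for the six summary features but not for fixation/saccade
  research.
* The artifact remover is a simplified eliminator; it is interface-
  compatible with, but not a re-derivation of, tunable wavelet artifact-
  removal algorithms from the literature.
* Classification numbers on synthetic cohorts characterize the pipeline's
  behavior under planted effects; they are not estimates of clinical
  screening performance.
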