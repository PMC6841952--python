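# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, and what the synthetic-data validation does and
does not establish.

## Auditory model

The frontend is a two-stage linear–nonlinear cascade.

**Cochlear stage.** The waveform is filtered into 34 subbands by 4th-order
gammatone filters whose center frequencies are equally spaced on the ERB_N
scale between 50 and 8097 Hz (ERB_N(f) = 24.7·(4.37 f/1000 + 1); the
gammatone decay parameter is 1.019·ERB_N of the center). Filtering is
zero-phase in the frequency domain with analytically evaluated magnitude
responses. Two residual channels — a lowpass below the first center and a
highpass above the last — fill the band edges, and the complete bank is then
power-normalised per frequency bin so that Σ_k |H_k(f)|² = 1 exactly. Because
the filters are real and zero-phase, the synthesis (paraconjugate) bank equals
the analysis bank and reconstruction is the exact transpose: the round-trip
error on broadband noise is at machine precision, far below the −40 dB
transparency target. The normalisation slightly reshapes the gammatone skirts
(at most a fraction of a dB mid-band); the residual channels carry no
statistics.

Pointwise normalisation also fixes the overlap structure: adjacent channels at
~0.96-ERB spacing share ~15% of their power, so a pure tone at a channel's
center puts ~85% of the subband energy in that channel and nearly all the rest
in its immediate neighbours.

**Envelope stage.** Subband envelopes are the magnitudes of the analytic
signal (Hilbert transform), raised to the power 0.3 — a standard model of
cochlear compression. Compression is applied to the envelope rather than the
signed subband waveform: for the narrowband signals a cochlear channel
carries, the two are equivalent, and envelope-domain compression avoids the
harmonic splatter a signed power law would create. Envelopes are anti-alias
filtered (FIR lowpass, cutoff 0.45·400 Hz) and polyphase-resampled to 400 Hz;
small negative resampling overshoots are clipped to zero.

**Modulation stage.** Each compressed envelope is filtered into 18 modulation
bands with half-octave spaced centers 0.5·2^(n/2) Hz (n = 0…17, i.e.
0.5–181 Hz) and constant Q = 2. The filters are zero-phase with Gaussian
magnitude on a log-frequency axis; the σ of the Gaussian is set so the
full-width-half-maximum bandwidth in Hz equals center/Q. The DC bin is zeroed,
so a constant envelope produces null modulation bands.

## Texture statistics

With window weights w(t) summing to one (uniform by default — nothing in the
procedure requires a taper, and a uniform window keeps segmented measurements
consistent), the statistic vector concatenates:

| class      | definition                                   | count (default) |
|------------|----------------------------------------------|-----------------|
| env_mean   | μ_k = Σ_t w·x_k                              | 34              |
| env_cv2    | Σ_t w·(x_k−μ_k)² / μ_k²                      | 34              |
| env_skew   | Σ_t w·(x_k−μ_k)³ / σ_k³                      | 34              |
| env_corr   | weighted Pearson r for pairs k−j = 1…8        | 236             |
| mod_power  | Var_w(b_{k,n}) / σ_k²                        | 34×18 = 612     |
| mod_corr   | weighted Pearson r across channels (k−j=1,2) at bands 3,5,7,9,11,13 (1–32 Hz) | 390 |

Envelope kurtosis is deliberately excluded. The modulation-correlation
denominator uses the weighted standard deviations of the modulation bands
themselves — the only reading that keeps the values in [−1, 1]. Channels or
bands with (numerically) zero variance are degenerate: the affected statistics
report 0 and carry a flag instead of raising, so silent channels do not abort
corpus runs. Under a global gain g every class is invariant except env_mean,
which scales as g^0.3.

## Synthesis

A target vector ζ* is imposed on a Gaussian noise seed (rms 0.1, deterministic
per seed) by an analysis–synthesis loop:

1. decompose the current signal and extract compressed envelopes (34 × T at
   400 Hz);
2. minimise Σ_classes Σ_i (ζ_i − ζ*_i)² / m_class over the envelope matrix
   with L-BFGS-B (nonnegativity as box bounds, memory 10, 80 inner iterations),
   where m_class is the mean squared target magnitude of the class — this
   balances classes whose natural scales differ by orders of magnitude. All
   gradients are analytic (the statistics are smooth functions of the envelope
   samples; modulation filtering is a symmetric linear operator, so its
   adjoint is itself). A finite-difference check is part of the test suite.
3. impose the optimised envelopes on the audio-rate subbands: divide each
   subband by its own envelope and multiply by the optimised one, both taken
   through the same upsample-then-decompress (power 1/0.3) pathway, with an
   epsilon guard of 1e−8 of the envelope maximum;
4. reconstruct, then run two per-channel gain-correction passes that match
   the envelope means exactly (multiplicative fixpoint). This step exists
   because cross-channel leakage on reconstruction otherwise makes the
   spectral (env_mean) class converge an order of magnitude more slowly than
   the rest;
5. repeat until every class's error SNR, 10·log10(Σζ*²/Σ(ζ−ζ*)²), reaches
   20 dB, or 60 outer iterations.

Non-convergence returns the best signal reached with a flag, never an
exception. Typical behaviour on an AM-noise target: convergence in ~13 outer
iterations (~1 minute for 2 s of audio on one CPU). Different noise seeds give
distinct exemplars (waveform cross-correlation peak well below 0.9) with the
same statistics. The 20 dB criterion and the iteration caps are package
choices; no universal stopping rule exists for this family of synthesis
systems.

**Morphs** synthesize from ζ interpolated linearly between a "mean" texture
and a reference, with the envelope means pinned to the mean texture's so the
spectrum is constant along the morph line; correlations are clipped to
[−1, 1] after interpolation. A preset grid (0, 0.25, 0.35, 0.4, 0.45, 0.55,
0.6, 0.65, 0.75, 1) is provided. **Steps** synthesize signal A from the first
statistics, then synthesize B from the second statistics *using A as the
optimisation seed*, and splice with rectangular windows at the step time; the
shared seed keeps the fine structure continuous across the step.

## Sound metrics

**Stationarity** follows a seven-step recipe: split the signal into adjacent
segments (lengths 0.125, 0.25, 0.5, 1, 2 s; trailing partials discarded),
measure the statistics per segment, take the standard deviation of each
statistic across segments (population sd), average within each class,
normalise each class by its median across the corpus, average across classes,
average across segment lengths, and take the negative natural logarithm. The
metric is therefore corpus-relative — a single sound has no stationarity
without a reference set — and the implementation requires ≥ 2 sounds. For
speed, segment statistics reuse one whole-signal envelope/modulation
decomposition and window the frames, rather than re-filtering each segment;
the difference is confined to segment edges.

A caveat discovered during validation: sinusoidal AM whose period divides the
segment lengths (e.g. 4 Hz against 0.25/0.5/1/2 s) presents the *same*
modulation phase to every segment and is genuinely segment-stationary — it can
measure as stationary as unmodulated noise. Periodic sounds are separated from
textures by the periodicity metric, not necessarily by stationarity; the
class-separation tests therefore use square-wave (gated) AM, whose on/off
alternation at the shortest segment length produces robust segment-to-segment
variability.

**Statistical distance** z-scores each statistic across the sound set under
analysis and returns the Euclidean norm of the difference — an exact metric
(identity, symmetry, triangle inequality). The standardisation record carries
a config hash and refuses vectors measured under a different model.

**Spectral/temporal density** are the negative natural log of the linear
cochleagram's variance across frequency (per frame, time-averaged) or across
time (per channel, frequency-averaged), floored at 1e−12 inside the log. The
values depend on the input scale through the compressed envelopes; compare
sounds at matched rms.

**Periodicity** is measured on the Hilbert envelope of the *broadband*
waveform (uncompressed), downsampled to 400 Hz, mean-removed, and
autocorrelated with lag-0 normalisation; the value/lag of the largest local
peak at lags of 125–500 ms (2–8 Hz) is returned, with a flag when no interior
local peak exists.

## Stimulus construction

Levels are rms-referenced dB (0 dB = rms 1); SPL calibration is a property of
playback hardware, not of waveforms. Crossfades use complementary
raised-cosine amplitude ramps (fade-in + fade-out = 1 at every sample,
sample-phase centred so the crossfade midpoint falls exactly at the nominal
boundary). The canonical interrupted-stimulus geometry concatenates
2.01 + 2.02 + 1.01 s excerpts with 20 ms ramps, giving exactly 5.000 s with
junction midpoints at 2 and 4 s; the masker *replaces* the inducer (no
superposition) except in control builds, where the inducer's middle is
superimposed 6 dB above the masker. Optional 200 ms silent gaps replace the
masker's first and/or last samples, with 20 ms edge ramps. Amplitude contours
for control trials are a single raised cosine whose phase and period produce
the requested shape over the 2 s window: dip = one full period peaking at the
edges, glimpse its complement, fade-in/out = a half period, continuous/absent
= 1/0.

The masker-level search scales the masker over a half-dB SNR grid
(−30…+30 dB re the inducer) and returns the highest SNR (quietest masker) at
which the mean absolute difference between the dB cochleagrams of the masker
and of masker + inducer is ≤ 3 dB. The difference is monotonically
non-increasing in masker level, so the implementation bisects the grid;
cochlear filtering is linear, so the analytic subbands of the two sources are
computed once and recombined per level.

## Psychometrics

The psychometric function is p(x) = γ + (c−γ)/(1 + exp(−(x−α)/β)) with the
range (γ, c) fixed by the task — (0.5, 1) for 2AFC detection, (0, 1) for
continuity — and (α, β) fitted by least squares to the across-participant mean
proportions (a Bernoulli maximum-likelihood option exists). Monotone
decreasing data are fitted as the reflected curve with β kept positive. The
PSE is α; the threshold at a fraction f of the dynamic range is
α + β·ln(f/(1−f)), so f = 2/3 gives the 0.833 point on a 2AFC range and the
0.667 point on a 0–1 range.

Step bias = PSE(up) − PSE(down). Uncertainty comes from a bootstrap that
resamples *participants* with replacement (the unit at which the experiment's
error is reported), recomputes mean curves, and refits; the CI is the 2.5–97.5
percentile interval and the p-value is the two-tailed tail probability of zero
under a Gaussian fitted to the replicate distribution. Bootstrap refits use a
vectorised Levenberg–Marquardt least-squares fitter (all replicates advanced
in parallel in numpy), validated in the tests against the scipy-based scalar
fit; this keeps 10,000-replicate bootstraps and repeated-simulation
calibration runs fast. Disattenuated correlation r_xy/√(r_xx·r_yy) is clipped
to [−1, 1] with a flag. Split-half reliability averages the Pearson
correlation of per-item means over random half-splits of participants (halves
differ by one for odd counts).

## Synthetic data

Generators are pure functions of (spec, seed): stationary Gaussian noise;
bandpass-filtered noise (default 500–4000 Hz, 4th-order Butterworth);
periodically amplitude-modulated noise at 2–8 Hz with depth in [0, 1]
(sinusoidal by default, square-gated as an option — see the stationarity
caveat); and sparse event trains (50 ms raised-cosine noise bursts at a 2 Hz
Poisson rate over a −40 dB floor). All are normalised to rms 0.1. Corpora
derive per-sound seeds from a master seed via `SeedSequence`, so subsets are
independently reproducible.

Simulated observers respond with Bernoulli draws from a range-limited logistic
in the stimulus variable. The simulated step experiment uses the 10-position
morph grid, 13 participants (the cohort size such discrimination experiments
typically retain after exclusions), 4 trials per cell (one per reference
texture per condition–position pairing), participant baseline jitter of
sd 0.05 on the morph scale (shared across conditions, which is what makes the
participant bootstrap meaningful), and slope β = 0.1.

Validation against these generators shows that the pipeline is *internally*
correct — statistics match an independent oracle, synthesis reproduces its
targets, fits recover known parameters, the bias test is calibrated under the
null (≈8–9% rejections at p < 0.05 with 13 participants; the participant
bootstrap is mildly anti-conservative at small cohort sizes) and has power
against a 0.3 bias. It does not show that the model predicts human perception,
and the synthetic classes do not mimic the spectral detail of specific natural
recordings — only the class-level statistical structure (stationary vs
periodic vs sparse) that the metrics are designed to separate.

## Windowed statistic measurement

Statistics of part of a signal (e.g. the two halves of a step stimulus) are
measured by applying rectangular statistic weights w(t) over the
*full-signal* decomposition, not by re-decomposing the excerpt: the slowest
modulation filters have impulse responses of seconds, and filtering a
truncated excerpt corrupts their bands. Even so, half-window estimates have
an intrinsic sampling floor set by the number of independent modulation
excursions in the window. For weakly structured targets (e.g. sinusoidal AM,
whose cross-channel modulation correlations are near zero outside the AM
band) that floor sits near 10 dB and no synthesis quality can beat it;
strongly comodulated textures (the `comod_noise` class, with true
correlations near 1 across all measured bands, whose estimators have variance
∝ (1−r²)²) have floors of 18–20 dB. Step-synthesis validation therefore uses
comodulated targets, selected by this floor — a property of the source
stimulus computable before any synthesis — and a 22 dB step convergence
criterion so the synthesis residual sits below the floor.

## Problem sizes

The validation suite and the acceptance script use: 2 s syntheses for
convergence checks and a 5 s step synthesis with the step at 2.5 s
(statistics measured in the two half-windows as above); a 12-sound metric
corpus of 10 s sounds (segment statistics of shorter sounds are too noisy for
the small noise-vs-AM stationarity gap); 100-seed psychometric recovery at 10
levels × 100 trials; and 200 null + 100 power simulations of the step
experiment at 1000 bootstrap replicates each.

## Known limitations

- No outer/middle-ear filtering, adaptation, or neural noise; mono only.
- The gammatone phase convention is zero-phase; systems built on causal
  (minimum-phase) gammatones will differ in fine timing.
- The statistics window is uniform; tapered windows would change segment
  statistics slightly.
- Density metrics are scale-dependent by construction.
- The synthesis stopping rule (20 dB/class, 60 outer iterations) is a
  documented package choice.
- WAV I/O supports PCM16 and float32 mono.
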