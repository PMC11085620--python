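# Methods

This note documents the models, numerical choices and limitations of
`bcgvitals`: a pipeline that estimates heart rate (HR) and respiratory
rate (RR) from ballistocardiogram (BCG) waveforms by adaptive-noise
empirical mode decomposition, R-R interval cleaning, autoregressive
(AR) spectral heart-rate-variability (HRV) features, and a CNN-LSTM
estimator.

## Synthetic BCG model

No public BCG corpus ships with the package, so every stage is
validated against a generative model with exact ground truth. A
recording is the sum of four components, returned separately so their
sum reconstructs the emitted waveform to machine precision:

- **Cardiac pulse train.** A template placed at jittered beat times.
  The template is a Gaussian bump (sigma = 0.8 x `pulse_width_s`,
  default width 0.25 s) carrying a damped wiggle at `1/pulse_width_s`
  Hz, giving each cycle the multi-extremum I-J-K-like morphology that
  exercises sifting non-trivially. The bump concentrates spectral mass
  at the beat-train fundamental, so the largest cardiac spectral line
  sits at `hr_bpm/60` Hz rather than at a harmonic; the template's
  global maximum is at the beat time, which makes detected peak times
  directly comparable to ground truth. Beat-to-beat intervals are
  `60/hr_bpm` seconds plus Gaussian jitter (`hrv_jitter_ms`, default
  25 ms), clipped to [0.3, 1.7] x the mean to stay physiological.
- **Respiration.** A sinusoid at `rr_brpm/60` Hz, relative amplitude
  0.4.
- **Drift.** A 0.01 Hz oscillation, relative amplitude 0.15 —
  baseline wander slower than the respiratory band.
- **Noise.** White Gaussian with standard deviation `noise_sd`
  (default 0.05, i.e. roughly 18 dB below the cardiac RMS).

Defaults describe a resting adult (72 bpm, 15 breaths/min). The
generator does **not** emulate heteroscedastic sensor noise, motion
artifacts, posture changes, fringe fading of the optical front end, or
HR/RR drift within a recording; conclusions from synthetic benchmarks
are therefore about pipeline correctness and ordering, not clinical
accuracy.

The R-R generator draws intervals around `60000/hr_bpm` ms and
injects, per beat with probability `ectopic_rate`, an interval scaled
by 0.5x or 1.6x (equal probability) — both factors guaranteed to
violate the 1.3x/0.7x-of-mean outlier bounds in each direction. The
AR generator validates stability (all poles strictly inside the unit
circle) and discards a 500-sample burn-in.

## Decomposition

`emd` implements classical sifting: cubic-spline envelopes through
local maxima/minima, subtract the envelope mean, repeat until the
iterate satisfies the intrinsic-mode conditions (extrema and
zero-crossing counts differing by at most one; envelope mean at most
`mean_tol` = 0.1 of the peak amplitude) *and* the sift-to-sift
standard-deviation statistic — the sum over samples of squared change
divided by the squared previous iterate, zero-denominator samples
excluded — falls below `sd_threshold` (default 0.2). Extraction stops
when the remainder has fewer than two maxima or two minima; the
residue is the input minus the IMF sum, so reconstruction is exact by
construction.

Numerical choices:

- **Boundary handling.** Two extrema are mirrored about each end
  before spline fitting, the standard mitigation of end swings.
- **Sift cap.** With a pointwise denominator the SD statistic is
  dominated by samples near zero crossings of the previous iterate and
  in practice never falls below classical thresholds, so the iteration
  cap is the effective stop. The default cap is 10 — the common
  fixed-sift practice — because longer sifting over-decomposes
  (more, worse modes) at proportional cost. When the cap is hit, the
  most recent iterate satisfying the extrema/zero-crossing condition
  is returned and the sift count is negated as a non-convergence flag.
- **Plateaus** in the extrema finder are collapsed onto their trailing
  edge via forward-filled slope signs.

`eemd` averages index-aligned EMD modes of `ensemble_size`
noise-perturbed copies (noise amplitude = `noise_amplitude` x the
signal's standard deviation; members with fewer modes are
zero-padded). Its reconstruction error equals the mean of the added
noises, whose RMS shrinks as `1/sqrt(N)`.

`dema` is the complete-ensemble adaptive-noise variant: stage k
averages, over the ensemble, the first sifted mode of the current
residue perturbed by the k-th EMD mode of stored unit-variance noise
realizations, re-scaled to `noise_amplitude` x the residue's current
standard deviation. The averaged mode is subtracted and the procedure
recurses, so reconstruction is exact for any seed and ensemble size,
and with zero noise and a single member the method coincides with
plain EMD bit for bit. Ensemble-averaged modes satisfy the strict
extrema/zero-crossing parity only approximately (averaging is not a
sift); the parity check therefore applies to sifted EMD modes.

Mode mixing is quantified by `mode_mixing_index`: the band energy of a
reference tone found *outside* the IMF that carries it (carrier = the
IMF best correlated with the tone over interior samples), normalized
by the tone's band energy. On the noisy two-tone fixture this index is
reliably lower for the adaptive-noise ensemble than for plain EMD; the
naive alternative (fast-band energy inside the slow IMF) is near zero
for both methods because mixing manifests as the fast tone splitting
across adjacent IMFs.

## R-R preprocessing

Beats are detected on the cardiac-band partial reconstruction (sum of
IMFs whose dominant periodogram frequency lies in 0.7-3 Hz) when a
decomposition is available, otherwise on the zero-phase
Butterworth-band-passed waveform; peaks must clear 1.5 robust standard
deviations (median absolute deviation scaled) and respect a 0.3 s
refractory period. An interval is an outlier when it exceeds 1.3x or
falls below 0.7x the global series mean (computed once, before
correction); each outlier is replaced by the median of its up to 30
nearest valid neighbours, and the bounds are re-checked once against
the corrected series. Literal squaring of the neighbourhood median is
dimensionally inconsistent (ms squared) and would itself violate the
bounds, so the correction is the plain median. Windows are
non-overlapping, aligned to the first beat, 300 s by default;
intervals belong to the window containing their terminating beat and a
trailing partial window is dropped.

## HRV features

Time domain: mean RR, SDNN, RMSSD, pNN50, HR = 60000/meanRR.
Frequency domain: the unevenly sampled tachogram is cubic-spline
resampled to 4 Hz (AR spectra over Hz bands require uniform
sampling), an AR(16) model is fitted to the biased autocorrelation via
the Levinson-Durbin recursion, and band powers are integrated over
VLF 0.003-0.04, LF 0.04-0.15 and HF 0.15-0.4 Hz. The evaluated
density follows `sigma^2 / (fs |1 - sum a_m e^{-i2pi f m/fs}|^2)` on
[0, fs/2]; band powers double it so that twice the half-band integral
recovers the process variance (Parseval). LF/HF is reported as NaN
when HF power is zero. Yule-Walker/Levinson-Durbin is used rather than
Burg: the recursion is the named method, and its prediction-error
variance `r0 prod(1-k_i^2)` feeds the spectrum directly. Features are
z-scored before PCA (mixed units); components are kept up to 95%
cumulative explained variance.

## Network and training

The estimator consumes a 6 x 1 x 56 x 1 grid per analysis window: six
equal sub-segments, each contributing 8 scalars (segment mean RR,
SDNN, RMSSD, HR from detected beats; RMS amplitude; cardiac-band
spectral centroid; whole-window and segment respiratory-band
centroids) plus a 48-bin log-periodogram over 0.05-3.05 Hz of the
(decomposition-denoised, when available) waveform. The reference stack
is Conv(32) - LeakyReLU - MaxPool - Dropout - Conv(64) - LeakyReLU -
MaxPool - Dropout - FC(512) - LeakyReLU - LSTM(512, sequences) -
LSTM(222, last step) - FC(222) - Softmax, applied time-distributed
over the six steps; `build_network` verifies the 14-row output-shape
trace and reports the first mismatching layer. Convolution kernels are
(1, 3) with same padding; LeakyReLU slope 0.01; dropout 0.3
(inverted, identity at inference).

Two heads are provided. The softmax head classifies into 222 uniform
bins decoded to bin centres — HR default [40, 151] bpm at 0.5 bpm,
RR default [4, 59.5] breaths/min at 0.25 — with cross-entropy loss.
The regression head replaces the last two layers with a linear map
(z-scored targets, MSE loss). One model is trained per target.
Training uses Adam at batch size 1 and learning rate 1e-4 by default,
an 80/20 train/test split, optional 10-fold cross-validation indices,
and early stopping with patience 10; all randomness (initialization,
shuffling, dropout) flows from one seed, so runs are bit-reproducible
on one device. The whole stack is float64 NumPy with hand-written
backpropagation, which lets analytic gradients be checked against
central finite differences at 1e-4 relative tolerance.

## Benchmark configuration

The end-to-end synthetic benchmark (`run_benchmark`) uses 5 subjects x
10 minutes at 50 Hz, HR drawn from [55, 90] bpm and RR from [10, 22]
breaths/min per subject, noise 0.05, decomposition by the
adaptive-noise ensemble (size 8), and 60 s analysis windows — 50
windows, 40 train / 10 test. Sixty-second windows are the package's
desk-scale choice so a small cohort yields enough training windows;
the 300 s default of the preprocessing stage is unchanged. The
benchmark network keeps the reference topology at reduced width
(conv 4/8, FC 24, LSTM 16/8, regression head, lr 3e-3, up to 60
epochs) — the full-width stack trains at the same code path but is
unnecessary for a 40-window problem. Typical held-out errors are well
under 1 bpm (HR) and 0.1 breaths/min (RR); these reflect the clean,
stationary synthetic conditions, not expected performance on real
recordings.

## Known limitations

- Synthetic subjects have constant HR/RR per recording, so per-subject
  R-squared on a constant-RR target is undefined (reported as NaN).
- On the synthetic benchmark the decomposition-denoised feature route
  does not consistently beat the raw-waveform route: the periodogram
  and band-centroid features are themselves noise-robust, so at desk
  scale the end-to-end benefit of decomposition is within seed
  variance (the mode-mixing reduction itself is real and tested at
  the decomposition level). Expect the gap to matter more on real
  recordings with structured, non-white interference.
- The ensemble decompositions are the pipeline's cost centre; ensemble
  sizes above ~20 are rarely worth it on the synthetic fixtures.
- Beat detection assumes the cardiac pulse maximum marks the beat;
  real BCG J-peak timing varies with posture and sensor coupling.
- The comparison harness's SVR and BP (multilayer perceptron)
  baselines are thin, untuned references for table structure, not
  faithful re-implementations of any published baseline.
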