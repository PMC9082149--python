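# Methods

## Problem and model

The package reconstructs a subject's lead-II ECG from their
simultaneously recorded PPG.  Both signals are driven by the same
cardiac cycle: the ECG records the heart's electrical activity, the PPG
the resulting peripheral blood-volume pulse, delayed by the pulse
arrival time (PAT).  The reconstructor is deliberately *subject-specific*
— one model per record — because the PPG→ECG transfer differs between
individuals, especially in circulatory disease.

The mapping is learned by a sequence-to-sequence bidirectional LSTM that
consumes an n-second PPG window (fs·n timesteps, one feature each) and
emits the co-temporal ECG window.  Working on fixed n-second windows
rather than beats is a deliberate design point: it requires no beat
detection at inference time and sidesteps beat-segmentation errors.

## Preprocessing

* **Band-pass filter.** Fourth-order Chebyshev type-II, ECG passband
  0.5–20 Hz, PPG 0.5–10 Hz.  The stopband attenuation (40 dB) and the
  stopband-edge placement (0.5× the lower and 1.25× the upper passband
  edge) are this package's choices — a standard, stable design at these
  orders.  The filter runs zero-phase (forward–backward, cascaded
  second-order sections): Alignment I compares peak *indices* across
  channels, and phase distortion would corrupt the measured lag.
  Second-order sections keep the 0.5 Hz edge numerically stable at
  fs = 125 Hz.
* **R-peak detection.** Pan-Tompkins: 5–15 Hz band-pass, derivative,
  squaring, 150 ms moving-window integration, adaptive signal/noise
  thresholds with search-back, 200 ms refractory period; each detection
  is refined to the local ECG maximum so indices mark the R wave itself.
* **Systolic-peak detection.** Two event-related moving averages: the
  clipped, squared PPG is smoothed with a 111 ms (peak-scale) and a
  667 ms (beat-scale) window; blocks where the short average exceeds the
  long one plus 0.02× the mean power, and that are at least one
  peak-width wide, each yield one systolic peak.
* **Alignment I.** For each R peak, its systolic partner is the first
  systolic peak in [R_k, R_{k+1}); the left edge is inclusive so a zero
  PAT still pairs the beats.  The PPG is shifted left by the lag of the
  third systolic peak relative to its R peak (the first beats of a
  record are often unreliable for detectors; if the third beat has no
  partner, the next paired beat is used and a warning logged), and both
  channels are truncated to common support.  The shift is applied to the
  PPG, not the ECG, because the operation removes the PPG's physiological
  delay.
* **Normalization.** PPG min-max scaled to [0, 1] over the whole aligned
  record — normalization precedes splitting in the pipeline order.  This
  leaks the test interval's min/max into training inputs; callers who
  need strictly leakage-free inputs can normalize the training minute
  only and apply those statistics throughout.  The ECG is never
  normalized, so reconstructed and reference ECG compare in mV.

## Split and segmentation

First 48 s training, next 12 s validation, 12 s discarded, 228 s test —
contiguous, non-overlapping, in that order; the test duration is 4.75×
the training duration, probing long-horizon use.  Each interval is cut
gaplessly into n-second windows (n ∈ {1,2,3,4}), giving
{48,12,228}, {24,6,114}, {16,4,76}, {12,3,57} segments.  If Alignment I
truncation leaves less than 300 s, the test interval shrinks to the
largest multiple of 12 s that fits (12 s = lcm of the allowed n), keeping
train/validation fixed so counts stay comparable across records.

## Reconstructor

One BiLSTM layer, 25 hidden units per direction (50 concatenated
features per timestep), sequence output, followed by a per-timestep
linear map to a single mV value (no output activation — targets are
signed).  L1 = L2 = 10⁻⁴ regularization applies to the input kernels of
both directions.  Loss is per-timestep MSE (matching the rmse
evaluation); the optimizer is Adam at learning rate 0.001; batch size 1;
at most 1000 epochs.  "Max epochs" is a cap, not a fixed count: early
stopping watches validation loss with patience 50 by default and
restores the best-validation weights; `early_stop_patience=None` runs
the full cap.  Windows are independent samples — no state crosses window
boundaries.  Initialization: Glorot-uniform kernels, orthogonal
recurrent matrices, zero biases with the forget gate at 1.

The network, backpropagation through time and Adam are implemented
directly on numpy arrays with numba-compiled kernels.  Everything is
driven by one integer seed and runs single-threaded, so training is
bit-reproducible on a platform: two runs with the same seed and data
produce identical histories, weights and reports.

## Evaluation

Pearson's r, rmse (mV), and a DTW distance whose local cost
d_ij = √((i−j)² + (x_i − y_j)²) mixes the sample-index difference with
the mV amplitude difference.  The mixed-unit cost is implemented
literally and the distance reported in mV, matching common reporting of
this metric; an amplitude-only cost is available via `index_weight=0`
for unit-consistent DTW.  The warping path uses steps (1,0), (0,1),
(1,1), is anchored at (1,1) and (m,m), and prefers the diagonal on ties.
Per-second distance d̄ is the literal quotient distance/duration.  (One
published figure pairs d = 533.218 mV over 228 s with 2.380 mV/s; the
literal quotient is 2.339, and this package reports the quotient.)

For stitched 228-s signals (m ≈ 28 500) the DP runs inside a Sakoe-Chiba
band of radius 1 s of samples by default — the optimal path of a
well-reconstructed signal hugs the diagonal — with the full lattice
available (`radius=None`) and used for per-segment distances.

**Alignment II** searches integer lags within ±80 ms, maximizing the
normalized cross-correlation of the overlapping samples.  Positive lag
means the reconstruction lags the reference.  Ties break to the smaller
|lag|, then negative before positive.  Aligned metrics are computed on
the truncated overlap — zero-padding would bias both r and rmse.
Per-segment aligned columns use a lag per segment; stitched aligned
columns use one global lag.  Cohort aggregation pools per-segment
columns over all segments of all records and stitched columns over
records, as mean ± sd.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes: beats
on a jittered RR grid (default 60 bpm, RR jitter sd 0.02 s — normal
resting variability); an ECG of five Gaussian bumps per beat (P, Q, R,
S, T with lead-II-like amplitudes); a PPG of systolic + diastolic
Gaussian bumps delayed by a record-constant PAT (default 0.2 s, a
typical R-peak-to-systolic-peak delay at the fingertip); optional white
Gaussian noise per channel; an arbitrary positive PPG scale.  Beat
centres snap to integer samples so every true systolic index equals its
R index + round(pat_s·fs) *exactly*, giving sharp ground truth for
detector and alignment tests.  `make_cohort` draws per-record heart rate
(55–95 bpm) and PAT (0.15–0.30 s) with per-record sub-seeds.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: baseline wander, motion artifacts,
arrhythmia, pathological morphology, beat-to-beat amplitude variability,
and a PPG→ECG transfer that is anything other than deterministic.  On
this synthetic family the mapping is learnable by construction, so
end-to-end correlations here are an upper bound, not a forecast, for
clinical recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run at fs = 125 Hz, n = 1 s windows,
320-s records (so the full 48/12/12/228 layout survives Alignment I
truncation), training capped at 150 epochs with patience 25 — on clean
synthetic subjects validation loss plateaus long before the cap.  The
acceptance script's end-to-end stage trains three subjects drawn by
`make_cohort` and aggregates across them, mirroring per-record results
tables.  Long-horizon generalization varies across data realizations:
a model can fit its training minute essentially perfectly and still
degrade minutes later, which is the known weakness of training on a
single minute; cohort averaging reflects how such results are reported.

Degenerate inputs fail loudly rather than silently: constant sequences
(undefined Pearson r, undefined min-max scaling), records shorter than
the split, fewer than three usable beat correspondences, non-finite
samples, NaN training loss.

## Known limitations

* Frequencies above the 20 Hz ECG passband are unrecoverable by design;
  high-frequency ECG features (e.g. abnormal ventricular conduction)
  are outside scope.
* The WFDB adapter reads only two-signal format-16 records — enough for
  header/.dat pairs of paired ECG+PPG exports; CSV is the canonical
  format.
* Training is CPU-only and single-threaded; wall-time grows linearly
  with epochs × windows × window length.
* Beat-level clinical feature comparison (QRS width, ST deviation) is
  not implemented.
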