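# Methods

## Analysis model

The pipeline treats score-based playing as the reference condition: a
sequence autoencoder is trained exclusively on score-task windows, and
improvisation windows are scored by how badly the model reconstructs them.
The underlying assumption is that a model fitted to one task's dynamics
generalizes to held-out windows of the same task but not to windows whose
temporal structure differs; the per-channel decomposition of the error then
localizes the deviation on the montage.

Windows are (W × 15) blocks of z-scored hemoglobin concentration change.
The normalizer is fitted on score-task recordings only and applied to both
tasks; this is deliberate — improv errors should reflect deviation from the
training *dynamics*, not trivial scale or offset differences, which
z-scoring against the score statistics would otherwise absorb into the
error.  A consequence worth knowing: planted effects that only shift a
channel's mean are nearly invisible to this pipeline, which is why the
synthetic effect perturbs dynamics (transients and variance), not level.

### Architecture

Encoder: LSTM(64, sequences) → LSTM(32, final state) → Dense(32) →
Dense(16); decoder: repeat the 16-d latent W times → per-step Dense(32) →
LSTM(32, sequences) → per-step linear map to 15 channels.  Hidden layers
use ReLU, including the LSTM cell activations (candidate and cell output);
gates remain sigmoid.  The output layer is linear because targets are
z-scored and can be negative — a ReLU output would clip half the range.
One multivariate model covers all channels jointly; channel-wise errors are
the per-output-channel decomposition of the window MSE, so the channel
errors average exactly to the scalar training criterion.

The network is implemented directly in NumPy (float32) with explicit
backpropagation through time.  Weight initialization is Glorot-uniform with
forget-gate biases at 1; both are seeded, so a (data, config, seed) triple
reproduces training bit-for-bit in single-threaded BLAS.

### Training

Adam (lr 1e-3, β₁ 0.9, β₂ 0.999), MSE loss, default 200 epochs and batch
1024.  ReLU-activated LSTM cells are unbounded, so gradients are clipped to
a global L2 norm of 5 each step; without clipping, occasional large
candidate activations destabilize early training.  The validation split is
a seeded random 20% of windows by default; a `split_by_subject` flag holds
out whole subjects instead, which is the leakage-safe choice when windows
overlap heavily (stride ≪ W) — with stride 1 the default window-level
split overstates generalization, and both modes are provided for exactly
that reason.  Reported per-epoch training loss is the running mean over the
epoch's batches (pre-update), the usual convention.

## Synthetic cohort generator

The generator emulates the study conditions the analysis targets: 22
subjects (16 "pianist", 6 "non_pianist"), 15 channels at 8 Hz, one 160-s
cycle per task per subject with blocks rest 30 / preparation 30 / rest 10 /
play 60 / rest 30 s.  Per channel, the signal is

  gain × (design ∗ double-gamma HRF) + drift·t + Σ aᵢ sin(2πfᵢt + φᵢ) + ε

with the double-gamma kernel peaking at 6 s (undershoot 16 s, ratio 1/6,
32-s support), per-subject channel gains drawn lognormal (σ = 0.2) to
emulate inter-subject amplitude variability, linear drift 0.002 units/s,
physiological sinusoids at 1.0 / 0.3 / 0.1 Hz (cardiac, respiratory, Mayer;
amplitudes 0.10 / 0.15 / 0.20) with per-channel uniform phase jitter, and
white noise of sd 0.3.  These noise amplitudes are conventional for
concentration-change fNIRS simulation; the spectrum (slow oscillations
dominating, white floor beneath) is what matters for giving the autoencoder
realistic autocorrelation to learn.

The planted effect is confined to the play block of target channels
(default 1 and 15) in pianists' improv recordings: a Poisson number
(rate 5 per block) of ~1-s Gaussian transients with amplitude
`burst_amp_sd` × white-sd (default 10) and random sign, plus white-noise
variance inflated ×2.  Score recordings are never injected.

What the generator does **not** model: motion artifacts, HbO/HbR coupling,
optode geometry or scalp coupling, non-stationary drift, and any realistic
spatial correlation between channels.  Passing tests on this generator
therefore demonstrate that the pipeline recovers dynamical anomalies of the
planted kind under realistic noise *spectra*; they do not certify behaviour
under motion contamination or physiological confounds correlated with task.

## Statistics

Per subject, improv window errors are averaged over the ROI channels
(default {1, 15}), floored at ε = 1e-12, and natural-log transformed.  The
base of the log only shifts summaries by a constant factor and is
irrelevant to the rank-based tests.  Three robust summaries per subject:
median (midpoint rule), trimmed mean dropping ⌊0.10·n⌋ per tail, and the
90th percentile by inclusive linear interpolation — stated explicitly
because upper quantiles on small n are convention-sensitive.  Summaries are
computed per subject and compared across subjects, the only statistically
valid unit when group sizes are 16 vs 6.

Tests per summary: Welch's *t* (scipy, Welch–Satterthwaite df),
Mann–Whitney *U* (U = #{aᵢ > bⱼ} + ½ ties; exact by enumeration when
n+m ≤ 12 without ties, tie-corrected normal approximation otherwise), and a
label-permutation test with the add-one estimator
p = (1 + #{|T*| ≥ |T|}) / (n_iter + 1), two-sided via the absolute
statistic, seeded.  Effect sizes: Cohen's *d* with (n−1)-weighted pooled SD
and Cliff's δ.  No multiple-testing correction is applied across the 3 × 3
battery; all nine results are reported and should be read jointly.

## Pipeline conventions

- Replicate seeds are master_seed + replicate index; replicate error maps
  are averaged before window selection and channel ranking.
- The group comparison runs only at the selected window size, pooling each
  subject's window errors across replicates.
- Channel ranking breaks ties by ascending channel id.
- "Train" error is the mean reconstruction error over score windows,
  "test" error over improv windows; anomaly separation is additionally
  reported against the *held-out* (validation) score windows, which is the
  fair baseline for the improv errors.
- Reports serialize to JSON with sorted keys and no timestamps, so a fixed
  master seed reproduces the file byte-for-byte.

## Problem sizes

Default training (stride 1, 200 epochs) is sized for real analyses.  The
test suite and the acceptance script use desk-scale settings chosen once as
this package's reference configuration for synthetic studies: stride 25
over 1800-sample recordings (72 windows per recording), 30 epochs, 2
replicates.  At this scale the planted default effect is recovered (ROI
channels rank top-2, improv ROI error ≈ 2× the held-out score ROI error)
and one pipeline run takes tens of seconds on one CPU.

## Degenerate inputs and numerical choices

- Zero-variance channels make z-scoring undefined → explicit
  degenerate-channel error naming the channel.
- Both samples constant → Welch's *t* undefined (error); zero pooled SD →
  Cohen's *d* undefined (error carrying the still-valid δ).
- All-tied Mann–Whitney samples have a zero-variance normal approximation;
  p is reported as 1.
- Reconstruction errors are accumulated in float64 even though the model
  computes in float32.
- Resampling is per-channel linear interpolation (shape-preserving, no
  ringing, endpoint-exact); the sampling rate is rescaled to preserve
  duration.

## Known limitations

- The ReLU LSTM can diverge at learning rates well above 1e-3; the clip
  norm is a guard, not a cure.
- Exact Mann–Whitney enumeration is limited to n+m ≤ 12; beyond that the
  normal approximation is used even when an exact test would be feasible.
- SNIRF support covers processed-hemoglobin continuous-wave files with a
  single data block only, read-only.
- The permutation test permutes subject labels; it assumes exchangeability
  of subjects under the null, not of windows.
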