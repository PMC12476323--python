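# Methods

## Problem setting

A needle advancing through tissue emits vibroacoustic energy that travels
along the shaft and is recorded as mono audio at 22 050 Hz. The task is
five-way tissue classification (kidney, liver, muscle, rib, skin) from
fixed-length segments of such recordings. Two obstacles shape the design:
the recordings are corrupted by a strong periodic impulsive interference,
and segments cut from one recording are strongly correlated, so naive
train/test splits leak.

## Periodic-interference model and denoiser

The interference is modelled as a strictly periodic additive pulse train:
amplitude · p[(t − φ) mod T] with a stable pulse shape p shorter than the
period T and a period long relative to the pulse (default T = 2048 samples,
i.e. ≈ 10.8 pulses per second). Under this model the denoiser is exact:

* **Period estimation.** The debiased, peak-normalized signal is swept with
  31 thresholds θ evenly spaced strictly inside (0.6, 0.9) (implemented as
  `linspace(0.6, 0.9, 33)[1:-1]`; the interval is open, so the endpoints are
  excluded). An upcrossing is an index t with x[t−1] ≤ θ < x[t]; per
  threshold the mode of consecutive upcrossing distances is taken, smallest
  value winning ties (multiples of the fundamental appear at high
  thresholds, so ties are biased toward the fundamental). Modal values
  within ±1 sample of an integer multiple (k ≥ 2) of a smaller candidate are
  folded onto that candidate; the candidate with the most per-threshold
  votes is the dominant period.
* **Template.** p̂[τ] is the per-phase median over all N = ⌊length/T̂⌋ full
  chunks; the trailing partial chunk is excluded from estimation but is
  still corrected using the template prefix during subtraction. The median
  makes the template immune to any corruption confined to fewer than ⌈N/2⌉
  chunks, which is what the non-stationary tissue signal amounts to.
* **Phase.** τ = 0 is anchored at sample 0 of the recording. No phase search
  is needed because the template is estimated from the same recording it is
  subtracted from.
* **Failure fallback.** If no threshold yields ≥ 2 upcrossings, or the
  estimated period leaves fewer than two full chunks, the recording passes
  through debiased/normalized only, with a logged warning — recordings are
  never dropped, so corpus counts stay stable.

Assumptions and their limits: the pulse shape and period must be stable over
the recording (no drift or jitter is tracked), the interference must be the
dominant peak after normalization (spikes above the threshold band, tissue
texture below it), and exact cancellation holds only for signals whose
upcrossing pattern reveals a true period — a periodic signal with several
comparable peaks per period can fool the mode toward an inter-peak distance.

A note on idempotence: the chain renormalizes peak amplitude to 1, so
applying `denoise` twice rescales the once-denoised signal before the second
pass. Idempotence therefore holds at the second pass's own scale — its
template subtraction changes RMS by well under 1 % — rather than as literal
equality of output RMS across passes.

## Spectrogram representations

* **Mel-dB**: centered STFT (reflect padding), 1024-point Hann window, hop
  512, giving ⌊n/512⌋ + 1 frames; 64 triangular Mel filters (HTK Mel scale,
  area-normalized) spanning 0 Hz–Nyquist; amplitude converted to dB as
  20·log₁₀(A/max A), floored at −80 dB. The dB reference is the per-segment
  maximum, so every non-silent spectrogram peaks at exactly 0 dB. Window,
  padding, filterbank style and floor follow the dominant audio-analysis
  convention and are overridable.
* **Morse CWT**: "perfectly symmetric" selects γ = 3 within the generalized
  Morse family; the time-bandwidth product βγ = 60 then fixes β = 20. The
  frequency-domain wavelet a ω^β e^(−ω^γ) (analytic, peak response 2, i.e.
  unit-gain for a real tone at the center frequency) is evaluated on a
  logarithmic grid of 10 voices per octave from 20 Hz to Nyquist, rows
  ordered by descending frequency, one column per sample; the signal is
  zero-padded to twice its length before the FFT to suppress circular
  wrap-around. Magnitude (not squared magnitude) is stored.
* **Resize**: bilinear, pixel-center convention (resizing to the same shape
  is the identity); CWT scalograms destined for fixed-input models are
  resized to 224 × 160, preserving the original aspect ratio choice. Mel
  spectrograms are fed to NeedleNet un-resized — its adaptive pooling
  accepts any input of at least 16 pixels per side.

## Grouped cross-validation split

Per-fold class quotas are class totals divided by the fold count (floor,
remainder to the lowest-indexed folds). Recordings are shuffled with a
seeded generator within each class and assigned whole to the fold with the
largest remaining quota for their class (lowest index on ties); overshoot at
the tail is absorbed by that same rule, since exact balance is impossible
when whole recordings are atomic. Consequently each fold's per-class count
deviates from the ideal quota by at most the largest single recording's
segment count. `verify_no_leakage` independently re-checks any assignment
against a manifest.

## Classifiers and training

NeedleNet blocks are conv → ReLU → dropout → batch-norm, following the
stated block description literally even though conv → BN → ReLU is more
common; the conventional order is available via
`NeedleNetConfig(block_order="conv_bn_relu_dropout")`. The head is a single
512 → 5 linear layer after global average pooling, with no dropout. Default
trainable parameter count: 1 554 309.

ResNet-34 uses the standard basic-block layout (3/4/6/3 blocks of
64/128/256/512 channels) with the final layer replaced by an n-class head;
single-channel spectrograms are replicated to three channels at input, and
no ImageNet normalization is applied. Pretrained weights require an online
weight cache and are therefore not supported; `pretrained=True` raises with
advice to use random initialization.

Training: SGD with classical momentum (v ← μv + g, p ← p − ηv), defaults
150 epochs, lr 0.01, momentum 0.9, batch 32, cross-entropy, 5 folds; no
learning-rate schedule, weight decay, early stopping or augmentation.
Inputs are standardized per segment (zero mean, unit variance per 2-D
image). Train-split metrics are accumulated from the training batches
themselves (dropout active), test metrics from an evaluation pass after
every epoch. Precision and F1 are macro-averaged over all five classes with
empty classes contributing 0 (`average="weighted"` available). One master
seed fans out (via `SeedSequence.spawn`) to per-fold seeds for weight
initialization, batch shuffling and dropout, making runs bit-reproducible.

The neural-network engine is pure numpy: im2col convolution over BLAS
matmul, exact analytic backward passes (verified against finite differences
in the tests). On one CPU core a NeedleNet forward+backward on a batch of
32 Mel segments takes ≈ 0.3 s, which sets the feasible study scale below.

## Synthetic corpus generator

Each tissue class is a `TissueClassProfile`: stationary Gaussian noise
band-passed around class-specific center frequencies (4th-order Butterworth,
±8 % bandwidth, ≥ 50 Hz), plus Poisson-timed transients (default 4 events/s)
— exponentially decaying tone bursts (default 20 ms decay) at the profile's
band centers, emulating stick-slip crackle. Default band centers are
disjoint across the five classes (350/900, 1500/2200, 3000/4000, 5200/6500,
8000/9500 Hz) so that a nearest-centroid periodogram classifier separates
classes with ≥ 95 % accuracy — the generator's contract that downstream
classification targets are attainable. Clean peak amplitude is normalized
to 0.5; the default interference (64-sample damped sinusoid, period 2048,
amplitude 8) then yields normalized spikes above 0.9 and background below
0.5 after debias/normalization, matching the corruption regime the period
estimator is designed for. Segments are cut non-overlapping; 1-second
segments hold ≈ 10 interference periods, enough chunks for a stable median
template.

What the generator does **not** emulate: real needle–tissue mechanics,
propagation filtering along the shaft, class-dependent non-stationarity
(insertion phases), interference period drift, sensor nonlinearity, or
overlapping tissue spectra. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline under its stated
model — not field performance on laboratory recordings, whose headline
accuracies depend on data that is not publicly available.

## Problem sizes used in tests and scripts

The scaled cross-validated study in the test suite uses 5 classes × 10
recordings × 4 one-second segments (200 segments), NeedleNet, 15 epochs,
5 folds, on raw and denoised Mel features — large enough for the denoising
comparison to be meaningful, small enough to run in minutes on one CPU.
Period-recovery calibration uses 100 seeded 3-second recordings over
periods {512, 1024, 2048, 4096}. The acceptance script synthesizes a single
10-second recording (220 500 samples). The default `RunConfig` mirrors the
same philosophy (60 segments, 15 epochs).

## Known limitations

* The denoiser assumes one interference source; concurrent pulse trains
  with different periods are not separated.
* Period estimation is integer-valued; fractional-sample periods would
  smear the median template.
* ResNet-34 without pretraining underperforms its transfer-learning
  potential by construction; it is included for architectural parity.
* The numpy engine is CPU-bound and single-device; the default 150-epoch
  protocol on a 1282-segment corpus is hours of compute, so study-scale
  defaults in the tests are scaled down as described above.
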