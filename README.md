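# vibrotissue

Tissue classification from the vibroacoustic signals of needle–tissue
interaction.

When a surgical needle advances through tissue, the interaction generates
mechanical vibrations that propagate along the needle shaft and can be
captured as audio at the proximal end. Those signals carry enough spectral
information to tell tissue types apart — a potential complement to imaging
guidance during biopsies and injections, where artifacts often obscure the
needle tip. `vibrotissue` implements the complete analysis chain for this
problem, aimed at researchers in interventional-device sensing and
biomedical acoustic signal processing:

1. **Periodic-interference denoising.** Laboratory recordings are corrupted
   by an additive impulsive pulse train with a long period T̂ (≈ 2048 samples
   at 22 050 Hz) — too sparse in frequency for classical filtering. After
   debiasing and normalizing x[t] to [−1, 1], the period is estimated from
   threshold upcrossings: for each threshold θ ∈ (0.6, 0.9) the mode of the
   distances Tₙ = tₙ − tₙ₋₁ between consecutive upcrossings is computed, and
   modal values that are near-multiples of a smaller candidate are folded
   back onto it (at high θ some spikes are missed, so the mode becomes a
   multiple of T̂). One period of the interference is then estimated as the
   per-phase **median** over the T̂-sample chunks of the recording,
   p̂[τ] = Median(x[τ], x[τ+T̂], …, x[τ+(N−1)T̂]), robust to the
   non-stationary tissue signal riding on top, and its periodic extension
   p̂[t] = p̂[t mod T̂] is subtracted: x̂[t] = x[t] − p̂[t].
2. **Spectrogram representations.** Mel-dB spectrograms (STFT with 1024-point
   Hann windows, hop 512, 64 Mel bins, amplitude→dB floored at −80 dB) and
   continuous-wavelet scalograms using the perfectly symmetric generalized
   Morse wavelet (γ = 3) with time-bandwidth product βγ = 60, resized to
   224 × 160 for fixed-input models.
3. **Leakage-free evaluation.** Segments cut from one physical recording are
   correlated, so folds are built from whole recordings: per-fold class
   quotas are filled by seeded random draws of recordings, and a verifier
   proves that no recording straddles folds.
4. **CNN classifiers.** *NeedleNet* (four conv blocks of 64/128/256/512
   filters, kernel 3 / stride 2 / padding 1, each conv → ReLU → dropout 0.2 →
   batch-norm, then adaptive average pooling and a linear head — input-size
   agnostic) and a ResNet-34 variant with a 5-way head, trained with SGD
   (lr 0.01, momentum 0.9, batch 32, cross-entropy) under 5-fold
   cross-validation, reporting accuracy, macro precision and macro F1 per
   epoch, aggregated as best-over-folds and average-final.

The study's phantom recordings are not publicly deposited, so the package
ships a first-class **synthetic corpus generator**: five spectrally distinct
tissue-class signatures (band-filtered noise plus decaying transients), a
configurable periodic impulsive interference with known period, phase and
pulse shape, and segmentation of many recordings into labelled WAV segments
with a manifest. Every stage is validated against this generator's ground
truth.

## Worked example

```python
import numpy as np
import vibrotissue as vt

profile = vt.default_profiles()[1]                      # liver-like signature
clean = vt.generate_recording(profile, duration_s=10.0, seed=7)
spec = vt.InterferenceSpec(period=2048, amplitude=8.0, phase_offset=512)
noisy = vt.inject_interference(clean, spec)

normed = vt.debias_normalize(noisy)
estimate = vt.estimate_period(normed)
print("estimated interference period:", estimate.dominant_period, "samples")
print("modal distances across thresholds:",
      sorted(set(estimate.modal_distance_per_threshold.values())))

denoised = vt.denoise(noisy)
rms = lambda x: float(np.sqrt(np.mean(x**2)))
print(f"RMS corrupted (normalized): {rms(normed.samples):.4f}")
print(f"RMS denoised:               {rms(denoised.samples):.4f}")

mel = vt.mel_spectrogram(vt.AudioRecording(denoised.samples[:22050]))
print("mel spectrogram shape:", mel.values.shape)
```

prints

```
estimated interference period: 2048 samples
modal distances across thresholds: [2048]
RMS corrupted (normalized): 0.0372
RMS denoised:               0.0139
mel spectrogram shape: (64, 44)
```

The threshold sweep finds the same modal upcrossing distance (2048 samples)
at all 31 thresholds; subtracting the median template removes nearly
two-thirds of the signal energy — the injected pulse train — while the
tissue signature survives. A one-second segment becomes a 64 × 44 Mel-dB
image (64 Mel bins, ⌊22050/512⌋ + 1 frames).

The same chain is available from the shell:

```bash
vibrotissue simulate --out corpus --classes 0:40,1:40,2:40,3:40,4:40 --per-class 10 --seed 1
vibrotissue denoise  --manifest corpus/manifest.csv --out corpus_denoised
vibrotissue featurize --manifest corpus_denoised/manifest.csv --repr mel --out mel.h5
vibrotissue split    --manifest corpus/manifest.csv --folds 5 --seed 1 --out folds.json
vibrotissue train    --features mel.h5 --folds folds.json --model needlenet --epochs 15 --seed 1 --out run/
vibrotissue run      # full pipeline from a single config
```

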