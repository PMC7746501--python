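# phonodose

Ambulatory phonation monitoring from single-channel audio.

Occupational voice users — teachers above all — accumulate vocal-fold load
that can progress to phonotraumatic injury (nodules, polyps). Monitoring
*how much* someone phonates during a working day requires classifying every
moment of a recording as speech or nonspeech and summarizing the result as
a **phonation ratio** and a distribution of speech/nonspeech segment
durations. `phonodose` implements a complete, self-contained toolkit for
this task, built around a deliberately simple, privacy-preserving detector:
it never looks at speech *content*, only at frame energy.

## The detector

Audio is resampled to 16 kHz mono and cut into non-overlapping 32 ms frames.
Each frame's feature is its power energy
`E_j = mean(x²)` over the frame. Frame *j* is classified as speech when its
energy exceeds an **adaptive threshold** built from the current and three
preceding frame energies:

```
AT_j = a₀·E_j + a₁·E_{j−1} + a₂·E_{j−2} + a₃·E_{j−3} + b
decision_j = 1  if E_j > AT_j  else 0
```

The five parameters `(a₀…a₃, b)` are fitted per recording by a real-valued
genetic algorithm that maximizes frame-level agreement with manually
labeled ground truth over 25 randomly chosen 10 s training windows
(5 further windows are held out for testing). For noisy conditions an
optional **logMMSE** speech-enhancement front end (decision-directed
a-priori SNR, noise-PSD tracking, log-spectral-amplitude gain) can be
switched on ahead of the energy stage. A noise lab mixes four background
archetypes — white, street, sharp speech bursts, crowd babble — into clean
recordings at exact SNRs (0/3/5 dB grid) to probe robustness.

Because real classroom recordings cannot be shipped, the package includes a
synthetic-lecture generator producing harmonic-burst "speech" with exact
ground-truth labels, so every stage is testable end to end with no external
data.

## Worked example

```python
import phonodose as pd

# 300 s synthetic lecture, 60% speech, with exact labels
audio, labels = pd.make_lecture(pd.SpeechSynthSpec(
    duration=300.0, target_speech_fraction=0.6, seed=11))

# fit the adaptive threshold on 25 random 10 s windows
train, test = pd.split_utterances(audio, labels, n_train=25, n_test=5,
                                  utterance_length=10.0, seed=11)
coef, trace = pd.fit_coefficients(train, pd.GAConfig(seed=11))

grid = pd.FrameGrid.for_signal(audio)
truth = pd.labels_to_frames(labels, grid)
track = pd.run_pipeline(audio, coef, grid)
summary = pd.frame_accuracy(track, truth)
print(f"agreement {100*summary.agreement:.1f}%  "
      f"phonation ratio {100*pd.phonation_ratio(track):.1f}%")
```

prints

```
agreement 99.8%  phonation ratio 60.1%
```

i.e. the fitted detector reproduces the known per-frame labels of the
synthetic lecture almost perfectly, and the measured phonation ratio
matches the 60% of speech that the generator actually synthesized. On real
audio the same quantities are computed by the CLI:

```
phonodose synth  --out clean.wav --labels truth.txt --duration 300 --seed 11
phonodose fit    --audio clean.wav --labels truth.txt --out coef.txt --seed 11
phonodose detect --audio clean.wav --coef coef.txt --out pred.txt
phonodose evaluate --pred pred.txt --truth truth.txt --duration 300 --out metrics.json
phonodose report --audio clean.wav --coef coef.txt --out-prefix session
```

`mix` and `denoise` subcommands drive the noise experiments. Every run
writes a `*.run.json` record (inputs, configuration, seeds, version) from
which it can be reproduced byte-for-byte.

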