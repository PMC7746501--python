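# Methods

## Detection model

The detector operates on 16 kHz mono audio divided into non-overlapping
32 ms frames (512 samples). The per-frame feature is power energy — the
mean squared amplitude under a rectangular window. Mean rather than sum
keeps the bias parameter's scale independent of frame length, so a fitted
`b` remains meaningful if the grid is reconfigured. The hop defaults to the
frame length (the simplest consistent reading of a fixed "frame size") but
is configurable down to any positive value ≤ the frame length;
`n_frames = floor((duration − frame)/hop) + 1`.

A frame is speech when its energy strictly exceeds the adaptive threshold

    AT_j = a₀·E_j + a₁·E_{j−1} + a₂·E_{j−2} + a₃·E_{j−3} + b.

Numerical conventions, chosen where the rule is under-specified:

* **Warm-up** (j < 3): missing history energies are taken as 0, so the
  decision track always has exactly one entry per frame.
* **Ties** (`E_j == AT_j`) resolve to nonspeech — the conservative reading
  when "exceeds" means speech and "lower" means nonspeech.
* Including the current frame's energy on the threshold side (the `a₀`
  term) is the default; a switch (`include_current=False`) zeroes that
  column for the alternative reading. With `a₀ = 0` decisions are pointwise
  non-increasing in `b`, and with `b = 0` they are invariant to amplitude
  scaling — both properties are tested.
* No decision smoothing by default; an odd-window median filter over the
  binary track is available (`smooth_window`) but off.

Ground-truth frame labels are derived from interval annotations by frame
**center** membership: frame j is speech iff its center time lies inside a
labeled speech interval. Center membership is unbiased at boundaries and
makes the labels→frames→labels round trip exact to one hop.

## Coefficient search

The five parameters are fitted per recording by a real-valued genetic
algorithm maximizing pooled frame agreement (both classes) against the
labeled ground truth of the training windows. Agreement — not speech
recall — is the fitness, because recall alone is maximized by the trivial
always-speech detector; recall and precision are nevertheless computed and
reported alongside it everywhere.

Defaults: population 50, 200 generations, tournament selection (size 3),
BLX-α blend crossover (α = 0.5) at rate 0.9, per-gene Gaussian mutation
(σ = 10 % of each bound's width) at rate 0.2, elitism 1 (the best-ever
individual always survives, so the fitness trace is monotone), bounds
aᵢ ∈ [−2, 2] and b ∈ [−0.1, 0.1] on the peak-normalized energy scale. All
settings live in `GAConfig`; a run is a pure function of the training set
and the seed. The coefficients are not identifiable — many (a, b) produce
identical decision boundaries — so recovery is assessed as *decision*
agreement on the generating set (≥ 99 % under the default budget), never as
parameter closeness.

Training windows are sampled by partitioning the recording into
utterance-length slots and drawing slots without replacement. This makes
disjointness structural, keeps the tight case (a 300 s recording yielding
exactly 30 disjoint 10 s windows) feasible, and is reproducible by seed.
The cost is that window starts are slot-aligned rather than arbitrary; for
fitting an energy threshold this alignment carries no information.

## Noise lab

`mix_at_snr` scales the noise by `g = sqrt(P_clean / (P_noise·10^(SNR/10)))`
with powers measured over the whole signal, so the achieved whole-signal
SNR equals the request exactly (tested to 1e-9 dB). Whole-signal rather
than speech-active SNR is the default because it needs no labels; an
active-frames variant is available when labels are supplied. Noise shorter
than the speech is looped and cropped at a seed-chosen offset.

The four archetype generators (all unit RMS, seed-deterministic) emulate
common background classes: Gaussian white noise; "street" as ≤ 500 Hz
low-passed noise under a slow level drift; "sharp speech" as sparse
300–3400 Hz bursts with abrupt onsets; "crowd" as the sum of eight
independent harmonic streams with wandering f0 and syllabic modulation
(babble). They are acknowledged stand-ins for field recordings: archetype
spectra and modulation statistics are plausible but not measured from any
real environment, so accuracy-drop magnitudes under these noises
characterize this generator, not any particular street or classroom.

`logmmse` implements the log-spectral-amplitude MMSE estimator: sqrt-Hann
analysis/synthesis windows at 32 ms / 50 % overlap with normalized
overlap-add (the input is zero-padded one frame on each side so output
length equals input length exactly, and `gain_floor = 1` reduces the chain
to an identity up to floating-point error); noise PSD initialized from the
first 6 frames and updated with smoothing 0.98 in frames judged
speech-absent; decision-directed a-priori SNR with α = 0.98 floored at
−25 dB; per-bin gain `(ξ/(1+ξ))·exp(E₁(v)/2)`, `v = ξγ/(1+ξ)`, floored at
0.1. Speech absence is decided by thresholding the mean per-bin
log-likelihood ratio at 0.05. The threshold sits in the middle of the
plateau (0.01–0.08) over which the tracked noise PSD stays on the true
stationary-noise power for harmonic (narrowband) speech content; the
statistic averages over all 257 bins, so values tuned for wideband speech
classify voiced frames as noise and the tracker absorbs speech energy.

## Synthetic lectures

`make_lecture` alternates voiced utterances and pauses. Utterances are
harmonic bursts: five harmonics with 1/h amplitudes at a per-utterance
fundamental drawn from 100–250 Hz (typical adult speech), 10 ms
attack/release ramps, and 4 Hz syllabic amplitude modulation — enough
structure for energy detection and for spectral enhancement to have
something to protect, with labels exact by construction. Utterance and
pause lengths are log-normal (medians 3 s and 1.5 s, σ = 0.5 in log-space),
so most segments fall under 10 s, the shape characteristic of continual
lecturing. The schedule draws utterances until the target speech time is
reached and then rescales the pause draws to fill the remainder exactly,
so the realized speech fraction lands within ±0.05 of the target even for
short fixtures; targets infeasible under the minimum span lengths (0.2 s
utterances, 0.1 s pauses) raise. Lectures open with a pause — recordings
start before the speaker does — which also gives the enhancer's noise
estimate a legitimate initialization window.

Pauses carry a Gaussian sensor-noise floor at amplitude 1e-3 (≈ −60 dB re
full scale), emulating a quiet room. Exact digital silence would make any
positive bias trivially optimal and the speech/silence energy contrast
undefined; with the floor, the median contrast still exceeds 100×, so the
clean-condition fit is easy but not degenerate.

What the generator does **not** model: real phonetic variety (fricatives,
plosives, breath), room reverberation, microphone coloration, level drift
of the talker, and competing talkers at conversational distance. Passing
the end-to-end suite therefore demonstrates the machinery is correct and
self-consistent, not that the ≈ 99 % clean agreement would transfer to real
classroom audio, where reported frame accuracies for comparable systems are
substantially lower.

## Metrics

Phonation ratio is speech frames / total frames; its trajectory is
available cumulatively or over a sliding window (default 60 s — the sliding
view exposes localized silent episodes that the cumulative curve smooths
away). Segment lists come from run-length encoding of the decision track
(durations are exact multiples of the hop; alternation and tiling are
invariants), and duration histograms use 10 log-spaced bins per decade over
0.032–1000 s with an explicit flagged overflow bin so totals are always
conserved. Ratio and accuracy computations are deliberately hop-agnostic —
they consume frame counts, not seconds — since session length and hop
cannot be reconstructed from frame counts alone. Percentages are reported
to one decimal place.

## Problem sizes

The test suite and the acceptance script run the full-budget GA
(50 × 200) on a 300 s lecture — about 9 400 frames — and the noise grid
(4 archetypes × 3 SNRs) on the same recording; population-batched fitness
evaluation makes the GA a fraction of a second and the complete acceptance
run well under a minute. Unit and property tests use 8–120 s fixtures.
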