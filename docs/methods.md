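# Methods

This note records the models implemented in `voicelevel`, the parameter
choices that matter, what the synthetic corpus does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Signal front end

Utterances are endpoint-trimmed by short-time energy on 10 ms sub-frames
(threshold −35 dB relative to the loudest sub-frame; above-threshold runs
shorter than 20 ms are ignored so clicks cannot anchor an endpoint).
Analysis frames are 25 ms Hamming windows with 75 % overlap; frame length
is `floor(0.025·fs)` samples and the hop `round(0.25·L)`, fixed so frame
counts are exactly reproducible (at 44.1 kHz: L = 1102, hop = 276).

## Frame-based features

**f0** — normalized autocorrelation over lags for 100–600 Hz (a pediatric
search range), divided by the Hamming window's own autocorrelation to
undo the taper-induced bias toward short lags, with parabolic peak
interpolation. A perfectly periodic frame has near-equal peaks at every
multiple of the period, so candidate scores carry a small penalty of
0.02 per octave of lag, preferring the shortest consistent period.
Frames whose peak normalized autocorrelation falls below 0.45 are
unvoiced and carry f0 = 0; they stay in the observation sequence.

**Formants** — the frame is decimated to ≈10 kHz (nearest integer
factor), pre-emphasized (0.97), and fit with an order-12 autocorrelation-
method AR model; poles with positive imaginary part and bandwidth under
400 Hz become formant candidates, sorted ascending. Missing formants are
NaN at this stage. Order 12 at ~10 kHz is the classical formant-tracking
operating point; at the native 44.1 kHz the order would have to grow to
~46 and estimation becomes fragile. Known limitation: with sparse
harmonic excitation (high f0, one strong resonance) LPC snaps the pole
estimate toward the nearest harmonic; accuracy is best when harmonics
straddle the resonance.

**Relative intensity** — frame RMS divided by the word's loudest frame,
so RI ∈ (0, 1] with max exactly 1.

**Nasality** — on the smoothed dB spectrum (60 Hz moving average), the
gap `diff = A(f1 peak) − max A(900–1100 Hz)`. Hypernasal voicing shows
an extra peak near 1 kHz, shrinking the gap, so the score is the
reciprocal `1/diff`, capped at `1/0.5 dB` so it stays finite — larger
score = more nasal. (The direct difference and its reciprocal appear in
different places in the literature; the reciprocal is implemented so the
feature increases with severity.)

**ApEn** — standard Pincus approximate entropy with self-matches,
m = 2, r = 0.2·SD (the field-standard defaults), computed per frame on
the frame's samples. The O(n²) template count is pruned exactly by a
sorted sliding window on the leading sample (a necessary condition for a
max-norm match), giving identical values at ~5× the speed; a numba
kernel does the counting when numba is importable.

Missing formant/nasality values are filled by carrying the last defined
value (leading gaps take the word median), because HMM observations must
be complete vectors; after filling, the formant triple is re-sorted per
frame so f1 ≤ f2 ≤ f3 always holds and f1/f2 is recomputed.

## Word-based features

**Higuchi fractal dimension** with kmax = 8 — appropriate for the
10³–10⁴-sample words; D = 1 for smooth curves, → 2 for white noise.

**Largest Lyapunov exponent** — Rosenstein small-data method: delay
embedding (m = 5), nearest neighbours outside a Theiler window of one
mean period (power-weighted mean frequency), slope of the mean log
divergence over the first 10 steps. The embedding delay is the first ACF
zero crossing (≈ quarter period), falling back to the first minimum:
for near-periodic signals the first ACF *minimum* is the half period,
where antiphase coordinates collapse the embedding onto a line and the
neighbour statistics degenerate. Long series are strided to ≤ 2000
embedded points and the slope rescaled to per-sample units. Limitation
inherent to the method: nearest-neighbour distances are minimum
statistics, so weakly contracting signals show a small spurious positive
relaxation slope; the sign is reliable for clearly chaotic or clearly
damped signals, and that relative ordering is what the classifier uses.

**Wavelet energies** — coefficients of the order-5 Gaussian-derivative
mother wavelet (5th derivative of a Gaussian, unit L2 norm, truncated at
|u| ≤ 5) at dyadic scales a = 2^j, j ∈ {7, 8, 9}, translations on the
scaled grid (steps of 2^j samples); energy is the mean squared
coefficient per scale. "Scales 7, 8, 9" is read as dyadic scale indices
with a0 = 2 — the reading is configurable (`WaveletConfig`) since raw
scale factors are an alternative convention. Signals are peak-normalized
first so the energies reflect spectral shape, not gain (RI already
carries loudness). Production coefficients come from an FFT convolution
of the sampled wavelet; tests verify them against the naive summation of
the defining inner product.

## Classifiers

**HMMs** — one per (word, level): 20 models. Topology is Bakis-1
(self-loop + single forward jump, start mass fixed on state 1) with 8
states; emissions are 4-component diagonal-covariance Gaussian mixtures.
Diagonal covariance is the standard speech choice and the only one
estimable from minutes of audio in 8 dimensions. Observations are
z-scored per feature with statistics from the training split only (the
features span Hz to nats; unscaled mixtures would be dominated by the
formants); the statistics are stored on the model. Initialization:
uniform time segmentation of each sequence into 8 blocks, k-means
(n_mix centers, fixed seed) per block; variances floored at 1e-3
post-normalization. Training: Baum-Welch with scaled forward/backward,
left-right zeros preserved exactly, max 50 iterations, stopping when the
relative log-likelihood gain drops below 1e-5. Scoring uses a log-space
forward recursion — per-frame rescaling underflows when a sequence is
scored under a badly mismatched model, which happens constantly during
classification. Ties in the level argmax resolve to the lower level.

**MLP** — one hidden layer, tanh hidden units, logistic outputs, plain
full-batch gradient descent on MSE against one-hot targets (lr 0.01,
up to 2000 epochs, optional early stopping on a validation split). The
word-feature classifier is a single pooled 5-10-4 net over all words'
feature vectors (a per-word variant is configurable); the stacked-fusion
meta-classifier is the 6-10-4 net, trained with a larger step (lr 0.5) —
its inputs live on [0, 1] and the meta-training split is small, so the
word-net's conservative rate underfits it badly.

**Fusion** — majority voting over the six crisp decisions (ties resolved
by the linear-combination evidence, then toward the lower level); linear
combination as the uniform-weight sum of per-level log-likelihoods
(simple averaging is optimal for bases of equal accuracy and
correlation), with the MLP contributing its log soft outputs as the
sixth row; stacked fusion feeds the six crisp decisions, scaled to
[0, 1] by (level−1)/3, into the meta-net trained only on data the base
classifiers never saw. Six scaled decisions (rather than the 24 raw
soft values) keep the meta-net's input layer at 6; a 24-input log-lik
encoding is available behind a config switch in spirit — the decision
encoding is the default because the meta-training split is small.

## Evaluation protocol

The experimental unit is an utterance set: one child saying all five
words once. Splits draw 60 % of sets for training and 40 % for testing,
stratified by level so every (word, level) model has data; a child's sets
may fall on both sides but no utterance does, and a child-disjoint mode
(`split_mode="child"`) supports the stricter generalization check.
Stacked fusion halves the test split into meta-training and final-test
parts. Per-level accuracy is correct/total within the true level × 100,
averaged over repetitions; entries below 50 % are flagged
"not classified". Degenerate splits are dropped with a warning rather
than aborting a run.

## Synthetic corpus

The generator is a classical source-filter model: a glottal impulse
train with per-period jitter (fractional period SD) and shimmer
(fractional amplitude SD), one leaky-integrator tilt (≈ −6 dB/oct net of
lip radiation), cascaded two-pole resonators following per-word
formant-target trajectories (20 interpolation segments, filter state
carried across segments), an optional parallel 1 kHz nasal resonator
(bandwidth 120 Hz) whose gain is the hypernasality control, an
attack-sustain-release loudness contour with slow random wobble, and
white noise at a controlled SNR.

Severity profiles (level 1 → 4): mean f0 330/300/270/240 Hz (between-
child SD 15 Hz), jitter 4.0/2.5/1.4/0.6 %, shimmer 14/9/5/2.5 %, nasal
gain +12/+8/+4/off dB, SNR 15/20/25/30 dB, vowel centralization
0.6/0.4/0.2/0 — the direction of every parameter follows the clinical
picture of deaf speech (elevated unstable f0, hypernasality, rough
phonation, centralized vowels); the magnitudes are chosen once as
plausible for this population and are deliberate free parameters of the
study design. Each child draws its parameters around the level means,
each utterance perturbs them again at 35 % of the between-child SD.
Durations are uniform on 0.40–0.55 s at 44.1 kHz; the corpus geometry is
6/6/6/12 children × 5 words × 7 repetitions.

What the generator does *not* emulate: consonant bursts (word identity
lives entirely in vowel formant trajectories), room acoustics and
channel effects, inter-speaker vocal-tract-length variation beyond the
level profiles, and any linguistic content. Passing the end-to-end test
therefore shows that the pipeline separates levels whose acoustic
signatures differ in the designed directions — not that it reaches any
particular accuracy on real clinical recordings.

## Problem sizes

The shipped experiment sizes keep a full run on one CPU comfortable:
the end-to-end evaluation uses the full 1050-utterance corpus with 3
random-subsampling repetitions (the protocol itself supports 10, the
default in `SystemConfig`); unit tests exercise a reduced 16 kHz corpus
(2 children per level, 2 repetitions) with smaller HMMs (4 states, 2
mixtures), sizes at which every (word, level) model remains trainable.
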