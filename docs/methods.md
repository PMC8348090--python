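# Methods

## Signal model and conventions

Segments are mono 16-bit PCM at 22 050 Hz, one ingestive event each.
Two amplitude conventions are used deliberately:

* For spectral work, samples are normalized by division by 2¹⁶, giving a
  range of [−0.5, 0.5). The ANM (absolute normalized magnitude) spectrum
  is |rfft| of these values rescaled to sum to one; the FFT length equals
  the segment length (no zero padding), so the spectrum is invariant to
  any positive gain.
* The segment-level amplitude *descriptor* is the peak-to-peak sample
  range divided by 2¹⁶, a unitless quantity in [0, 1]. This is the scale
  on which published per-behavior amplitudes (up to ~0.55) are reported;
  a literal peak/2¹⁶ convention could never exceed 0.5, so peak-to-peak
  is the only reading consistent with those magnitudes. Which convention
  the original labels used (peak, peak-to-peak, offset-normalized) is not
  documented; this choice is ours and is applied consistently between the
  generator and the descriptor extractor, so parameter-recovery tests
  close the loop regardless.

## Synthetic generator

The generator emulates the statistical structure of the forehead-
microphone jaw-movement recordings, not their physiology. Per behavior ×
forage condition (alfalfa/tall fescue × tall/short), amplitude and
duration are drawn from normal distributions truncated to their physical
ranges (amplitude in (0, 1], duration > 0.02 s). The location parameter
of each truncated normal is solved numerically so the mean of the
*truncated* law equals the published condition mean — naive truncation
would bias the short-duration chew conditions upward by roughly half a
standard error, which matters because tests demand empirical means within
two standard errors of the nominal values.

Condition means are the published interaction-cell values (e.g. bite on
short tall fescue: amplitude 0.488, duration 0.205 s). Only pooled
standard errors of those means are published, not per-segment standard
deviations; per-segment SDs default to 5× the pooled SEM, a configurable
modeling choice giving realistic within-class spread (bite amplitude SD
0.085, chew 0.015, chew-bite 0.06).

Waveform templates are chosen to match the qualitative spectro-temporal
patterns of the three behaviors while keeping the task learnable but not
trivial:

* **bite** — band-limited Gaussian noise under a fast-attack envelope
  decaying with time constant duration/5;
* **chew** — stationary band-limited noise with short fade-in/out;
* **chew_bite** — the chew texture at 0.45 relative gain plus a decaying
  burst starting at the final third of the segment.

The carrier band defaults to 70–1000 Hz, matching the observation that
cow ingestive sounds live mostly below 1 kHz. Device beeps are pure
sinusoids (default 4 kHz, inside the documented 3.6–4.5 kHz range),
placed by a Poisson process at a configurable rate and clipped into the
int16 range after superposition.

A fixed two-threshold rule on (amplitude, duration) — quiet → chew, loud
and short → bite, loud and long → chew-bite — reaches ≥ 0.8 accuracy on
the default conditions, establishing a learnability floor below the
deep models' operating range. What the generator does **not** model:
cow-to-cow variation, microphone transfer functions, overlapping events,
background farm noise, or amplitude/duration correlation within a
condition. Passing tests therefore demonstrate the pipeline's mechanics
and the architectures' capacity on well-posed data, not field
performance on real recordings.

## Cleaning

The beep bandstop is a 4th-order Butterworth over 3.6–4.5 kHz applied
forward-backward (zero phase), then requantized to int16. The filter
design is a package choice: zero-phase application avoids smearing
impulsive bite transients, and order 4 (8th-order effective response)
gives > 30 dB stopband attenuation with < 1 dB passband ripple at 500 Hz.

Uninformative-data removal works on absolute raw 16-bit samples averaged
over 1100-sample blocks. "Several means at various steps of averaging"
is implemented as windows of 1100 samples launched at `n_offsets`
staggered starting offsets (default 4, i.e. offset step 275); each
non-overlapping block retains the maximum mean over every window that
overlaps it, and blocks with a retained maximum below 100 (strictly —
equality is kept) are dropped and the remainder concatenated without
padding. A tail shorter than one block is averaged over its actual
length. Note one consequence of max-over-overlapping-windows: a silent
block adjacent to a loud run can be retained because a straddling window
raises its maximum; this is what makes the operation idempotent (every
retained block still holds a qualifying window after concatenation, and
junction windows can only add candidate means).

## Featurization

STFT: 512-sample (23 ms) Hann window, 220-sample (10 ms) hop, frame
count ⌊(N−512)/220⌋+1 with zero padding of sub-window inputs; per-frame
real FFT and squared magnitude (frames are transformed independently —
no overlap-add). 26 triangular filters with centers equally spaced on
the Mel scale between 0 Hz and Nyquist pool the 257-bin power rows; band
energies become 10·log₁₀(E + 1e−10) clamped at −80 dB. The Hann window,
ε, and floor are conventional numerical guards, all configurable (a
rectangular window is available for strict-literal runs). An optional
orthonormal DCT-II over the bands produces cepstral coefficients; the
default feeds log-Mel directly, which is the documented dataflow.

Variable-length segments are center-cropped or symmetrically padded at
the floor value to 98 frames (1.0 s) — events typically last under 1 s,
so 98 frames covers almost all segments without truncation.

## Classifiers

No deep-learning framework is a dependency: the three networks run on a
compact in-package reverse-mode autograd (float32, CPU, fully
deterministic given seeds), with valid-mode im2col convolutions,
axis-wise max pooling, gated recurrence, dropout, and Adam.

* `conv1d`: per-frame (time-distributed) 1-D convolutions over the 26
  Mel bands (3×8 then 3×16, each followed by pool-2), temporal max
  pooling (factor 4), flatten, dense-64, softmax. ~124 k parameters.
* `conv2d`: three 3×3 convolution + 2×2 max-pool blocks (8/16/32
  channels) over the time × Mel image, flatten, dense-64, softmax.
  ~27 k parameters.
* `lstm`: two serial units, each concatenating a time-distributed
  dense-32 skip path with a 16-unit bidirectional LSTM over the frame
  sequence; a time-distributed dense-16 head is flattened into the
  softmax. ~25 k parameters.

These are scaled-down renditions of the published designs (printed sizes
348 770 / 431 290 / 392 050 parameters; exact layer widths were never
printed): the topology per architecture is preserved while widths are
sized so all three train their full 30 epochs in minutes on one CPU
core. On the synthetic task the reduced capacity is not limiting (the
LSTM exceeds 0.99 test macro-F1).

Training protocol: Adam (lr 1e−3, batch 32 — unstated upstream, standard
defaults), categorical cross-entropy, dropout 0.1 on dense heads and
after each recurrent unit, relu on convolutional/dense paths and
tanh/sigmoid gating in the recurrence, 30 epochs with per-epoch train
and validation curves. Features are standardized by the training set's
global mean/SD (stored with the model). Training aborts with a
diagnostic on non-finite loss. Given seeds, initialization, shuffling,
and dropout masks are deterministic, so repeated runs are bit-identical.

## Dataset protocol

Inventory follows the reference dataset's 12-cell structure (behavior ×
species × height); the published cell counts and durations are embedded
so accounting arithmetic (3038 segments, 1647.37 s; behavior totals
521/1617/900) is checkable without the recordings. Count-balancing
subsamples each behavior uniformly without replacement to the minority
count (521), keeping the minority class — and hence all 547.04 s of bite
audio — in full; the resulting chew/chew-bite durations depend on the
draw and are not reproducible against any particular published run.
Splitting is floor(0.7 n)/floor(0.1 n)/remainder, stratified by behavior
by default (applied per stratum; a `none` option applies the floors
globally). Whether the original protocol stratified is unstated;
stratification guarantees per-class representation in every partition.

## Evaluation

Metrics are computed from the 3×3 confusion matrix by one-vs-rest
TP/FP/FN counting. "Overall" rows are support-weighted averages by
default (macro available via a flag): on imbalanced data the weighted
average tracks the chew-dominated per-class values, which matches how
overall scores behave in the reference results. Zero-division (a class
never predicted) yields metric 0 with a warning. Both count and
row-normalized confusion views are emitted. Normalized processing speed
(1000 × processing time / audio duration, ms per second of audio) is
reported but never asserted — it is hardware-bound — and is kept in a
separate `timing.json` so `report.json` stays byte-deterministic.

## Problem sizes

The default synthetic study dataset is 600 segments (50 per condition),
split 420/60/120; acceptance-scale experiments train all three
architectures for the full 30 epochs on this size. These sizes were
chosen as the package's desk-scale operating point: large enough that
the split is class-balanced and the learnability margin is wide, small
enough that a full experiment completes in about 90 seconds on one CPU
core.

## Known limitations

* Synthetic data only, unless the real recordings are supplied; see the
  generator caveats above.
* The uninformative-removal offset/grouping scheme is one reading of an
  ambiguous description; `n_offsets` is configurable.
* Reduced model widths mean parameter counts are not comparable to the
  printed model sizes.
* No statistical comparison between models (no McNemar/bootstrap), no
  calibration analysis, no data augmentation.
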