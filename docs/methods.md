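# Methods

## Data model

A recording is a `VideoRecord`: a subject id, one of 16 emotion labels with a
fixed valence (4 negative, 12 positive), a `FeatureSequence` (T×D per-frame
matrix at 30 fps), an optional audio energy envelope with its own frame rate,
and optional emotional-phase boundaries. Appearance features are the
OpenFace action-unit outputs: 17 intensities (AU 1, 2, 4, 5, 6, 7, 9, 10, 12,
14, 15, 17, 20, 23, 25, 26, 45, each 0–5) followed by 18 presences (the same
set plus AU28, each 0/1), in ascending AU number — the column order is fixed
by the package because trained models are only reproducible under a fixed
order. Deep features are 2048-dim per-frame vectors consumed from files or
the synthetic generator; the package never runs a CNN extractor. Presence
columns are parsed as floats and binarized at 0.5, and a frame counts as
"face detected" when the `success` column is ≥ 0.5; header whitespace is
stripped (OpenFace writes padded headers).

Gap filling: frames without a detected face are replaced by the most recent
detected frame; undetected runs at either end of the recording are dropped
rather than extrapolated. The operation is idempotent.

## Segmentation

The emotional phase is recovered from the audio envelope alone. A frame is
active when its energy is at least `threshold_frac` (default 0.1) of the
envelope's maximum; active runs separated by silences shorter than
`min_gap_s` (default 0.3 s) are merged, and the longest merged run — ties
broken by earliest start, for determinism — is extended by `pad_after_s`
(default 1.0 s) and clipped at the end of the recording. The extension
exists because facial expressions outlast speech. Envelope and feature
streams may run at different rates; envelope-frame bounds map to feature
frames with floor(start·fps_feat/fps_env) and ceil for the end, so the
feature window never undershoots the detected segment.

The defaults are the simplest settings that satisfy the
longest-nonsilent-segment contract; no spectral or learned voice-activity
detection is attempted.

## Synthetic corpus

The generator emulates the structure of a Wizard-of-Oz smartphone study of
posed emotions, at reduced scale. Defaults: 15 subjects; per-emotion counts
of 15 (negative) and 6 (positive), preserving the ~2.5:1 imbalance of such
designs, 132 videos in total; phases of roughly 1 s preparation, 2 s voiced
emotional phase, 1 s disengagement, each jittered ±25% per video; 30 fps
features and a 100 Hz envelope.

Each emotion has an archetype vector `baseline + separability · direction`,
where the direction comes from a fixed table of AU–emotion associations
(e.g. happiness loads on AU6/AU12) and unlisted emotions receive
deterministic sparse pseudo-random directions. Pairwise archetype distances
are therefore exactly linear in `separability` (default 1.5), and
`separability = 0` produces class-uninformative features. A frame is
`baseline + g(t)·(archetype − baseline) + subject_offset + noise`, where
g(t) is a rise–sustain–decay envelope (0.3 s ramps) spanning the voiced
interval plus a 1 s expressive tail; intensities are clipped to [0, 5] and
presence propensities binarized at 0.5. Subject offsets (sd 0.12) are what
make speaker-independent evaluation harder than a random split; frame noise
has sd 0.12. The stored ground-truth phase is the expressive window (voiced
interval + 1 s tail), which is also what the detector, with its 1 s pad, is
built to recover — the audio envelope itself is high only while the subject
"speaks".

Deep features are a fixed random linear map (35 → 2048) of the appearance
features plus noise; the map is shared across corpora, mimicking a fixed
external extractor, so only the noise depends on the seed. Simulated human
raters are independently correct with probability `accuracy_target` and
otherwise uniform over the wrong labels.

What the generator does **not** emulate: real AU estimation error structure
(OpenFace errors are correlated with pose and lighting), lip-reading cues,
inter-subject differences in expressive style beyond an additive offset, or
temporal dynamics richer than one rise–sustain–decay event. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
models can exploit class structure of this kind — not that comparable
accuracy would be reached on real videos.

## Partitioning

Difficulty scores are leave-one-subject-out 16-class UARs of the SVM
baseline over time-averaged appearance features; a held-out subject's UAR
averages only over the classes that subject has. Subjects sorted by
descending score are dealt 3-train/1-validation/1-test per round; ties break
lexicographically by subject id so the assignment is deterministic under
input permutation. For subject counts not divisible by 5, `tail='strict'`
continues the pattern (63 → 39/12/12) while `tail='balanced'` gives each
leftover subject to the split furthest below its ideal 3:1:1 share
(63 → 37/13/13). Both are exposed because the strict reading of the
round-robin rule and a 37/13/13-style outcome are mutually inconsistent;
neither is privileged. Difficulty scoring operates on whatever features the
records carry; the pipeline segments records first so scoring matches the
model-training data path.

## Models

The SVM baseline is scikit-learn's SVC (RBF kernel, C=1, gamma='scale')
behind a StandardScaler, predicting hard labels from video-level means.

The sequence classifiers are implemented in NumPy, including
backpropagation through time and Adam — verified against central finite
differences in the test suite (agreement ~1e-10 absolute on small networks).
Architecture: a 1-directional stacked GRU, 3 layers, hidden size 35; one of
three pooling heads; an MLP with two 24-unit ReLU layers; softmax output
(2 classes for the valence task, 16 for the emotion task — the binary model
is trained separately, not derived from the 16-class model).

Heads. *Average*: masked uniform mean over time. *Attention*: u_t =
tanh(W·h_t + b), α = softmax_t(u_tᵀc), output Σ α_t h_t, with the context
dimension equal to the GRU hidden size; W, b, c are zero-initialized, so the
head starts as exact averaging (the average head is literally the
uniform-weight special case of the same weighted-sum code path, making the
equivalence bit-for-bit). *Convolution*: depthwise 1-D convolution, kernel
3, stride 1, zero "same" padding, then masked temporal averaging; depthwise
because the kernel is applied to the same feature across consecutive frames
(a full-channel variant is not provided — masking plus channel mixing adds
complexity with no tested benefit).

Training: cross-entropy, Adam (lr 0.001, β = 0.9/0.999), batch size 64,
sequences zero-padded to the batch maximum with padded frames masked in the
GRU recursion (the hidden state is carried through unchanged) and in every
head. Inputs are z-scored per feature using training-split statistics
(zero-variance columns pass through); scaling is applied to the neural nets
as well as the SVM because 2048-dim deep features are unusable raw. Early
stopping monitors validation UAR: an epoch improves only if strictly
greater, training stops after `patience` (default 30) non-improving epochs,
and the best epoch's weights are restored. `max_epochs` defaults to 500 in
`ModelConfig`; the default experiment configuration uses 200, which is past
convergence for the default corpus. Epochs are 1-based in histories and
`best_epoch`. Training is bitwise reproducible from the config seed.

## Evaluation

All metrics are computed from the K×K contingency matrix A (rows = truth).
UAR averages per-class recalls over classes with at least one true instance;
per-class balanced accuracy is one-vs-rest (sensitivity + specificity)/2,
undefined (and omitted) for classes with neither true nor predicted
instances. Cohen's κ uses product-of-marginals expected agreement and is
defined as 1 when both raters are constant and identical; Fleiss' κ follows
the standard fixed-rater-count formulation. κ values are labelled slight
(≤0.2), fair (≤0.4), moderate (≤0.6), substantial (≤0.8), almost perfect
(>0.8). Confidence intervals are percentile bootstrap over item resamples
(B = 1000, seeded); "bootstrapped" alone does not pin a method, and the
percentile variant is the conventional default. The binomial test is exact,
one-sided (upper tail), with chance p₀ = 0.5 for the valence task and 1/16
for the emotion task. Reported percentages round half-up to one decimal.

## Problem sizes and expected numbers

The default experiment uses the default 132-video corpus. With 15 subjects
the splits come out 9/3/3 subjects (79/27/26 videos at seed 0). On this
corpus the binary task is essentially solved by every head (test UAR ≥ 0.93
across seeds), while the 16-class task — with only one or two test videos
per class — lands several multiples above the 6.25% chance UAR with large
seed-to-seed spread. Label-shuffled training collapses both tasks into the
Monte-Carlo chance band, and the leave-one-subject-out difficulty scores on
the default corpus are near 1 (the video-level means are nearly separable).
These numbers are recomputed, not asserted from memory, by
`scripts/acceptance.py` and the test suite.

## Known limitations

* The generator's class structure is additive and stationary within a video;
  it cannot probe models' ability to use expression dynamics beyond the
  single onset/offset event.
* 16-class UAR estimates on the default corpus rest on a 26-video test set
  and are correspondingly noisy across seeds.
* The NumPy implementation is single-threaded per batch step and intended
  for corpora of hundreds of videos, not tens of thousands.
* Fleiss' κ returns NaN when expected agreement is 1 but observed agreement
  is not, which can only occur with degenerate single-category inputs.
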