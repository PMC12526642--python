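# Methods

This note documents the models, the synthetic data, the numerical choices
and the known limitations of the `silentspeech` pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Task and data model

The target task is closed-vocabulary, sentence-level silent speech
recognition: four command phrases over ten words ("Need", "Medical",
"Assistance", "Land", "Here", "Do", "Not", "Pick", "Us", "Up") plus a
NOISE class, decoded from single-channel EMG and EEG sampled at 4096 Hz.
Two corpus shapes exist: an isolated-word corpus (all eleven classes,
defaults of 150 repetitions per word) used for pretraining and reference
selection, and a continuous-sentence corpus (defaults of 100 repetitions
per phrase) used for moving-window retraining and all sentence-level
evaluation. Within each class or phrase, recordings are split 70/30 into
train/test.

On disk a corpus is a tab-separated manifest plus one single-column
amplitude CSV per modality per recording. Amplitudes are written with 17
significant digits, so a write→read round trip reproduces float64 values
exactly. Augmented recordings carry a `parent_id` provenance column.

## Synthetic generator

The generator makes the whole pipeline testable without the recorded
dataset. Each word class gets one fixed template per modality: a sum of
12 random-phase sinusoids drawn uniformly from a modality band (EMG-like
20–450 Hz, EEG-like 1–40 Hz), normalized to unit RMS. An isolated word
instance is its template, amplitude-scaled by `1 ± amp_jitter` (uniform),
time-warped by resampling to `1 ± time_warp` of the nominal duration
(warp and amplitude shared across the two channels of one utterance,
noise independent), plus white Gaussian noise of standard deviation
`noise_sd`. NOISE-class instances are pure noise.

Sentences emulate the two systematic ways continuous speech differs from
isolated citation forms:

* **Boundary blending.** Adjacent word instances are joined with a linear
  crossfade (`crossfade` samples), so boundary regions match neither
  word's template and the sentence is not the concatenation of its words.
* **Tempo compression.** Every in-sentence word instance is resampled to
  `sentence_tempo` (default 0.85) of its isolated duration. Connected
  speech is faster than isolated citation; the resampling shifts each
  word's spectral content uniformly, which is exactly the kind of
  systematic isolated-vs-continuous mismatch a pretrained-only model
  cannot absorb but window-level retraining can.

Leading and trailing noise pads (`pad_noise` samples) surround the speech
span; the generator records the pad sizes in recording metadata, which
positional labeling consumes.

Default levels — `noise_sd` 0.3 (relative to unit-RMS templates),
`amp_jitter` 0.15, `time_warp` 0.08, `crossfade` 120, `sentence_tempo`
0.85, word duration 800 samples (≈0.2 s, longer than the 700-sample
analysis window) — were fixed once so that isolated words are reliably
separable while continuous decoding shows the qualitative behavior the
pipeline exists to fix (see "Benchmark profile"). The generator does
**not** attempt physiological realism: no motor-unit statistics, no 1/f
EEG background, no blink/motion artifacts, no inter-session drift.
Passing tests therefore demonstrate the pipeline's mechanics and its
orderings under controlled conditions, not field performance on human
data.

## Siamese few-shot classifier

The encoder is `n` blocks of (1-D convolution, kernel 7, padding 3 →
ReLU → average-pool stride 2), a global average pool, a linear projection
and L2 normalization; defaults: 3 blocks of 8/16/32 channels, 64-d
embedding. Segments are z-scored before encoding (constant segments map
to zeros); recordings longer than the 700-sample input are center-cropped
and shorter ones mean-padded. The two Siamese branches are one shared
object, so weight sharing is structural rather than enforced by
synchronization.

Training pairs are (segment, reference) — references act as anchors —
with the contrastive loss `y·d² + (1−y)·max(0, m−d)²` over cosine
distance and margin `m = 1` (mismatched pairs are pushed to at least
orthogonality). Each epoch samples 2 positive and 3 negative references
per training segment; optimization is Adam (lr 3·10⁻³, batch 64),
implemented with hand-written backpropagation in numpy — the problem
sizes here never justify a deep-learning framework dependency.

The reference set holds 5 recordings per class (55 total). Selection is
medoid-like and seed-free: per class, the train-split non-augmented
recordings with the highest mean raw-signal cosine similarity to the rest
of their class. Reference recordings (and their augmented descendants)
are excluded from the training pair pool, and a fingerprint of the set is
stored on the model so retraining can verify the anchors never changed.

Classification of a segment averages its cosine distance to each class's
5 reference embeddings and ranks classes ascending; exact ties break by
vocabulary order. Confidences are a softmax over `−distance/τ` with
temperature `τ = 0.1`; the distance-based classifier has no native
probabilities, and the LM stage needs some, so the temperature softmax is
a deliberate, isolated calibration choice.

## Fusion

The fused encoder runs one convolutional branch per modality (same shape,
separate weights), concatenates the pooled branch features and mixes them
into a single L2-normalized embedding. The default head is a single
linear layer: the parallel branches are already multi-layer, and in
experiments here a deeper ReLU head trained markedly less reliably at
these pair counts (it was kept available via `FusionConfig.head_layers`).
The fused model has roughly twice the parameters of a unimodal one, so
the benchmark gives it a proportionally larger epoch budget. Unimodal
ablations use the single-branch encoder, not a masked fusion model, and a
fusion model refuses unpaired input rather than silently degrading.

## Moving-window decoding

Windows of width `W = 700` slide with stride `S = 380` (overlap preserves
transitional content); starts are `0, S, 2S, …` while the window fits,
and trailing samples shorter than `W` are discarded. Coordinates are
0-based and half-open throughout. For retraining, the speech span
(recording minus known pads) is divided into one equal interval per word;
a window takes the label of the word interval overlapping it most (ties
to the earlier word) and is labeled NOISE when no interval covers at
least half the window. Retraining continues contrastive training on these
positionally-labeled window crops from the sentence train split (plus
augmented variants), keeping the original reference set; the updated
encoder re-embeds the references implicitly.

At decode time each window is classified independently; the raw word
sequence is the per-window top-1 with NOISE dropped, and adjacent
duplicate runs are collapsed afterwards ("Pick Us Us Up" → "Pick Us Up").
No HMM/CTC-style alignment is attempted — per-window argmax plus dedup
plus LM correction *is* the decoder under study.

## Trigram language model and correction

The LM stores raw 1/2/3-gram counts over boundary-padded training
phrases (two `<s>`, one `</s>`) and scores with add-k smoothing,
`P(w|u,v) = (c(u,v,w)+k) / (c(u,v,·)+k(V+1))`, default `k = 0.01`. Add-k
was chosen over backoff/Kneser–Ney because the vocabulary is ten words
and the scheme is exactly checkable against a count-and-multiply oracle;
with `k = 0` the implementation matches that oracle identically. The LM
trains on the four command phrases themselves (pluggable for larger
corpora).

Correction enumerates paths over each window's top-`m` non-noise
candidates (beam width 500, scores summed log-confidences), collapses and
deduplicates them, then filters any hypothesis containing a trigram with
**zero raw count and smoothed probability below 0.02**. The threshold
operationalizes "statistically rare": observed-history zero-count
trigrams score ≈0.009 at the defaults (filtered), while an entirely
unseen history scores `1/(V+1) ≈ 0.09` (kept, since the corpus says
nothing about it). Survivors are ranked by per-word-normalized LM
log-probability, truncated to the top `K = 5`, and the winner maximizes
the length-normalized mixture `[λ·logP_LM + (1−λ)·logP_SNN]/n_words`
with `λ = 0.5`; ties break by LM score, then lexicographically. If every
path is filtered, the uncorrected collapsed sequence is returned and
flagged. With this filter and a four-phrase corpus, any accepted
correction is one of the training commands — the intended closed-world
behavior for a command interface.

## Evaluation and metrics

* **Word accuracy** — top-1 on held-out isolated-word recordings.
* **Window accuracy** — per-window top-1 against the positional label on
  held-out sentences; this is the "words in sentence" surface and the
  quantity the retraining objective directly optimizes.
* **Slot accuracy** — per ground-truth word slot after collapsing:
  positionwise matches when prediction and reference have equal length,
  otherwise longest-common-subsequence hits divided by the number of
  slots (deterministic, penalizes insertions and deletions). Window and
  slot accuracy are both reported because "word-in-sentence accuracy" is
  ambiguous between the two granularities.
* **Sentence accuracy** — exact match of the final decoded sequence.

Before any fit, the experiment driver asserts train/test/reference id
sets are pairwise disjoint.

## Benchmark profile

`silentspeech.benchmark` defines the package's standard desk-scale
benchmark: the full vocabulary and all four phrases, 16 repetitions per
word and 12 per sentence (70/30 split ⇒ 55 held-out words, 16 held-out
sentences), 2 augmented variants per train recording, 6 pretraining
epochs (12 for fusion), 4 retraining epochs. One three-modality run takes
on the order of 1–2 minutes on a single CPU; a `fusion-stress` variant
raises per-modality noise (EMG 1.5, EEG 1.8) into the regime where each
unimodal model errs independently and fusion has something to combine.
These sizes are the package's own choice of a small, fully reproducible
experiment; the generator defaults keep the full-study corpus sizes for
users who want them.

The acceptance suite checks the benchmark's qualitative orderings per
seed: pretrained-only word accuracy high but collapsing by ≥30 points on
sentence windows, window retraining recovering to within 15 points,
LM correction never reducing sentence accuracy, and stressed fusion
matching or beating the better unimodal model. With a 16-sentence test
set, sentence accuracy moves in 6.25 % steps — orderings are meaningful,
absolute percentages are coarse.

## Numerical and degenerate-input choices

* Average pooling (not max) keeps gradients simple and dense; odd-length
  tails are dropped.
* He-initialized convolutions/dense layers; float64 throughout.
* `fit_length` center-crops or mean-pads; z-scoring guards zero variance.
* Cosine distance raises on zero vectors; embeddings are normalized with
  an ε-guard of 10⁻¹².
* Empty training sets, empty sentences, too-short recordings, OOV words,
  non-overlapping strides and invalid crop/shift parameters all raise
  `ValidationError` rather than degrading silently.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integer tuples, so corpora, training and reports are
  bit-reproducible given a seed.

## Known limitations

* The synthetic corpora are template-based; real EMG/EEG variability
  (electrode shift, fatigue, artifacts, inter-subject differences) is out
  of scope, so absolute accuracies here say nothing about human data.
* The evenly-spaced-words labeling assumption is exactly true of the
  generator (up to warp and crossfade) but only approximately true of
  real speech.
* The fusion architecture is one reasonable reading of parallel
  multi-layer sensor fusion; its internals (branch depth, head shape) are
  configuration, not a claim about any previously published variant.
* The LM stage assumes a closed command vocabulary; it cannot produce a
  sentence it has never counted, which is a feature for command
  interfaces and a limitation for open vocabularies.
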