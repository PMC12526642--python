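"""End-to-end experiment orchestration and the three accuracy surfaces.

Three models are compared per modality (EMG-only, EEG-only, fusion):

* Model A - pretrained on the isolated-word corpus only;
* Model B - Model A further trained on positionally-labeled moving
  windows of the sentence corpus;
* Model C - Model B with trigram-LM candidate correction at decode time.

Accuracies reported (all percentages):

* word accuracy - top-1 on held-out isolated-word recordings;
* window accuracy - per-window top-1 vs. the positional label on held-out
  sentences (the "words in sentence" surface);
* slot accuracy - per ground-truth word slot after collapsing the decoded
  sequence (exact-position match when lengths agree, else
  longest-common-subsequence hits / number of slots);
* sentence accuracy - exact match of the final decoded word sequence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .augmentation import AugmentPlan, augment_corpus
from .errors import ValidationError
from .fusion import FusionConfig
from .lm import TrigramModel, correct_sentence, fit_trigram
from .signal_model import (
    DEFAULT_SENTENCES,
    DEFAULT_VOCABULARY,
    NOISE_LABEL,
    Corpus,
)
from .snn import (
    EncoderConfig,
    ReferenceSet,
    SiameseModel,
    build_reference_set,
    classify_segment,
    pretrain,
)
from .synthetic import SynthConfig, synth_corpora
from .windows import (
    WindowSpec,
    assign_window_labels,
    collapse_repeats,
    infer_word_sequence,
    retrain,
)


def evaluate_words(model: SiameseModel, corpus_a: Corpus, refs: ReferenceSet) -> float:
    """Top-1 accuracy (%) on the word corpus' test split."""
    test = [r for r in corpus_a.test if r.kind in ("word", "noise")]
    if not test:
        raise ValidationError("empty word test set")
    hits = 0
    for rec in test:
        ranking = classify_segment(model, _unprepared(model, rec), refs)
        hits += ranking.top1 == rec.label
    return 100.0 * hits / len(test)


def _unprepared(model: SiameseModel, rec) -> np.ndarray:
    """Raw fixed-length cut of a recording (classify_segment re-standardizes)."""
    from .util import fit_length

    if model.modality == "fusion":
        return np.stack([fit_length(rec.signal("emg"), model.input_length),
                         fit_length(rec.signal("eeg"), model.input_length)])
    return fit_length(rec.signal(model.modality), model.input_length)


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Longest common subsequence length (classic DP)."""
    n, m = len(a), len(b)
    dp = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1]:
                dp[i][j] = dp[i - 1][j - 1] + 1
            else:
                dp[i][j] = max(dp[i - 1][j], dp[i][j - 1])
    return dp[n][m]


def sequence_scores(predicted: Sequence[str], truth: Sequence[str]) -> Tuple[float, int, bool]:
    """Score a decoded word sequence against the reference.

    Returns (slot_hits, n_slots, exact): positionwise matches when lengths
    agree, LCS hits otherwise; ``exact`` is full-sequence equality.
    """
    predicted, truth = list(predicted), list(truth)
    if len(predicted) == len(truth):
        hits = float(sum(p == t for p, t in zip(predicted, truth)))
    else:
        hits = float(lcs_length(predicted, truth))
    return hits, len(truth), predicted == truth


@dataclass
class SentenceEval:
    window_accuracy: float
    slot_accuracy: float
    sentence_accuracy: float
    n_sentences: int
    n_windows: int


def evaluate_sentences(model: SiameseModel, corpus_b: Corpus, refs: ReferenceSet,
                       spec: WindowSpec, lm: Optional[TrigramModel] = None,
                       K: int = 5, top_m: int = 3, lam: float = 0.5) -> SentenceEval:
    """Window, slot and sentence accuracy (%) on the sentence test split.

    With ``lm`` given, the final sequence is the LM-corrected one;
    otherwise it is the collapsed raw top-1 sequence.
    """
    test = [r for r in corpus_b.test if r.kind == "sentence" and r.length >= spec.width]
    if not test:
        raise ValidationError("empty sentence test set")
    win_hits = win_total = 0
    slot_hits = slot_total = 0.0
    sent_hits = 0
    for rec in test:
        truth = rec.words
        rankings, raw_words = infer_word_sequence(model, rec, refs, spec)
        gt = assign_window_labels(rec, spec)
        for seg, ranking in zip(gt, rankings):
            win_hits += ranking.top1 == seg.assigned_label
            win_total += 1
        if lm is not None:
            predicted = correct_sentence(rankings, lm, K=K, top_m=top_m, lam=lam).words
        else:
            predicted = collapse_repeats(raw_words)
        hits, n_slots, exact = sequence_scores(predicted, truth)
        slot_hits += hits
        slot_total += n_slots
        sent_hits += exact
    return SentenceEval(
        window_accuracy=100.0 * win_hits / win_total,
        slot_accuracy=100.0 * slot_hits / slot_total,
        sentence_accuracy=100.0 * sent_hits / len(test),
        n_sentences=len(test),
        n_windows=win_total,
    )


# ---------------------------------------------------------------------------
# Experiment orchestration


@dataclass
class ExperimentConfig:
    """Everything one Model A/B/C run needs, in one reproducible bundle."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    vocabulary: Tuple[str, ...] = DEFAULT_VOCABULARY
    sentences: Tuple[Tuple[str, ...], ...] = DEFAULT_SENTENCES
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    fusion_head_layers: Tuple[int, ...] = ()
    fusion_epochs: Optional[int] = None    # None -> encoder.epochs
    window: WindowSpec = field(default_factory=WindowSpec)
    augment: AugmentPlan = field(default_factory=AugmentPlan)
    modalities: Tuple[str, ...] = ("emg", "eeg", "fusion")
    shots_per_class: int = 5
    retrain_epochs: Optional[int] = None   # None -> encoder.epochs
    lm_k_smooth: float = 0.01
    lm_K: int = 5
    lm_top_m: int = 3
    lm_lambda: float = 0.5
    seed: int = 0

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(
            self,
            seed=seed,
            synth=replace(self.synth, seed=seed),
            encoder=replace(self.encoder, seed=seed),
            augment=replace(self.augment, seed=seed),
        )

    def model_config(self, modality: str):
        if modality == "fusion":
            branch = self.encoder
            if self.fusion_epochs is not None:
                branch = replace(branch, epochs=self.fusion_epochs)
            return FusionConfig(branch=branch,
                                head_layers=self.fusion_head_layers,
                                embedding_dim=self.encoder.embedding_dim)
        return self.encoder


@dataclass
class ExperimentReport:
    """Accuracy surfaces per modality and model, plus provenance."""

    results: Dict[str, Dict[str, Dict[str, float]]]
    seed: int
    config: Dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"seed": self.seed, "results": self.results,
                           "config": self.config}, indent=indent, sort_keys=True)

    def accuracy(self, modality: str, model: str, metric: str) -> float:
        return self.results[modality][model][metric]


def _assert_no_leakage(corpus: Corpus, refs: ReferenceSet) -> None:
    train = {r.id for r in corpus.train}
    test = {r.id for r in corpus.test}
    if train & test:
        raise ValidationError("train/test splits overlap")
    ref_ids = set(refs.all_ids)
    if ref_ids & test:
        raise ValidationError("reference recordings leak into the test split")


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run the full Model A/B/C protocol on synthetic corpora.

    Generates the corpora, augments the train splits, builds the reference
    set, pretrains per modality, retrains with moving windows, applies the
    trigram LM, and reports every accuracy surface. Deterministic given
    ``config.seed``.
    """
    corpus_a, corpus_b = synth_corpora(config.vocabulary, config.sentences, config.synth)
    corpus_a = augment_corpus(corpus_a, config.augment)
    corpus_b = augment_corpus(corpus_b, config.augment)
    refs = build_reference_set(corpus_a, shots_per_class=config.shots_per_class,
                               input_length=config.encoder.input_length)
    _assert_no_leakage(corpus_a, refs)
    _assert_no_leakage(corpus_b, refs)
    lm = fit_trigram([list(s) for s in config.sentences], k_smooth=config.lm_k_smooth,
                     vocabulary=[w for w in config.vocabulary if w != NOISE_LABEL])

    results: Dict[str, Dict[str, Dict[str, float]]] = {}
    for modality in config.modalities:
        model_cfg = config.model_config(modality)
        model_a = pretrain(corpus_a, refs, model_cfg, modality=modality)
        word_acc_a = evaluate_words(model_a, corpus_a, refs)
        eval_a = evaluate_sentences(model_a, corpus_b, refs, config.window)

        model_b = retrain(model_a, corpus_b, refs, config.window,
                          epochs=config.retrain_epochs)
        eval_b = evaluate_sentences(model_b, corpus_b, refs, config.window)
        eval_c = evaluate_sentences(model_b, corpus_b, refs, config.window, lm=lm,
                                    K=config.lm_K, top_m=config.lm_top_m,
                                    lam=config.lm_lambda)

        results[modality] = {
            "model_a": {
                "word_accuracy": word_acc_a,
                "window_accuracy": eval_a.window_accuracy,
                "slot_accuracy": eval_a.slot_accuracy,
                "sentence_accuracy": eval_a.sentence_accuracy,
            },
            "model_b": {
                "window_accuracy": eval_b.window_accuracy,
                "slot_accuracy": eval_b.slot_accuracy,
                "sentence_accuracy": eval_b.sentence_accuracy,
            },
            "model_c": {
                "window_accuracy": eval_c.window_accuracy,
                "slot_accuracy": eval_c.slot_accuracy,
                "sentence_accuracy": eval_c.sentence_accuracy,
            },
        }

    snapshot = {
        "synth": asdict(config.synth),
        "encoder": asdict(config.encoder),
        "window": {"width": config.window.width, "stride": config.window.stride},
        "augment": {"per_recording_count": config.augment.per_recording_count},
        "modalities": list(config.modalities),
        "retrain_epochs": config.retrain_epochs,
        "lm": {"k_smooth": config.lm_k_smooth, "K": config.lm_K,
               "top_m": config.lm_top_m, "lambda": config.lm_lambda},
    }
    return ExperimentReport(results=results, seed=config.seed, config=snapshot)
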