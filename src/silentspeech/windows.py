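"""Moving-window machinery for continuous sentence signals.

A fixed-width window (default 700 samples) slides with a fixed stride
(default 380) across a sentence recording; overlapping windows preserve
transitional content at word boundaries. For retraining, each window gets
a positional ground-truth label under the assumption of evenly spaced
words across the speech span; at decode time each window is classified
independently and the per-window top-1 sequence (noise dropped, adjacent
repeats collapsed) is the raw transcription.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .signal_model import NOISE_LABEL, Corpus, Recording
from .snn import CandidateRanking, ReferenceSet, SiameseModel, classify_segment, fit_pairs


@dataclass(frozen=True)
class WindowSpec:
    """Moving-window geometry: width and stride in samples."""

    width: int = 700
    stride: int = 380

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("window width must be > 0")
        if not (0 < self.stride <= self.width):
            raise ValidationError("stride must be in (0, width] so windows overlap")


@dataclass
class WindowSegment:
    """One labeled window of a sentence recording (0-based, half-open)."""

    recording_id: str
    start: int
    end: int
    assigned_label: str


def slide(recording_length: int, spec: WindowSpec) -> List[Tuple[int, int]]:
    """All (start, end) positions: starts 0, S, 2S, ... while end <= length."""
    if recording_length < spec.width:
        raise ValidationError(
            f"recording length {recording_length} shorter than window {spec.width}"
        )
    out = []
    start = 0
    while start + spec.width <= recording_length:
        out.append((start, start + spec.width))
        start += spec.stride
    return out


def assign_window_labels(sentence: Recording, spec: WindowSpec,
                         min_overlap_fraction: float = 0.5) -> List[WindowSegment]:
    """Positional ground truth for every window of a sentence.

    The speech span (recording minus any known pad regions) is divided
    into one equal interval per word, in order. A window is labeled with
    the word whose interval overlaps it most (ties to the earlier word);
    if no interval overlaps it by at least ``min_overlap_fraction`` of the
    window width it is labeled noise.
    """
    if sentence.kind != "sentence":
        raise ValidationError("assign_window_labels requires a sentence recording")
    words = sentence.words
    if not words:
        raise ValidationError("sentence has no words")
    L = sentence.length
    lo = sentence.pad_left
    hi = L - sentence.pad_right
    if hi <= lo:
        raise ValidationError("speech span is empty after removing padding")
    n = len(words)
    edges = np.linspace(lo, hi, n + 1)
    segments = []
    for start, end in slide(L, spec):
        overlaps = np.minimum(end, edges[1:]) - np.maximum(start, edges[:-1])
        overlaps = np.maximum(overlaps, 0.0)
        best = int(np.argmax(overlaps))  # argmax takes the earliest max: tie -> earlier word
        if overlaps[best] < min_overlap_fraction * spec.width:
            label = NOISE_LABEL
        else:
            label = words[best]
        segments.append(WindowSegment(sentence.id, start, end, label))
    return segments


def collapse_repeats(words: Sequence[str]) -> List[str]:
    """Collapse adjacent duplicate runs ("Pick Us Us Up" -> "Pick Us Up")."""
    return [w for w, _ in groupby(words)]


def retrain(model: SiameseModel, corpus_b: Corpus, refs: ReferenceSet,
            spec: WindowSpec, epochs: Optional[int] = None) -> SiameseModel:
    """Continue training on positionally-labeled windows of the sentence
    corpus; returns a new updated model (the input model is untouched).

    The reference set must be byte-identical to the one the model was
    pretrained with - the 55 anchors are retained across stages - and its
    embeddings are implicitly recomputed under the updated encoder.
    """
    if model.refs_fingerprint is not None and refs.fingerprint() != model.refs_fingerprint:
        raise ValidationError("reference set differs from the one used at pretraining")
    segments, labels = [], []
    for rec in corpus_b.train:
        if rec.kind != "sentence":
            continue
        if rec.length < spec.width:
            continue
        for seg in assign_window_labels(rec, spec):
            segments.append(_cut_segment(model, rec, seg.start, seg.end))
            labels.append(seg.assigned_label)
    if not segments:
        raise ValidationError("no retraining windows available")
    updated = model.copy()
    n_epochs = model.config.epochs if epochs is None else epochs
    if n_epochs > 0:
        fit_pairs(updated, np.stack(segments), labels, refs,
                  epochs=n_epochs, stage="retrain", rng_seed=2)
    return updated


def _cut_segment(model: SiameseModel, rec: Recording, start: int, end: int) -> np.ndarray:
    if model.modality == "fusion":
        raw = np.stack([rec.signal("emg")[start:end], rec.signal("eeg")[start:end]])
    else:
        raw = rec.signal(model.modality)[start:end]
    return model.prepare_segment(raw)


def infer_word_sequence(model: SiameseModel, sentence: Recording,
                        refs: ReferenceSet, spec: WindowSpec
                        ) -> Tuple[List[CandidateRanking], List[str]]:
    """Classify every window of a sentence.

    Returns one ranking per window plus the raw word sequence: per-window
    top-1 classes in order, with noise predictions dropped and repeats
    *not* yet collapsed.
    """
    rankings = []
    for wi, (start, end) in enumerate(slide(sentence.length, spec)):
        if model.modality == "fusion":
            raw = np.stack([sentence.signal("emg")[start:end],
                            sentence.signal("eeg")[start:end]])
        else:
            raw = sentence.signal(model.modality)[start:end]
        rankings.append(classify_segment(model, raw, refs, window_index=wi))
    raw_words = [r.top1 for r in rankings if r.top1 != NOISE_LABEL]
    return rankings, raw_words


def decode_dump(rankings: List[CandidateRanking], spec: WindowSpec) -> str:
    """Audit TSV: window_index, start, end, top1, avg_distance, confidence."""
    lines = ["window_index\tstart\tend\ttop1\tavg_distance\tconfidence"]
    for r in rankings:
        cls_name, dist, conf = r.entries[0]
        start = r.window_index * spec.stride
        lines.append(f"{r.window_index}\t{start}\t{start + spec.width}\t"
                     f"{cls_name}\t{dist:.6f}\t{conf:.6f}")
    return "\n".join(lines) + "\n"
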