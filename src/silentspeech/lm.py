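"""Trigram language model over the command vocabulary, and the
candidate-filtering / re-ranking correction of decoded sentences.

The model stores raw 1/2/3-gram counts over boundary-padded sentences
(two start tokens, one end token) and scores sequences with add-k
smoothed conditional probabilities

    P(w | u, v) = (c(u, v, w) + k) / (c(u, v, .) + k * (V + 1)),

where V is the vocabulary size and the +1 admits the end token. The
correction stage enumerates per-window candidate paths from the
classifier's rankings, collapses repeats, filters hypotheses containing
any unseen-and-rare trigram, keeps the top-K by length-normalized LM
score, and picks the hypothesis maximizing a length-normalized mixture of
LM log-probability and classifier log-confidence.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import ValidationError
from .signal_model import NOISE_LABEL
from .windows import CandidateRanking, collapse_repeats

BOS = "<s>"
EOS = "</s>"


@dataclass
class TrigramModel:
    """Smoothed trigram counts with sentence-boundary tokens."""

    counts: Dict[Tuple[str, ...], int]
    vocabulary: List[str]
    k_smooth: float = 0.01

    def __post_init__(self) -> None:
        if self.k_smooth < 0:
            raise ValidationError("k_smooth must be >= 0")
        # context totals: how often each (u, v) history was continued
        self._context: Counter = Counter()
        for ngram, c in self.counts.items():
            if len(ngram) == 3:
                self._context[ngram[:2]] += c

    def count(self, *ngram: str) -> int:
        return self.counts.get(tuple(ngram), 0)

    def cond_prob(self, w: str, u: str, v: str) -> float:
        """Smoothed P(w | u, v); w may be the end token."""
        k = self.k_smooth
        num = self.count(u, v, w) + k
        den = self._context.get((u, v), 0) + k * (len(self.vocabulary) + 1)
        if den == 0.0:
            return 0.0
        return num / den

    def save(self, path) -> None:
        """Plain-text count table: tokens TAB-joined, then the count."""
        with open(path, "w") as fh:
            fh.write(f"#vocabulary\t{' '.join(self.vocabulary)}\n")
            fh.write(f"#k_smooth\t{self.k_smooth!r}\n")
            for ngram in sorted(self.counts):
                fh.write(f"{' '.join(ngram)}\t{self.counts[ngram]}\n")

    @classmethod
    def load(cls, path) -> "TrigramModel":
        vocab: List[str] = []
        k = 0.01
        counts: Dict[Tuple[str, ...], int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                key, val = line.split("\t")
                if key == "#vocabulary":
                    vocab = val.split()
                elif key == "#k_smooth":
                    k = float(val)
                else:
                    counts[tuple(key.split(" "))] = int(val)
        return cls(counts=counts, vocabulary=vocab, k_smooth=k)


def fit_trigram(training_sentences: Sequence[Sequence[str]],
                k_smooth: float = 0.01,
                vocabulary: Optional[Sequence[str]] = None) -> TrigramModel:
    """Count all 1/2/3-grams over boundary-padded training sentences."""
    sentences = [list(s) for s in training_sentences]
    if not sentences or any(len(s) == 0 for s in sentences):
        raise ValidationError("training sentences must be nonempty")
    if vocabulary is None:
        vocab: List[str] = []
        for s in sentences:
            for w in s:
                if w not in vocab:
                    vocab.append(w)
    else:
        vocab = list(vocabulary)
        for s in sentences:
            for w in s:
                if w not in vocab:
                    raise ValidationError(f"sentence word {w!r} not in vocabulary")
    counts: Counter = Counter()
    for s in sentences:
        padded = [BOS, BOS] + s + [EOS]
        for n in (1, 2, 3):
            for i in range(len(padded) - n + 1):
                counts[tuple(padded[i : i + n])] += 1
    return TrigramModel(counts=dict(counts), vocabulary=vocab, k_smooth=k_smooth)


def ngram_logprob(model: TrigramModel, words: Sequence[str]) -> float:
    """Total log probability of a word sequence under the trigram model,
    including the end-of-sentence transition. Returns -inf when an
    unsmoothed (k=0) probability is zero."""
    words = list(words)
    vocab = set(model.vocabulary)
    for w in words:
        if w not in vocab:
            raise ValidationError(f"word {w!r} not in LM vocabulary")
    if not words:
        raise ValidationError("cannot score an empty sequence")
    padded = [BOS, BOS] + words + [EOS]
    total = 0.0
    for i in range(2, len(padded)):
        p = model.cond_prob(padded[i], padded[i - 2], padded[i - 1])
        if p <= 0.0:
            return -math.inf
        total += math.log(p)
    return total


@dataclass
class SentenceHypothesis:
    """One candidate transcription with its three scores."""

    words: List[str]
    lm_logprob: float
    snn_logconf: float
    combined: Optional[float] = None


def combined_confidence(hyp: SentenceHypothesis, lam: float = 0.5) -> float:
    """Length-normalized mixture of LM and classifier evidence:
    [lam * lm_logprob + (1 - lam) * snn_logconf] / n_words."""
    if not (0.0 <= lam <= 1.0):
        raise ValidationError("lambda must be in [0, 1]")
    n = len(hyp.words)
    if n == 0:
        raise ValidationError("hypothesis has no words")
    hyp.combined = (lam * hyp.lm_logprob + (1.0 - lam) * hyp.snn_logconf) / n
    return hyp.combined


def _has_rare_trigram(model: TrigramModel, words: Sequence[str],
                      prune_threshold: float) -> bool:
    padded = [BOS, BOS] + list(words) + [EOS]
    for i in range(2, len(padded)):
        u, v, w = padded[i - 2], padded[i - 1], padded[i]
        if model.count(u, v, w) == 0 and model.cond_prob(w, u, v) < prune_threshold:
            return True
    return False


def enumerate_candidates(rankings: Sequence[CandidateRanking], top_m: int,
                         K: int, model: TrigramModel,
                         prune_threshold: float = 0.02,
                         beam_width: int = 500) -> List[SentenceHypothesis]:
    """Beam-enumerate sentence hypotheses from per-window rankings.

    Each window contributes its ``top_m`` non-noise candidates; a path's
    classifier score is the sum of the log confidences of its chosen
    candidates. Paths are collapsed (adjacent repeats merged) and
    deduplicated keeping the best classifier score; hypotheses containing
    a trigram that was never observed *and* is rare after smoothing are
    filtered out; survivors are ranked by per-word-normalized LM
    log-probability and truncated to the top K.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    if top_m < 1:
        raise ValidationError("top_m must be >= 1")
    if not rankings:
        raise ValidationError("no rankings to enumerate")
    # beam over windows
    paths: List[Tuple[Tuple[str, ...], float]] = [((), 0.0)]
    for ranking in rankings:
        options = [(c, conf) for c, _, conf in ranking.entries if c != NOISE_LABEL][:top_m]
        new_paths = []
        for words, score in paths:
            for c, conf in options:
                new_paths.append((words + (c,), score + math.log(max(conf, 1e-300))))
        new_paths.sort(key=lambda p: -p[1])
        paths = new_paths[:beam_width]

    best: Dict[Tuple[str, ...], float] = {}
    for words, score in paths:
        seq = tuple(collapse_repeats(words))
        if seq and (seq not in best or score > best[seq]):
            best[seq] = score

    survivors = []
    for seq, snn_logconf in best.items():
        if _has_rare_trigram(model, seq, prune_threshold):
            continue
        survivors.append(SentenceHypothesis(
            words=list(seq),
            lm_logprob=ngram_logprob(model, seq),
            snn_logconf=snn_logconf,
        ))
    survivors.sort(key=lambda h: -h.lm_logprob / max(len(h.words), 1))
    return survivors[:K]


@dataclass
class CorrectionResult:
    """Final corrected transcription plus the surviving hypotheses."""

    words: List[str]
    fallback: bool
    hypotheses: List[SentenceHypothesis]


def correct_sentence(rankings: Sequence[CandidateRanking], model: TrigramModel,
                     K: int = 5, top_m: int = 3, lam: float = 0.5,
                     prune_threshold: float = 0.02) -> CorrectionResult:
    """Pick the final transcription by combined confidence over the top-K
    LM-plausible hypotheses.

    Ties break by LM log-probability, then lexicographically. If every
    candidate path is filtered out, falls back to the uncorrected
    collapsed top-1 sequence and flags it.
    """
    hyps = enumerate_candidates(rankings, top_m=top_m, K=K, model=model,
                                prune_threshold=prune_threshold)
    if not hyps:
        raw = [r.top1 for r in rankings if r.top1 != NOISE_LABEL]
        return CorrectionResult(words=collapse_repeats(raw), fallback=True,
                                hypotheses=[])
    for h in hyps:
        combined_confidence(h, lam=lam)
    # deterministic tie-break: combined, then lm_logprob, then lexicographic
    ordered = sorted(hyps, key=lambda h: (-h.combined, -h.lm_logprob, h.words))
    chosen = ordered[0]
    return CorrectionResult(words=list(chosen.words), fallback=False, hypotheses=hyps)
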