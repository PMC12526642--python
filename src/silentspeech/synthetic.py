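"""Synthetic EMG/EEG corpus generator.

Every downstream stage (augmentation, Siamese training, window decoding,
LM correction) is exercised on data from this module, which emulates the
shape of the two study corpora:

* an isolated-word corpus (``n_word_reps`` repetitions of each vocabulary
  word, plus the same number of pure-noise recordings for the noise class),
* a continuous-sentence corpus (``n_sentence_reps`` repetitions of each
  command phrase).

Each word class gets a fixed band-limited template per modality (sum of
random-phase sinusoids: 20-450 Hz content for the EMG-like channel, 1-40 Hz
for the EEG-like channel). Word instances vary around their template by
amplitude jitter, time warping and additive Gaussian noise, reproducing the
within-class variability of repeated utterances. Sentences are built by
concatenating word instances with a linear crossfade at each boundary plus
leading/trailing noise padding, so a sentence is *not* the plain
concatenation of its words - the coarticulation-style boundary distortion
that makes continuous decoding hard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .signal_model import (
    DEFAULT_SENTENCES,
    DEFAULT_VOCABULARY,
    NOISE_LABEL,
    Corpus,
    Recording,
)

#: Frequency band (Hz) of the template content per modality.
BANDS = {"emg": (20.0, 450.0), "eeg": (1.0, 40.0)}

_N_COMPONENTS = 12  # sinusoids per template


@dataclass
class SynthConfig:
    """Generation parameters for the synthetic corpora.

    Defaults mirror the study conditions: 150 repetitions per word,
    100 per sentence, 4096 Hz sampling. ``word_duration`` of 800 samples
    (~0.2 s) keeps a word longer than the 700-sample analysis window.
    Noise / jitter / warp levels are chosen so that isolated words are
    reliably separable while windows over sentences are genuinely harder.
    """

    n_word_reps: int = 150
    n_sentence_reps: int = 100
    word_duration: int = 800
    noise_sd: float = 0.3          # additive Gaussian, relative to unit-RMS templates
    amp_jitter: float = 0.15       # uniform amplitude scale in 1 +/- amp_jitter
    time_warp: float = 0.08        # uniform duration scale in 1 +/- time_warp
    crossfade: int = 120           # samples of linear blend at word boundaries
    sentence_tempo: float = 0.85   # duration scale of words in connected speech
    pad_noise: int = 200           # leading/trailing noise samples on sentences
    seed: int = 0
    sampling_rate: float = 4096.0
    noise_sd_emg: float | None = None   # per-modality override (None -> noise_sd)
    noise_sd_eeg: float | None = None

    def __post_init__(self) -> None:
        if self.n_word_reps <= 0 or self.n_sentence_reps <= 0 or self.word_duration <= 0:
            raise ValidationError("all counts must be > 0")
        if not (0 <= self.crossfade < self.word_duration):
            raise ValidationError("crossfade must be in [0, word_duration)")
        if not (0.0 <= self.time_warp <= 0.3):
            raise ValidationError("time_warp must be in [0, 0.3]")
        if not (0.0 < self.sentence_tempo <= 1.0):
            raise ValidationError("sentence_tempo must be in (0, 1]")
        if self.crossfade >= self.word_duration * self.sentence_tempo * (1 - self.time_warp):
            raise ValidationError("crossfade must be shorter than the shortest in-sentence word")
        if self.noise_sd < 0 or self.amp_jitter < 0 or self.pad_noise < 0:
            raise ValidationError("noise_sd, amp_jitter and pad_noise must be >= 0")

    def modality_noise_sd(self, modality: str) -> float:
        override = {"emg": self.noise_sd_emg, "eeg": self.noise_sd_eeg}[modality]
        return self.noise_sd if override is None else override


@dataclass
class WordBank:
    """Fixed per-class template waveforms, one per modality."""

    templates: Dict[str, Dict[str, np.ndarray]]  # word -> modality -> waveform
    word_duration: int
    seed: int

    def __contains__(self, word: str) -> bool:
        return word in self.templates or word == NOISE_LABEL

    @property
    def words(self) -> List[str]:
        return list(self.templates)


def _template(rng: np.random.Generator, duration: int, sampling_rate: float,
              band: Tuple[float, float]) -> np.ndarray:
    t = np.arange(duration) / sampling_rate
    freqs = rng.uniform(band[0], band[1], size=_N_COMPONENTS)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=_N_COMPONENTS)
    amps = rng.uniform(0.5, 1.5, size=_N_COMPONENTS)
    wave = np.sum(amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]), axis=0)
    rms = np.sqrt(np.mean(wave ** 2))
    return wave / rms if rms > 0 else wave


def make_word_bank(vocabulary: Sequence[str], config: SynthConfig) -> WordBank:
    """Draw one unit-RMS band-limited template per word per modality.

    The noise class gets no template (its instances are pure noise).
    Deterministic given ``config.seed``; duplicate class names are rejected.
    """
    words = [w for w in vocabulary if w != NOISE_LABEL]
    if not words:
        raise ValidationError("vocabulary must contain at least one non-noise word")
    if len(set(vocabulary)) != len(list(vocabulary)):
        raise ValidationError("duplicate class names in vocabulary")
    templates: Dict[str, Dict[str, np.ndarray]] = {}
    for wi, word in enumerate(words):
        templates[word] = {}
        for mi, modality in enumerate(("emg", "eeg")):
            rng = np.random.default_rng([config.seed, 101, wi, mi])
            templates[word][modality] = _template(
                rng, config.word_duration, config.sampling_rate, BANDS[modality]
            )
    return WordBank(templates=templates, word_duration=config.word_duration, seed=config.seed)


def _resample_to(signal: np.ndarray, target: int) -> np.ndarray:
    if target == len(signal):
        return signal.copy()
    old = np.linspace(0.0, 1.0, len(signal))
    new = np.linspace(0.0, 1.0, target)
    return np.interp(new, old, signal)


def _word_instance(bank: WordBank, word: str, config: SynthConfig,
                   rng: np.random.Generator) -> Dict[str, np.ndarray]:
    """One jittered/warped/noisy instance of ``word``, both modalities.

    Warp and amplitude draws are shared across modalities (one utterance,
    one duration); noise is independent per channel.
    """
    warp = 1.0 + rng.uniform(-config.time_warp, config.time_warp)
    amp = 1.0 + rng.uniform(-config.amp_jitter, config.amp_jitter)
    duration = max(2, int(round(config.word_duration * warp)))
    out: Dict[str, np.ndarray] = {}
    for modality in ("emg", "eeg"):
        sd = config.modality_noise_sd(modality)
        if word == NOISE_LABEL:
            sig = rng.normal(0.0, sd, size=config.word_duration) if sd > 0 else np.zeros(config.word_duration)
        else:
            base = _resample_to(bank.templates[word][modality], duration)
            sig = amp * base
            if sd > 0:
                sig = sig + rng.normal(0.0, sd, size=duration)
        out[modality] = sig
    return out


def synth_word_recording(bank: WordBank, word: str, config: SynthConfig,
                         rep_seed: int) -> Recording:
    """Generate one isolated-word (or pure-noise) recording."""
    if word != NOISE_LABEL and word not in bank.templates:
        raise KeyError(f"word {word!r} not in bank")
    rng = np.random.default_rng([config.seed, 7, rep_seed])
    inst = _word_instance(bank, word, config, rng)
    return Recording(
        id=f"w_{word}_{rep_seed}",
        kind="noise" if word == NOISE_LABEL else "word",
        label=word,
        emg=inst["emg"],
        eeg=inst["eeg"],
        sampling_rate=config.sampling_rate,
    )


def synth_sentence_recording(bank: WordBank, words: Sequence[str], config: SynthConfig,
                             rep_seed: int) -> Recording:
    """Generate one continuous-sentence recording with crossfaded boundaries.

    With zero crossfade/pad/noise/jitter/warp this degenerates to the exact
    concatenation of the word templates; otherwise boundary regions blend
    adjacent words, so no segment of the sentence matches a clean template.
    """
    words = list(words)
    if not words:
        raise ValidationError("sentence must contain at least one word")
    for w in words:
        if w not in bank.templates:
            raise ValidationError(f"sentence word {w!r} not in bank")
    rng = np.random.default_rng([config.seed, 13, rep_seed])
    instances = []
    for w in words:
        inst = _word_instance(bank, w, config, rng)
        if config.sentence_tempo != 1.0:
            # connected speech is faster than isolated citation forms: each
            # word is time-compressed, shifting its spectral content - the
            # systematic isolated-vs-continuous mismatch of coarticulation
            target = max(2, int(round(len(inst["emg"]) * config.sentence_tempo)))
            inst = {m: _resample_to(sig, target) for m, sig in inst.items()}
        instances.append(inst)
    cf = config.crossfade
    out: Dict[str, np.ndarray] = {}
    for modality in ("emg", "eeg"):
        acc = instances[0][modality].copy()
        for inst in instances[1:]:
            nxt = inst[modality]
            if cf > 0:
                ramp = np.linspace(0.0, 1.0, cf)
                blended = (1.0 - ramp) * acc[-cf:] + ramp * nxt[:cf]
                acc = np.concatenate([acc[:-cf], blended, nxt[cf:]])
            else:
                acc = np.concatenate([acc, nxt])
        sd = config.modality_noise_sd(modality)
        if config.pad_noise > 0:
            pad = lambda: rng.normal(0.0, sd, size=config.pad_noise) if sd > 0 else np.zeros(config.pad_noise)
            acc = np.concatenate([pad(), acc, pad()])
        out[modality] = acc
    # channels must stay simultaneous; warp draws are shared so lengths agree
    if len(out["emg"]) != len(out["eeg"]):
        raise AssertionError("modality lengths diverged")
    return Recording(
        id=f"s_{rep_seed}",
        kind="sentence",
        label=" ".join(words),
        emg=out["emg"],
        eeg=out["eeg"],
        sampling_rate=config.sampling_rate,
        meta={"pad_left": config.pad_noise, "pad_right": config.pad_noise},
    )


def _assign_split(ids: List[str], rng: np.random.Generator,
                  train_fraction: float = 0.7) -> Dict[str, str]:
    n_train = int(round(train_fraction * len(ids)))
    order = rng.permutation(len(ids))
    split = {}
    for rank, idx in enumerate(order):
        split[ids[idx]] = "train" if rank < n_train else "test"
    return split


def synth_corpora(vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
                  sentences: Sequence[Sequence[str]] = DEFAULT_SENTENCES,
                  config: SynthConfig | None = None) -> Tuple[Corpus, Corpus]:
    """Generate the word corpus and the sentence corpus.

    Corpus A holds ``n_word_reps`` recordings per vocabulary word plus the
    same number of noise-class recordings; Corpus B holds
    ``n_sentence_reps`` recordings per sentence. A 70/30 train/test split is
    assigned independently within each class / sentence. Deterministic
    given ``config.seed``.
    """
    config = config or SynthConfig()
    vocabulary = list(vocabulary)
    if NOISE_LABEL not in vocabulary:
        vocabulary = vocabulary + [NOISE_LABEL]
    vocab_set = set(vocabulary)
    for sent in sentences:
        for w in sent:
            if w not in vocab_set or w == NOISE_LABEL:
                raise ValidationError(f"sentence word {w!r} not in vocabulary")

    bank = make_word_bank(vocabulary, config)
    split_rng = np.random.default_rng([config.seed, 99])

    recs_a: List[Recording] = []
    split_a: Dict[str, str] = {}
    for word in vocabulary:
        ids = []
        for rep in range(config.n_word_reps):
            rep_seed = hashable_rep_seed(vocabulary.index(word), rep)
            rec = synth_word_recording(bank, word, config, rep_seed)
            rec.id = f"A_{word}_{rep:03d}"
            recs_a.append(rec)
            ids.append(rec.id)
        split_a.update(_assign_split(ids, split_rng))
    corpus_a = Corpus(recordings=recs_a, vocabulary=vocabulary, split=split_a)

    recs_b: List[Recording] = []
    split_b: Dict[str, str] = {}
    for si, sent in enumerate(sentences):
        ids = []
        for rep in range(config.n_sentence_reps):
            rep_seed = hashable_rep_seed(1000 + si, rep)
            rec = synth_sentence_recording(bank, sent, config, rep_seed)
            rec.id = f"B_s{si}_{rep:03d}"
            recs_b.append(rec)
            ids.append(rec.id)
        split_b.update(_assign_split(ids, split_rng))
    corpus_b = Corpus(recordings=recs_b, vocabulary=vocabulary, split=split_b)
    return corpus_a, corpus_b


def hashable_rep_seed(class_index: int, rep: int) -> int:
    """Stable per-repetition seed component (fits comfortably in 32 bits)."""
    return class_index * 100003 + rep
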