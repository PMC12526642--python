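"""Signal augmentation operators and corpus-level augmentation plans.

Four operator families: time shifting with mean-padding, cropping, and
up/down-sampling by linear interpolation. Augmentation serves two roles:
it enlarges the small training sets, and - by shifting and truncating word
content - it exposes the encoder to the partial, misaligned word signals
that sliding windows over continuous sentences produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .signal_model import Corpus, Recording


def shift_pad(signal: np.ndarray, offset: int) -> np.ndarray:
    """Shift ``signal`` by ``offset`` samples, filling vacated positions
    with the pre-shift signal mean.

    Positive offsets move content right (fill at the head), negative move
    left (fill at the tail). Output length equals input length.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    if abs(offset) >= n:
        raise ValidationError(f"|offset| {abs(offset)} must be < signal length {n}")
    if offset == 0:
        return signal.copy()
    mu = float(signal.mean())
    out = np.full(n, mu)
    if offset > 0:
        out[offset:] = signal[: n - offset]
    else:
        out[: n + offset] = signal[-offset:]
    return out


def crop(signal: np.ndarray, start: int, length: int) -> np.ndarray:
    """Return the half-open slice ``[start, start+length)``."""
    signal = np.asarray(signal, dtype=float)
    if length < 1:
        raise ValidationError("crop length must be >= 1")
    if start < 0 or start + length > len(signal):
        raise ValidationError(
            f"crop [{start}, {start + length}) out of range for length {len(signal)}"
        )
    return signal[start : start + length].copy()


def resample_linear(signal: np.ndarray, target_length: int) -> np.ndarray:
    """Resample to ``target_length`` by linear interpolation on the
    normalized index grid; endpoints are preserved exactly."""
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 2:
        raise ValidationError("signal must have length >= 2")
    if target_length < 2:
        raise ValidationError("target_length must be >= 2")
    if target_length == len(signal):
        return signal.copy()
    old = np.linspace(0.0, 1.0, len(signal))
    new = np.linspace(0.0, 1.0, target_length)
    return np.interp(new, old, signal)


_FAMILIES = ("shift", "crop", "upsample", "downsample")


@dataclass
class AugmentPlan:
    """Parameter pools for corpus augmentation.

    Each augmented variant applies one operator drawn from a family; the
    families are cycled so the default four variants cover shift, crop,
    upsample and downsample once each. Expansion is deterministic given
    ``seed``.
    """

    shifts: Sequence[int] = (-80, -40, 40, 80)
    crops: Sequence[Tuple[float, float]] = ((0.0, 0.85), (0.1, 0.85), (0.05, 0.9))
    upsample_factors: Sequence[float] = (1.05, 1.1, 1.15)
    downsample_factors: Sequence[float] = (0.85, 0.9, 0.95)
    per_recording_count: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_recording_count < 0:
            raise ValidationError("per_recording_count must be >= 0")
        for f in list(self.upsample_factors) + list(self.downsample_factors):
            if f <= 0:
                raise ValidationError("resample factors must be > 0")
        for s, l in self.crops:
            if not (0.0 <= s < 1.0) or not (0.0 < l <= 1.0):
                raise ValidationError("crop fractions must have start in [0,1), length in (0,1]")


def _apply_op(sig: np.ndarray, family: str, param, pad: Tuple[int, int]) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Apply one operator; returns (signal, adjusted (pad_left, pad_right))."""
    pl, pr = pad
    n = len(sig)
    if family == "shift":
        off = int(param)
        out = shift_pad(sig, off)
        return out, (max(0, pl + off), max(0, pr - off))
    if family == "crop":
        s_frac, l_frac = param
        start = int(round(s_frac * n))
        length = max(1, int(round(l_frac * n)))
        length = min(length, n - start)
        out = crop(sig, start, length)
        new_pl = max(0, pl - start)
        new_pr = max(0, pr - (n - (start + length)))
        return out, (min(new_pl, len(out)), min(new_pr, len(out)))
    # up/downsample
    factor = float(param)
    target = max(2, int(round(n * factor)))
    out = resample_linear(sig, target)
    scale = target / n
    return out, (int(round(pl * scale)), int(round(pr * scale)))


def _pick_param(plan: AugmentPlan, family: str, rng: np.random.Generator):
    pool = {
        "shift": list(plan.shifts),
        "crop": list(plan.crops),
        "upsample": list(plan.upsample_factors),
        "downsample": list(plan.downsample_factors),
    }[family]
    return pool[int(rng.integers(len(pool)))]


def augment_corpus(corpus: Corpus, plan: AugmentPlan) -> Corpus:
    """Extend ``corpus`` with augmented variants of its *train* recordings.

    Each train recording gains ``per_recording_count`` variants tagged with
    provenance (``parent_id``); both modalities of a paired recording get
    the same operator and parameters so the channels stay aligned. Test
    recordings are never touched.
    """
    new_recs: List[Recording] = list(corpus.recordings)
    new_split = dict(corpus.split)
    for ri, rec in enumerate(corpus.recordings):
        if corpus.split.get(rec.id) != "train":
            continue
        for k in range(plan.per_recording_count):
            family = _FAMILIES[k % len(_FAMILIES)]
            rng = np.random.default_rng([plan.seed, ri, k])
            param = _pick_param(plan, family, rng)
            pad = (rec.pad_left, rec.pad_right)
            out = {}
            for modality in rec.modalities:
                out[modality], new_pad = _apply_op(rec.signal(modality), family, param, pad)
            meta = dict(rec.meta)
            if "pad_left" in meta or "pad_right" in meta:
                meta["pad_left"], meta["pad_right"] = new_pad
            variant = Recording(
                id=f"{rec.id}__aug{k}",
                kind=rec.kind,
                label=rec.label,
                emg=out.get("emg"),
                eeg=out.get("eeg"),
                sampling_rate=rec.sampling_rate,
                parent_id=rec.id,
                meta=meta,
            )
            new_recs.append(variant)
            new_split[variant.id] = "train"
    return Corpus(recordings=new_recs, vocabulary=corpus.vocabulary, split=new_split)
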