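"""Domain types for biosignal recordings and corpora, plus on-disk I/O.

A :class:`Recording` is one labeled trace (EMG, EEG or both, sampled at a
common rate); a :class:`Corpus` is a collection of recordings with a fixed
class vocabulary and a train/test split. Corpora round-trip through a plain
text format: a tab-separated manifest plus one single-column amplitude CSV
per modality per recording, so diffs stay inspectable and the round trip is
value-exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CorpusIOError, ValidationError

NOISE_LABEL = "NOISE"

#: Command vocabulary of the four-phrase task: ten target words plus the
#: noise class used for non-speech segments.
DEFAULT_VOCABULARY: tuple = (
    "Need", "Medical", "Assistance", "Land", "Here",
    "Do", "Not", "Pick", "Us", "Up", NOISE_LABEL,
)

#: The four command phrases, as word sequences over the vocabulary.
DEFAULT_SENTENCES: tuple = (
    ("Need", "Medical", "Assistance"),
    ("Land", "Here"),
    ("Do", "Not", "Land", "Here"),
    ("Pick", "Us", "Up"),
)

MANIFEST_COLUMNS = [
    "id", "kind", "label", "sampling_rate", "emg_file", "eeg_file",
    "split", "parent_id", "pad_left", "pad_right",
]

_KINDS = ("word", "sentence", "noise")


@dataclass
class Recording:
    """One labeled biosignal trace (single modality or paired EMG+EEG).

    Parameters
    ----------
    id : str
        Unique identifier within a corpus.
    kind : {"word", "sentence", "noise"}
    label : str
        Class name for words; space-separated word sequence for sentences.
    emg, eeg : ndarray or None
        Amplitude samples (arbitrary units). At least one must be present;
        when both are, they must have equal length (simultaneous channels).
    sampling_rate : float
        Hz; 4096 matches the acquisition hardware this emulates.
    parent_id : str or None
        Provenance link for augmented variants.
    meta : dict
        Free-form metadata; ``pad_left``/``pad_right`` (samples) mark
        known non-speech padding around a sentence's speech span.
    """

    id: str
    kind: str
    label: str
    emg: Optional[np.ndarray] = None
    eeg: Optional[np.ndarray] = None
    sampling_rate: float = 4096.0
    parent_id: Optional[str] = None
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValidationError(f"recording {self.id!r}: unknown kind {self.kind!r}")
        if self.emg is None and self.eeg is None:
            raise ValidationError(f"recording {self.id!r}: no modality present")
        if self.emg is not None:
            self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg is not None:
            self.eeg = np.asarray(self.eeg, dtype=float)
        if self.emg is not None and self.eeg is not None and len(self.emg) != len(self.eeg):
            raise ValidationError(
                f"recording {self.id!r}: EMG length {len(self.emg)} != EEG length {len(self.eeg)}"
            )
        if self.sampling_rate <= 0:
            raise ValidationError(f"recording {self.id!r}: sampling_rate must be > 0")
        if self.kind != "noise" and not self.label:
            raise ValidationError(f"recording {self.id!r}: empty label")

    @property
    def length(self) -> int:
        sig = self.emg if self.emg is not None else self.eeg
        return int(len(sig))

    @property
    def words(self) -> List[str]:
        """Label as a word list (singleton for word/noise recordings)."""
        return self.label.split() if self.kind == "sentence" else [self.label]

    @property
    def modalities(self) -> List[str]:
        out = []
        if self.emg is not None:
            out.append("emg")
        if self.eeg is not None:
            out.append("eeg")
        return out

    def signal(self, modality: str) -> np.ndarray:
        """Samples for ``modality`` in {"emg", "eeg"}; error if absent."""
        if modality == "emg":
            sig = self.emg
        elif modality == "eeg":
            sig = self.eeg
        else:
            raise ValidationError(f"unknown modality {modality!r}")
        if sig is None:
            raise ValidationError(f"recording {self.id!r}: modality {modality!r} absent")
        return sig

    @property
    def pad_left(self) -> int:
        return int(self.meta.get("pad_left", 0))

    @property
    def pad_right(self) -> int:
        return int(self.meta.get("pad_right", 0))


@dataclass
class Corpus:
    """Recordings plus vocabulary and train/test split assignment."""

    recordings: List[Recording]
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY
    split: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vocabulary = list(self.vocabulary)
        self.validate()

    def validate(self) -> None:
        vocab = set(self.vocabulary)
        seen = set()
        for rec in self.recordings:
            if rec.id in seen:
                raise ValidationError(f"duplicate recording id {rec.id!r}")
            seen.add(rec.id)
            for word in rec.words:
                if word and word not in vocab:
                    raise ValidationError(
                        f"recording {rec.id!r}: label word {word!r} not in vocabulary"
                    )
        for rid, part in self.split.items():
            if part not in ("train", "test"):
                raise ValidationError(f"recording {rid!r}: split must be train|test, got {part!r}")

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(self.recordings)

    def by_id(self, rid: str) -> Recording:
        for rec in self.recordings:
            if rec.id == rid:
                return rec
        raise KeyError(rid)

    def subset(self, part: str) -> List[Recording]:
        """Recordings assigned to split ``part`` ("train" or "test")."""
        return [r for r in self.recordings if self.split.get(r.id) == part]

    @property
    def train(self) -> List[Recording]:
        return self.subset("train")

    @property
    def test(self) -> List[Recording]:
        return self.subset("test")


# ---------------------------------------------------------------------------
# On-disk format


def _read_amplitudes(path: Path) -> np.ndarray:
    try:
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
    except OSError as exc:
        raise CorpusIOError(f"cannot read signal file {path}: {exc}") from exc
    if lines and lines[0].lower() == "amplitude":
        lines = lines[1:]
    return np.array([float(x) for x in lines], dtype=float)


def _write_amplitudes(path: Path, values: np.ndarray) -> None:
    # %.17g preserves float64 exactly; comfortably above the 9 significant
    # digits the format guarantees.
    with open(path, "w") as fh:
        fh.write("amplitude\n")
        for v in np.asarray(values, dtype=float):
            fh.write(f"{v:.17g}\n")


def read_corpus(manifest_path: os.PathLike | str,
                vocabulary: Optional[Sequence[str]] = None) -> Corpus:
    """Load a corpus from a manifest TSV.

    Signal file paths in the manifest are resolved relative to the manifest's
    directory; an empty file field means the modality is absent. If
    ``vocabulary`` is not given it is taken from a ``vocabulary.txt`` sidecar
    (one class per line) when present, else derived from the labels.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CorpusIOError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "kind", "label", "sampling_rate", "emg_file", "eeg_file"):
        if col not in df.columns:
            raise CorpusIOError(f"manifest missing required column {col!r}")

    if vocabulary is None:
        sidecar = base / "vocabulary.txt"
        if sidecar.exists():
            vocabulary = [ln.strip() for ln in sidecar.read_text().splitlines() if ln.strip()]

    recordings: List[Recording] = []
    split: Dict[str, str] = {}
    for row in df.itertuples(index=False):
        emg = _read_amplitudes(base / row.emg_file) if row.emg_file else None
        eeg = _read_amplitudes(base / row.eeg_file) if row.eeg_file else None
        meta: Dict = {}
        pl = getattr(row, "pad_left", "")
        pr = getattr(row, "pad_right", "")
        if pl not in ("", None):
            meta["pad_left"] = int(pl)
        if pr not in ("", None):
            meta["pad_right"] = int(pr)
        rec = Recording(
            id=row.id,
            kind=row.kind,
            label=row.label,
            emg=emg,
            eeg=eeg,
            sampling_rate=float(row.sampling_rate),
            parent_id=(getattr(row, "parent_id", "") or None),
            meta=meta,
        )
        recordings.append(rec)
        part = getattr(row, "split", "")
        if part:
            split[rec.id] = part

    if vocabulary is None:
        vocabulary = sorted({w for rec in recordings for w in rec.words if w})
    return Corpus(recordings=recordings, vocabulary=vocabulary, split=split)


def write_corpus(corpus: Corpus, out_dir: os.PathLike | str) -> Path:
    """Write ``corpus`` to ``out_dir``; returns the manifest path.

    Emits ``manifest.tsv``, ``vocabulary.txt`` and one amplitude CSV per
    modality per recording, named ``<id>_<modality>.csv``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise CorpusIOError(f"cannot create corpus directory {out_dir}: {exc}") from exc

    rows = []
    for rec in corpus.recordings:
        emg_file = eeg_file = ""
        if rec.emg is not None:
            emg_file = f"{rec.id}_emg.csv"
            _write_amplitudes(out_dir / emg_file, rec.emg)
        if rec.eeg is not None:
            eeg_file = f"{rec.id}_eeg.csv"
            _write_amplitudes(out_dir / eeg_file, rec.eeg)
        rows.append({
            "id": rec.id,
            "kind": rec.kind,
            "label": rec.label,
            "sampling_rate": f"{rec.sampling_rate:.17g}",
            "emg_file": emg_file,
            "eeg_file": eeg_file,
            "split": corpus.split.get(rec.id, ""),
            "parent_id": rec.parent_id or "",
            "pad_left": str(rec.meta["pad_left"]) if "pad_left" in rec.meta else "",
            "pad_right": str(rec.meta["pad_right"]) if "pad_right" in rec.meta else "",
        })
    manifest_path = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest_path, sep="\t", index=False)
    (out_dir / "vocabulary.txt").write_text("\n".join(corpus.vocabulary) + "\n")
    return manifest_path
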