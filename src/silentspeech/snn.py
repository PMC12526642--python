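"""Siamese few-shot classifier for fixed-length biosignal segments.

The model is a 1-D convolutional encoder (kernel 7, padding 3) mapping a
700-sample segment to a unit-norm embedding. Training is contrastive over
(input, reference) pairs with cosine distance: matched pairs are pulled
together, mismatched pairs pushed beyond a margin,

    L = y * d^2 + (1 - y) * max(0, m - d)^2,   d = 1 - <a, b>.

Classification compares a segment's embedding with the stored reference
("shot") embeddings - five per class - and ranks classes by their average
cosine distance; a temperature softmax over negative distances provides the
classification probabilities the language-model stage consumes. Because
classes live only in the reference set, new classes can be added without
retraining the encoder.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._nn import Adam, ConvStack, Dense, Param, l2_normalize, l2_normalize_backward
from .errors import ValidationError
from .signal_model import Corpus, Recording
from .util import fit_length, standardize


@dataclass
class EncoderConfig:
    """Architecture and training hyperparameters of the unimodal encoder."""

    input_length: int = 700
    kernel_size: int = 7
    padding: int = 3
    n_conv_blocks: int = 3
    channels: Tuple[int, ...] = (8, 16, 32)
    embedding_dim: int = 64
    margin: float = 1.0
    lr: float = 3e-3
    epochs: int = 8
    batch_size: int = 64
    seed: int = 0
    temperature: float = 0.1   # softmax temperature for confidences
    n_pos_refs: int = 2        # positive references sampled per segment per epoch
    n_neg_refs: int = 3        # negative references sampled per segment per epoch

    def __post_init__(self) -> None:
        if self.kernel_size % 2 != 1:
            raise ValidationError("kernel_size must be odd")
        if self.padding != (self.kernel_size - 1) // 2:
            raise ValidationError("padding must equal (kernel_size - 1) / 2")
        if self.embedding_dim <= 0:
            raise ValidationError("embedding_dim must be > 0")
        if len(self.channels) != self.n_conv_blocks:
            raise ValidationError("channels must list one width per conv block")
        if self.margin <= 0:
            raise ValidationError("margin must be > 0")


# ---------------------------------------------------------------------------
# Distance and loss


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """d = 1 - cos(a, b), in [0, 2]; symmetric; zero vectors are invalid."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValidationError("cosine distance undefined for zero vectors")
    return float(1.0 - a @ b / (na * nb))


def contrastive_loss(d: float, y: int, m: float) -> float:
    """Contrastive loss for one pair: y*d^2 + (1-y)*max(0, m-d)^2."""
    if y not in (0, 1):
        raise ValidationError("pair label y must be 0 or 1")
    if m <= 0:
        raise ValidationError("margin must be > 0")
    if y == 1:
        return float(d) ** 2
    return max(0.0, m - float(d)) ** 2


# ---------------------------------------------------------------------------
# Encoders


class UnimodalEncoder:
    """ConvStack -> global average pool -> linear -> L2 normalization."""

    n_channels = 1

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.stack = ConvStack(1, config.channels, config.kernel_size, rng)
        self.head = Dense(self.stack.out_channels, config.embedding_dim, rng)

    def params(self) -> List[Param]:
        return self.stack.params() + self.head.params()

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, tuple]:
        # x: (B, L) standardized segments
        feat, s_cache = self.stack.forward(x[:, None, :])
        z, d_cache = self.head.forward(feat)
        emb, n_cache = l2_normalize(z)
        return emb, (s_cache, d_cache, n_cache)

    def backward(self, cache: tuple, demb: np.ndarray) -> None:
        s_cache, d_cache, n_cache = cache
        dz = l2_normalize_backward(n_cache, demb)
        dfeat = self.head.backward(d_cache, dz)
        self.stack.backward(s_cache, dfeat)


class SiameseModel:
    """A trained (or trainable) Siamese encoder for one modality.

    The two "twins" of the Siamese pair are literally the same encoder
    object (`left is right`), which is what weight sharing means here.
    """

    def __init__(self, config, modality: str, encoder):
        self.config = config
        self.modality = modality
        self.encoder = encoder
        self.version = 0
        self.train_log: List[Dict] = []
        self.refs_fingerprint: Optional[str] = None

    # -- construction -------------------------------------------------

    @classmethod
    def build(cls, config, modality: str = "emg") -> "SiameseModel":
        if modality in ("emg", "eeg"):
            if not isinstance(config, EncoderConfig):
                raise ValidationError("unimodal model requires an EncoderConfig")
            rng = np.random.default_rng([config.seed, 555])
            return cls(config, modality, UnimodalEncoder(config, rng))
        if modality == "fusion":
            from .fusion import FusedEncoder, FusionConfig

            if not isinstance(config, FusionConfig):
                raise ValidationError("fusion model requires a FusionConfig")
            rng = np.random.default_rng([config.seed, 555])
            return cls(config, modality, FusedEncoder(config, rng))
        raise ValidationError(f"unknown modality {modality!r}")

    # -- twins (shared weights) ---------------------------------------

    @property
    def left(self):
        return self.encoder

    @property
    def right(self):
        return self.encoder

    # -- segments ------------------------------------------------------

    @property
    def input_length(self) -> int:
        return self.config.input_length

    def prepare_recording(self, rec: Recording) -> np.ndarray:
        """Fit a recording to the encoder input: crop/pad to input_length
        and z-score, per modality."""
        if self.modality == "fusion":
            return np.stack([
                standardize(fit_length(rec.signal("emg"), self.input_length)),
                standardize(fit_length(rec.signal("eeg"), self.input_length)),
            ])
        return standardize(fit_length(rec.signal(self.modality), self.input_length))

    def prepare_segment(self, segment: np.ndarray) -> np.ndarray:
        """Validate an already-cut segment and z-score it."""
        segment = np.asarray(segment, dtype=float)
        if self.modality == "fusion":
            if segment.ndim != 2 or segment.shape[0] != 2 or segment.shape[1] != self.input_length:
                raise ValidationError(
                    f"fusion segment must have shape (2, {self.input_length})"
                )
            return np.stack([standardize(segment[0]), standardize(segment[1])])
        if segment.ndim != 1 or segment.shape[0] != self.input_length:
            raise ValidationError(
                f"segment length {segment.shape} != input_length {self.input_length}"
            )
        return standardize(segment)

    # -- inference ------------------------------------------------------

    def encode_batch(self, segments: np.ndarray) -> np.ndarray:
        segments = np.asarray(segments, dtype=float)
        emb, _ = self.encoder.forward(segments)
        return emb

    def encode(self, segment: np.ndarray) -> np.ndarray:
        """Embed one segment (validated, z-scored); unit L2 norm."""
        x = self.prepare_segment(segment)
        return self.encode_batch(x[None])[0]

    # -- persistence -----------------------------------------------------

    def save(self, path, refs: Optional["ReferenceSet"] = None) -> None:
        """Write a checkpoint (npz): weights, config, modality, train log,
        and optionally the reference set's signals."""
        arrays = {f"param_{i:03d}": p.value for i, p in enumerate(self.encoder.params())}
        meta = {
            "modality": self.modality,
            "config_class": type(self.config).__name__,
            "config": _config_dict(self.config),
            "version": self.version,
            "train_log": self.train_log,
            "refs_fingerprint": self.refs_fingerprint,
            "format_version": 1,
        }
        if refs is not None:
            ref_meta = []
            for cls_name in refs.classes:
                for si, rec in enumerate(refs.shots[cls_name]):
                    key = f"ref_{cls_name}_{si}"
                    ref_meta.append({"class": cls_name, "id": rec.id, "kind": rec.kind,
                                     "key": key, "sampling_rate": rec.sampling_rate})
                    if rec.emg is not None:
                        arrays[key + "_emg"] = rec.emg
                    if rec.eeg is not None:
                        arrays[key + "_eeg"] = rec.eeg
            meta["refs"] = {"classes": list(refs.classes),
                            "shots_per_class": refs.shots_per_class,
                            "recordings": ref_meta}
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> Tuple["SiameseModel", Optional["ReferenceSet"]]:
        from .fusion import FusionConfig

        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg_cls = {"EncoderConfig": EncoderConfig, "FusionConfig": FusionConfig}[meta["config_class"]]
        config = _config_from_dict(cfg_cls, meta["config"])
        model = cls.build(config, meta["modality"])
        for i, p in enumerate(model.encoder.params()):
            p.value[...] = data[f"param_{i:03d}"]
        model.version = meta["version"]
        model.train_log = meta["train_log"]
        model.refs_fingerprint = meta.get("refs_fingerprint")
        refs = None
        if "refs" in meta:
            shots: Dict[str, List[Recording]] = {c: [] for c in meta["refs"]["classes"]}
            for rm in meta["refs"]["recordings"]:
                emg = data.get(rm["key"] + "_emg")
                eeg = data.get(rm["key"] + "_eeg")
                shots[rm["class"]].append(Recording(
                    id=rm["id"], kind=rm["kind"], label=rm["class"],
                    emg=emg, eeg=eeg, sampling_rate=rm["sampling_rate"],
                ))
            refs = ReferenceSet(classes=meta["refs"]["classes"], shots=shots,
                                shots_per_class=meta["refs"]["shots_per_class"])
        return model, refs

    def copy(self) -> "SiameseModel":
        clone = SiameseModel.build(self.config, self.modality)
        for pc, ps in zip(clone.encoder.params(), self.encoder.params()):
            pc.value[...] = ps.value
        clone.version = self.version
        clone.train_log = list(self.train_log)
        clone.refs_fingerprint = self.refs_fingerprint
        return clone


def _config_dict(config) -> Dict:
    return asdict(config)


def _config_from_dict(cfg_cls, d: Dict):
    d = dict(d)
    if cfg_cls.__name__ == "FusionConfig" and isinstance(d.get("branch"), dict):
        b = dict(d["branch"])
        b["channels"] = tuple(b["channels"])
        d["branch"] = EncoderConfig(**b)
    if "channels" in d and isinstance(d["channels"], list):
        d["channels"] = tuple(d["channels"])
    if "head_layers" in d and isinstance(d["head_layers"], list):
        d["head_layers"] = tuple(d["head_layers"])
    return cfg_cls(**d)


# ---------------------------------------------------------------------------
# Reference set


@dataclass
class ReferenceSet:
    """The few-shot anchors: ``shots_per_class`` recordings per class."""

    classes: List[str]
    shots: Dict[str, List[Recording]]
    shots_per_class: int = 5
    _emb_cache: Dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cls_name in self.classes:
            got = len(self.shots.get(cls_name, []))
            if got != self.shots_per_class:
                raise ValidationError(
                    f"class {cls_name!r} has {got} reference recordings, "
                    f"expected {self.shots_per_class}"
                )

    @property
    def size(self) -> int:
        return self.shots_per_class * len(self.classes)

    @property
    def all_ids(self) -> List[str]:
        return [r.id for c in self.classes for r in self.shots[c]]

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        for cls_name in self.classes:
            h.update(cls_name.encode())
            for rec in self.shots[cls_name]:
                h.update(rec.id.encode())
                if rec.emg is not None:
                    h.update(np.ascontiguousarray(rec.emg).tobytes())
                if rec.eeg is not None:
                    h.update(np.ascontiguousarray(rec.eeg).tobytes())
        return h.hexdigest()

    def embeddings(self, model) -> Dict[str, np.ndarray]:
        """Per-class (shots_per_class, D) embeddings under ``model``,
        cached until the model trains further."""
        key = (id(model), getattr(model, "version", 0))
        if key not in self._emb_cache:
            per_class = {}
            for cls_name in self.classes:
                segs = np.stack([model.prepare_recording(r) for r in self.shots[cls_name]])
                per_class[cls_name] = model.encode_batch(segs)
            self._emb_cache.clear()
            self._emb_cache[key] = per_class
        return self._emb_cache[key]

    def extended(self, cls_name: str, recordings: Sequence[Recording]) -> "ReferenceSet":
        """New ReferenceSet with an extra class (few-shot class addition,
        no retraining)."""
        if cls_name in self.classes:
            raise ValidationError(f"class {cls_name!r} already present")
        shots = {c: list(v) for c, v in self.shots.items()}
        shots[cls_name] = list(recordings)
        return ReferenceSet(classes=self.classes + [cls_name], shots=shots,
                            shots_per_class=self.shots_per_class)


def build_reference_set(corpus: Corpus, shots_per_class: int = 5,
                        input_length: int = 700) -> ReferenceSet:
    """Pick the most representative train recordings of each class.

    Representativeness is medoid-like and seed-free: among a class's
    non-augmented train recordings, the ``shots_per_class`` whose mean
    raw-signal cosine similarity to the rest of the class is highest.
    Augmented variants are never eligible. Chosen recordings should be
    excluded from the training pair pool by the caller (pretrain does so).
    """
    shots: Dict[str, List[Recording]] = {}
    for cls_name in corpus.vocabulary:
        pool = [r for r in corpus.train
                if r.parent_id is None and r.label == cls_name]
        if len(pool) < shots_per_class:
            raise ValidationError(
                f"class {cls_name!r}: only {len(pool)} experimental train "
                f"recordings, need {shots_per_class}"
            )
        vecs = []
        for rec in pool:
            parts = [fit_length(rec.signal(m), input_length) for m in rec.modalities]
            vecs.append(np.concatenate(parts))
        V = np.stack(vecs)
        norms = np.linalg.norm(V, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        U = V / norms
        sim = U @ U.T
        n = len(pool)
        score = (sim.sum(axis=1) - 1.0) / max(n - 1, 1)  # mean similarity to others
        order = sorted(range(n), key=lambda i: (-score[i], pool[i].id))
        shots[cls_name] = [pool[i] for i in order[:shots_per_class]]
    return ReferenceSet(classes=list(corpus.vocabulary), shots=shots,
                        shots_per_class=shots_per_class)


# ---------------------------------------------------------------------------
# Training


def fit_pairs(model: SiameseModel, segments: np.ndarray, labels: Sequence[str],
              refs: ReferenceSet, epochs: int, stage: str = "train",
              rng_seed: int = 0) -> SiameseModel:
    """Contrastive training on (segment, reference) pairs, in place.

    For each training segment, each epoch samples ``n_pos_refs`` same-class
    and ``n_neg_refs`` other-class references as anchors. Per-epoch mean
    loss and train classification accuracy are appended to
    ``model.train_log``.
    """
    cfg = model.config
    if len(segments) == 0:
        raise ValidationError("empty training set")
    labels = list(labels)
    cls_index = {c: i for i, c in enumerate(refs.classes)}
    for lab in labels:
        if lab not in cls_index:
            raise ValidationError(f"training label {lab!r} has no reference class")

    ref_segs, ref_cls = [], []
    for cls_name in refs.classes:
        for rec in refs.shots[cls_name]:
            ref_segs.append(model.prepare_recording(rec))
            ref_cls.append(cls_name)
    R = np.stack(ref_segs)
    ref_cls = np.array(ref_cls)
    by_class = {c: np.flatnonzero(ref_cls == c) for c in refs.classes}

    opt = Adam(model.encoder.params(), lr=cfg.lr)
    m = cfg.margin

    for epoch in range(epochs):
        rng = np.random.default_rng([cfg.seed, rng_seed, 17, epoch])
        pair_i, pair_j, pair_y = [], [], []
        for i in rng.permutation(len(segments)):
            lab = labels[i]
            pos = by_class[lab]
            n_pos = min(cfg.n_pos_refs, len(pos))
            for j in rng.choice(pos, size=n_pos, replace=False):
                pair_i.append(i); pair_j.append(j); pair_y.append(1)
            neg = np.flatnonzero(ref_cls != lab)
            for j in rng.choice(neg, size=min(cfg.n_neg_refs, len(neg)), replace=False):
                pair_i.append(i); pair_j.append(j); pair_y.append(0)
        order = rng.permutation(len(pair_i))
        pair_i = np.asarray(pair_i)[order]
        pair_j = np.asarray(pair_j)[order]
        pair_y = np.asarray(pair_y, dtype=float)[order]

        total_loss = 0.0
        bs = cfg.batch_size
        for b0 in range(0, len(pair_i), bs):
            ii = pair_i[b0 : b0 + bs]
            jj = pair_j[b0 : b0 + bs]
            yy = pair_y[b0 : b0 + bs]
            opt.zero_grad()
            ea, cache_a = model.encoder.forward(segments[ii])
            eb, cache_b = model.encoder.forward(R[jj])
            d = 1.0 - np.sum(ea * eb, axis=1)
            shortfall = np.maximum(0.0, m - d)
            losses = yy * d ** 2 + (1.0 - yy) * shortfall ** 2
            total_loss += float(losses.sum())
            # dL/dd per pair, averaged over the batch
            dd = (2.0 * yy * d - 2.0 * (1.0 - yy) * shortfall) / len(ii)
            model.encoder.backward(cache_a, -dd[:, None] * eb)
            model.encoder.backward(cache_b, -dd[:, None] * ea)
            opt.step()
        model.version += 1

        mean_loss = total_loss / max(len(pair_i), 1)
        acc = _train_accuracy(model, segments, labels, refs)
        model.train_log.append({"stage": stage, "epoch": epoch,
                                "loss": mean_loss, "train_accuracy": acc})
    return model


def _train_accuracy(model: SiameseModel, segments: np.ndarray,
                    labels: Sequence[str], refs: ReferenceSet) -> float:
    ref_emb = refs.embeddings(model)
    emb = _encode_chunked(model, segments)
    dists = np.stack([(1.0 - emb @ ref_emb[c].T).mean(axis=1)
                      for c in refs.classes], axis=1)
    pred = np.argmin(dists, axis=1)
    truth = np.array([refs.classes.index(l) for l in labels])
    return float(np.mean(pred == truth))


def _encode_chunked(model: SiameseModel, segments: np.ndarray,
                    chunk: int = 256) -> np.ndarray:
    outs = [model.encode_batch(segments[i : i + chunk])
            for i in range(0, len(segments), chunk)]
    return np.concatenate(outs, axis=0)


def pretrain(corpus_a: Corpus, refs: ReferenceSet, config,
             modality: str = "emg") -> SiameseModel:
    """Pretrain a Siamese model on the isolated-word corpus.

    Training pairs are (train recording, reference recording) with match
    label 1 iff same class; the reference recordings themselves (and their
    augmented descendants) are excluded from the pair pool.
    """
    ref_ids = set(refs.all_ids)
    train = [r for r in corpus_a.train
             if r.id not in ref_ids and r.parent_id not in ref_ids]
    if not train:
        raise ValidationError("empty train split after excluding references")
    model = SiameseModel.build(config, modality)
    model.refs_fingerprint = refs.fingerprint()
    segments = np.stack([model.prepare_recording(r) for r in train])
    labels = [r.label for r in train]
    fit_pairs(model, segments, labels, refs, epochs=config.epochs,
              stage="pretrain", rng_seed=1)
    return model


# ---------------------------------------------------------------------------
# Classification


@dataclass
class CandidateRanking:
    """Per-segment ranked candidates: (class, avg cosine distance,
    confidence), ascending in distance; confidences sum to 1."""

    entries: List[Tuple[str, float, float]]
    window_index: int = 0

    @property
    def top1(self) -> str:
        return self.entries[0][0]

    def confidence_of(self, cls_name: str) -> float:
        for c, _, p in self.entries:
            if c == cls_name:
                return p
        raise KeyError(cls_name)

    def top(self, k: int) -> List[Tuple[str, float, float]]:
        return self.entries[:k]


def classify_segment(model, segment: np.ndarray, refs: ReferenceSet,
                     window_index: int = 0) -> CandidateRanking:
    """Rank classes for one segment by average cosine distance to each
    class's reference embeddings.

    Confidence is a softmax over -avg_distance / temperature; exact
    distance ties are broken by vocabulary (reference-class) order.
    """
    ref_emb = refs.embeddings(model)
    emb = model.encode(segment)
    dists = np.array([float(np.mean(1.0 - ref_emb[c] @ emb)) for c in refs.classes])
    tau = getattr(model.config, "temperature", 0.1) if hasattr(model, "config") else 0.1
    logits = -dists / tau
    logits -= logits.max()
    conf = np.exp(logits)
    conf /= conf.sum()
    order = sorted(range(len(refs.classes)), key=lambda i: (dists[i], i))
    entries = [(refs.classes[i], float(dists[i]), float(conf[i])) for i in order]
    return CandidateRanking(entries=entries, window_index=window_index)
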