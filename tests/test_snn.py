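import numpy as np
import pytest

from silentspeech.errors import ValidationError
from silentspeech.signal_model import NOISE_LABEL, Corpus, Recording
from silentspeech.snn import (
    CandidateRanking,
    EncoderConfig,
    ReferenceSet,
    SiameseModel,
    build_reference_set,
    classify_segment,
    contrastive_loss,
    cosine_distance,
    pretrain,
)
from silentspeech.synthetic import SynthConfig, synth_corpora

from conftest import TINY_VOCAB


class TestCosineDistance:
    def test_identity_orthogonal_antipodal(self):
        a = np.array([1.0, 0.0])
        b = np.array([0.0, 1.0])
        assert cosine_distance(a, a) == pytest.approx(0.0)
        assert cosine_distance(a, b) == pytest.approx(1.0)
        assert cosine_distance(a, -a) == pytest.approx(2.0)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        assert cosine_distance(a, b) == pytest.approx(cosine_distance(b, a))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            cosine_distance(np.zeros(4), np.ones(4))


class TestContrastiveLoss:
    @pytest.mark.parametrize(
        "d,y,m,expected",
        [
            (0.0, 1, 1.0, 0.0),        # matched identical pair
            (1.2, 0, 1.0, 0.0),        # mismatch beyond margin
            (0.0, 0, 0.5, 0.25),       # mismatch at zero distance
            (0.3, 1, 1.0, 0.09),
        ],
    )
    def test_values(self, d, y, m, expected):
        assert contrastive_loss(d, y, m) == pytest.approx(expected)

    def test_nonnegative_everywhere(self):
        for d in np.linspace(0, 2, 21):
            for y in (0, 1):
                assert contrastive_loss(float(d), y, 1.0) >= 0.0

    def test_invalid_label_rejected(self):
        with pytest.raises(ValidationError):
            contrastive_loss(0.5, 2, 1.0)


class TestEncoder:
    def test_embedding_is_unit_norm_and_deterministic(self, tiny_model, rng):
        seg = rng.normal(size=tiny_model.input_length)
        e1 = tiny_model.encode(seg)
        e2 = tiny_model.encode(seg)
        np.testing.assert_array_equal(e1, e2)
        assert np.linalg.norm(e1) == pytest.approx(1.0, abs=1e-6)
        assert e1.shape == (tiny_model.config.embedding_dim,)

    def test_twins_share_weights(self, tiny_model, rng):
        """The two Siamese branches are literally the same function."""
        assert tiny_model.left is tiny_model.right
        seg = rng.normal(size=tiny_model.input_length)
        x = tiny_model.prepare_segment(seg)[None]
        el, _ = tiny_model.left.forward(x)
        er, _ = tiny_model.right.forward(x)
        np.testing.assert_array_equal(el, er)

    def test_wrong_length_rejected(self, tiny_model):
        with pytest.raises(ValidationError):
            tiny_model.encode(np.zeros(tiny_model.input_length + 1))

    def test_config_invariants(self):
        with pytest.raises(ValidationError):
            EncoderConfig(kernel_size=8)
        with pytest.raises(ValidationError):
            EncoderConfig(kernel_size=7, padding=2)


class TestReferenceSet:
    def test_five_per_class_eleven_classes(self):
        cfg = SynthConfig(n_word_reps=8, n_sentence_reps=2, seed=1)
        vocab = [f"W{i}" for i in range(10)] + [NOISE_LABEL]
        corpus_a, _ = synth_corpora(vocab, [("W0", "W1")], cfg)
        refs = build_reference_set(corpus_a, shots_per_class=5)
        assert refs.size == 55
        assert all(len(refs.shots[c]) == 5 for c in refs.classes)

    def test_references_come_from_experimental_train_split(self, tiny_corpora, tiny_refs):
        corpus_a, _ = tiny_corpora
        train_ids = {r.id for r in corpus_a.train}
        for rid in tiny_refs.all_ids:
            assert rid in train_ids
            assert corpus_a.by_id(rid).parent_id is None

    def test_insufficient_class_named_in_error(self, tiny_corpora):
        corpus_a, _ = tiny_corpora
        # drop all but 2 train recordings of one class
        keep = []
        dropped = 0
        for rec in corpus_a:
            if rec.label == "Here" and corpus_a.split[rec.id] == "train" and dropped < 4:
                dropped += 1
                continue
            keep.append(rec)
        small = Corpus(recordings=keep, vocabulary=corpus_a.vocabulary,
                       split={r.id: corpus_a.split[r.id] for r in keep})
        with pytest.raises(ValidationError, match="Here"):
            build_reference_set(small, shots_per_class=5)

    def test_exactly_five_available_forces_selection(self):
        rng = np.random.default_rng(0)
        recs = [Recording(id=f"r{i}", kind="word", label="Us", emg=rng.normal(size=100))
                for i in range(5)]
        corpus = Corpus(recordings=recs, vocabulary=("Us", NOISE_LABEL),
                        split={r.id: "train" for r in recs})
        with pytest.raises(ValidationError):
            build_reference_set(corpus, shots_per_class=5)  # NOISE has none
        corpus2 = Corpus(
            recordings=recs + [Recording(id=f"n{i}", kind="noise", label=NOISE_LABEL,
                                         emg=rng.normal(size=100)) for i in range(5)],
            vocabulary=("Us", NOISE_LABEL),
            split={**{r.id: "train" for r in recs}, **{f"n{i}": "train" for i in range(5)}},
        )
        refs = build_reference_set(corpus2, shots_per_class=5)
        assert sorted(r.id for r in refs.shots["Us"]) == [f"r{i}" for i in range(5)]


class _StubModel:
    """Identity-like 2-D encoder: embeds a segment by its (normalized)
    first two samples; used to cross-check classification against brute
    force without any trained weights."""

    class _Cfg:
        input_length = 8
        embedding_dim = 2
        temperature = 0.1

    config = _Cfg()
    modality = "emg"
    version = 0
    input_length = 8

    def prepare_recording(self, rec):
        from silentspeech.util import fit_length
        return fit_length(rec.signal("emg"), self.input_length)

    def prepare_segment(self, seg):
        return np.asarray(seg, dtype=float)

    def encode_batch(self, segs):
        v = np.asarray(segs, dtype=float)[:, :2]
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def encode(self, seg):
        return self.encode_batch(np.asarray(seg)[None])[0]


def _stub_refs(vectors):
    """vectors: class -> list of 8-sample signals."""
    shots = {
        c: [Recording(id=f"{c}{i}", kind="word", label=c, emg=np.array(sig, dtype=float))
            for i, sig in enumerate(sigs)]
        for c, sigs in vectors.items()
    }
    return ReferenceSet(classes=list(vectors), shots=shots,
                        shots_per_class=len(next(iter(vectors.values()))))


class TestClassifySegment:
    def test_agrees_with_brute_force(self, rng):
        """Parameter-free oracle: ranking equals an explicit nearest-mean-
        distance computation for every probe."""
        model = _StubModel()
        vectors = {
            "A": [np.concatenate([[1, 0.1 * i], np.zeros(6)]) for i in range(2)],
            "B": [np.concatenate([[0.1 * i, 1], np.zeros(6)]) for i in range(2)],
            "C": [np.concatenate([[-1, 0.05 * i], np.zeros(6)]) for i in range(2)],
        }
        refs = _stub_refs(vectors)
        for _ in range(20):
            seg = np.concatenate([rng.normal(size=2), np.zeros(6)])
            ranking = classify_segment(model, seg, refs)
            emb = model.encode(seg)
            brute = {
                c: np.mean([1.0 - model.encode(s.emg) @ emb for s in refs.shots[c]])
                for c in refs.classes
            }
            expect = sorted(refs.classes, key=lambda c: (brute[c], refs.classes.index(c)))
            assert [c for c, _, _ in ranking.entries] == expect
            for c, d, _ in ranking.entries:
                assert d == pytest.approx(brute[c], abs=1e-9)

    def test_tie_broken_by_vocabulary_order(self):
        model = _StubModel()
        # B and C are mirror images around the probe -> identical distances
        vectors = {
            "B": [np.concatenate([[1, 1], np.zeros(6)])],
            "C": [np.concatenate([[1, -1], np.zeros(6)])],
        }
        refs = _stub_refs(vectors)
        ranking = classify_segment(model, np.concatenate([[1, 0], np.zeros(6)]), refs)
        assert ranking.entries[0][1] == pytest.approx(ranking.entries[1][1])
        assert ranking.top1 == "B"

    def test_confidences_sum_to_one(self, tiny_model, tiny_refs, rng):
        seg = rng.normal(size=tiny_model.input_length)
        ranking = classify_segment(tiny_model, seg, tiny_refs)
        total = sum(p for _, _, p in ranking.entries)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert NOISE_LABEL in [c for c, _, _ in ranking.entries]

    def test_self_reference_is_top1(self, tiny_model, tiny_refs):
        rec = tiny_refs.shots["Land"][0]
        ranking = classify_segment(
            tiny_model, tiny_model.prepare_recording(rec), tiny_refs
        )
        assert ranking.top1 == "Land"


class TestPretrain:
    def test_two_separable_classes_reach_perfect_train_accuracy(self):
        cfg = SynthConfig(n_word_reps=10, n_sentence_reps=2, noise_sd=0.1, seed=2)
        corpus_a, _ = synth_corpora(("Need", "Land", NOISE_LABEL), [("Need", "Land")], cfg)
        enc = EncoderConfig(n_conv_blocks=2, channels=(4, 8), embedding_dim=16,
                            epochs=5, seed=2)
        refs = build_reference_set(corpus_a, shots_per_class=5)
        model = pretrain(corpus_a, refs, enc, modality="emg")
        assert model.train_log[-1]["train_accuracy"] == pytest.approx(1.0)

    def test_training_reduces_loss(self, tiny_model):
        log = [e for e in tiny_model.train_log if e["stage"] == "pretrain"]
        assert log[-1]["loss"] <= log[0]["loss"]

    def test_empty_train_split_rejected(self, tiny_refs, tiny_encoder_config, tiny_corpora):
        corpus_a, _ = tiny_corpora
        stripped = Corpus(recordings=list(corpus_a.recordings),
                          vocabulary=corpus_a.vocabulary,
                          split={r.id: "test" for r in corpus_a})
        with pytest.raises(ValidationError):
            pretrain(stripped, tiny_refs, tiny_encoder_config, modality="emg")

    def test_save_load_round_trip(self, tiny_model, tiny_refs, tmp_path, rng):
        path = tmp_path / "model.npz"
        tiny_model.save(path, refs=tiny_refs)
        loaded, loaded_refs = SiameseModel.load(path)
        probe = rng.normal(size=(4, tiny_model.input_length))
        for seg in probe:
            np.testing.assert_array_equal(tiny_model.encode(seg), loaded.encode(seg))
        assert loaded_refs.fingerprint() == tiny_refs.fingerprint()
        assert loaded.modality == tiny_model.modality


class TestFewShotExtension:
    def test_new_class_recognized_without_retraining(self, tiny_model, tiny_refs,
                                                     tiny_synth_config):
        """Adding a 12th (here 6th) well-separated class to the reference
        set gives above-chance recall on it with the frozen encoder."""
        extended_vocab = TINY_VOCAB[:-1] + ("Pick", NOISE_LABEL)
        cfg = SynthConfig(n_word_reps=12, n_sentence_reps=2,
                          seed=tiny_synth_config.seed + 1)
        corpus, _ = synth_corpora(extended_vocab, [("Pick", "Need")], cfg)
        new = [r for r in corpus if r.label == "Pick"]
        refs2 = tiny_refs.extended("Pick", new[:5])
        probes = new[5:]
        hits = 0
        for rec in probes:
            seg = tiny_model.prepare_recording(rec)
            hits += classify_segment(tiny_model, seg, refs2).top1 == "Pick"
        assert hits / len(probes) > 1.0 / len(refs2.classes)
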