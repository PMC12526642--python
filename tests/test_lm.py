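import math
from collections import Counter

import pytest

from silentspeech.errors import ValidationError
from silentspeech.lm import (
    BOS,
    EOS,
    SentenceHypothesis,
    TrigramModel,
    combined_confidence,
    correct_sentence,
    enumerate_candidates,
    fit_trigram,
    ngram_logprob,
)
from silentspeech.signal_model import DEFAULT_SENTENCES
from silentspeech.windows import CandidateRanking

COMMANDS = [list(s) for s in DEFAULT_SENTENCES]


# ---------------------------------------------------------------------------
# Independent oracle: count-and-multiply over the padded corpus


def oracle_prob(sentences, words, k=0.0):
    tri = Counter()
    ctx = Counter()
    vocab = sorted({w for s in sentences for w in s})
    for s in sentences:
        padded = [BOS, BOS] + list(s) + [EOS]
        for i in range(2, len(padded)):
            tri[tuple(padded[i - 2 : i + 1])] += 1
            ctx[tuple(padded[i - 2 : i])] += 1
    p = 1.0
    padded = [BOS, BOS] + list(words) + [EOS]
    for i in range(2, len(padded)):
        num = tri[tuple(padded[i - 2 : i + 1])] + k
        den = ctx[tuple(padded[i - 2 : i])] + k * (len(vocab) + 1)
        if den == 0:
            return 0.0
        p *= num / den
    return p


@pytest.fixture(scope="module")
def lm():
    return fit_trigram(COMMANDS, k_smooth=0.01)


@pytest.fixture(scope="module")
def lm_unsmoothed():
    return fit_trigram(COMMANDS, k_smooth=0.0)


class TestFitTrigram:
    def test_command_corpus_vocabulary(self, lm):
        assert len(lm.vocabulary) == 10

    def test_hand_counted_bigram(self, lm):
        # "Land Here" appears in both "Land Here" and "Do Not Land Here"
        assert lm.count("Land", "Here") == 2
        assert lm.count("Pick", "Here") == 0

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValidationError):
            fit_trigram([])

    def test_save_load_bit_exact(self, lm, tmp_path):
        path = tmp_path / "lm.txt"
        lm.save(path)
        back = TrigramModel.load(path)
        assert back.counts == lm.counts
        assert back.vocabulary == lm.vocabulary
        assert back.k_smooth == lm.k_smooth


class TestNgramLogprob:
    def test_land_here_hand_computation(self, lm_unsmoothed):
        # P(Land|<s><s>) = 1/4, P(Here|<s> Land) = 1, P(</s>|Land Here) = 1
        assert ngram_logprob(lm_unsmoothed, ["Land", "Here"]) == pytest.approx(math.log(0.25))

    def test_matches_oracle_on_training_sentences(self, lm_unsmoothed):
        for s in COMMANDS:
            expect = oracle_prob(COMMANDS, s, k=0.0)
            assert math.exp(ngram_logprob(lm_unsmoothed, s)) == pytest.approx(expect)

    def test_matches_oracle_on_random_strings(self, lm_unsmoothed, lm, rng):
        vocab = lm.vocabulary
        for _ in range(25):
            words = list(rng.choice(vocab, size=rng.integers(1, 6)))
            for model, k in ((lm_unsmoothed, 0.0), (lm, 0.01)):
                expect = oracle_prob(COMMANDS, words, k=k)
                got = ngram_logprob(model, words)
                assert math.exp(got) == pytest.approx(expect, abs=1e-12)

    def test_logprob_nonpositive(self, lm, rng):
        for _ in range(10):
            words = list(rng.choice(lm.vocabulary, size=3))
            assert ngram_logprob(lm, words) <= 0.0

    def test_smoothing_prefers_observed_continuation(self, lm):
        # brute-force smoothed table check: after "Pick Us", "Up" beats "Here"
        assert lm.cond_prob("Up", "Pick", "Us") > lm.cond_prob("Here", "Pick", "Us")

    def test_oov_rejected(self, lm):
        with pytest.raises(ValidationError):
            ngram_logprob(lm, ["Banana"])

    def test_smoothed_distributions_sum_to_one(self, lm):
        histories = {ng[:2] for ng in lm.counts if len(ng) == 3}
        for u, v in histories:
            total = sum(lm.cond_prob(w, u, v) for w in lm.vocabulary + [EOS])
            assert total == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Candidate enumeration and correction


def rankings_from(windows):
    """Build CandidateRankings from per-window [(word, confidence), ...]
    lists (descending confidence); distances are synthesized consistently."""
    out = []
    for wi, cands in enumerate(windows):
        total = sum(c for _, c in cands)
        entries = [(w, 0.1 * i, c / total) for i, (w, c) in enumerate(cands)]
        out.append(CandidateRanking(entries=entries, window_index=wi))
    return out


def windows_for(words, second_choices, p1=0.6, p2=0.3, p3=0.1):
    """Top-1 path spells ``words``; window i's runner-up comes from
    ``second_choices``."""
    wins = []
    for w, alt in zip(words, second_choices):
        third = "Medical" if "Medical" not in (w, alt) else "Not"
        wins.append([(w, p1), (alt, p2), (third, p3)])
    return wins


TABLE3_CASES = [
    # (wrong top-1 path, runner-ups making the truth reachable, truth)
    (["Need", "Medical", "Assistance", "Land"],
     ["Medical", "Need", "Medical", "Assistance"],
     ["Need", "Medical", "Assistance"]),
    (["Do", "Not", "Land", "Need", "Here"],
     ["Not", "Do", "Not", "Here", "Land"],
     ["Do", "Not", "Land", "Here"]),
    (["Pick", "Land", "Here"],
     ["Land", "Pick", "Land"],
     ["Land", "Here"]),
    (["Pick", "Us", "Up", "Here"],
     ["Us", "Pick", "Us", "Up"],
     ["Pick", "Us", "Up"]),
]


class TestCorrectSentence:
    @pytest.mark.parametrize("wrong,alts,truth", TABLE3_CASES)
    def test_printed_corrections_reproduced(self, lm, wrong, alts, truth):
        """The four worked corrections: wrong sequence on top, truth
        reachable in the beam, LM filtering recovers the command."""
        rankings = rankings_from(windows_for(wrong, alts))
        result = correct_sentence(rankings, lm, K=5, top_m=3)
        assert result.words == truth
        assert not result.fallback

    def test_training_sentence_is_fixed_point(self, lm):
        for command in COMMANDS:
            rankings = rankings_from(windows_for(command, [command[0]] * len(command)))
            result = correct_sentence(rankings, lm, K=5, top_m=3)
            assert result.words == command

    def test_fallback_when_everything_filtered(self, lm):
        # no in-beam path forms a plausible command
        wins = [[("Up", 0.9), ("Here", 0.1)], [("Do", 0.9), ("Not", 0.1)]]
        result = correct_sentence(rankings_from(wins), lm, K=5, top_m=2)
        assert result.fallback
        assert result.words == ["Up", "Do"]  # uncorrected collapsed top-1

    def test_correction_never_emits_oov(self, lm, rng):
        vocab = lm.vocabulary
        for _ in range(10):
            n = int(rng.integers(2, 6))
            wins = []
            for _ in range(n):
                picks = rng.choice(vocab, size=3, replace=False)
                wins.append([(w, c) for w, c in zip(picks, (0.5, 0.3, 0.2))])
            result = correct_sentence(rankings_from(wins), lm, K=4, top_m=3)
            assert all(w in vocab for w in result.words)
            assert len(result.hypotheses) <= 4


class TestEnumerateCandidates:
    def test_enumeration_bound(self, lm):
        wins = [[("Land", 0.6), ("Here", 0.4)], [("Here", 0.7), ("Up", 0.3)]]
        hyps = enumerate_candidates(rankings_from(wins), top_m=2, K=10, model=lm,
                                    prune_threshold=0.0)
        assert 1 <= len(hyps) <= 4

    def test_truth_and_wrong_path_both_reachable(self, lm):
        wins = windows_for(["Need", "Medical", "Assistance", "Land"],
                           ["Medical", "Need", "Medical", "Assistance"])
        hyps = enumerate_candidates(rankings_from(wins), top_m=3, K=50, model=lm,
                                    prune_threshold=0.0)
        seqs = [tuple(h.words) for h in hyps]
        assert ("Need", "Medical", "Assistance", "Land") in seqs
        assert ("Need", "Medical", "Assistance") in seqs

    def test_k_one_returns_single_best(self, lm):
        wins = [[("Land", 0.6), ("Here", 0.4)], [("Here", 0.7), ("Up", 0.3)]]
        hyps = enumerate_candidates(rankings_from(wins), top_m=2, K=1, model=lm)
        assert len(hyps) == 1

    def test_invalid_arguments(self, lm):
        wins = rankings_from([[("Land", 1.0)]])
        with pytest.raises(ValidationError):
            enumerate_candidates(wins, top_m=2, K=0, model=lm)
        with pytest.raises(ValidationError):
            enumerate_candidates([], top_m=2, K=2, model=lm)


class TestCombinedConfidence:
    def test_hand_computed_mixture(self):
        hyp = SentenceHypothesis(words=["a", "b", "c"], lm_logprob=-2.0, snn_logconf=-4.0)
        assert combined_confidence(hyp, lam=0.5) == pytest.approx(-1.0)

    def test_boundaries_of_the_mixture(self):
        hyp = SentenceHypothesis(words=["a", "b"], lm_logprob=-2.0, snn_logconf=-6.0)
        assert combined_confidence(hyp, lam=1.0) == pytest.approx(-1.0)
        assert combined_confidence(hyp, lam=0.0) == pytest.approx(-3.0)

    def test_empty_hypothesis_rejected(self):
        hyp = SentenceHypothesis(words=[], lm_logprob=-1.0, snn_logconf=-1.0)
        with pytest.raises(ValidationError):
            combined_confidence(hyp)
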