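"""Metric implementations against independent oracles, and the corpus report."""

import math
import random
from collections import Counter

import numpy as np
import pytest

from synthletters.adapters import (
    HashingDocEmbedder,
    OneHotEmbedder,
    SubjectivityLexicon,
    UniformLanguageModel,
)
from synthletters.evaluation import (
    EvalReport,
    bertscore_f1,
    clinical_similarity,
    evaluate_corpus,
    invalid_prediction_rate,
    meteor_score,
    readability_scores,
    rouge_scores,
    text_quality_scores,
)


# --- independent brute-force oracle -----------------------------------------


def _oracle_f(cand, ref):
    if not cand and not ref:
        return 100.0
    if not cand or not ref:
        return 0.0
    hits = 0
    pool = list(ref)
    for g in cand:
        if g in pool:
            pool.remove(g)
            hits += 1
    p, r = hits / len(cand), hits / len(ref)
    return 100 * (2 * p * r / (p + r)) if p + r else 0.0


def _oracle_rouge(candidate, reference):
    import re

    c = re.findall(r"[a-z0-9]+", candidate.lower())
    r = re.findall(r"[a-z0-9]+", reference.lower())

    def lcs(a, b):
        if not a or not b:
            return 0
        table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
        for i in range(1, len(a) + 1):
            for j in range(1, len(b) + 1):
                table[i][j] = (
                    table[i - 1][j - 1] + 1 if a[i - 1] == b[j - 1] else max(table[i - 1][j], table[i][j - 1])
                )
        return table[-1][-1]

    r1 = _oracle_f(c, r)
    r2 = _oracle_f(list(zip(c, c[1:])), list(zip(r, r[1:])))
    if not c and not r:
        rl = 100.0
    elif not c or not r:
        rl = 0.0
    else:
        l = lcs(c, r)
        p, rec = l / len(c), l / len(r)
        rl = 100 * (2 * p * rec / (p + rec)) if p + rec else 0.0
    return r1, r2, rl


class TestRouge:
    def test_identity_is_100(self):
        assert rouge_scores("the cat sat", "the cat sat") == (100.0, 100.0, 100.0)

    def test_hand_counted_example(self):
        r1, r2, rl = rouge_scores("the cat sat", "the cat ran")
        assert r1 == pytest.approx(100 * 2 / 3)
        assert r2 == pytest.approx(50.0)
        assert rl == pytest.approx(100 * 2 / 3)

    def test_disjoint_vocabulary_is_zero(self):
        assert rouge_scores("alpha beta", "gamma delta") == (0.0, 0.0, 0.0)

    def test_empty_cases(self):
        assert rouge_scores("", "") == (100.0, 100.0, 100.0)
        assert rouge_scores("word", "") == (0.0, 0.0, 0.0)

    def test_agrees_with_brute_force_oracle_on_random_pairs(self):
        rng = random.Random(1234)
        vocab = ["the", "cat", "sat", "ran", "dog", "on", "mat", "big", "was", "a"]
        for _ in range(100):
            cand = " ".join(rng.choices(vocab, k=rng.randint(1, 10)))
            ref = " ".join(rng.choices(vocab, k=rng.randint(1, 10)))
            got = rouge_scores(cand, ref)
            want = _oracle_rouge(cand, ref)
            assert got == pytest.approx(want), (cand, ref)


class TestBertscore:
    def test_identity_close_to_one(self):
        assert bertscore_f1("the same text", "the same text") == pytest.approx(1.0, abs=1e-6)

    def test_one_hot_equals_hand_computed_greedy(self):
        # cand: [the cat sat], ref: [the cat ran]
        # one-hot: best match is 1 for shared surfaces, 0 otherwise
        # P = 2/3, R = 2/3, F1 = 2/3
        assert bertscore_f1("the cat sat", "the cat ran", OneHotEmbedder()) == pytest.approx(2 / 3)

    def test_orthogonal_embeddings_give_zero(self):
        assert bertscore_f1("aa bb", "cc dd", OneHotEmbedder()) == pytest.approx(0.0)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            bertscore_f1("", "reference")

    def test_exhaustive_greedy_on_tiny_pair(self):
        # cand [a b a], ref [a b]: P=(1+1+1)/3=1, R=(1+1)/2=1
        assert bertscore_f1("a b a", "a b", OneHotEmbedder()) == pytest.approx(1.0)
        # cand [a c], ref [a b]: P=(1+0)/2, R=(1+0)/2 -> F1=0.5
        assert bertscore_f1("a c", "a b", OneHotEmbedder()) == pytest.approx(0.5)


class TestMeteor:
    def test_identity_near_one(self):
        s = meteor_score("the patient was admitted overnight", "the patient was admitted overnight")
        # one chunk, penalty 0.5*(1/5)^3
        assert s == pytest.approx(1 - 0.5 * (1 / 5) ** 3)
        assert s >= 0.99

    def test_no_match_is_zero(self):
        assert meteor_score("alpha beta", "gamma delta") == 0.0

    def test_bounds(self):
        rng = random.Random(7)
        vocab = ["a", "b", "c", "d", "e"]
        for _ in range(50):
            c = " ".join(rng.choices(vocab, k=rng.randint(1, 8)))
            r = " ".join(rng.choices(vocab, k=rng.randint(1, 8)))
            assert 0.0 <= meteor_score(c, r) <= 1.0


class TestReadability:
    def test_hand_formulas_on_three_words(self):
        scores = readability_scores("The cat sat.")
        assert scores.flesch_reading_ease == pytest.approx(119.19, abs=0.01)
        assert scores.flesch_kincaid_grade == pytest.approx(-2.62, abs=0.01)
        assert scores.smog == pytest.approx(3.1291)  # zero polysyllables
        assert scores.below_smog_range

    def test_polysyllables_raise_smog(self):
        low = readability_scores("The cat sat.").smog
        high = readability_scores("Immediately hospitalized individuals recuperated.").smog
        assert high > low

    def test_no_words_is_error(self):
        with pytest.raises(ValueError):
            readability_scores("...")


class TestTextQuality:
    def test_entropy_two_symbol_uniform(self):
        assert text_quality_scores("a b a b")["entropy"] == pytest.approx(1.0)

    def test_entropy_single_symbol_zero(self):
        assert text_quality_scores("word word word")["entropy"] == 0.0

    def test_uniform_lm_perplexity_is_vocab_size(self):
        out = text_quality_scores("some words here", lm=UniformLanguageModel(37))
        assert out["perplexity"] == pytest.approx(37.0)

    def test_perplexity_omitted_without_lm(self):
        assert "perplexity" not in text_quality_scores("some words here")

    def test_subjectivity_lexicon_mean(self):
        lex = SubjectivityLexicon({"good": 0.6, "bad": 0.8})
        assert text_quality_scores("good bad day", lexicon=lex)["subjectivity"] == pytest.approx(0.7)


class TestInvalidRate:
    class _FC:
        def __init__(self, validity):
            self.validity = validity
            self.predictions = validity

    def test_definition_instance(self):
        fcs = [self._FC(["invalid", "invalid", "valid"])]
        assert invalid_prediction_rate(fcs) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("validity,expected", [(["valid"] * 4, 0.0), (["invalid"] * 3, 1.0)])
    def test_boundary_rates(self, validity, expected):
        assert invalid_prediction_rate([self._FC(validity)]) == expected

    def test_zero_predictions_is_error(self):
        with pytest.raises(ValueError, match="no masked predictions"):
            invalid_prediction_rate([self._FC([])])


class TestClinicalSimilarity:
    def test_identity_is_one(self):
        assert clinical_similarity("same text here", "same text here") == pytest.approx(1.0)

    def test_orthogonal_stub_vectors_zero(self):
        vecs = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        assert clinical_similarity("a", "b", embedder=lambda t: vecs[t]) == pytest.approx(0.0)

    def test_zero_vector_is_error(self):
        with pytest.raises(ValueError):
            clinical_similarity("a", "b", embedder=lambda t: np.zeros(4))


class TestEvaluateCorpus:
    def test_identity_synthetics_hit_ceiling_and_beat_baseline(self, letters):
        originals = [lt.text for lt in letters[:4]]
        masked = [t.replace("patient", "[MASK]") for t in originals]
        report = evaluate_corpus(originals, masked, list(originals))
        summary = report.summary()
        assert summary.loc["rouge1", "generation"] == pytest.approx(100.0)
        for metric in ("rouge1", "rouge2", "rougeL", "bertscore_f1", "meteor", "clinical_cosine"):
            assert summary.loc[metric, "generation"] >= summary.loc[metric, "baseline"]

    def test_every_similarity_metric_has_baseline_row(self, letters):
        originals = [lt.text for lt in letters[:2]]
        report = evaluate_corpus(originals, originals, originals)
        got = report.per_letter
        for metric in ("rouge1", "rouge2", "rougeL", "bertscore_f1", "meteor", "clinical_cosine"):
            variants = set(got[got.metric == metric].variant)
            assert variants == {"generation", "baseline"}

    def test_intrinsic_metrics_cover_three_variants(self, letters):
        originals = [lt.text for lt in letters[:2]]
        report = evaluate_corpus(originals, originals, originals)
        got = report.per_letter
        assert set(got[got.metric == "entropy"].variant) == {"original", "masked", "synthetic"}

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_corpus([], [], [])

    def test_misaligned_corpora_rejected(self):
        with pytest.raises(ValueError, match="misalignment"):
            evaluate_corpus(["a"], ["a", "b"], ["a"])

    def test_report_serializes(self, tmp_path, letters):
        originals = [lt.text for lt in letters[:2]]
        report = evaluate_corpus(originals, originals, originals)
        report.to_csv(tmp_path / "eval.csv")
        report.to_json(tmp_path / "eval.json")
        assert (tmp_path / "eval.csv").exists() and (tmp_path / "eval.json").exists()
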