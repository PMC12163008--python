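"""Tokenization and the per-token feature detectors."""

import pytest

from synthletters.corpus_io import EntityAnnotation
from synthletters.features import (
    AdapterBundle,
    ContractViolation,
    annotate_features,
    detect_clinical_terms,
    detect_private,
    detect_special_patterns,
    detect_structure,
    tag_pos,
    tokenize_with_offsets,
)


def _flagged(tokens, flags):
    return [t.text for t in tokens if flags[t.index]]


class TestTokenizer:
    def test_words_and_punctuation_with_offsets(self):
        tokens = tokenize_with_offsets("from ladder.")
        assert [t.text for t in tokens] == ["from", "ladder", "."]
        assert [(t.start, t.end) for t in tokens] == [(0, 4), (5, 11), (11, 12)]

    def test_every_token_slices_to_surface(self, letters):
        for lt in letters[:6]:
            for t in tokenize_with_offsets(lt.text):
                assert lt.text[t.start : t.end] == t.text

    def test_empty_text_has_no_tokens(self):
        assert tokenize_with_offsets("") == []

    def test_placeholder_is_single_token(self):
        tokens = tokenize_with_offsets("a ___ b ______ c")
        assert [t.text for t in tokens if set(t.text) == {"_"}] == ["___", "______"]


class TestStructure:
    def test_header_line_fully_flagged(self):
        text = "Discharge Instructions:\nHe fell from a ladder"
        tokens = tokenize_with_offsets(text)
        flags = detect_structure(text, tokens)
        assert _flagged(tokens, flags) == ["Discharge", "Instructions", ":"]

    def test_plain_line_not_flagged(self):
        text = "He fell from a ladder"
        tokens = tokenize_with_offsets(text)
        assert not any(detect_structure(text, tokens))

    def test_mid_line_colon_not_flagged(self):
        text = "Seen at 12:30 in clinic"
        tokens = tokenize_with_offsets(text)
        assert not any(detect_structure(text, tokens))

    def test_lowercase_function_word_allowed_in_header(self):
        text = "History of Present Illness:\n"
        tokens = tokenize_with_offsets(text)
        flags = detect_structure(text, tokens)
        assert all(flags[t.index] for t in tokens)

    def test_long_line_ending_with_colon_not_header(self):
        text = "he said the following things were very important and noted them here:"
        tokens = tokenize_with_offsets(text)
        assert not any(detect_structure(text, tokens))


class TestPrivate:
    @pytest.mark.parametrize(
        "text,kind",
        [
            ("write to john.doe@mail.com today", "email"),
            ("call (555) 123-4567 now", "phone"),
            ("MRN 1234567 on file", "phone"),
            ("seen on 01/02/2023 at clinic", "date"),
        ],
    )
    def test_rule_kinds(self, text, kind):
        tokens = tokenize_with_offsets(text)
        flags, kinds = detect_private(text, tokens)
        hit = [kinds[t.index] for t in tokens if flags[t.index]]
        assert hit and set(hit) == {kind}

    def test_adapter_spans_flagged_with_kind(self):
        text = "Seen in Boston yesterday"
        tokens = tokenize_with_offsets(text)
        start = text.index("Boston")
        flags, kinds = detect_private(text, tokens, ner=lambda t: [(start, start + 6, "location")])
        assert _flagged(tokens, flags) == ["Boston"]
        boston = next(t for t in tokens if t.text == "Boston")
        assert kinds[boston.index] == "location"

    def test_adapter_failure_degrades_to_rules(self):
        text = "email a@b.co now"

        def broken(_):
            raise RuntimeError("backend down")

        tokens = tokenize_with_offsets(text)
        flags, kinds = detect_private(text, tokens, ner=broken)
        assert any(flags)


class TestClinical:
    def test_manual_annotation_tokens_flagged(self):
        text = "Allergies:\nNo Known Allergies\n"
        s = text.index("No Known")
        tokens = tokenize_with_offsets(text)
        ann = EntityAnnotation("A", s, s + len("No Known Allergies"), "609328004")
        flags, sources = detect_clinical_terms(tokens, entities=[ann])
        assert _flagged(tokens, flags) == ["No", "Known", "Allergies"]
        assert {sources[t.index] for t in tokens if flags[t.index]} == {"manual_annotation"}

    def test_no_adapter_means_manual_only(self):
        tokens = tokenize_with_offsets("chest x-ray was clear")
        flags, _ = detect_clinical_terms(tokens, entities=[])
        assert not any(flags)

    def test_adapter_span_flagged_with_source(self):
        text = "chest x-ray was clear"
        tokens = tokenize_with_offsets(text)
        flags, sources = detect_clinical_terms(
            tokens, entities=[], ner=lambda t: [(0, len("chest x-ray"), "Test")], chunk_text=text
        )
        assert _flagged(tokens, flags) == ["chest", "x", "-", "ray"]
        assert sources[0] == "ner_adapter"


class TestSpecialPatterns:
    def test_dose_ratio_expression(self):
        text = "enoxaparin 40 mg/0.4 ml daily"
        tokens = tokenize_with_offsets(text)
        flags = detect_special_patterns(text, tokens)
        assert _flagged(tokens, flags) == ["40", "mg", "/", "0.4", "ml"]

    def test_dotted_abbreviation(self):
        text = "take twice b.i.d. with food"
        tokens = tokenize_with_offsets(text)
        flags = detect_special_patterns(text, tokens)
        assert "b" in _flagged(tokens, flags) and "d" in _flagged(tokens, flags)

    def test_comparison_dose(self):
        text = "Ibuprofen > 200 mg as needed"
        tokens = tokenize_with_offsets(text)
        flags = detect_special_patterns(text, tokens)
        assert _flagged(tokens, flags) == [">", "200", "mg"]

    def test_invalid_user_regex_is_config_error(self):
        tokens = tokenize_with_offsets("x")
        with pytest.raises(ValueError, match="invalid special-pattern regex"):
            detect_special_patterns("x", tokens, patterns={"bad": "(unclosed"})


class TestPOS:
    def test_stub_tagger_mapped_to_coarse(self):
        tokens = tokenize_with_offsets("ladder fell")
        coarse = tag_pos(tokens, lambda ws: ["NN", "VBD"])
        assert coarse == ["noun", "verb"]

    def test_count_mismatch_is_contract_violation(self):
        tokens = tokenize_with_offsets("a b c")
        with pytest.raises(ContractViolation):
            tag_pos(tokens, lambda ws: ["NN"])


class TestAnnotateFeatures:
    def test_classifications(self):
        text = "Pain well controlled . 40 mg dose with ___ noted"
        feats = annotate_features(text)
        by_text = {f.token.text: f for f in feats}
        assert by_text["."].is_punct
        assert by_text["40"].is_number and by_text["40"].is_special_pattern
        assert by_text["___"].is_placeholder
        assert by_text["with"].is_stopword
        assert not by_text["Pain"].is_punct

    def test_one_record_per_token_and_pure(self, letters):
        lt = letters[0]
        a = annotate_features(lt.text, entities=lt.entities)
        b = annotate_features(lt.text, entities=lt.entities)
        assert len(a) == len(tokenize_with_offsets(lt.text))
        assert [vars(x.token) for x in a] == [vars(x.token) for x in b]
        assert [(x.is_private, x.is_clinical, x.pos) for x in a] == [
            (x.is_private, x.is_clinical, x.pos) for x in b
        ]


def test_detector_recall_is_total_on_fixture_gold(corpus):
    """Every generator-emitted instance of a feature class is detected."""
    flag_of = {
        "structure": "is_structure",
        "private": "is_private",
        "clinical_entity": "is_clinical",
        "special_pattern": "is_special_pattern",
        "placeholder": "is_placeholder",
    }
    for lt, gold in corpus:
        feats = annotate_features(lt.text, entities=lt.entities)
        for category, spans in gold.spans.items():
            attr = flag_of[category]
            for s, e, surface in spans:
                overlapping = [f for f in feats if f.token.start < e and f.token.end > s]
                assert overlapping, (category, surface)
                missed = [f.token.text for f in overlapping if not getattr(f, attr)]
                assert not missed, (category, surface, missed)
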