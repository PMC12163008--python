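"""Eligibility precedence, strategy selection, ratios, rendering."""

import numpy as np
import pytest

from synthletters.features import annotate_features, tokenize_with_offsets
from synthletters.masking import (
    SEQ2SEQ_PROMPT,
    MaskStrategy,
    compute_eligibility,
    render_masked_text,
    select_mask_targets,
)


def _features(text, entities=()):
    return annotate_features(text, entities=entities)


def _protected_indices(feats):
    return {
        f.token.index
        for f in feats
        if not f.is_private
        and (
            f.is_clinical
            or f.is_structure
            or f.is_special_pattern
            or f.is_punct
            or f.is_placeholder
            or f.is_number
        )
    }


class TestStrategy:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            MaskStrategy(kind="everything")

    def test_ratio_bounds_enforced(self):
        with pytest.raises(ValueError):
            MaskStrategy(kind="random", ratio=1.5)

    def test_hybrid_requires_components(self):
        with pytest.raises(ValueError):
            MaskStrategy(kind="hybrid")


class TestEligibility:
    def test_entity_tokens_protected(self, letters):
        lt = letters[0]
        feats = _features(lt.text, lt.entities)
        E, F = compute_eligibility(feats, MaskStrategy(kind="random", ratio=0.5))
        clinical = {f.token.index for f in feats if f.is_clinical}
        assert not (E & clinical) and not (F & clinical)

    def test_private_forced_only_with_deidentify(self):
        text = "call (555) 123-4567 for help"
        feats = _features(text)
        private = {f.token.index for f in feats if f.is_private}
        assert private
        E0, F0 = compute_eligibility(feats, MaskStrategy(kind="random", ratio=0.5))
        assert F0 == frozenset() and not (E0 & private)
        E1, F1 = compute_eligibility(feats, MaskStrategy(kind="random", ratio=0.5, deidentify=True))
        assert F1 == private and not (E1 & private)

    def test_fully_protected_chunk_selects_only_forced(self):
        text = "40 mg . ___"
        feats = _features(text)
        strat = MaskStrategy(kind="random", ratio=1.0)
        E, F = compute_eligibility(feats, strat)
        assert E == frozenset()
        plan = select_mask_targets(E, F, feats, strat, seed=0)
        assert plan.masked == F and plan.eligible_ratio == 0.0


class TestSelection:
    TEXT = "the patient was walking slowly around the quiet ward before lunch and dinner today"

    def test_boundary_ratios(self):
        feats = _features(self.TEXT)
        for r, expect_all in ((0.0, False), (1.0, True)):
            strat = MaskStrategy(kind="random", ratio=r)
            E, F = compute_eligibility(feats, strat)
            plan = select_mask_targets(E, F, feats, strat, seed=3)
            assert plan.masked == (E if expect_all else frozenset())

    def test_rounding_half_up(self):
        feats = _features(self.TEXT)
        strat = MaskStrategy(kind="random", ratio=0.25)
        E, F = compute_eligibility(feats, strat)
        plan = select_mask_targets(E, F, feats, strat, seed=0)
        (_, _, pool, k), = plan.component_counts
        assert k == int(np.floor(0.25 * pool + 0.5))
        assert len(plan.masked) == k

    def test_hybrid_union_of_component_draws(self):
        feats = _features(self.TEXT)
        strat = MaskStrategy(kind="hybrid", components=(("noun", 0.5), ("stopword", 0.5)))
        E, F = compute_eligibility(feats, strat)
        plan = select_mask_targets(E, F, feats, strat, seed=9)
        nouns = {f.token.index for f in feats if f.pos == "noun"} & E
        stops = {f.token.index for f in feats if f.is_stopword} & E
        assert plan.masked <= (nouns | stops)
        total_k = sum(k for *_, k in plan.component_counts)
        assert len(plan.masked) == total_k - plan.overlap

    def test_determinism_and_seed_sensitivity(self):
        feats = _features(self.TEXT)
        strat = MaskStrategy(kind="random", ratio=0.5)
        E, F = compute_eligibility(feats, strat)
        a = select_mask_targets(E, F, feats, strat, seed=5).masked
        b = select_mask_targets(E, F, feats, strat, seed=5).masked
        c = select_mask_targets(E, F, feats, strat, seed=6).masked
        assert a == b
        assert a != c  # overwhelmingly likely with this pool

    def test_masked_count_monotone_in_ratio(self):
        feats = _features(self.TEXT)
        for kind in ("random", "stopword", "pos_noun"):
            sizes = []
            for r in np.linspace(0, 1, 11):
                strat = MaskStrategy(kind=kind, ratio=float(r))
                E, F = compute_eligibility(feats, strat)
                sizes.append(len(select_mask_targets(E, F, feats, strat, seed=11).masked))
            assert sizes == sorted(sizes)

    def test_draws_nested_across_ratios(self):
        feats = _features(self.TEXT)
        strat_small = MaskStrategy(kind="random", ratio=0.3)
        strat_big = MaskStrategy(kind="random", ratio=0.8)
        E, F = compute_eligibility(feats, strat_small)
        small = select_mask_targets(E, F, feats, strat_small, seed=2).masked
        big = select_mask_targets(E, F, feats, strat_big, seed=2).masked
        assert small <= big

    def test_category_pools_respected(self):
        feats = _features(self.TEXT)
        for kind, pred in (
            ("pos_noun", lambda f: f.pos == "noun"),
            ("pos_verb", lambda f: f.pos == "verb"),
            ("stopword", lambda f: f.is_stopword),
        ):
            strat = MaskStrategy(kind=kind, ratio=1.0)
            E, F = compute_eligibility(feats, strat)
            plan = select_mask_targets(E, F, feats, strat, seed=1)
            assert plan.masked == {f.token.index for f in feats if pred(f)} & E


class TestProtectionFuzz:
    def test_masked_never_intersects_protected(self, corpus):
        strategies = [
            MaskStrategy(kind="random", ratio=0.8, deidentify=True),
            MaskStrategy(kind="hybrid", components=(("random", 0.6), ("stopword", 1.0))),
        ]
        checked = 0
        for lt, _ in corpus[:10]:
            feats = _features(lt.text, lt.entities)
            protected = _protected_indices(feats)
            for strat in strategies:
                E, F = compute_eligibility(feats, strat)
                for seed in range(25):
                    plan = select_mask_targets(E, F, feats, strat, seed=seed)
                    assert not (plan.masked & protected)
                    checked += 1
        assert checked == 500


class TestRender:
    def test_no_masks_encoder_identity(self):
        text = "nothing to mask here"
        feats = _features(text)
        strat = MaskStrategy(kind="random", ratio=0.0)
        E, F = compute_eligibility(feats, strat)
        plan = select_mask_targets(E, F, feats, strat, seed=0)
        tokens = [f.token for f in feats]
        masked = render_masked_text(text, tokens, plan)
        assert masked.text == text and masked.n_slots == 0

    def test_encoder_mask_symbol_and_slot_map(self):
        text = "alpha beta gamma"
        feats = _features(text)
        strat = MaskStrategy(kind="random", ratio=1.0)
        E, F = compute_eligibility(feats, strat)
        plan = select_mask_targets(E, F, feats, strat, seed=0)
        tokens = [f.token for f in feats]
        masked = render_masked_text(text, tokens, plan, mask_symbol="[MASK]")
        assert masked.text == "[MASK] [MASK] [MASK]"
        assert [s.original for s in masked.slots] == ["alpha", "beta", "gamma"]

    def test_seq2seq_sentinels_ordered_and_prompted(self):
        text = "alpha beta"
        feats = _features(text)
        strat = MaskStrategy(kind="random", ratio=1.0)
        E, F = compute_eligibility(feats, strat)
        plan = select_mask_targets(E, F, feats, strat, seed=0)
        tokens = [f.token for f in feats]
        masked = render_masked_text(text, tokens, plan, dialect="seq2seq_sentinel")
        assert masked.text == "<extra_id_0> <extra_id_1>"
        assert masked.prompt == SEQ2SEQ_PROMPT
        assert masked.model_input.startswith(
            "Fill in the blanks in the following sentence in the clinical background"
        )

    def test_plan_record_round_trips_ratios(self):
        text = "the patient was resting comfortably all afternoon"
        feats = _features(text)
        strat = MaskStrategy(kind="random", ratio=0.5)
        E, F = compute_eligibility(feats, strat)
        plan = select_mask_targets(E, F, feats, strat, seed=4)
        rec = plan.to_record()
        assert rec["eligible_ratio"] == round(len(plan.masked - plan.forced) / len(E), 6)
        assert rec["actual_ratio"] == round(len(plan.masked) / len(feats), 6)
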