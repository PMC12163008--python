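"""Mask eligible tokens under a strategy and fill them with a mock backend.

Clinical entities, headers, dosages, punctuation, numbers and "___"
placeholders are protected; the strategy picks a fraction of what
remains. The deterministic lexicon filler stands in for a masked
language model.
"""

from synthletters.adapters import LexiconFiller
from synthletters.features import annotate_features, tokenize_with_offsets
from synthletters.fixtures import FixtureSpec, generate_letter
from synthletters.generation import fill_masks, splice_predictions
from synthletters.masking import (
    MaskStrategy,
    compute_eligibility,
    render_masked_text,
    select_mask_targets,
)

letter, _ = generate_letter(FixtureSpec(seed=5, placeholder_rate=1.0), 2)
text = letter.text.split("\n\n")[0]  # first section only, for display
entities = [e for e in letter.entities if e.end <= len(text)]

tokens = tokenize_with_offsets(text)
features = annotate_features(text, tokens=tokens, entities=entities)
strategy = MaskStrategy(kind="random", ratio=0.5)
eligible, forced = compute_eligibility(features, strategy)
plan = select_mask_targets(eligible, forced, features, strategy, seed=3)
print(f"{len(tokens)} tokens, {len(eligible)} eligible, {len(plan.masked)} masked")
print(f"eligible ratio {plan.eligible_ratio:.2f}, actual ratio {plan.actual_ratio:.2f}")
print("(the requested ratio applies to eligible tokens only, so the actual")
print(" whole-text ratio is always lower when much is protected)")

masked = render_masked_text(text, tokens, plan)
print("\n--- masked -------------------------------------------------")
print(masked.text)

filler = LexiconFiller(seed=11)
predictions = fill_masks(masked, filler)
print("\n--- filled -------------------------------------------------")
print(splice_predictions(masked, predictions))

seq = render_masked_text(text, tokens, plan, dialect="seq2seq_sentinel")
print("\n--- sentinel dialect input (first 160 chars) ----------------")
print(seq.model_input[:160] + "...")
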