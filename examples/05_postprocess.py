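"""Re-fill "___" privacy placeholders and correct misspellings.

Placeholders mark redacted protected health information; predicting
fresh content for them yields natural-reading letters that invent, not
leak, the removed details. Spelling correction is word-level and never
touches protected entity spans.
"""

from synthletters.adapters import ConstantFiller
from synthletters.fixtures import FixtureSpec, fixture_vocabulary, generate_letter
from synthletters.postprocess import DictionaryCorrector, correct_spelling, fill_placeholders

text = "___ caught a cold and was previously healhty."
filled, fill_log = fill_placeholders(text, ConstantFiller("patient"))
print(f"before: {text}")
print(f"filled: {filled}")

corrector = DictionaryCorrector(fixture_vocabulary() | {"healthy", "caught", "cold", "was"})
corrected, corr_log = correct_spelling(filled, corrector)
print(f"corrected: {corrected}")
print(f"corrections: {[(r['original'], r['corrected']) for r in corr_log]}")

letter, gold = generate_letter(FixtureSpec(seed=3, misspelling_rate=0.05), 1)
protected = [(s, e) for spans in gold.spans.values() for s, e, _ in spans]
fixed, log = correct_spelling(letter.text, DictionaryCorrector(fixture_vocabulary()), protected)
print(f"\nfull letter: {len(gold.misspellings)} injected misspellings, "
      f"{len(log)} corrected, protected spans untouched.")
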