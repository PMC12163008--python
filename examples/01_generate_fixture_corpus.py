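"""Generate a small synthetic discharge-letter corpus with gold labels.

The generator emulates the structure of annotated discharge summaries:
colon-terminated section headers, sentences carrying entity annotations,
"___" privacy placeholders, medication-dosage lines and a few injected
misspellings. Gold labels live in a sidecar the pipeline never reads.
"""

from synthletters.corpus_io import merge_corpus, read_annotations, read_letters
from synthletters.fixtures import FixtureSpec, generate_corpus, load_gold

spec = FixtureSpec(n_letters=5, seed=42, misspelling_rate=0.03)
paths = generate_corpus(spec, "scratch/example_corpus")

letters = read_letters(paths["letters"])
annotations = read_annotations(paths["annotations"])
corpus = merge_corpus(letters, annotations, strict=True)
gold = load_gold(paths["gold"])

print(f"generated {len(corpus)} letters, {len(annotations)} entity annotations")
first = corpus[0]
print("--- first letter -------------------------------------------")
print(first.text)
print("--- its annotations ----------------------------------------")
for e in first.entities:
    print(f"  [{e.start:4d},{e.end:4d}) concept {e.concept_id}: {e.surface!r}")
counts = {k: len(v) for k, v in gold[0].spans.items()}
print(f"gold feature spans in letter 1: {counts}")
print("Each annotation slices to its surface; the gold spans are what the")
print("feature detectors must find to keep those tokens out of the mask pool.")
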