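You are an experienced clinician reviewing a synthetic clinical letter.
Compare the synthetic letter with the original letter and rate, on a
scale from 1 (poor) to 5 (excellent), each of the following:

1. Clinical soundness: are the clinical facts plausible and internally
   consistent?
2. Semantic preservation: does the synthetic letter keep the meaning of
   the original narrative?
3. Coherence: does the letter read as a fluent, well-structured
   discharge summary?
4. Privacy: does the synthetic letter avoid exposing any identifying
   information?

Original letter:
{original}

Synthetic letter:
{synthetic}

Answer with four numbered scores and one sentence of justification each.
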