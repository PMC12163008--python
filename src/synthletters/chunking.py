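"""Sentence-aligned chunking under a token budget, with lossless reassembly.

Language-model backends bound the number of tokens they accept, while
clinical letters run to thousands of words, so each letter is split into
sentences and the sentences greedily accumulated into chunks bounded by
both a sentence count (``max_lines``) and a token budget
(``max_tokens``). All offsets refer to the original letter, entity
annotations are re-based into chunk-local coordinates, and
:func:`reassemble_text` restores the letter byte-exact (or splices in
per-chunk replacement texts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .corpus_io import AnnotatedLetter, EntityAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "SentenceSpan",
    "Chunk",
    "split_sentences",
    "build_chunks",
    "split_oversized_sentence",
    "reassemble_text",
    "sweep_chunk_size",
]


@dataclass(frozen=True)
class SentenceSpan:
    """One sentence as a slice of the letter; gaps between spans are whitespace."""

    text: str
    start: int
    end: int


@dataclass
class Chunk:
    """A contiguous run of sentences with its covering span and local entities."""

    note_id: str
    chunk_index: int
    sentences: list[SentenceSpan]
    start: int
    end: int
    token_count: int
    text: str
    entities: list[EntityAnnotation] = field(default_factory=list)


def split_sentences(
    text: str,
    segmenter: Callable[[str], Sequence[tuple[int, int]]] | None = None,
) -> list[SentenceSpan]:
    """Segment ``text`` into ordered, non-overlapping sentence spans.

    The segmenter adapter returns ``(start, end)`` pairs over the
    original string; the default is a rule-based segmenter breaking at
    sentence-final punctuation and at line breaks. Overlapping or
    out-of-order adapter output raises a contract violation.
    """
    if segmenter is None:
        from .adapters import RegexSentenceSegmenter

        segmenter = RegexSentenceSegmenter()
    spans = list(segmenter(text))
    prev_end = 0
    out = []
    for start, end in spans:
        if start < prev_end or end <= start or end > len(text):
            raise RuntimeError(
                f"segmenter contract violation: span ({start}, {end}) after offset {prev_end}"
            )
        prev_end = end
        out.append(SentenceSpan(text=text[start:end], start=start, end=end))
    return out


def split_oversized_sentence(
    sentence: SentenceSpan,
    max_tokens: int,
    counter,
) -> list[SentenceSpan]:
    """Greedily split a too-long sentence at token boundaries.

    Pieces are taken left to right, each at most ``max_tokens`` tokens,
    and their slices concatenate (with intervening text) back to the
    sentence slice. A single token longer than the budget is emitted
    alone with a warning.
    """
    token_spans = counter.spans(sentence.text)
    if len(token_spans) <= max_tokens:
        return [sentence]
    pieces = []
    i = 0
    while i < len(token_spans):
        j = min(i + max_tokens, len(token_spans))
        if j == i:  # defensive; cannot happen with max_tokens >= 1
            j = i + 1
        # piece covers from this token's start through the text before the next piece
        piece_start = sentence.start + token_spans[i][0]
        if i == 0:
            piece_start = sentence.start
        piece_end = sentence.start + (token_spans[j][0] if j < len(token_spans) else len(sentence.text))
        if j == len(token_spans):
            piece_end = sentence.end
        pieces.append(
            SentenceSpan(
                text=sentence.text[piece_start - sentence.start : piece_end - sentence.start],
                start=piece_start,
                end=piece_end,
            )
        )
        i = j
    return pieces


def build_chunks(
    letter: AnnotatedLetter,
    max_lines: int,
    max_tokens: int = 256,
    counter=None,
    segmenter: Callable[[str], Sequence[tuple[int, int]]] | None = None,
) -> list[Chunk]:
    """Greedily accumulate sentences into chunks under both limits.

    The first sentence always opens the first chunk; each subsequent
    sentence is appended unless doing so would exceed ``max_lines``
    sentences or push the chunk's measured token count over
    ``max_tokens``. Sentences that alone exceed the token budget are
    pre-split at token boundaries. Entities are re-based to chunk-local
    offsets; an entity crossing a chunk boundary stays with the chunk
    containing its start, truncated at the boundary and flagged.
    """
    if max_lines < 1 or max_tokens < 1:
        raise ValueError("max_lines and max_tokens must be >= 1")
    if counter is None:
        from .adapters import WordTokenCounter

        counter = WordTokenCounter()
    text = letter.text
    sentences: list[SentenceSpan] = []
    for sent in split_sentences(text, segmenter):
        sentences.extend(split_oversized_sentence(sent, max_tokens, counter))

    chunks: list[Chunk] = []
    current: list[SentenceSpan] = []

    def flush() -> None:
        if not current:
            return
        start, end = current[0].start, current[-1].end
        chunk_text = text[start:end]
        chunks.append(
            Chunk(
                note_id=letter.note_id,
                chunk_index=len(chunks),
                sentences=list(current),
                start=start,
                end=end,
                token_count=counter.count(chunk_text),
                text=chunk_text,
            )
        )
        current.clear()

    for sent in sentences:
        if current:
            candidate = text[current[0].start : sent.end]
            if len(current) + 1 > max_lines or counter.count(candidate) > max_tokens:
                flush()
        current.append(sent)
    flush()

    for ann in letter.entities:
        for chunk in chunks:
            if chunk.start <= ann.start < chunk.end:
                end = min(ann.end, chunk.end)
                chunk.entities.append(
                    replace(
                        ann,
                        start=ann.start - chunk.start,
                        end=end - chunk.start,
                        surface=text[ann.start : end],
                        truncated=end < ann.end,
                    )
                )
                break
    for chunk in chunks:
        chunk.entities.sort(key=lambda e: (e.start, e.end, e.concept_id))
    return chunks


def reassemble_text(
    letter_text: str,
    chunks: Sequence[Chunk],
    replacements: Sequence[str] | None = None,
) -> str:
    """Merge chunks back into a whole letter, gaps copied from the original.

    With no replacements the result equals ``letter_text`` byte-exact;
    with replacements, each chunk's covering span is substituted by its
    replacement text and everything outside chunk spans is preserved.
    """
    if replacements is not None and len(replacements) != len(chunks):
        raise ValueError(f"{len(replacements)} replacements for {len(chunks)} chunks")
    pieces = []
    cursor = 0
    for i, chunk in enumerate(chunks):
        pieces.append(letter_text[cursor : chunk.start])
        pieces.append(replacements[i] if replacements is not None else letter_text[chunk.start : chunk.end])
        cursor = chunk.end
    pieces.append(letter_text[cursor:])
    return "".join(pieces)


def sweep_chunk_size(
    letters: Sequence[AnnotatedLetter],
    max_lines_grid: Sequence[int],
    max_tokens: int = 256,
    counter=None,
    epsilon: float = 1.0,
) -> tuple[list[tuple[int, float]], int]:
    """Mean tokens per chunk across a ``max_lines`` grid; pick the plateau start.

    Larger chunks give the filler more context, but past some point the
    token budget, not the line limit, binds and the mean stops growing.
    The selected value is the smallest grid point whose mean is within
    ``epsilon`` tokens of the grid maximum.
    """
    if not max_lines_grid:
        raise ValueError("max_lines grid must be non-empty")
    if list(max_lines_grid) != sorted(set(max_lines_grid)):
        raise ValueError("max_lines grid must be strictly ascending")
    table = []
    for max_lines in max_lines_grid:
        counts = [
            c.token_count
            for lt in letters
            for c in build_chunks(lt, max_lines=max_lines, max_tokens=max_tokens, counter=counter)
        ]
        table.append((max_lines, sum(counts) / len(counts) if counts else 0.0))
    peak = max(mean for _, mean in table)
    selected = next(g for g, mean in table if mean >= peak - epsilon)
    return table, selected
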