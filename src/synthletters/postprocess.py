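"""Post-processing: re-fill privacy placeholders and correct misspellings.

The source corpora mark removed protected health information with runs
of three underscores. Re-predicting those slots with a filler backend
("___ caught a cold" → "patient caught a cold") produces letters that
read naturally while inventing, not leaking, the redacted content.
Spelling correction is word-level and never touches protected spans —
clinical terms are easily misread as misspellings by general-domain
correctors.
"""

from __future__ import annotations

import logging
import re
from typing import Callable, Sequence

from .features import tokenize_with_offsets
from .generation import FillerContract, fill_masks
from .masking import MaskedText, MaskSlot

logger = logging.getLogger(__name__)

__all__ = ["fill_placeholders", "correct_spelling", "DictionaryCorrector"]

_PLACEHOLDER_RE = re.compile(r"_{3,}")


def render_placeholder_masks(text: str, dialect: str, mask_symbol: str = "[MASK]") -> MaskedText:
    """Turn every maximal run of >=3 underscores into one mask slot."""
    slots = []
    pieces = []
    cursor = 0
    for k, m in enumerate(_PLACEHOLDER_RE.finditer(text)):
        symbol = mask_symbol if dialect == "encoder_mask" else f"<extra_id_{k}>"
        pieces.append(text[cursor : m.start()])
        pieces.append(symbol)
        cursor = m.end()
        slots.append(MaskSlot(order=k, token_index=-1, start=m.start(), end=m.end(), original=m.group()))
    pieces.append(text[cursor:])
    return MaskedText(
        text="".join(pieces),
        dialect=dialect,
        mask_symbol=mask_symbol,
        slots=tuple(slots),
        source_text=text,
    )


def fill_placeholders(text: str, filler: FillerContract) -> tuple[str, list[dict]]:
    """Replace each ``___`` placeholder with the filler's prediction.

    Every maximal underscore run of length >= 3 is one slot, whatever
    the redacted content originally held. All non-placeholder characters
    are preserved. Returns the new text and a log of
    ``{start, end, placeholder, prediction}`` records (offsets in the
    input text).
    """
    masked = render_placeholder_masks(text, dialect=filler.dialect, mask_symbol=filler.mask_symbol)
    if not masked.slots:
        return text, []
    predictions = fill_masks(masked, filler)
    log = [
        {"start": s.start, "end": s.end, "placeholder": s.original, "prediction": p}
        for s, p in zip(masked.slots, predictions)
    ]
    pieces, cursor = [], 0
    for slot, pred in zip(masked.slots, predictions):
        pieces.append(text[cursor : slot.start])
        pieces.append(pred)
        cursor = slot.end
    pieces.append(text[cursor:])
    return "".join(pieces), log


class DictionaryCorrector:
    """Word-level corrector targeting adjacent-character transpositions.

    A word absent from the vocabulary is corrected iff some single
    adjacent transposition of it is a known word (ties broken
    lexicographically); anything else is left alone. No context is used.
    """

    def __init__(self, vocabulary: Sequence[str]):
        self.vocabulary = frozenset(w.lower() for w in vocabulary)

    def __call__(self, word: str) -> str | None:
        if len(word) < 3 or not word.isalpha() or word.lower() in self.vocabulary:
            return None
        # swap the original characters (case intact), check lowercase in vocab:
        # un-transposing restores capitals wherever the corruption moved them
        candidates = set()
        for i in range(len(word) - 1):
            if word[i].lower() != word[i + 1].lower():
                cand = word[:i] + word[i + 1] + word[i] + word[i + 2 :]
                if cand.lower() in self.vocabulary:
                    candidates.add(cand)
        return min(candidates) if candidates else None


def correct_spelling(
    text: str,
    corrector: Callable[[str], str | None],
    protected: Sequence[tuple[int, int]] = (),
) -> tuple[str, list[dict]]:
    """Run the corrector over every word outside the protected spans.

    The corrector returns a replacement or ``None`` (leave unchanged);
    an adapter exception leaves the word unchanged and is logged.
    Protected spans are byte-identical in the output. Returns the
    corrected text and a log of ``{start, end, original, corrected}``.
    """
    edits: list[tuple[int, int, str, str]] = []
    for tok in tokenize_with_offsets(text):
        if any(tok.start < e and tok.end > s for s, e in protected):
            continue
        try:
            corrected = corrector(tok.text)
        except Exception:
            logger.warning("spelling adapter failed on %r; left unchanged", tok.text, exc_info=True)
            continue
        if corrected is not None and corrected != tok.text:
            edits.append((tok.start, tok.end, tok.text, corrected))
    out = text
    for start, end, _orig, new in reversed(edits):
        out = out[:start] + new + out[end:]
    log = [
        {"start": s, "end": e, "original": o, "corrected": c} for s, e, o, c in edits
    ]
    return out, log
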