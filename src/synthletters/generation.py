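"""Mask filling, prediction validity, splicing and whole-letter synthesis.

Fillers are pluggable backends behind :class:`FillerContract`: given a
rendered masked text they return exactly one top-scoring prediction per
slot, decoded independently left to right in a single pass. The test
suite and the no-download profile run entirely on deterministic mock
fillers; real masked-language-model adapters satisfy the same contract.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

from .chunking import build_chunks, reassemble_text
from .corpus_io import AnnotatedLetter
from .features import ContractViolation, annotate_features, tokenize_with_offsets
from .masking import MaskedText, MaskPlan, compute_eligibility, render_masked_text, select_mask_targets

__all__ = [
    "FillerContract",
    "FilledChunk",
    "SyntheticLetter",
    "DialectMismatch",
    "fill_masks",
    "classify_prediction",
    "splice_predictions",
    "synthesize_letter",
    "derive_seed",
]


class DialectMismatch(RuntimeError):
    """The filler's dialect does not match the rendered masked text."""


class FillerContract:
    """Base contract every filler backend implements.

    Attributes
    ----------
    name:
        Backend identifier recorded in provenance.
    dialect:
        ``encoder_mask`` (one mask symbol per slot) or
        ``seq2seq_sentinel`` (ordered ``<extra_id_k>`` sentinels with a
        prompt prefix).
    mask_symbol:
        The symbol rendered into encoder-dialect masked text.
    continuation_marker:
        Sub-word continuation prefix of the backend's tokenizer (e.g.
        ``##`` for WordPiece); predictions starting with it are invalid.
    """

    name: str = "abstract"
    dialect: str = "encoder_mask"
    mask_symbol: str = "[MASK]"
    continuation_marker: str | None = None

    def fill(self, masked: MaskedText) -> list[str]:
        raise NotImplementedError


@dataclass
class FilledChunk:
    """Per-slot predictions for one chunk, classified and spliced."""

    plan: MaskPlan
    masked: MaskedText
    predictions: list[str]
    validity: list[str]  # per slot: valid | invalid
    spliced_text: str


def fill_masks(masked: MaskedText, filler: FillerContract) -> list[str]:
    """Run the filler and enforce the one-prediction-per-slot contract."""
    if filler.dialect != masked.dialect:
        raise DialectMismatch(
            f"filler {filler.name!r} speaks {filler.dialect!r} but text was rendered for {masked.dialect!r}"
        )
    predictions = list(filler.fill(masked))
    if len(predictions) != masked.n_slots:
        raise ContractViolation(
            f"filler {filler.name!r} returned {len(predictions)} predictions for {masked.n_slots} slots"
        )
    return predictions


def classify_prediction(pred: str, filler: FillerContract) -> str:
    """``invalid`` iff the prediction is empty/whitespace, has no
    alphanumeric character, or starts with the backend's sub-word
    continuation marker; otherwise ``valid``."""
    if not pred or not pred.strip():
        return "invalid"
    if filler.continuation_marker and pred.startswith(filler.continuation_marker):
        return "invalid"
    if not any(ch.isalnum() for ch in pred):
        return "invalid"
    return "valid"


def splice_predictions(masked: MaskedText, predictions: Sequence[str]) -> str:
    """Substitute each masked token span by its prediction; everything
    outside masked spans stays byte-identical to the source chunk text."""
    if len(predictions) != masked.n_slots:
        raise ContractViolation(
            f"{len(predictions)} predictions for {masked.n_slots} slots"
        )
    pieces = []
    cursor = 0
    for slot, pred in zip(masked.slots, predictions):
        pieces.append(masked.source_text[cursor : slot.start])
        pieces.append(pred)
        cursor = slot.end
    pieces.append(masked.source_text[cursor:])
    return "".join(pieces)


def derive_seed(seed: int, note_id: str, chunk_index: int = 0) -> int:
    """Stable per-chunk sub-seed below 2^31, so subsetting a corpus never
    reshuffles another letter's mask plans."""
    digest = hashlib.sha256(f"{seed}:{note_id}:{chunk_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class SyntheticLetter:
    """One synthesized letter with its masked baseline text and provenance."""

    note_id: str
    original_text: str
    masked_text: str
    text: str
    chunks: list[FilledChunk] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def synthesize_letter(
    letter: AnnotatedLetter,
    config,
    filler: FillerContract,
    seed: int,
) -> SyntheticLetter:
    """Full per-letter pipeline: chunk → features → eligibility → plan →
    render → fill → splice → reassemble.

    ``config`` is a :class:`~synthletters.config.PipelineConfig` (or any
    object with the same chunking/strategy/adapters attributes). The
    masked baseline letter (mask symbols in place) is reassembled
    alongside the synthetic one.
    """
    chunks = build_chunks(
        letter,
        max_lines=config.max_lines,
        max_tokens=config.max_tokens,
        counter=config.counter,
        segmenter=config.segmenter,
    )
    filled: list[FilledChunk] = []
    masked_texts: list[str] = []
    spliced_texts: list[str] = []
    for chunk in chunks:
        tokens = tokenize_with_offsets(chunk.text)
        features = annotate_features(
            chunk.text, tokens=tokens, entities=chunk.entities, adapters=config.adapters
        )
        eligible, forced = compute_eligibility(features, config.strategy)
        plan = select_mask_targets(
            eligible,
            forced,
            features,
            config.strategy,
            seed=derive_seed(seed, letter.note_id, chunk.chunk_index),
            note_id=letter.note_id,
            chunk_index=chunk.chunk_index,
        )
        masked = render_masked_text(
            chunk.text, tokens, plan, dialect=filler.dialect, mask_symbol=filler.mask_symbol
        )
        predictions = fill_masks(masked, filler)
        validity = [classify_prediction(p, filler) for p in predictions]
        spliced = splice_predictions(masked, predictions)
        filled.append(
            FilledChunk(plan=plan, masked=masked, predictions=predictions, validity=validity, spliced_text=spliced)
        )
        masked_texts.append(masked.text)
        spliced_texts.append(spliced)
    return SyntheticLetter(
        note_id=letter.note_id,
        original_text=letter.text,
        masked_text=reassemble_text(letter.text, chunks, masked_texts),
        text=reassemble_text(letter.text, chunks, spliced_texts),
        chunks=filled,
        provenance={
            "strategy": config.strategy.kind,
            "ratio": config.strategy.ratio,
            "deidentify": config.strategy.deidentify,
            "seed": seed,
            "filler": filler.name,
        },
    )
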