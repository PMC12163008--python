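"""Token eligibility, mask-target selection and masked-text rendering.

Seven preservation/masking principles govern which tokens may be masked:
manually annotated clinical entities, document structure, recognized
medical terminology, non-private numbers, punctuation, privacy
placeholders and special patterns are preserved; detected private
information is force-masked when de-identification is on; everything
else is eligible. A strategy (random, nouns-only, verbs-only,
stopwords-only, or a hybrid of per-category components) then selects a
requested fraction *r* of its pool, seeded for replayability.

Two masking ratios are reported per plan: the *eligible* ratio
(strategy-masked tokens over eligible tokens) and the *actual* ratio
(all masked tokens over all tokens) — requested ratios are always
relative to the eligible pool, never to the whole text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import TokenFeatures, TokenSpan

__all__ = [
    "MaskStrategy",
    "MaskPlan",
    "MaskSlot",
    "MaskedText",
    "compute_eligibility",
    "select_mask_targets",
    "render_masked_text",
    "SEQ2SEQ_PROMPT",
    "STRATEGY_KINDS",
]

#: Input prefix prepended for sentinel-style (T5-family) span infilling.
SEQ2SEQ_PROMPT = "Fill in the blanks in the following sentence in the clinical background"

STRATEGY_KINDS = ("random", "pos_noun", "pos_verb", "stopword", "hybrid")
_CATEGORIES = ("random", "noun", "verb", "stopword")
_KIND_TO_CATEGORY = {"random": "random", "pos_noun": "noun", "pos_verb": "verb", "stopword": "stopword"}


@dataclass(frozen=True)
class MaskStrategy:
    """A named masking strategy with its eligible-relative ratio.

    ``kind="hybrid"`` draws independently from several category pools,
    e.g. ``components=[("noun", 0.5), ("stopword", 0.5)]`` masks 50% of
    nouns and 50% of stopwords simultaneously; the masked set is the
    union of the component draws.
    """

    kind: str
    ratio: float = 0.0
    components: tuple[tuple[str, float], ...] = ()
    deidentify: bool = False

    def __post_init__(self) -> None:
        if self.kind not in STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind {self.kind!r}; expected one of {STRATEGY_KINDS}")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"ratio must be in [0, 1], got {self.ratio}")
        if self.kind == "hybrid":
            if not self.components:
                raise ValueError("hybrid strategy requires a non-empty components list")
            for cat, r in self.components:
                if cat not in _CATEGORIES:
                    raise ValueError(f"unknown hybrid category {cat!r}")
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"component ratio must be in [0, 1], got {r}")

    def component_list(self) -> list[tuple[str, float]]:
        if self.kind == "hybrid":
            return list(self.components)
        return [(_KIND_TO_CATEGORY[self.kind], self.ratio)]


@dataclass
class MaskPlan:
    """The resolved mask set for one chunk, fully replayable from its record."""

    note_id: str
    chunk_index: int
    n_tokens: int
    eligible: frozenset[int]
    forced: frozenset[int]
    masked: frozenset[int]
    strategy: MaskStrategy
    seed: int
    #: per component: (category, ratio, pool size, draw count k)
    component_counts: tuple[tuple[str, float, int, int], ...] = ()
    #: tokens drawn by more than one hybrid component (Σk − |union|)
    overlap: int = 0

    @property
    def eligible_ratio(self) -> float:
        """|masked ∖ forced| / |eligible|; 0 when nothing is eligible."""
        if not self.eligible:
            return 0.0
        return len(self.masked - self.forced) / len(self.eligible)

    @property
    def actual_ratio(self) -> float:
        """|masked| / total token count; 0 for an empty chunk."""
        if self.n_tokens == 0:
            return 0.0
        return len(self.masked) / self.n_tokens

    def to_record(self) -> dict:
        return {
            "note_id": self.note_id,
            "chunk_index": self.chunk_index,
            "masked": sorted(self.masked),
            "strategy": self.strategy.kind,
            "ratio": self.strategy.ratio,
            "components": list(self.strategy.components),
            "deidentify": self.strategy.deidentify,
            "seed": self.seed,
            "eligible_ratio": round(self.eligible_ratio, 6),
            "actual_ratio": round(self.actual_ratio, 6),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_record(), sort_keys=True)


def compute_eligibility(
    features: Sequence[TokenFeatures], strategy: MaskStrategy
) -> tuple[frozenset[int], frozenset[int]]:
    """Split token indices into eligible set E and forced set F.

    Precedence: a private token is force-masked (F) when de-identification
    is on and is never eligible; otherwise any preservation flag
    (clinical term, structure, special pattern, punctuation, placeholder,
    number) protects the token; all remaining tokens are eligible.
    """
    eligible: set[int] = set()
    forced: set[int] = set()
    for f in features:
        i = f.token.index
        if f.is_private:
            if strategy.deidentify:
                forced.add(i)
            continue
        if (
            f.is_clinical
            or f.is_structure
            or f.is_special_pattern
            or f.is_punct
            or f.is_placeholder
            or f.is_number
        ):
            continue
        eligible.add(i)
    return frozenset(eligible), frozenset(forced)


def _category_pool(category: str, eligible: frozenset[int], features: Sequence[TokenFeatures]) -> list[int]:
    if category == "random":
        return sorted(eligible)
    if category == "noun":
        return sorted(i for i in eligible if features[i].pos == "noun")
    if category == "verb":
        return sorted(i for i in eligible if features[i].pos == "verb")
    if category == "stopword":
        return sorted(i for i in eligible if features[i].is_stopword)
    raise ValueError(f"unknown category {category!r}")


def select_mask_targets(
    eligible: frozenset[int],
    forced: frozenset[int],
    features: Sequence[TokenFeatures],
    strategy: MaskStrategy,
    seed: int,
    note_id: str = "",
    chunk_index: int = 0,
) -> MaskPlan:
    """Draw mask targets from each component pool; M = union of draws ∪ F.

    Per component the draw count is ``k = ⌊r·|pool| + 0.5⌋`` (nearest
    integer, half up) and the draw is a seeded uniform sample without
    replacement. Draws for growing *r* at a fixed seed are nested
    (prefixes of one seeded shuffle), so the masked count is
    non-decreasing in *r*.
    """
    union: set[int] = set()
    counts: list[tuple[str, float, int, int]] = []
    total_k = 0
    for ci, (category, ratio) in enumerate(strategy.component_list()):
        pool = _category_pool(category, eligible, features)
        k = int(np.floor(ratio * len(pool) + 0.5))
        rng = np.random.default_rng([max(seed, 0), ci])
        order = rng.permutation(len(pool))
        draw = {pool[j] for j in order[:k]}
        union |= draw
        counts.append((category, ratio, len(pool), k))
        total_k += k
    masked = union | set(forced)
    return MaskPlan(
        note_id=note_id,
        chunk_index=chunk_index,
        n_tokens=len(features),
        eligible=eligible,
        forced=frozenset(forced),
        masked=frozenset(masked),
        strategy=strategy,
        seed=seed,
        component_counts=tuple(counts),
        overlap=total_k - len(union),
    )


@dataclass(frozen=True)
class MaskSlot:
    """One masked position: slot order, source token index and span, original surface."""

    order: int
    token_index: int
    start: int
    end: int
    original: str


@dataclass
class MaskedText:
    """Rendered masked text plus the slot map needed to splice fills back."""

    text: str
    dialect: str  # encoder_mask | seq2seq_sentinel
    mask_symbol: str
    slots: tuple[MaskSlot, ...]
    prompt: str = ""
    source_text: str = ""

    @property
    def n_slots(self) -> int:
        return len(self.slots)

    @property
    def model_input(self) -> str:
        """The full backend input (prompt-prefixed for sentinel dialects)."""
        return f"{self.prompt} {self.text}" if self.prompt else self.text


def render_masked_text(
    chunk_text: str,
    tokens: Sequence[TokenSpan],
    plan: MaskPlan,
    dialect: str = "encoder_mask",
    mask_symbol: str = "[MASK]",
    prompt: str = SEQ2SEQ_PROMPT,
) -> MaskedText:
    """Replace each masked token by a mask symbol or an ordered sentinel.

    ``encoder_mask`` substitutes ``mask_symbol`` for every masked token
    span, preserving all inter-token text; ``seq2seq_sentinel``
    substitutes ``<extra_id_k>`` with *k* increasing left to right and
    records the prompt to prepend. One symbol is used per word token.
    """
    if dialect not in ("encoder_mask", "seq2seq_sentinel"):
        raise ValueError(f"unknown dialect {dialect!r}")
    order = sorted(plan.masked)
    slots = []
    pieces = []
    cursor = 0
    for k, idx in enumerate(order):
        tok = tokens[idx]
        symbol = mask_symbol if dialect == "encoder_mask" else f"<extra_id_{k}>"
        pieces.append(chunk_text[cursor : tok.start])
        pieces.append(symbol)
        cursor = tok.end
        slots.append(MaskSlot(order=k, token_index=idx, start=tok.start, end=tok.end, original=tok.text))
    pieces.append(chunk_text[cursor:])
    return MaskedText(
        text="".join(pieces),
        dialect=dialect,
        mask_symbol=mask_symbol,
        slots=tuple(slots),
        prompt=prompt if dialect == "seq2seq_sentinel" else "",
        source_text=chunk_text,
    )
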