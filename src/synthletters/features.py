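"""Per-token feature extraction driving masking eligibility.

Every chunk is tokenized into offset-faithful word tokens, and each token
receives a flag vector: document structure (colon-terminated header
lines), private information (regex rules plus an optional NER adapter),
clinical terms (manual annotations plus an optional clinical NER
adapter), special patterns (medication doses, dotted abbreviations,
comparison expressions), punctuation, numbers, privacy placeholders
(``___``), stopwords, and a coarse part-of-speech tag. The masking
module compiles these flags into an eligibility set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .corpus_io import EntityAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "TokenSpan",
    "TokenFeatures",
    "AdapterBundle",
    "ContractViolation",
    "tokenize_with_offsets",
    "detect_structure",
    "detect_private",
    "detect_clinical_terms",
    "detect_special_patterns",
    "tag_pos",
    "annotate_features",
    "DEFAULT_SPECIAL_PATTERNS",
    "DEFAULT_PRIVACY_RULES",
]


class ContractViolation(RuntimeError):
    """An adapter returned output violating its declared contract."""


@dataclass(frozen=True)
class TokenSpan:
    """One word token with its character offsets inside the chunk text."""

    text: str
    start: int
    end: int
    index: int


@dataclass
class TokenFeatures:
    """Flag vector for one token; precedence is applied at eligibility time."""

    token: TokenSpan
    is_structure: bool = False
    is_private: bool = False
    private_kind: str = "none"  # name|date|location|phone|postcode|email|none
    is_clinical: bool = False
    clinical_source: str = "none"  # manual_annotation|ner_adapter|none
    is_special_pattern: bool = False
    is_punct: bool = False
    is_number: bool = False
    is_placeholder: bool = False
    is_stopword: bool = False
    pos: str = "none"  # noun|verb|other|none


# "___" privacy placeholders kept whole; words keep internal apostrophes;
# numbers keep decimal points; every other character is its own token.
_TOKEN_RE = re.compile(r"_{3,}|[A-Za-z]+(?:['’][A-Za-z]+)*|\d+(?:\.\d+)?|\S")

_NUMBER_RE = re.compile(r"^\d+(?:\.\d+)?$")


def tokenize_with_offsets(text: str) -> list[TokenSpan]:
    """Offset-faithful word tokenization; ``chunk_text[start:end] == text``."""
    return [
        TokenSpan(text=m.group(), start=m.start(), end=m.end(), index=i)
        for i, m in enumerate(_TOKEN_RE.finditer(text))
    ]


# ---------------------------------------------------------------------------
# structure

_HEADER_FUNCTION_WORDS = frozenset({"of", "on", "at", "to", "in", "and", "or", "for", "the", "a", "an"})


def detect_structure(
    chunk_text: str,
    tokens: Sequence[TokenSpan],
    max_header_tokens: int = 6,
    require_capitalized: bool = True,
) -> list[bool]:
    """Flag tokens on colon-terminated header lines.

    A physical line qualifies when it ends with ``:`` (after optional
    trailing whitespace), has at most ``max_header_tokens`` tokens before
    the colon, and (optionally) every alphabetic word is capitalized or
    all-caps — lowercase function words are allowed mid-header, as in
    ``History of Present Illness:``. All tokens on a qualifying line are
    flagged, the colon included. A colon in mid-line (``Seen at 12:30``)
    never qualifies.
    """
    flags = [False] * len(tokens)
    pos = 0
    for line in chunk_text.splitlines(keepends=True):
        start, end = pos, pos + len(line)
        pos = end
        stripped = line.rstrip("\r\n").rstrip()
        if not stripped.endswith(":"):
            continue
        line_tokens = [t for t in tokens if t.start >= start and t.end <= end]
        pre_colon = [t for t in line_tokens if t.text != ":"]
        if len(pre_colon) == 0 or len(pre_colon) > max_header_tokens:
            continue
        words = [t.text for t in pre_colon if t.text[:1].isalpha()]
        if require_capitalized and not all(
            w[0].isupper() or w.isupper() or w.lower() in _HEADER_FUNCTION_WORDS
            for w in words
        ):
            continue
        for t in line_tokens:
            flags[t.index] = True
    return flags


# ---------------------------------------------------------------------------
# privacy

DEFAULT_PRIVACY_RULES: dict[str, str] = {
    "email": r"\b[A-Za-z0-9._%+-]+@[A-Za-z0-9.-]+\.[A-Za-z]{2,}\b",
    # 7+ digits with optional separators/parentheses, e.g. (555) 123-4567
    "phone": r"(?<!\w)(?:\+?\d{1,3}[\s.-]?)?\(?\d{3}\)?[\s.-]?\d{3}[\s.-]?\d{4}(?!\w)",
    # UK (M1 1AA style) and US ZIP(+4) postal codes
    "postcode": r"\b(?:[A-Z]{1,2}\d[A-Z\d]?\s*\d[A-Z]{2}|\d{5}(?:-\d{4})?)\b",
    "date": r"\b\d{1,2}[/-]\d{1,2}[/-]\d{2,4}\b|\b\d{4}-\d{2}-\d{2}\b",
    # bare long digit runs (MRNs, account numbers)
    "phone_like_digits": r"(?<!\d)\d{6,}(?!\d)",
}

_PRIVACY_KIND_MAP = {"phone_like_digits": "phone"}


def detect_private(
    chunk_text: str,
    tokens: Sequence[TokenSpan],
    ner: Callable[[str], Iterable[tuple[int, int, str]]] | None = None,
    rules: dict[str, str] | None = None,
) -> tuple[list[bool], list[str]]:
    """Union of regex rule matches and NER-adapter spans of kinds name/date/location.

    The adapter, when present, returns ``(start, end, kind)`` spans over the
    chunk text. On adapter failure the detector degrades to rules-only with
    a warning. Returns per-token flags and kinds.
    """
    flags = [False] * len(tokens)
    kinds = ["none"] * len(tokens)

    def mark(start: int, end: int, kind: str) -> None:
        for t in tokens:
            if t.start < end and t.end > start:
                flags[t.index] = True
                if kinds[t.index] == "none":
                    kinds[t.index] = kind

    for name, pattern in (rules if rules is not None else DEFAULT_PRIVACY_RULES).items():
        kind = _PRIVACY_KIND_MAP.get(name, name)
        for m in re.finditer(pattern, chunk_text):
            mark(m.start(), m.end(), kind)
    if ner is not None:
        try:
            spans = list(ner(chunk_text))
        except Exception:  # adapter failure -> degrade to rules-only
            logger.warning("privacy NER adapter failed; using rules only", exc_info=True)
            spans = []
        for start, end, kind in spans:
            if kind in ("name", "date", "location"):
                mark(start, end, kind)
    return flags, kinds


# ---------------------------------------------------------------------------
# clinical terms


def detect_clinical_terms(
    tokens: Sequence[TokenSpan],
    entities: Sequence[EntityAnnotation] = (),
    ner: Callable[[str], Iterable[tuple[int, int, str]]] | None = None,
    chunk_text: str = "",
) -> tuple[list[bool], list[str]]:
    """Flag tokens covered by manual annotations or clinical-NER spans.

    Manual annotations (chunk-local offsets) always win the recorded
    source; adapter absence never removes manual flags.
    """
    flags = [False] * len(tokens)
    sources = ["none"] * len(tokens)
    for ann in entities:
        for t in tokens:
            if t.start < ann.end and t.end > ann.start:
                flags[t.index] = True
                sources[t.index] = "manual_annotation"
    if ner is not None:
        try:
            spans = list(ner(chunk_text))
        except Exception:
            logger.warning("clinical NER adapter failed; manual annotations only", exc_info=True)
            spans = []
        for start, end, _label in spans:
            for t in tokens:
                if t.start < end and t.end > start and not flags[t.index]:
                    flags[t.index] = True
                    sources[t.index] = "ner_adapter"
    return flags, sources


# ---------------------------------------------------------------------------
# special patterns

_UNITS = r"(?:mcg|mg|ml|mL|g|kg|L|units?|mEq|mmol|hrs?|h)"

DEFAULT_SPECIAL_PATTERNS: dict[str, str] = {
    # enoxaparin 40 mg/0.4 ml ; Vitamin C ^1,000 mg ; 2 g
    "dose": rf"[\^]?\d[\d,]*(?:\.\d+)?\s*{_UNITS}(?:\s*/\s*\d[\d,]*(?:\.\d+)?\s*{_UNITS})?\b",
    # Ibuprofen > 200 mg
    "comparison_dose": rf"[<>=≤≥]\s*\d[\d,]*(?:\.\d+)?(?:\s*{_UNITS})?\b",
    # b.i.d., q.d., p.r.n.
    "dotted_abbrev": r"\b(?:[A-Za-z]\.){2,}",
}


def compile_patterns(patterns: dict[str, str]) -> dict[str, re.Pattern]:
    """Compile a user pattern registry, raising a config error on bad regexes."""
    compiled = {}
    for name, pattern in patterns.items():
        try:
            compiled[name] = re.compile(pattern)
        except re.error as exc:
            raise ValueError(f"invalid special-pattern regex {name!r}: {exc}") from exc
    return compiled


def detect_special_patterns(
    chunk_text: str,
    tokens: Sequence[TokenSpan],
    patterns: dict[str, str] | None = None,
) -> list[bool]:
    """Flag tokens overlapping any registry match (doses, notations, comparisons)."""
    flags = [False] * len(tokens)
    for pat in compile_patterns(
        patterns if patterns is not None else DEFAULT_SPECIAL_PATTERNS
    ).values():
        for m in pat.finditer(chunk_text):
            for t in tokens:
                if t.start < m.end() and t.end > m.start():
                    flags[t.index] = True
    return flags


# ---------------------------------------------------------------------------
# POS


def tag_pos(
    tokens: Sequence[TokenSpan],
    tagger: Callable[[Sequence[str]], Sequence[str]],
    noun_prefixes: tuple[str, ...] = ("NN",),
    verb_prefixes: tuple[str, ...] = ("VB",),
) -> list[str]:
    """Map a fine-grained tagger's output to coarse {noun, verb, other} buckets."""
    fine = list(tagger([t.text for t in tokens]))
    if len(fine) != len(tokens):
        raise ContractViolation(
            f"POS tagger returned {len(fine)} tags for {len(tokens)} tokens"
        )
    coarse = []
    for tag in fine:
        if any(tag.startswith(p) for p in noun_prefixes):
            coarse.append("noun")
        elif any(tag.startswith(p) for p in verb_prefixes):
            coarse.append("verb")
        else:
            coarse.append("other")
    return coarse


# ---------------------------------------------------------------------------
# bundle


@dataclass
class AdapterBundle:
    """Pluggable backends for feature extraction; every member has a
    deterministic built-in default so the pipeline runs with no downloads."""

    pos_tagger: Callable[[Sequence[str]], Sequence[str]] | None = None
    privacy_ner: Callable[[str], Iterable[tuple[int, int, str]]] | None = None
    clinical_ner: Callable[[str], Iterable[tuple[int, int, str]]] | None = None
    privacy_rules: dict[str, str] | None = None
    special_patterns: dict[str, str] | None = None
    stopwords: frozenset[str] | None = None
    header_max_tokens: int = 6


def _is_punct(text: str) -> bool:
    return not any(ch.isalnum() for ch in text) and not set(text) == {"_"}


def annotate_features(
    chunk_text: str,
    tokens: Sequence[TokenSpan] | None = None,
    entities: Sequence[EntityAnnotation] = (),
    adapters: AdapterBundle | None = None,
    stopword_list: frozenset[str] | None = None,
) -> list[TokenFeatures]:
    """Run every detector and classifier; one TokenFeatures per token.

    Stopword membership is case-insensitive. Extraction is pure: the same
    chunk text, entities and adapters always yield identical flags.
    """
    adapters = adapters or AdapterBundle()
    if tokens is None:
        tokens = tokenize_with_offsets(chunk_text)
    if stopword_list is None:
        stopword_list = adapters.stopwords if adapters.stopwords is not None else load_stopwords()

    structure = detect_structure(chunk_text, tokens, max_header_tokens=adapters.header_max_tokens)
    private, private_kinds = detect_private(
        chunk_text, tokens, ner=adapters.privacy_ner, rules=adapters.privacy_rules
    )
    clinical, clinical_sources = detect_clinical_terms(
        tokens, entities=entities, ner=adapters.clinical_ner, chunk_text=chunk_text
    )
    special = detect_special_patterns(chunk_text, tokens, patterns=adapters.special_patterns)
    if adapters.pos_tagger is not None:
        pos = tag_pos(tokens, adapters.pos_tagger)
    else:
        from .adapters import LexiconPOSTagger

        pos = tag_pos(tokens, LexiconPOSTagger())

    out = []
    for t in tokens:
        i = t.index
        out.append(
            TokenFeatures(
                token=t,
                is_structure=structure[i],
                is_private=private[i],
                private_kind=private_kinds[i],
                is_clinical=clinical[i],
                clinical_source=clinical_sources[i],
                is_special_pattern=special[i],
                is_punct=_is_punct(t.text),
                is_number=bool(_NUMBER_RE.match(t.text)),
                is_placeholder=set(t.text) == {"_"} and len(t.text) >= 3,
                is_stopword=t.text.lower() in stopword_list,
                pos=pos[i],
            )
        )
    return out


_STOPWORDS_CACHE: frozenset[str] | None = None


def load_stopwords() -> frozenset[str]:
    """Load the shipped English stopword list (editable data file)."""
    global _STOPWORDS_CACHE
    if _STOPWORDS_CACHE is None:
        from importlib.resources import files

        raw = files("synthletters.data").joinpath("stopwords.txt").read_text()
        _STOPWORDS_CACHE = frozenset(w.strip().lower() for w in raw.splitlines() if w.strip())
    return _STOPWORDS_CACHE
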