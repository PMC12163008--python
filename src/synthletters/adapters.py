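"""Deterministic built-in adapters for every pluggable backend.

The pipeline talks to sentence segmenters, token counters, POS taggers,
NER tools, fillers and embedders only through narrow contracts, so that
large pretrained backends can be swapped in where available. The
implementations here are rule-based and fully deterministic: the whole
pipeline, its tests and its evaluation run with no model downloads.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .features import tokenize_with_offsets
from .generation import FillerContract
from .masking import MaskedText

__all__ = [
    "RegexSentenceSegmenter",
    "WordTokenCounter",
    "LexiconPOSTagger",
    "IdentityFiller",
    "ConstantFiller",
    "LexiconFiller",
    "NoisyFiller",
    "OneHotEmbedder",
    "HashingDocEmbedder",
    "UniformLanguageModel",
    "SubjectivityLexicon",
    "GazetteerTagger",
    "MemorizingTrainer",
]


# ---------------------------------------------------------------------------
# segmentation and counting


class RegexSentenceSegmenter:
    """Rule-based sentence segmenter returning (start, end) spans.

    Breaks after sentence-final punctuation (``.``, ``!``, ``?``)
    followed by whitespace, and at line breaks — clinical letters place
    headers and medication lines on their own physical lines. Spans are
    trimmed of surrounding whitespace; inter-span gaps are whitespace
    only, so chunk reassembly is lossless.
    """

    _BREAK = re.compile(r"(?<=[.!?])\s+")

    def __call__(self, text: str) -> list[tuple[int, int]]:
        spans: list[tuple[int, int]] = []
        offset = 0
        for line in text.splitlines(keepends=True):
            content = line.rstrip("\r\n")
            pieces, cursor = [], 0
            for m in self._BREAK.finditer(content):
                pieces.append((cursor, m.start()))
                cursor = m.end()
            pieces.append((cursor, len(content)))
            for s, e in pieces:
                seg = content[s:e]
                lead = len(seg) - len(seg.lstrip())
                trail = len(seg) - len(seg.rstrip())
                if seg.strip():
                    spans.append((offset + s + lead, offset + e - trail))
            offset += len(line)
        return spans


class WordTokenCounter:
    """Token counter measuring word tokens of the feature tokenizer.

    A filler backend may supply its own counter (the budget exists to
    satisfy the model); this default keeps counts reproducible without
    any model tokenizer.
    """

    def count(self, text: str) -> int:
        return len(tokenize_with_offsets(text))

    def spans(self, text: str) -> list[tuple[int, int]]:
        return [(t.start, t.end) for t in tokenize_with_offsets(text)]


# ---------------------------------------------------------------------------
# POS tagging

_PRONOUNS = {"i", "you", "he", "she", "it", "we", "they", "him", "her", "them", "his", "hers", "their", "its", "this", "that", "these", "those"}
_DETERMINERS = {"a", "an", "the", "no", "any", "some", "each", "every", "all", "both"}
_PREPOSITIONS = {"of", "in", "on", "at", "to", "from", "with", "for", "by", "about", "as", "into", "during", "after", "before", "over", "under", "w"}
_CONJUNCTIONS = {"and", "or", "but", "if", "while", "because", "than", "so", "nor"}
_AUX = {"is", "are", "was", "were", "be", "been", "being", "am", "has", "have", "had", "do", "does", "did", "will", "would", "can", "could", "may", "might", "shall", "should", "must"}
_ADVERBS_LY = re.compile(r"^[a-z]+ly$")

#: Irregular and clinical-register verbs the suffix rules would miss.
_VERB_LEXICON = {
    "fell", "felt", "saw", "came", "went", "took", "gave", "got", "found",
    "underwent", "began", "ate", "drank", "woke", "broke", "spoke", "told",
    "said", "made", "kept", "left", "sent", "met", "ran", "sat", "lay",
    "denies", "reports", "presents", "presenting", "complains", "states",
    "takes", "take", "continue", "follow", "call", "return", "seek", "rest",
    "caught", "remains", "improved", "tolerated", "ambulating", "feels",
}

_ADJECTIVES = {
    "healthy", "stable", "mild", "moderate", "severe", "acute", "chronic",
    "normal", "abnormal", "elevated", "low", "high", "old", "new", "well",
    "alert", "oriented", "afebrile", "intact", "clear", "soft", "tender",
    "nontender", "previously", "daily", "further", "male", "female",
}


class LexiconPOSTagger:
    """Heuristic fine-grained POS tagger (Penn-style tags).

    Function words, auxiliaries, ``-ly`` adverbs and a small verb/
    adjective lexicon are tagged by lookup; ``-ed``/``-ing``/``-s``(after
    a known verb stem) forms as verbs; remaining alphabetic words default
    to nouns — a deliberate noun-heavy default that matches the
    clinical-letter register, where content words are dominated by
    nominal terms. Deterministic and dependency-free; any tagger
    returning one fine tag per token can replace it.
    """

    def __call__(self, words: Sequence[str]) -> list[str]:
        tags = []
        for w in words:
            lw = w.lower()
            if not w or not any(ch.isalnum() for ch in w):
                tags.append(".")
            elif w.replace(".", "").replace(",", "").isdigit():
                tags.append("CD")
            elif lw in _PRONOUNS:
                tags.append("PRP")
            elif lw in _DETERMINERS:
                tags.append("DT")
            elif lw in _PREPOSITIONS:
                tags.append("IN")
            elif lw in _CONJUNCTIONS:
                tags.append("CC")
            elif lw in _AUX:
                tags.append("MD" if lw in ("will", "would", "can", "could", "may", "might", "shall", "should", "must") else "VBZ")
            elif lw in _VERB_LEXICON:
                tags.append("VBD")
            elif lw.endswith("ing") and len(lw) > 4:
                tags.append("VBG")
            elif lw.endswith("ed") and len(lw) > 3:
                tags.append("VBD")
            elif lw in _ADJECTIVES or _ADVERBS_LY.match(lw):
                tags.append("JJ")
            elif lw.isalpha():
                tags.append("NN")
            else:
                tags.append("NN")
        return tags


# ---------------------------------------------------------------------------
# fillers


class IdentityFiller(FillerContract):
    """Test backend returning each slot's original token.

    Exists to prove pipeline losslessness: with this filler the
    synthetic letter must equal the original byte-exact for every
    strategy, ratio and seed.
    """

    name = "identity"

    def __init__(self, dialect: str = "encoder_mask"):
        self.dialect = dialect

    def fill(self, masked: MaskedText) -> list[str]:
        return [slot.original for slot in masked.slots]


class ConstantFiller(FillerContract):
    """Backend predicting the same word for every slot."""

    def __init__(self, word: str = "patient", dialect: str = "encoder_mask"):
        self.word = word
        self.dialect = dialect
        self.name = f"constant:{word}"

    def fill(self, masked: MaskedText) -> list[str]:
        return [self.word] * masked.n_slots


_DEFAULT_FILL_VOCAB = (
    "patient", "hospital", "stable", "noted", "reviewed", "normal",
    "continued", "daily", "mild", "improved", "routine", "history",
    "observed", "admitted", "recommended", "tolerated", "clinic", "further",
)


class LexiconFiller(FillerContract):
    """Deterministic mock language model choosing words from a fixed vocabulary.

    The choice for a slot is a stable hash of (seed, left context,
    slot order), so identical inputs always reproduce identical
    predictions, imitating a greedy top-1 decoder without any model.
    """

    def __init__(
        self,
        vocabulary: Sequence[str] = _DEFAULT_FILL_VOCAB,
        seed: int = 0,
        dialect: str = "encoder_mask",
    ):
        self.vocabulary = tuple(vocabulary)
        self.seed = seed
        self.dialect = dialect
        self.name = f"lexicon:{seed}"

    def fill(self, masked: MaskedText) -> list[str]:
        preds = []
        for slot in masked.slots:
            context = masked.source_text[max(0, slot.start - 24) : slot.start]
            digest = hashlib.sha256(f"{self.seed}|{context}|{slot.order}".encode()).digest()
            preds.append(self.vocabulary[int.from_bytes(digest[:4], "big") % len(self.vocabulary)])
        return preds


class NoisyFiller(FillerContract):
    """Wrap a filler so a seeded fraction of slots yields invalid output
    (punctuation or sub-word continuation pieces), emulating the failure
    modes of real masked-language models."""

    _INVALID = (",", "##s", ".", "##ing", "")

    def __init__(self, base: FillerContract, invalid_rate: float = 0.1, seed: int = 0):
        if not 0.0 <= invalid_rate <= 1.0:
            raise ValueError("invalid_rate must be in [0, 1]")
        self.base = base
        self.invalid_rate = invalid_rate
        self.seed = seed
        self.name = f"noisy({base.name}, {invalid_rate})"
        self.dialect = base.dialect
        self.mask_symbol = base.mask_symbol
        self.continuation_marker = "##"

    def fill(self, masked: MaskedText) -> list[str]:
        preds = self.base.fill(masked)
        rng = np.random.default_rng([self.seed, len(masked.source_text)])
        out = []
        for slot, pred in zip(masked.slots, preds):
            if rng.random() < self.invalid_rate:
                out.append(self._INVALID[int(rng.integers(len(self._INVALID)))])
            else:
                out.append(pred)
        return out


# ---------------------------------------------------------------------------
# embedders and language models


class OneHotEmbedder:
    """Token embedder assigning every distinct surface its own axis.

    Under this embedder greedy-match BERTScore reduces to exact-match
    token overlap — the hand-checkable floor of the semantic metric.
    """

    def __call__(self, tokens: Sequence[str]) -> np.ndarray:
        vocab = {t: i for i, t in enumerate(dict.fromkeys(tokens))}
        mat = np.zeros((len(tokens), max(len(vocab), 1)))
        for row, tok in enumerate(tokens):
            mat[row, vocab[tok]] = 1.0
        return mat


class PairedVocabularyEmbedder:
    """One-hot embedder over a shared vocabulary fixed at construction,
    so candidate and reference tokens embed into the same space."""

    def __init__(self, vocabulary: Sequence[str]):
        self.vocab = {t: i for i, t in enumerate(dict.fromkeys(vocabulary))}

    def __call__(self, tokens: Sequence[str]) -> np.ndarray:
        mat = np.zeros((len(tokens), max(len(self.vocab), 1) + 1))
        for row, tok in enumerate(tokens):
            mat[row, self.vocab.get(tok, len(self.vocab))] = 1.0
        return mat


class HashingDocEmbedder:
    """Document embedder: a hashed bag-of-words vector (stable across runs).

    A stand-in for contextual document embeddings: cosine similarity
    under it measures vocabulary overlap weighted by term frequency.
    """

    def __init__(self, dim: int = 256, lowercase: bool = True):
        self.dim = dim
        self.lowercase = lowercase

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim)
        for tok in tokenize_with_offsets(text):
            word = tok.text.lower() if self.lowercase else tok.text
            h = int.from_bytes(hashlib.md5(word.encode()).digest()[:4], "big")
            vec[h % self.dim] += 1.0
        return vec


class UniformLanguageModel:
    """Stub causal LM assigning every word probability 1/V; its perplexity
    is exactly V, the closed-form check for the perplexity plumbing."""

    def __init__(self, vocab_size: int):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.vocab_size = vocab_size

    def log_probs(self, words: Sequence[str]) -> list[float]:
        return [-float(np.log(self.vocab_size))] * len(words)


class SubjectivityLexicon:
    """Word-lexicon subjectivity scorer in [0, 1]; mean over matched words."""

    _DEFAULT = {
        "good": 0.6, "bad": 0.7, "great": 0.8, "terrible": 0.9, "well": 0.4,
        "unfortunately": 0.9, "hopefully": 0.9, "severe": 0.6, "mild": 0.4,
        "significant": 0.5, "normal": 0.2, "stable": 0.3, "unremarkable": 0.3,
        "worst": 1.0, "best": 1.0, "comfortable": 0.7, "healthy": 0.5,
    }

    def __init__(self, lexicon: dict[str, float] | None = None):
        self.lexicon = dict(self._DEFAULT if lexicon is None else lexicon)

    def __call__(self, text: str) -> float:
        scores = [
            self.lexicon[t.text.lower()]
            for t in tokenize_with_offsets(text)
            if t.text.lower() in self.lexicon
        ]
        return float(np.mean(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# NER taggers (downstream harness)


class GazetteerTagger:
    """Reference tagger matching a surface→label gazetteer over raw text.

    Whole-word occurrences of each gazetteer surface are emitted as
    labeled spans; overlap resolution is left to the harness
    (longest-first).
    """

    def __init__(self, gazetteer: dict[str, str]):
        self.gazetteer = dict(gazetteer)

    def __call__(self, text: str) -> list[tuple[int, int, str]]:
        spans = []
        for surface, label in self.gazetteer.items():
            pattern = r"(?<![A-Za-z0-9])" + re.escape(surface) + r"(?![A-Za-z0-9])"
            for m in re.finditer(pattern, text):
                spans.append((m.start(), m.end(), label))
        return sorted(spans)


@dataclass
class MemorizingTrainer:
    """Trainable-tagger adapter that memorizes training surfaces.

    Training collects every (surface, label) pair from the silver
    annotations into a gazetteer; prediction is gazetteer matching. A
    genuine, if minimal, learner: it generalizes to unseen documents
    exactly in so far as they reuse training surfaces.
    """

    case_sensitive: bool = True

    def train(self, docs: Sequence, seed: int = 0) -> GazetteerTagger:
        gazetteer: dict[str, str] = {}
        for doc in docs:
            for start, end, label in doc.entities:
                gazetteer.setdefault(doc.text[start:end], label)
        return GazetteerTagger(gazetteer)
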