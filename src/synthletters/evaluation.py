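"""Quantitative evaluation of synthetic letters against masked baselines.

Every similarity metric (ROUGE-1/2/L, BERTScore, METEOR, document
cosine) is computed twice per letter: synthetic vs. original
("generation") and masked text vs. original ("baseline"). The baseline
is the floor a filler must beat — a score below it means the model did
worse than leaving mask symbols in place — while a score of exactly the
maximum means nothing changed. Readability (Flesch Reading Ease,
Flesch–Kincaid grade, SMOG), word-frequency entropy and subjectivity
are computed per text variant, and the invalid prediction rate
summarizes filler failures (punctuation, empty or sub-word outputs).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "rouge_scores",
    "bertscore_f1",
    "meteor_score",
    "readability_scores",
    "ReadabilityScores",
    "text_quality_scores",
    "invalid_prediction_rate",
    "clinical_similarity",
    "evaluate_corpus",
    "EvalReport",
]

_WORD_RE = re.compile(r"[a-z0-9]+")


def _words(text: str) -> list[str]:
    return _WORD_RE.findall(text.lower())


# ---------------------------------------------------------------------------
# ROUGE


def _overlap_f(cand: list, ref: list) -> float:
    if not cand and not ref:
        return 1.0
    if not cand or not ref:
        return 0.0
    matches = sum((Counter(cand) & Counter(ref)).values())
    p, r = matches / len(cand), matches / len(ref)
    return 2 * p * r / (p + r) if p + r else 0.0


def _lcs_len(a: list[str], b: list[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, 1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def rouge_scores(candidate: str, reference: str) -> tuple[float, float, float]:
    """ROUGE-1, ROUGE-2 and ROUGE-L F-measures on word tokens, × 100.

    Tokens are lowercased alphanumeric words, no stemming. Two texts
    whose n-gram multisets are both empty score 100 at that order
    (vacuous identity); one-sided emptiness scores 0.
    """
    c, r = _words(candidate), _words(reference)
    if not c and not r:
        return 100.0, 100.0, 100.0
    if not c or not r:
        return 0.0, 0.0, 0.0
    r1 = _overlap_f(c, r)
    r2 = _overlap_f(list(zip(c, c[1:])), list(zip(r, r[1:])))
    lcs = _lcs_len(c, r)
    p, rec = lcs / len(c), lcs / len(r)
    rl = 2 * p * rec / (p + rec) if p + rec else 0.0
    return 100 * r1, 100 * r2, 100 * rl


# ---------------------------------------------------------------------------
# BERTScore


def bertscore_f1(
    candidate: str,
    reference: str,
    embedder: Callable[[Sequence[str]], np.ndarray] | None = None,
) -> float:
    """Greedy-match BERTScore F1, unrescaled.

    The embedder is called once on the concatenated candidate+reference
    token list (so per-pair embedders like one-hot share a space) and
    must return one vector per token. Precision is the mean over
    candidate tokens of the best cosine against any reference token,
    recall the converse; F1 is their harmonic mean.
    """
    c, r = _words(candidate), _words(reference)
    if not c or not r:
        raise ValueError("bertscore_f1 requires non-empty candidate and reference")
    if embedder is None:
        from .adapters import OneHotEmbedder

        embedder = OneHotEmbedder()
    emb = np.asarray(embedder(c + r), dtype=float)
    if emb.shape[0] != len(c) + len(r):
        raise ValueError("embedder must return one vector per token")
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    sim = emb[: len(c)] @ emb[len(c) :].T
    precision = float(sim.max(axis=1).mean())
    recall = float(sim.max(axis=0).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# METEOR (exact-match stage; stemming/synonym stages are adapter territory)


def meteor_score(candidate: str, reference: str) -> float:
    """Unigram-match METEOR with the standard fragmentation penalty.

    F_mean = 10PR/(R + 9P); penalty = 0.5 · (chunks/matches)³;
    score = F_mean · (1 − penalty). Matching is exact (first-unmatched
    greedy alignment); no stemming or synonymy.
    """
    c, r = _words(candidate), _words(reference)
    if not c or not r:
        return 0.0
    taken = [False] * len(r)
    pairs: list[tuple[int, int]] = []
    for i, w in enumerate(c):
        for j, v in enumerate(r):
            if not taken[j] and v == w:
                taken[j] = True
                pairs.append((i, j))
                break
    m = len(pairs)
    if m == 0:
        return 0.0
    p, rec = m / len(c), m / len(r)
    f_mean = 10 * p * rec / (rec + 9 * p)
    chunks = 1
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        if i1 != i0 + 1 or j1 != j0 + 1:
            chunks += 1
    penalty = 0.5 * (chunks / m) ** 3
    return f_mean * (1 - penalty)


# ---------------------------------------------------------------------------
# readability


def _count_syllables(word: str) -> int:
    w = "".join(ch for ch in word.lower() if ch.isalpha())
    if not w:
        return 1
    groups = re.findall(r"[aeiouy]+", w)
    n = len(groups)
    if w.endswith("e") and not w.endswith(("le", "ee", "ye")) and n > 1:
        n -= 1
    return max(n, 1)


@dataclass(frozen=True)
class ReadabilityScores:
    flesch_reading_ease: float
    flesch_kincaid_grade: float
    smog: float
    n_sentences: int
    n_words: int
    #: SMOG was designed for 30+ sentence samples; short letters are flagged
    below_smog_range: bool


def readability_scores(text: str) -> ReadabilityScores:
    """Flesch Reading Ease, Flesch–Kincaid grade and SMOG.

    FRE = 206.835 − 1.015·(words/sentences) − 84.6·(syllables/words);
    FKGL = 0.39·(words/sentences) + 11.8·(syllables/words) − 15.59;
    SMOG = 1.0430·√(polysyllables · 30/sentences) + 3.1291,
    where polysyllables are words of three or more syllables.
    """
    from .chunking import split_sentences
    from .features import tokenize_with_offsets

    sentences = split_sentences(text)
    words = [t.text for t in tokenize_with_offsets(text) if any(ch.isalnum() for ch in t.text)]
    if not sentences or not words:
        raise ValueError("readability requires at least one sentence with words")
    n_sent, n_words = len(sentences), len(words)
    syllables = sum(_count_syllables(w) for w in words)
    poly = sum(1 for w in words if _count_syllables(w) >= 3)
    fre = 206.835 - 1.015 * (n_words / n_sent) - 84.6 * (syllables / n_words)
    fkgl = 0.39 * (n_words / n_sent) + 11.8 * (syllables / n_words) - 15.59
    smog = 1.0430 * math.sqrt(poly * 30 / n_sent) + 3.1291
    return ReadabilityScores(
        flesch_reading_ease=fre,
        flesch_kincaid_grade=fkgl,
        smog=smog,
        n_sentences=n_sent,
        n_words=n_words,
        below_smog_range=n_sent < 30,
    )


# ---------------------------------------------------------------------------
# entropy / subjectivity / perplexity


def text_quality_scores(
    text: str,
    lm=None,
    lexicon: Callable[[str], float] | None = None,
) -> dict[str, float]:
    """Word-frequency Shannon entropy (bits), subjectivity, optional perplexity.

    Entropy is over the empirical word-frequency distribution, base 2.
    Perplexity is ``exp(−mean log p)`` under the causal-LM adapter and
    omitted when no adapter is configured.
    """
    words = _words(text)
    out: dict[str, float] = {}
    if words:
        freqs = np.array(list(Counter(words).values()), dtype=float)
        p = freqs / freqs.sum()
        out["entropy"] = float(-(p * np.log2(p)).sum())
    else:
        out["entropy"] = 0.0
    if lexicon is None:
        from .adapters import SubjectivityLexicon

        lexicon = SubjectivityLexicon()
    out["subjectivity"] = float(lexicon(text))
    if lm is not None and words:
        log_probs = np.asarray(lm.log_probs(words), dtype=float)
        out["perplexity"] = float(np.exp(-log_probs.mean()))
    return out


def invalid_prediction_rate(filled: Sequence) -> float:
    """Invalid predictions over all masked predictions, across a run."""
    total = sum(len(fc.predictions) for fc in filled)
    if total == 0:
        raise ValueError("no masked predictions")
    invalid = sum(v == "invalid" for fc in filled for v in fc.validity)
    return invalid / total


def clinical_similarity(
    original: str,
    synthetic: str,
    embedder: Callable[[str], np.ndarray] | None = None,
) -> float:
    """Cosine similarity between document embeddings of the two letters."""
    if embedder is None:
        from .adapters import HashingDocEmbedder

        embedder = HashingDocEmbedder()
    a = np.asarray(embedder(original), dtype=float)
    b = np.asarray(embedder(synthetic), dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero document vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# corpus report

_SIMILARITY_METRICS = ("rouge1", "rouge2", "rougeL", "bertscore_f1", "meteor", "clinical_cosine")


@dataclass
class EvalReport:
    """Per-letter metric table plus corpus aggregates.

    ``per_letter`` is long-form: columns ``note_id, metric, variant,
    value``. Similarity metrics carry variants ``generation``
    (synthetic vs original) and ``baseline`` (masked vs original);
    intrinsic metrics carry ``original``, ``masked``, ``synthetic``.
    """

    per_letter: pd.DataFrame
    invalid_rate: float | None = None

    def summary(self) -> pd.DataFrame:
        """Corpus means: metric rows × variant columns."""
        return self.per_letter.pivot_table(index="metric", columns="variant", values="value", aggfunc="mean")

    def to_csv(self, path) -> None:
        self.per_letter.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "summary": {
                m: row.dropna().to_dict() for m, row in self.summary().iterrows()
            },
            "invalid_prediction_rate": self.invalid_rate,
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def load_judge_prompt_template() -> str:
    """The clinician-style rating prompt for external LLM judging.

    Shipped as a template only; this package never calls a hosted model.
    Format with ``original=...`` and ``synthetic=...``.
    """
    from importlib.resources import files

    return files("synthletters.data").joinpath("judge_prompt.txt").read_text()


def _similarity_row(candidate: str, reference: str, embedder, doc_embedder) -> dict[str, float]:
    r1, r2, rl = rouge_scores(candidate, reference)
    return {
        "rouge1": r1,
        "rouge2": r2,
        "rougeL": rl,
        "bertscore_f1": bertscore_f1(candidate, reference, embedder),
        "meteor": meteor_score(candidate, reference),
        "clinical_cosine": clinical_similarity(reference, candidate, doc_embedder),
    }


def evaluate_corpus(
    originals: Sequence[str],
    masked: Sequence[str],
    synthetics: Sequence[str],
    note_ids: Sequence[str] | None = None,
    embedder=None,
    doc_embedder=None,
    lexicon=None,
    lm=None,
    filled: Sequence | None = None,
) -> EvalReport:
    """Evaluate three aligned corpora: originals, masked texts, synthetics.

    Every similarity metric appears twice per letter (generation and
    masked baseline); readability, entropy and subjectivity are computed
    for all three variants. ``filled`` (FilledChunk lists) adds the
    run-level invalid prediction rate.
    """
    if not originals:
        raise ValueError("empty corpus")
    if not (len(originals) == len(masked) == len(synthetics)):
        raise ValueError(
            f"corpus misalignment: {len(originals)} originals, {len(masked)} masked, {len(synthetics)} synthetics"
        )
    if note_ids is None:
        note_ids = [str(i) for i in range(len(originals))]
    rows = []
    for nid, orig, msk, syn in zip(note_ids, originals, masked, synthetics):
        for variant, cand in (("generation", syn), ("baseline", msk)):
            for metric, value in _similarity_row(cand, orig, embedder, doc_embedder).items():
                rows.append({"note_id": nid, "metric": metric, "variant": variant, "value": value})
        for variant, text in (("original", orig), ("masked", msk), ("synthetic", syn)):
            try:
                rd = readability_scores(text)
                rows.append({"note_id": nid, "metric": "flesch_reading_ease", "variant": variant, "value": rd.flesch_reading_ease})
                rows.append({"note_id": nid, "metric": "flesch_kincaid_grade", "variant": variant, "value": rd.flesch_kincaid_grade})
                rows.append({"note_id": nid, "metric": "smog", "variant": variant, "value": rd.smog})
            except ValueError:
                pass
            tq = text_quality_scores(text, lm=lm, lexicon=lexicon)
            for metric, value in tq.items():
                rows.append({"note_id": nid, "metric": metric, "variant": variant, "value": value})
    rate = invalid_prediction_rate(filled) if filled else None
    return EvalReport(per_letter=pd.DataFrame(rows), invalid_rate=rate)
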