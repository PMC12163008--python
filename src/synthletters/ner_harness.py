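"""Downstream NER harness: do synthetic letters train taggers as well as originals?

A reference tagger produces silver-standard annotations; a trainable
tagger is trained on those annotations over original letters and,
separately, over synthetic ones; both are scored on their test split
with strict span+label matching, and the per-metric delta (synthetic −
original) says how much training signal synthesis lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SilverDoc",
    "NERScore",
    "silver_annotate",
    "train_tagger",
    "evaluate_tagger",
    "compare_sources",
    "letter_split",
]


@dataclass
class SilverDoc:
    """One document with machine-produced (start, end, label) entity spans."""

    note_id: str
    text: str
    entities: list[tuple[int, int, str]] = field(default_factory=list)


@dataclass(frozen=True)
class NERScore:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def _resolve_overlaps(spans: Sequence[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    # longest-first; a span is dropped if it overlaps an already-kept one
    kept: list[tuple[int, int, str]] = []
    for span in sorted(spans, key=lambda s: (-(s[1] - s[0]), s[0], s[2])):
        if not any(span[0] < e and span[1] > s for s, e, _ in kept):
            kept.append(span)
    return sorted(kept)


def silver_annotate(
    letters: Sequence[tuple[str, str]],
    reference: Callable[[str], Sequence[tuple[int, int, str]]],
) -> list[SilverDoc]:
    """Run the reference tagger over ``(note_id, text)`` pairs.

    Overlapping spans are resolved longest-first so the silver standard
    is a flat, non-overlapping annotation layer.
    """
    docs = []
    for note_id, text in letters:
        spans = list(reference(text))
        for s, e, _ in spans:
            if not (0 <= s < e <= len(text)):
                raise ValueError(f"reference tagger emitted out-of-bounds span ({s}, {e}) for {note_id!r}")
        docs.append(SilverDoc(note_id=note_id, text=text, entities=_resolve_overlaps(spans)))
    return docs


def train_tagger(train: Sequence[SilverDoc], trainer, seed: int = 0):
    """Train the trainable-tagger adapter on silver docs (seeded)."""
    if not train:
        raise ValueError("empty training set")
    if trainer is None:
        raise ValueError("no trainer adapter configured")
    return trainer.train(train, seed=seed)


def evaluate_tagger(tagger, test: Sequence[SilverDoc]) -> NERScore:
    """Micro-averaged strict-match P/R/F1 against the silver spans.

    A prediction counts as a true positive only with identical start,
    end and label. No predictions at all scores 0 by convention.
    """
    if not test:
        raise ValueError("empty test set")
    tp = fp = fn = 0
    for doc in test:
        gold = set(doc.entities)
        pred = set(_resolve_overlaps(list(tagger(doc.text))))
        tp += len(gold & pred)
        fp += len(pred - gold)
        fn += len(gold - pred)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return NERScore(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)


def letter_split(note_ids: Sequence[str], split_seed: int, test_fraction: float = 0.2) -> tuple[list[str], list[str]]:
    """Seeded letter-level 80/20 split (never chunk-level, to avoid leakage)."""
    ids = list(note_ids)
    rng = np.random.default_rng(split_seed)
    order = rng.permutation(len(ids))
    n_test = max(1, int(round(len(ids) * test_fraction)))
    test = {ids[i] for i in order[:n_test]}
    return [i for i in ids if i not in test], [i for i in ids if i in test]


def compare_sources(
    originals: Sequence[tuple[str, str]],
    synthetics: Sequence[tuple[str, str]],
    reference: Callable[[str], Sequence[tuple[int, int, str]]],
    trainer,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Train on originals vs. synthetics under an identical letter split.

    Both corpora must be aligned by ``note_id``. For each source, silver
    annotations come from the reference tagger run on that same source;
    one tagger is trained per source and evaluated on its test split.
    Returns a table with f1/precision/recall for both sources and the
    delta (synthetic − original).
    """
    orig_ids = [nid for nid, _ in originals]
    syn_ids = [nid for nid, _ in synthetics]
    if orig_ids != syn_ids:
        raise ValueError("corpora are not aligned by note_id")
    train_ids, test_ids = letter_split(orig_ids, split_seed)

    def score(corpus: Sequence[tuple[str, str]]) -> NERScore:
        silver = {d.note_id: d for d in silver_annotate(corpus, reference)}
        tagger = train_tagger([silver[i] for i in train_ids], trainer, seed=split_seed)
        return evaluate_tagger(tagger, [silver[i] for i in test_ids])

    s_orig, s_syn = score(originals), score(synthetics)
    rows = []
    for metric in ("f1", "precision", "recall"):
        o, s = getattr(s_orig, metric), getattr(s_syn, metric)
        rows.append({"metric": metric, "original": o, "synthetic": s, "delta": s - o})
    return pd.DataFrame(rows)
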