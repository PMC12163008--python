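"""Reading, validating and merging the letters and annotations tables.

The corpus arrives as two CSV files: a letters table with a ``note_id``
column (unique identifier) and a ``text`` column holding the full letter,
and an annotations table with ``note_id``, ``start``, ``end`` and
``concept_id`` columns giving character-offset entity spans into the
letter text. Offsets are 0-based, half-open ``[start, end)``, so
``text[start:end]`` is the annotated surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawLetter",
    "EntityAnnotation",
    "AnnotatedLetter",
    "SchemaError",
    "ValidationError",
    "read_letters",
    "read_annotations",
    "merge_corpus",
    "write_letters",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """Row-level content violates the corpus contract."""


@dataclass(frozen=True)
class RawLetter:
    """One clinical letter, text preserved byte-exact from file."""

    note_id: str
    text: str


@dataclass(frozen=True)
class EntityAnnotation:
    """A character-offset entity span inside one letter.

    ``surface`` is filled at merge time and always equals
    ``letter.text[start:end]``. ``truncated`` marks entities cut at a
    chunk boundary during chunking.
    """

    note_id: str
    start: int
    end: int
    concept_id: str
    surface: str | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValidationError(
                f"invalid span [{self.start}, {self.end}) for note {self.note_id!r}"
            )


@dataclass
class AnnotatedLetter:
    """A letter together with its entity annotations, sorted by start."""

    letter: RawLetter
    entities: list[EntityAnnotation] = field(default_factory=list)

    @property
    def note_id(self) -> str:
        return self.letter.note_id

    @property
    def text(self) -> str:
        return self.letter.text


def read_letters(
    path: str | Path, schema: tuple[str, str] = ("note_id", "text")
) -> list[RawLetter]:
    """Read the letters CSV, preserving embedded newlines byte-exact.

    Parameters
    ----------
    path:
        CSV file with a header row containing both schema columns.
    schema:
        ``(id_column, text_column)`` names, default ``("note_id", "text")``.

    Raises
    ------
    SchemaError
        If either configured column is missing.
    ValidationError
        If any ``note_id`` occurs more than once.
    """
    id_col, text_col = schema
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (id_col, text_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path} (found {list(df.columns)})")
    dupes = df[id_col][df[id_col].duplicated()].unique().tolist()
    if dupes:
        raise ValidationError(f"duplicate note_id values: {dupes}")
    empty = df.index[df[id_col] == ""].tolist()
    if empty:
        raise ValidationError(f"empty note_id at rows {empty}")
    return [RawLetter(note_id=r, text=t) for r, t in zip(df[id_col], df[text_col])]


def read_annotations(path: str | Path) -> list[EntityAnnotation]:
    """Read the annotations CSV; surfaces are filled later by :func:`merge_corpus`.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValidationError
        If an offset does not parse as a non-negative integer or a span
        is empty/inverted (the error message carries the row number).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("note_id", "start", "end", "concept_id")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"column {col!r} missing from {path}")
    out: list[EntityAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise ValidationError(f"row {i}: non-integer offset ({row.start!r}, {row.end!r})") from exc
        if start < 0 or end <= start:
            raise ValidationError(f"row {i}: invalid span [{start}, {end})")
        out.append(EntityAnnotation(note_id=row.note_id, start=start, end=end, concept_id=row.concept_id))
    return out


def _entity_key(e: EntityAnnotation) -> tuple[int, int, str]:
    return (e.start, e.end, e.concept_id)


def merge_corpus(
    letters: Sequence[RawLetter],
    annotations: Iterable[EntityAnnotation],
    strict: bool = True,
) -> list[AnnotatedLetter]:
    """Attach each annotation to its letter, filling surfaces from the text.

    Letters without annotations are kept with an empty entity list.
    Entities are sorted by ``(start, end, concept_id)``; overlapping and
    nested spans are all retained. In strict mode an annotation with an
    unknown ``note_id`` or an out-of-bounds span raises; in lenient mode
    it is logged and skipped (real corpora are dirty).
    """
    by_id: dict[str, AnnotatedLetter] = {
        lt.note_id: AnnotatedLetter(letter=lt) for lt in letters
    }
    for ann in annotations:
        holder = by_id.get(ann.note_id)
        if holder is None:
            if strict:
                raise ValidationError(f"annotation references unknown note_id {ann.note_id!r}")
            logger.warning("skipping annotation for unknown note_id %r", ann.note_id)
            continue
        text = holder.text
        if ann.end > len(text):
            if strict:
                raise ValidationError(
                    f"annotation [{ann.start}, {ann.end}) exceeds length {len(text)} "
                    f"of note {ann.note_id!r}"
                )
            logger.warning("skipping out-of-bounds annotation %r in %r", ann, ann.note_id)
            continue
        holder.entities.append(replace(ann, surface=text[ann.start : ann.end]))
    for holder in by_id.values():
        holder.entities.sort(key=_entity_key)
    return list(by_id.values())


def write_letters(
    letters: Sequence[RawLetter],
    path: str | Path,
    provenance: dict[str, object] | None = None,
) -> None:
    """Write letters in the corpus schema, optionally with provenance columns.

    ``provenance`` maps extra column names (e.g. ``strategy``, ``ratio``,
    ``seed``) to constant values recorded on every row.
    """
    data: dict[str, list | object] = {
        "note_id": [lt.note_id for lt in letters],
        "text": [lt.text for lt in letters],
    }
    if provenance:
        for key, value in provenance.items():
            data[key] = [value] * len(letters)
    pd.DataFrame(data).to_csv(path, index=False)
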