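"""Synthetic discharge-letter corpora with gold labels for every detector.

The real study corpus (annotated discharge summaries) is access
controlled, so this module generates letters with the structural and
statistical properties the pipeline assumes: colon-terminated section
headers, free-text sentences carrying annotated clinical-entity spans,
``___`` privacy placeholders, medication-dosage lines, occasional
phone/email contact lines, and injected adjacent-transposition
misspellings. Alongside each letter it emits gold labels for every
feature class the generator produces, written as a sidecar file that
the pipeline itself never reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import AnnotatedLetter, EntityAnnotation, RawLetter, write_letters
from .features import tokenize_with_offsets

__all__ = [
    "FixtureSpec",
    "GoldLabels",
    "generate_letter",
    "generate_corpus",
    "load_gold",
    "inject_misspellings",
    "fixture_vocabulary",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Generation parameters; the same spec + seed yields an identical corpus."""

    n_letters: int = 10
    seed: int = 0
    sections_per_letter: tuple[int, int] = (3, 6)
    sentences_per_section: tuple[int, int] = (2, 5)
    #: probability a free-text sentence carries an annotated entity
    entity_rate: float = 0.6
    #: expected "___" placeholders per letter (Poisson-planned)
    placeholder_rate: float = 2.0
    #: probability a section carries medication-dosage lines
    dosage_line_rate: float = 0.4
    #: probability a section carries a phone/email contact sentence
    private_line_rate: float = 0.3
    #: per-word probability of an adjacent-transposition misspelling
    misspelling_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("entity_rate", "dosage_line_rate", "private_line_rate", "misspelling_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.placeholder_rate < 0 or self.n_letters < 0:
            raise ValueError("counts and rates must be non-negative")


@dataclass
class GoldLabels:
    """True character spans per feature category, plus the misspelling map.

    ``spans`` maps each category in {structure, clinical_entity, private,
    special_pattern, placeholder} to ``(start, end, surface)`` triples;
    every span slices to its recorded surface.
    """

    note_id: str
    spans: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    misspellings: list[dict] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "note_id": self.note_id,
            "spans": {k: [list(t) for t in v] for k, v in sorted(self.spans.items())},
            "misspellings": self.misspellings,
        }


_HEADERS = (
    "Allergies:",
    "Chief Complaint:",
    "History of Present Illness:",
    "Past Medical History:",
    "Physical Exam:",
    "Medications on Admission:",
    "Discharge Medications:",
    "Discharge Diagnosis:",
    "Discharge Instructions:",
    "Followup Instructions:",
)

#: (surface, SNOMED-style concept code) pairs used for annotated entities
_ENTITIES = (
    ("No Known Allergies", "609328004"),
    ("hypertension", "38341003"),
    ("chest pain", "29857009"),
    ("pneumonia", "233604007"),
    ("type 2 diabetes", "44054006"),
    ("atrial fibrillation", "49436004"),
    ("asthma", "195967001"),
    ("urinary tract infection", "68566005"),
    ("congestive heart failure", "42343007"),
    ("anemia", "271737000"),
)

_PLAIN_TEMPLATES = (
    "She denies fever and reports that the pain improved with rest.",
    "The team reviewed the plan and continued the current medications.",
    "He fell from a ladder at home and presented to the emergency department.",
    "Laboratory results were reviewed and were within normal limits.",
    "The patient tolerated the procedure well and was ambulating without difficulty.",
    "Follow up with your primary care doctor within one week.",
    "The patient was counseled about the findings and agreed with the plan.",
    "Vital signs remained stable throughout the admission.",
    "Please call the office with any new questions or concerns.",
    "The family was updated at the bedside this morning.",
)

_ENTITY_TEMPLATES = (
    "The patient was admitted with {ENT} and remained stable overnight.",
    "He was treated for {ENT} during the hospital stay.",
    "Imaging showed {ENT} without any acute change.",
    "She was evaluated for {ENT} and started on appropriate therapy.",
    "His history is notable for {ENT} followed in clinic.",
    "The examination was consistent with {ENT} on admission.",
)

_PLACEHOLDER_TEMPLATES = (
    "___ was seen in the clinic today.",
    "___ will follow up with the patient after discharge.",
    "The patient was discharged home on ___ in good condition.",
    "Records were requested from ___ for review.",
)

_DRUGS = ("enoxaparin", "metoprolol", "lisinopril", "atorvastatin", "amoxicillin", "furosemide")

_FIRST_NAMES = ("john", "jane", "alex", "maria", "sam", "lee")
_LAST_NAMES = ("doe", "smith", "jones", "garcia", "chen", "patel")


def fixture_vocabulary() -> frozenset[str]:
    """Every lowercase alphabetic word the generator can emit.

    Serves as the dictionary for spelling-correction tests: any word the
    misspelling injector corrupts has its original form in this set.
    """
    words: set[str] = set()
    sources = list(_HEADERS) + list(_PLAIN_TEMPLATES) + list(_ENTITY_TEMPLATES) + list(_PLACEHOLDER_TEMPLATES)
    sources += [s for s, _ in _ENTITIES] + list(_DRUGS)
    sources += ["mg", "ml", "PO", "Contact", "the", "clinic", "at", "with", "any",
                "questions", "Messages", "can", "be", "sent", "to", "if", "needed"]
    for src in sources:
        for tok in tokenize_with_offsets(src):
            if tok.text.isalpha():
                words.add(tok.text.lower())
    return frozenset(words)


class _Builder:
    """Accumulates text pieces while recording span bookkeeping."""

    def __init__(self, note_id: str):
        self.note_id = note_id
        self.parts: list[str] = []
        self.pos = 0
        self.annotations: list[EntityAnnotation] = []
        self.gold = GoldLabels(note_id=note_id, spans={k: [] for k in
                               ("structure", "clinical_entity", "private", "special_pattern", "placeholder")})

    def append(self, piece: str) -> int:
        start = self.pos
        self.parts.append(piece)
        self.pos += len(piece)
        return start

    def mark(self, category: str, start: int, end: int) -> None:
        self.gold.spans[category].append((start, end, self.text_slice(start, end)))

    def text_slice(self, start: int, end: int) -> str:
        return "".join(self.parts)[start:end]

    @property
    def text(self) -> str:
        return "".join(self.parts)


def inject_misspellings(
    text: str,
    rate: float,
    protected: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    vocabulary: frozenset[str] | None = None,
) -> tuple[str, list[dict]]:
    """Corrupt words by adjacent-character transposition, sparing protected spans.

    Each alphabetic word of five or more letters outside the protected
    spans is corrupted with probability ``rate`` by swapping one random
    pair of adjacent differing characters (``healthy`` → ``healhty``).
    When a vocabulary is given, transpositions that collide with a real
    word are skipped so every corruption is unambiguously a misspelling.
    Transposition preserves length, so all character offsets survive.
    Returns the corrupted text and a map of
    ``{start, end, original, corrupted}`` records.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0:
        return text, []
    rng = np.random.default_rng(seed)
    chars = list(text)
    log: list[dict] = []
    for tok in tokenize_with_offsets(text):
        if len(tok.text) < 5 or not tok.text.isalpha():
            continue
        if any(tok.start < e and tok.end > s for s, e in protected):
            continue
        if rng.random() >= rate:
            continue
        positions = rng.permutation(len(tok.text) - 1)
        for i in positions:
            if tok.text[i] == tok.text[i + 1]:
                continue
            corrupted = tok.text[:i] + tok.text[i + 1] + tok.text[i] + tok.text[i + 2 :]
            if vocabulary is not None and corrupted.lower() in vocabulary:
                continue
            chars[tok.start : tok.end] = corrupted
            log.append({"start": tok.start, "end": tok.end, "original": tok.text, "corrupted": corrupted})
            break
    return "".join(chars), log


def _entity_sentence(b: _Builder, rng: np.random.Generator) -> None:
    template = _ENTITY_TEMPLATES[int(rng.integers(len(_ENTITY_TEMPLATES)))]
    surface, concept = _ENTITIES[int(rng.integers(len(_ENTITIES)))]
    prefix = template[: template.index("{ENT}")]
    sent_start = b.append(template.format(ENT=surface))
    ent_start = sent_start + len(prefix)
    ent_end = ent_start + len(surface)
    b.annotations.append(
        EntityAnnotation(note_id=b.note_id, start=ent_start, end=ent_end, concept_id=concept)
    )
    b.mark("clinical_entity", ent_start, ent_end)


def _placeholder_sentence(b: _Builder, rng: np.random.Generator) -> None:
    template = _PLACEHOLDER_TEMPLATES[int(rng.integers(len(_PLACEHOLDER_TEMPLATES)))]
    start = b.append(template)
    ph = start + template.index("___")
    b.mark("placeholder", ph, ph + 3)


def _private_sentence(b: _Builder, rng: np.random.Generator) -> None:
    if rng.random() < 0.5:
        number = f"({rng.integers(200, 999)}) {rng.integers(100, 999)}-{rng.integers(1000, 9999)}"
        sentence = f"Contact the clinic at {number} with any questions."
        start = b.append(sentence)
        pstart = start + sentence.index(number)
        b.mark("private", pstart, pstart + len(number))
    else:
        email = (
            f"{_FIRST_NAMES[int(rng.integers(len(_FIRST_NAMES)))]}"
            f".{_LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]}@example.com"
        )
        sentence = f"Messages can be sent to {email} if needed."
        start = b.append(sentence)
        pstart = start + sentence.index(email)
        b.mark("private", pstart, pstart + len(email))


def _dosage_lines(b: _Builder, rng: np.random.Generator) -> None:
    for _ in range(int(rng.integers(1, 3))):
        drug = _DRUGS[int(rng.integers(len(_DRUGS)))]
        if rng.random() < 0.5:
            dose = f"{rng.integers(10, 90)} mg/{rng.integers(1, 9)}.{rng.integers(1, 9)} ml"
            line = f"{drug} {dose}"
            start = b.append(line)
            dstart = start + line.index(dose)
            b.mark("special_pattern", dstart, dstart + len(dose))
        else:
            dose = f"{rng.integers(100, 900)} mg"
            line = f"{drug} {dose} PO b.i.d."
            start = b.append(line)
            dstart = start + line.index(dose)
            b.mark("special_pattern", dstart, dstart + len(dose))
            bid = start + line.index("b.i.d.")
            b.mark("special_pattern", bid, bid + len("b.i.d."))
        b.append("\n")


def generate_letter(spec: FixtureSpec, index: int) -> tuple[AnnotatedLetter, GoldLabels]:
    """Generate one deterministic letter with its gold labels.

    Every annotation slices to its surface by construction, placeholder
    count equals the planned insertions, and all gold spans are emitted
    in-grammar for their detectors.
    """
    rng = np.random.default_rng([spec.seed, index])
    note_id = f"SYN-{spec.seed}-{index:05d}-DS"
    b = _Builder(note_id)

    ph_quota = int(rng.poisson(spec.placeholder_rate)) if spec.placeholder_rate > 0 else 0
    lo, hi = spec.sections_per_letter
    n_sections = int(rng.integers(lo, hi + 1)) if hi >= lo else lo
    headers = list(_HEADERS)
    rng.shuffle(headers)
    for s in range(max(n_sections, 0)):
        header = headers[s % len(headers)]
        if s > 0:
            b.append("\n")
        start = b.append(header)
        b.mark("structure", start, start + len(header))
        b.append("\n")
        if rng.random() < spec.dosage_line_rate:
            _dosage_lines(b, rng)
        slo, shi = spec.sentences_per_section
        n_sent = int(rng.integers(slo, shi + 1)) if shi >= slo else slo
        for t in range(max(n_sent, 0)):
            if t > 0:
                b.append(" ")
            if ph_quota > 0 and rng.random() < 0.5:
                _placeholder_sentence(b, rng)
                ph_quota -= 1
            elif t == 0 and rng.random() < spec.private_line_rate:
                _private_sentence(b, rng)
            elif rng.random() < spec.entity_rate:
                _entity_sentence(b, rng)
            else:
                b.append(_PLAIN_TEMPLATES[int(rng.integers(len(_PLAIN_TEMPLATES)))])
        b.append("\n")
    while ph_quota > 0:
        b.append("\n")
        _placeholder_sentence(b, rng)
        ph_quota -= 1
        b.append("\n")

    text = b.text
    protected = [(s, e) for spans in b.gold.spans.values() for s, e, _ in spans]
    if spec.misspelling_rate > 0:
        text, misspellings = inject_misspellings(
            text,
            spec.misspelling_rate,
            protected=protected,
            seed=int(rng.integers(2**31)),
            vocabulary=fixture_vocabulary(),
        )
        b.gold.misspellings = misspellings

    entities = [
        EntityAnnotation(
            note_id=note_id, start=a.start, end=a.end, concept_id=a.concept_id,
            surface=text[a.start : a.end],
        )
        for a in b.annotations
    ]
    entities.sort(key=lambda e: (e.start, e.end, e.concept_id))
    letter = AnnotatedLetter(letter=RawLetter(note_id=note_id, text=text), entities=entities)
    return letter, b.gold


def generate_corpus(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a full fixture corpus: letters CSV + annotations CSV + gold sidecar.

    The letters and annotations files use the corpus schema and
    round-trip through :mod:`synthletters.corpus_io`; the gold-labels
    sidecar is JSON-lines, one record per letter, and is never consumed
    by the pipeline itself.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    letters, annotations, gold = [], [], []
    for i in range(spec.n_letters):
        lt, gl = generate_letter(spec, i)
        letters.append(lt.letter)
        annotations.extend(lt.entities)
        gold.append(gl)
    paths = {
        "letters": out_dir / "letters.csv",
        "annotations": out_dir / "annotations.csv",
        "gold": out_dir / "gold_labels.jsonl",
    }
    write_letters(letters, paths["letters"])
    pd.DataFrame(
        [
            {"note_id": a.note_id, "start": a.start, "end": a.end, "concept_id": a.concept_id}
            for a in annotations
        ],
        columns=["note_id", "start", "end", "concept_id"],
    ).to_csv(paths["annotations"], index=False)
    with open(paths["gold"], "w") as fh:
        for gl in gold:
            fh.write(json.dumps(gl.to_record(), sort_keys=True) + "\n")
    return paths


def load_gold(path: str | Path) -> list[GoldLabels]:
    """Read a gold-labels sidecar back into :class:`GoldLabels` records."""
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append(
                GoldLabels(
                    note_id=rec["note_id"],
                    spans={k: [tuple(t) for t in v] for k, v in rec["spans"].items()},
                    misspellings=rec["misspellings"],
                )
            )
    return out
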