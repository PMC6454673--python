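"""Annotation data model for Chinese resident admit notes (RANs).

The corpus unit is an :class:`AnnotatedDocument`: NFC-normalized text plus
typed entity mentions (character spans) and binary relations anchored on
``MedicalDiscovery`` ("symptom") mentions.  Nine entity types and four
relation types are admitted; the schema enforces the annotation principles
used when the corpus was built:

* entity spans never overlap or nest,
* entity surface strings match the document text exactly,
* punctuation is not annotated on its own and should not lead/trail a span
  (a warning, since symbols with clinical meaning are legitimately kept),
* each relation links a MedicalDiscovery to a compatible partner type.

Offsets are 0-based, half-open, in Unicode code points of the NFC form.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Callable, Iterable, Mapping, Sequence


class EntityType(str, Enum):
    """The nine clinical entity types annotated in admit notes."""

    MEDICAL_DISCOVERY = "MedicalDiscovery"
    TEMPORAL_WORD = "TemporalWord"
    INSPECTION = "Inspection"
    LABORATORY_TEST = "LaboratoryTest"
    TREATMENT = "Treatment"
    MEASUREMENT = "Measurement"
    DISEASE = "Disease"
    MEDICATION = "Medication"
    BODY_PART = "BodyPart"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RelationType(str, Enum):
    """The four symptom-centred relation types.

    Each relation connects a MedicalDiscovery ("symptom") mention with one
    partner entity: the body part where it was found (BrSy), the temporal
    word qualifying it (TrSy), the inspection that produced it (IrSy) or the
    laboratory test that produced it (LrSy).
    """

    BRSY = "BrSy"
    TRSY = "TrSy"
    IRSY = "IrSy"
    LRSY = "LrSy"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Partner entity type required on the non-discovery side of each relation.
RELATION_PARTNER: Mapping[RelationType, EntityType] = {
    RelationType.BRSY: EntityType.BODY_PART,
    RelationType.TRSY: EntityType.TEMPORAL_WORD,
    RelationType.IRSY: EntityType.INSPECTION,
    RelationType.LRSY: EntityType.LABORATORY_TEST,
}


@dataclass(frozen=True)
class EntityMention:
    """A typed character span. ``text`` must equal ``doc.text[start:end]``."""

    id: str
    type: EntityType
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class RelationMention:
    """A typed link between two entity mentions, stored head -> tail.

    By convention the head is the non-MedicalDiscovery participant and the
    tail is the MedicalDiscovery mention.
    """

    id: str
    type: RelationType
    head: str
    tail: str


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    relations: list[RelationMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.text = unicodedata.normalize("NFC", self.text)

    def entity_by_id(self) -> dict[str, EntityMention]:
        return {e.id: e for e in self.entities}


@dataclass(frozen=True)
class Violation:
    """One schema problem found by :func:`validate_document`.

    ``severity`` is ``"error"`` for hard schema breaks (bad offsets, overlap,
    text mismatch, incompatible relations) and ``"warning"`` for the
    punctuation principle, which admits clinically meaningful exceptions.
    """

    kind: str
    mention_id: str
    message: str
    severity: str = "error"


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def validate_document(doc: AnnotatedDocument) -> list[Violation]:
    """Check a document against every schema rule; return all violations.

    An empty return value means the document is schema-clean.  Malformed
    offsets are reported as error items, never silently dropped.
    """
    violations: list[Violation] = []
    n = len(doc.text)

    seen_ids: set[str] = set()
    well_formed: list[EntityMention] = []
    for ent in doc.entities:
        if ent.id in seen_ids:
            violations.append(
                Violation("duplicate-id", ent.id, f"entity id {ent.id!r} reused")
            )
        seen_ids.add(ent.id)
        if not (0 <= ent.start < ent.end <= n):
            violations.append(
                Violation(
                    "bad-span",
                    ent.id,
                    f"span [{ent.start}, {ent.end}) invalid for text of length {n}",
                )
            )
            continue
        well_formed.append(ent)
        if doc.text[ent.start : ent.end] != ent.text:
            violations.append(
                Violation(
                    "text-mismatch",
                    ent.id,
                    f"mention text {ent.text!r} != document substring "
                    f"{doc.text[ent.start:ent.end]!r}",
                )
            )
        else:
            if _is_punct(ent.text[0]) or _is_punct(ent.text[-1]):
                violations.append(
                    Violation(
                        "punctuation-edge",
                        ent.id,
                        f"span {ent.text!r} starts or ends with punctuation",
                        severity="warning",
                    )
                )

    # sweep in start order; the inner loop stops at the first non-overlapping
    # span, so every overlapping (or nested) pair is reported exactly once
    ordered = sorted(well_formed, key=lambda e: (e.start, e.end))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if b.start >= a.end:
                break
            violations.append(
                Violation(
                    "overlap",
                    b.id,
                    f"span [{b.start}, {b.end}) of {b.id} overlaps "
                    f"[{a.start}, {a.end}) of {a.id}",
                )
            )

    by_id = {e.id: e for e in doc.entities}
    for rel in doc.relations:
        missing = [m for m in (rel.head, rel.tail) if m not in by_id]
        if missing:
            violations.append(
                Violation(
                    "dangling-relation",
                    rel.id,
                    f"relation {rel.id} references unknown mention(s) {missing}",
                )
            )
            continue
        head, tail = by_id[rel.head], by_id[rel.tail]
        partner = RELATION_PARTNER[rel.type]
        types = {head.type, tail.type}
        if types != {partner, EntityType.MEDICAL_DISCOVERY}:
            violations.append(
                Violation(
                    "relation-type",
                    rel.id,
                    f"{rel.type} must link {partner.value} with "
                    f"MedicalDiscovery, got {head.type.value}->{tail.type.value}",
                )
            )
    return violations


# ---------------------------------------------------------------------------
# corpus statistics
# ---------------------------------------------------------------------------

@dataclass
class CorpusStats:
    """Aggregate counts over a corpus plus the entity type distribution."""

    n_documents: int
    n_sentences: int
    n_words: int
    n_characters: int
    n_entities: int
    per_type_counts: dict[EntityType, int]
    per_type_percent: dict[EntityType, float]

    def to_frame(self):
        """Entity distribution as a pandas DataFrame (count, percent)."""
        import pandas as pd

        rows = [
            {"type": t.value, "count": self.per_type_counts[t],
             "percent": self.per_type_percent[t]}
            for t in EntityType
        ]
        rows.append({"type": "Total", "count": self.n_entities, "percent": 100.0})
        return pd.DataFrame(rows)


def type_distribution(counts: Mapping[EntityType, int]) -> dict[EntityType, float]:
    """Percent of total entities per type, rounded to two decimals.

    This is the arithmetic behind the corpus distribution table: each cell is
    ``100 * count / total``.  Rounding is applied per cell, so the column sums
    to 100 only up to rounding error (within 0.05).
    """
    total = sum(counts.values())
    if total == 0:
        return {t: 0.0 for t in EntityType}
    return {t: round(100.0 * counts.get(t, 0) / total, 2) for t in EntityType}


def corpus_stats(
    corpus: Sequence[AnnotatedDocument],
    sentence_splitter: Callable[[str], list] | None = None,
    tokenizer: Callable[[str], list] | None = None,
) -> CorpusStats:
    """Compute document/sentence/word/character/entity counts over a corpus.

    ``sentence_splitter`` and ``tokenizer`` default to the bundled pipeline
    (terminator-based splitting, per-character segmentation).
    """
    if not corpus:
        raise ValueError("corpus_stats requires a non-empty corpus")
    if sentence_splitter is None or tokenizer is None:
        from . import pipeline

        if sentence_splitter is None:
            sentence_splitter = pipeline.split_sentences
        if tokenizer is None:
            seg = pipeline.CharSegmenter()

            def tokenizer(sentence: str) -> list:
                return pipeline.tokenize(sentence, seg)

    n_sent = 0
    n_words = 0
    n_chars = 0
    counts: dict[EntityType, int] = {t: 0 for t in EntityType}
    for doc in corpus:
        n_chars += len(doc.text)
        sentences = sentence_splitter(doc.text)
        n_sent += len(sentences)
        for sent, _off in sentences:
            n_words += len(tokenizer(sent))
        for ent in doc.entities:
            counts[ent.type] += 1
    n_entities = sum(counts.values())
    return CorpusStats(
        n_documents=len(corpus),
        n_sentences=n_sent,
        n_words=n_words,
        n_characters=n_chars,
        n_entities=n_entities,
        per_type_counts=counts,
        per_type_percent=type_distribution(counts),
    )
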