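"""Synthetic admit-note corpora with known gold annotations.

The real 255-document hospital corpus cannot be redistributed, so every
other module is exercised on generated data that mimics its *structure*:
short clinical sentences built from templates with typed slots, entity
surfaces drawn from small per-type CJK lexicons, the empirical entity-type
distribution of the corpus distribution table, and the documented document
scale (~54.6 sentences per admit note).  No attempt is made at grammatical
Chinese — only distributional and structural fidelity.

A second annotator is simulated by perturbing the gold annotations with the
disagreement modes observed between human annotators: missed mentions
(deletions), spurious mentions, boundary disagreements, and type confusion
(e.g. discoveries confused with diseases).  Deletions and spurious additions
have closed-form expected agreement: with deletion rate ``d`` and spurious
rate ``a``, recall against gold is ``1 - d`` and precision is
``(1 - d) / (1 - d + a)`` in expectation.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .schema import (
    RELATION_PARTNER,
    AnnotatedDocument,
    EntityMention,
    EntityType,
    RelationMention,
)
from .pipeline import split_sentences

# Entity counts of the source corpus distribution table; normalized, these
# are the default sampling weights (Body part 22.34% of 66,943 etc.).
CORPUS_TYPE_COUNTS: dict[EntityType, int] = {
    EntityType.MEDICAL_DISCOVERY: 29247,
    EntityType.TEMPORAL_WORD: 1631,
    EntityType.INSPECTION: 6915,
    EntityType.LABORATORY_TEST: 2127,
    EntityType.TREATMENT: 2601,
    EntityType.MEASUREMENT: 2839,
    EntityType.DISEASE: 5286,
    EntityType.MEDICATION: 1344,
    EntityType.BODY_PART: 14953,
}

_TOTAL = sum(CORPUS_TYPE_COUNTS.values())

DEFAULT_TYPE_WEIGHTS: dict[EntityType, float] = {
    t: c / _TOTAL for t, c in CORPUS_TYPE_COUNTS.items()
}

# Small built-in surface inventories.  Strings are disjoint across types, so
# the default lexicons are unambiguous; a few romanized laboratory tokens
# mimic real test names.
DEFAULT_LEXICONS: dict[EntityType, list[str]] = {
    EntityType.BODY_PART: [
        "心脏", "肝脏", "双肺", "腹部", "头部", "颈部", "右肾", "左膝", "脾脏", "胸腔",
    ],
    EntityType.MEDICAL_DISCOVERY: [
        "杂音", "疼痛", "肿大", "浮肿", "头晕", "咳嗽", "发热", "乏力", "气短", "压痛",
    ],
    EntityType.TEMPORAL_WORD: [
        "10月余", "三天前", "一周后", "晚饭后", "两年余", "数小时", "半月前", "清晨",
    ],
    EntityType.DISEASE: [
        "高血压", "糖尿病", "冠心病", "肺炎", "胃炎", "脑梗死", "先天性心脏病",
    ],
    EntityType.MEDICATION: [
        "阿司匹林", "胰岛素", "青霉素", "头孢拉定", "止痛药", "降压药",
    ],
    EntityType.TREATMENT: [
        "抗炎治疗", "手术治疗", "注射治疗", "对症支持", "输血治疗", "化疗",
    ],
    EntityType.INSPECTION: [
        "心脏彩超", "胸部CT", "心电图", "腹部B超", "巴氏征", "生理反射", "移动性浊音",
    ],
    EntityType.LABORATORY_TEST: [
        "血常规", "尿常规", "肝功能", "ALT", "AST", "血糖", "肌酐",
    ],
    EntityType.MEASUREMENT: [
        "38.5℃", "120次/分", "537U/L", "24.6mmol/L", "130/80mmHg",
    ],
}

#: A template is a tuple of pieces: literal filler strings, or slot markers
#: ``"<*>"`` (entity type drawn from the configured weights) /
#: ``"<TypeName>"`` (fixed type).  Literals always separate adjacent slots so
#: greedy dictionary segmentation cannot merge across entity boundaries.
DEFAULT_TEMPLATES: list[tuple[str, ...]] = [
    ("患者", "<*>", "。"),
    ("<*>", "伴", "<*>", "。"),
    ("查", "<*>", "示", "<*>", "。"),
    ("患者", "<*>", "出现", "<*>", "，无", "<*>", "。"),
    ("自起病以来", "<*>", "，", "<*>", "。"),
    ("予以", "<*>", "后好转", "。"),
    ("入院后", "<*>", "提示", "<*>", "，", "<*>", "。"),
]


@dataclass
class GeneratorConfig:
    """Distributional knobs of the corpus generator.

    Defaults reproduce the documented study conditions: the per-type entity
    distribution derived from the corpus distribution counts, and a mean of
    54.6 sentences per document.  ``sentences_per_doc`` is a Poisson mean
    (clipped to at least one sentence).
    """

    n_documents: int = 255
    sentences_per_doc: float = 54.6
    entity_type_weights: dict[EntityType, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_WEIGHTS)
    )
    lexicons: dict[EntityType, list[str]] = field(
        default_factory=lambda: {t: list(v) for t, v in DEFAULT_LEXICONS.items()}
    )
    templates: list[tuple[str, ...]] = field(
        default_factory=lambda: [tuple(t) for t in DEFAULT_TEMPLATES]
    )
    with_relations: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.entity_type_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"entity_type_weights sum to {total}, expected 1")
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        if self.sentences_per_doc <= 0:
            raise ValueError("sentences_per_doc must be positive")

    def dictionary(self) -> list[str]:
        """All lexicon surfaces plus template literals, for segmentation."""
        words = {w for lst in self.lexicons.values() for w in lst}
        for template in self.templates:
            for piece in template:
                if not _is_slot(piece):
                    words.add(piece.strip("，。"))
        return sorted(w for w in words if w)


def _is_slot(piece: str) -> bool:
    return piece.startswith("<") and piece.endswith(">")


def _slot_type(piece: str, weights, types, probs, rng) -> EntityType:
    name = piece[1:-1]
    if name == "*":
        return types[rng.choice(len(types), p=probs)]
    return EntityType(name)


def generate_document(
    config: GeneratorConfig, doc_id: str, rng: np.random.Generator
) -> AnnotatedDocument:
    types = list(config.entity_type_weights.keys())
    probs = np.array([config.entity_type_weights[t] for t in types], dtype=float)
    probs = probs / probs.sum()

    n_sentences = max(1, int(rng.poisson(config.sentences_per_doc)))
    pieces: list[str] = []
    entities: list[EntityMention] = []
    pos = 0
    for _ in range(n_sentences):
        template = config.templates[rng.choice(len(config.templates))]
        for piece in template:
            if _is_slot(piece):
                etype = _slot_type(piece, config.entity_type_weights, types, probs, rng)
                lexicon = config.lexicons.get(etype, [])
                if not lexicon:
                    raise ValueError(
                        f"empty lexicon for slot type {etype.value!r}"
                    )
                surface = lexicon[rng.choice(len(lexicon))]
                entities.append(
                    EntityMention(
                        f"T{len(entities) + 1}", etype, pos, pos + len(surface), surface
                    )
                )
                pieces.append(surface)
                pos += len(surface)
            else:
                pieces.append(piece)
                pos += len(piece)
    doc = AnnotatedDocument(doc_id, "".join(pieces), entities)
    if config.with_relations:
        generate_relations(doc)
    return doc


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedDocument]:
    """Generate a corpus; identical configs (and seeds) give identical output."""
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_documents))
    return [
        generate_document(config, f"doc{i + 1:0{width}d}", rng)
        for i in range(config.n_documents)
    ]


def generate_relations(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Add schema-compatible relations within each sentence, in place.

    Every BodyPart / TemporalWord / Inspection / LaboratoryTest mention is
    linked to the nearest MedicalDiscovery mention in the same sentence with
    the matching relation type (BrSy / TrSy / IrSy / LrSy).  Sentences
    without a discovery contribute no relations.
    """
    partner_to_rel = {v: k for k, v in RELATION_PARTNER.items()}
    relations: list[RelationMention] = []
    for sent, offset in split_sentences(doc.text):
        lo, hi = offset, offset + len(sent)
        local = [e for e in doc.entities if e.start >= lo and e.end <= hi]
        discoveries = [e for e in local if e.type == EntityType.MEDICAL_DISCOVERY]
        if not discoveries:
            continue
        for ent in local:
            rel_type = partner_to_rel.get(ent.type)
            if rel_type is None:
                continue
            nearest = min(discoveries, key=lambda d: abs(d.start - ent.start))
            relations.append(
                RelationMention(
                    f"R{len(relations) + 1}", rel_type, ent.id, nearest.id
                )
            )
    doc.relations = relations
    return doc


# ---------------------------------------------------------------------------
# simulated second annotator
# ---------------------------------------------------------------------------

@dataclass
class PerturbationConfig:
    """Error model of a simulated annotator.

    Each gold mention is independently deleted with probability
    ``deletion_rate``, relabeled according to the row-stochastic
    ``type_confusion`` matrix, and boundary-shifted (one side, up to
    ``shift_max`` characters) with probability ``boundary_shift_rate``.
    Spurious mentions are then added over unannotated spans at rate
    ``spurious_rate`` (expected spurious count = rate x original mention
    count), which keeps the closed-form precision exact.
    """

    deletion_rate: float = 0.0
    spurious_rate: float = 0.0
    boundary_shift_rate: float = 0.0
    shift_max: int = 1
    type_confusion: dict[EntityType, dict[EntityType, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("deletion_rate", "spurious_rate", "boundary_shift_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.type_confusion is not None:
            for src, row in self.type_confusion.items():
                total = sum(row.values())
                if abs(total - 1.0) > 1e-6:
                    raise ValueError(
                        f"confusion row for {src.value} sums to {total}, expected 1"
                    )

    def confuse(self, etype: EntityType, rng: np.random.Generator) -> EntityType:
        if self.type_confusion is None or etype not in self.type_confusion:
            return etype
        row = self.type_confusion[etype]
        targets = list(row.keys())
        probs = np.array([row[t] for t in targets], dtype=float)
        return targets[rng.choice(len(targets), p=probs / probs.sum())]


def _punct_edge(surface: str) -> bool:
    if not surface:
        return True
    cats = (unicodedata.category(surface[0]), unicodedata.category(surface[-1]))
    return any(c.startswith("P") or c.startswith("Z") for c in cats)


def _overlaps(span: tuple[int, int], spans: Sequence[tuple[int, int]]) -> bool:
    s, e = span
    return any(s < oe and e > os_ for os_, oe in spans)


def perturb_document(
    doc: AnnotatedDocument, p: PerturbationConfig, rng: np.random.Generator
) -> AnnotatedDocument:
    sentence_bounds = [
        (off, off + len(sent)) for sent, off in split_sentences(doc.text)
    ]

    def sentence_of(start: int, end: int) -> tuple[int, int] | None:
        for lo, hi in sentence_bounds:
            if start >= lo and end <= hi:
                return lo, hi
        return None

    kept: list[EntityMention] = []
    for ent in doc.entities:
        if rng.random() < p.deletion_rate:
            continue
        new_type = p.confuse(ent.type, rng)
        start, end = ent.start, ent.end
        if p.boundary_shift_rate > 0 and rng.random() < p.boundary_shift_rate:
            others = [
                (e.start, e.end) for e in doc.entities if e.id != ent.id
            ] + [(e.start, e.end) for e in kept if e.id != ent.id]
            bounds = sentence_of(ent.start, ent.end) or (0, len(doc.text))
            for _attempt in range(10):
                delta = int(rng.integers(1, p.shift_max + 1))
                if rng.random() < 0.5:
                    delta = -delta
                if rng.random() < 0.5:
                    cand = (ent.start + delta, ent.end)
                else:
                    cand = (ent.start, ent.end + delta)
                s, e = cand
                if not (bounds[0] <= s < e <= bounds[1]):
                    continue
                if _overlaps(cand, others):
                    continue
                if _punct_edge(doc.text[s:e]):
                    continue
                start, end = cand
                break
        kept.append(
            EntityMention(ent.id, new_type, start, end, doc.text[start:end])
        )

    # spurious mentions over unannotated filler spans only
    occupied = [(e.start, e.end) for e in kept]
    n_spurious = rng.binomial(len(doc.entities), p.spurious_rate) if doc.entities else 0
    types = list(EntityType)
    added = 0
    next_id = max(
        [int(e.id[1:]) for e in doc.entities if e.id[1:].isdigit()], default=0
    )
    attempts = 0
    while added < n_spurious and attempts < 50 * max(1, n_spurious):
        attempts += 1
        if len(doc.text) < 2:
            break
        length = int(rng.integers(1, 3))
        start = int(rng.integers(0, max(1, len(doc.text) - length + 1)))
        span = (start, start + length)
        surface = doc.text[span[0] : span[1]]
        if "\n" in surface or _punct_edge(surface):
            continue
        if _overlaps(span, occupied):
            continue
        etype = types[rng.choice(len(types))]
        next_id += 1
        kept.append(EntityMention(f"T{next_id}", etype, span[0], span[1], surface))
        occupied.append(span)
        added += 1

    kept.sort(key=lambda e: e.start)
    by_id = {e.id: e for e in kept}
    partner_of = RELATION_PARTNER
    relations = [
        r
        for r in doc.relations
        if r.head in by_id
        and r.tail in by_id
        and {by_id[r.head].type, by_id[r.tail].type}
        == {partner_of[r.type], EntityType.MEDICAL_DISCOVERY}
    ]
    return AnnotatedDocument(doc.doc_id, doc.text, kept, relations)


def perturb_annotations(
    corpus: Sequence[AnnotatedDocument], p: PerturbationConfig
) -> list[AnnotatedDocument]:
    """Simulate a second annotator over a whole corpus (schema-clean output)."""
    rng = np.random.default_rng(p.seed)
    return [perturb_document(doc, p, rng) for doc in corpus]


def expected_agreement(p: PerturbationConfig) -> tuple[float, float]:
    """Closed-form expected (precision, recall) of the perturbed annotator
    against gold under deletions and spurious additions alone (fractions,
    not percent)."""
    keep = 1.0 - p.deletion_rate
    precision = keep / (keep + p.spurious_rate) if keep + p.spurious_rate else 0.0
    return precision, keep
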