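"""Reader/writer for brat-style standoff annotation.

One document is a ``.txt`` / ``.ann`` pair, UTF-8.  The dialect covers two
line types::

    T1<TAB>BodyPart 0 2<TAB>心脏
    R1<TAB>BrSy Arg1:T1 Arg2:T2

Offsets are 0-based half-open code-point offsets into the NFC text.  Reading
then writing a schema-clean document reproduces the annotation lines exactly
(ids are preserved, never renumbered).
"""

from __future__ import annotations

import os
import unicodedata
from pathlib import Path

from .schema import (
    AnnotatedDocument,
    EntityMention,
    EntityType,
    RelationMention,
    RelationType,
)


class StandoffParseError(ValueError):
    """Raised with the offending line number on malformed annotation input."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def parse_standoff(text: str, ann: str, doc_id: str = "doc") -> AnnotatedDocument:
    """Build an :class:`AnnotatedDocument` from text and annotation strings."""
    text = unicodedata.normalize("NFC", text)
    entities: list[EntityMention] = []
    relations: list[RelationMention] = []
    seen: set[str] = set()

    for lineno, raw in enumerate(ann.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        ident = fields[0]
        if ident in seen:
            raise StandoffParseError(lineno, f"duplicate annotation id {ident!r}")
        seen.add(ident)

        if ident.startswith("T"):
            if len(fields) != 3:
                raise StandoffParseError(
                    lineno, "entity line needs 3 tab-separated fields"
                )
            head = fields[1].split(" ")
            if len(head) != 3:
                raise StandoffParseError(
                    lineno, f"expected '<Type> <start> <end>', got {fields[1]!r}"
                )
            type_label, s_start, s_end = head
            try:
                etype = EntityType(type_label)
            except ValueError:
                raise StandoffParseError(
                    lineno, f"unknown entity type {type_label!r}"
                ) from None
            try:
                start, end = int(s_start), int(s_end)
            except ValueError:
                raise StandoffParseError(
                    lineno, f"non-integer offsets {s_start!r} {s_end!r}"
                ) from None
            if not (0 <= start < end <= len(text)):
                raise StandoffParseError(
                    lineno,
                    f"offsets [{start}, {end}) out of range for text of "
                    f"length {len(text)}",
                )
            surface = fields[2]
            if text[start:end] != surface:
                raise StandoffParseError(
                    lineno,
                    f"surface {surface!r} != text[{start}:{end}] "
                    f"== {text[start:end]!r}",
                )
            entities.append(EntityMention(ident, etype, start, end, surface))
        elif ident.startswith("R"):
            if len(fields) != 2:
                raise StandoffParseError(
                    lineno, "relation line needs 2 tab-separated fields"
                )
            parts = fields[1].split(" ")
            if len(parts) != 3:
                raise StandoffParseError(
                    lineno, f"expected '<Type> Arg1:Tx Arg2:Ty', got {fields[1]!r}"
                )
            type_label, arg1, arg2 = parts
            try:
                rtype = RelationType(type_label)
            except ValueError:
                raise StandoffParseError(
                    lineno, f"unknown relation type {type_label!r}"
                ) from None
            if not (arg1.startswith("Arg1:") and arg2.startswith("Arg2:")):
                raise StandoffParseError(lineno, "relation args must be Arg1:/Arg2:")
            relations.append(
                RelationMention(ident, rtype, arg1[5:], arg2[5:])
            )
        else:
            raise StandoffParseError(
                lineno, f"unknown annotation line type {ident!r}"
            )

    known = {e.id for e in entities}
    for rel in relations:
        for ref in (rel.head, rel.tail):
            if ref not in known:
                raise StandoffParseError(
                    0, f"relation {rel.id} references unknown mention {ref!r}"
                )
    return AnnotatedDocument(doc_id, text, entities, relations)


def format_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Render a document back to its (text, ann) string pair."""
    lines = [
        f"{e.id}\t{e.type.value} {e.start} {e.end}\t{e.text}" for e in doc.entities
    ]
    lines += [
        f"{r.id}\t{r.type.value} Arg1:{r.head} Arg2:{r.tail}" for r in doc.relations
    ]
    return doc.text, "\n".join(lines) + ("\n" if lines else "")


def read_standoff(text_path: str | os.PathLike, ann_path: str | os.PathLike
                  ) -> AnnotatedDocument:
    text_path = Path(text_path)
    text = text_path.read_text(encoding="utf-8")
    ann = Path(ann_path).read_text(encoding="utf-8")
    return parse_standoff(text, ann, doc_id=text_path.stem)


def write_standoff(doc: AnnotatedDocument, out_dir: str | os.PathLike
                   ) -> tuple[Path, Path]:
    """Write ``<doc_id>.txt`` and ``<doc_id>.ann`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    text, ann = format_standoff(doc)
    text_path = out / f"{doc.doc_id}.txt"
    ann_path = out / f"{doc.doc_id}.ann"
    text_path.write_text(text, encoding="utf-8")
    ann_path.write_text(ann, encoding="utf-8")
    return text_path, ann_path


def read_corpus(corpus_dir: str | os.PathLike) -> list[AnnotatedDocument]:
    """Read every ``*.txt`` + ``*.ann`` pair in a directory, sorted by name."""
    corpus_dir = Path(corpus_dir)
    docs = []
    for text_path in sorted(corpus_dir.glob("*.txt")):
        ann_path = text_path.with_suffix(".ann")
        if not ann_path.exists():
            raise FileNotFoundError(f"missing annotation file {ann_path}")
        docs.append(read_standoff(text_path, ann_path))
    if not docs:
        raise FileNotFoundError(f"no *.txt documents under {corpus_dir}")
    return docs


def write_corpus(docs, out_dir: str | os.PathLike) -> None:
    for doc in docs:
        write_standoff(doc, out_dir)
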