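"""Text pipeline: sentences, tokens, BIO tags, vocabularies, padded batches.

Sequence labeling is done at sentence level.  A document is split into
sentences at newlines and after the Chinese terminators 。！？；, each
sentence is segmented into words by a pluggable segmenter, each word is
decomposed into characters, and entity spans are converted to token-aligned
BIO tags.  Words, characters and tags are finally mapped to dense indexes
and grouped into padded batches for the tagger.

The segmenter is an injected interface, not a dependency: any callable that
maps a sentence to non-overlapping, ordered ``(start, end)`` spans covering
every non-whitespace character works.  Two deterministic implementations are
bundled — per-character segmentation and greedy longest-match against a
dictionary — because segmentation errors propagate to the tagger and tests
need full control over them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .schema import AnnotatedDocument, EntityMention, EntityType

logger = logging.getLogger(__name__)

PAD = "<PAD>"
UNK = "<UNK>"

#: sentence terminators kept attached to the sentence they end
_TERMINATORS = "。！？；"
_SENT_RE = re.compile(rf"[^\n{_TERMINATORS}]*[{_TERMINATORS}]?")


def split_sentences(text: str) -> list[tuple[str, int]]:
    """Split text into sentences, returning ``(sentence, start_offset)`` pairs.

    Sentences end after a terminator (。！？；) or at a newline; terminators
    stay inside the sentence while newlines act as separators.  Every
    non-newline character belongs to exactly one sentence, so concatenating
    the sentences and separators reconstructs the text.
    """
    sentences: list[tuple[str, int]] = []
    for m in _SENT_RE.finditer(text):
        if m.group():
            sentences.append((m.group(), m.start()))
    return sentences


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

Segmenter = Callable[[str], list[tuple[int, int]]]


class CharSegmenter:
    """One token per non-whitespace character."""

    def __call__(self, sentence: str) -> list[tuple[int, int]]:
        return [(i, i + 1) for i, ch in enumerate(sentence) if not ch.isspace()]


class DictSegmenter:
    """Greedy longest-match segmentation against a fixed word list.

    At each position the longest dictionary word matching the remaining text
    is taken; if none matches, a single character becomes a token.
    Whitespace is skipped.
    """

    def __init__(self, words: Iterable[str]):
        self.words = {w for w in words if w}
        self._max_len = max((len(w) for w in self.words), default=1)

    def __call__(self, sentence: str) -> list[tuple[int, int]]:
        spans: list[tuple[int, int]] = []
        i, n = 0, len(sentence)
        while i < n:
            if sentence[i].isspace():
                i += 1
                continue
            match_end = i + 1
            for length in range(min(self._max_len, n - i), 1, -1):
                if sentence[i : i + length] in self.words:
                    match_end = i + length
                    break
            spans.append((i, match_end))
            i = match_end
        return spans


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int

    @property
    def chars(self) -> list[str]:
        return list(self.text)


def tokenize(sentence: str, segmenter: Segmenter) -> list[Token]:
    """Run a segmenter and validate its output spans."""
    spans = segmenter(sentence)
    prev_end = 0
    tokens = []
    for start, end in spans:
        if not (0 <= start < end <= len(sentence)):
            raise ValueError(f"segmenter returned out-of-range span ({start}, {end})")
        if start < prev_end:
            raise ValueError(f"segmenter returned overlapping span ({start}, {end})")
        if any(not c.isspace() for c in sentence[prev_end:start]):
            raise ValueError(
                f"segmenter skipped non-whitespace text {sentence[prev_end:start]!r}"
            )
        tokens.append(Token(sentence[start:end], start, end))
        prev_end = end
    if any(not c.isspace() for c in sentence[prev_end:]):
        raise ValueError("segmenter left a non-whitespace tail uncovered")
    return tokens


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------

@dataclass
class TaggedSequence:
    """A sentence with its tokens and 1:1 aligned BIO labels."""

    text: str
    tokens: list[Token]
    tags: list[str]
    doc_id: str = ""
    offset: int = 0  # sentence start within the source document

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must align 1:1")


def entities_to_bio(
    tokens: Sequence[Token],
    entities: Sequence[EntityMention],
    policy: str = "error",
) -> list[str]:
    """Convert entity character spans to token-level BIO tags.

    ``policy`` controls what happens when an entity boundary falls inside a
    token: ``"error"`` raises, ``"snap-outward"`` widens the entity to the
    enclosing token boundaries and logs a warning.
    """
    if policy not in ("error", "snap-outward"):
        raise ValueError(f"unknown boundary policy {policy!r}")
    tags = ["O"] * len(tokens)
    for ent in sorted(entities, key=lambda e: e.start):
        covered = [
            i for i, t in enumerate(tokens) if t.start < ent.end and t.end > ent.start
        ]
        if not covered:
            raise ValueError(f"entity {ent.id} covers no tokens")
        first, last = covered[0], covered[-1]
        if tokens[first].start != ent.start or tokens[last].end != ent.end:
            if policy == "error":
                raise ValueError(
                    f"entity {ent.id} [{ent.start},{ent.end}) does not align with "
                    f"token boundaries [{tokens[first].start},{tokens[last].end})"
                )
            logger.warning(
                "snapping entity %s [%d,%d) outward to [%d,%d)",
                ent.id, ent.start, ent.end, tokens[first].start, tokens[last].end,
            )
        for i in covered:
            tags[i] = ("B-" if i == first else "I-") + ent.type.value
    return tags


def bio_to_entities(
    tokens: Sequence[Token],
    tags: Sequence[str],
    id_prefix: str = "T",
) -> list[EntityMention]:
    """Extract entity mentions from BIO tags, repairing invalid sequences.

    An ``I-X`` that follows ``O``, the sentence start, or a different type is
    reinterpreted as ``B-X`` — the model's CRF may emit any tag sequence, and
    this is the conlleval-compatible repair.  Output spans never overlap.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must align 1:1")
    entities: list[EntityMention] = []
    cur_type: str | None = None
    cur_start = cur_end = 0

    def flush() -> None:
        nonlocal cur_type
        if cur_type is not None:
            n = len(entities) + 1
            text = "".join(
                t.text for t in tokens if t.start >= cur_start and t.end <= cur_end
            )
            entities.append(
                EntityMention(
                    f"{id_prefix}{n}", EntityType(cur_type), cur_start, cur_end, text
                )
            )
        cur_type = None

    for token, tag in zip(tokens, tags):
        if tag == "O":
            flush()
            continue
        prefix, _, label = tag.partition("-")
        if prefix == "B" or cur_type != label:
            flush()
            cur_type = label
            cur_start = token.start
        cur_end = token.end
    flush()
    return entities


def is_valid_bio(tags: Sequence[str]) -> bool:
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            if prev == "O" or prev[2:] != tag[2:]:
                return False
        prev = tag
    return True


def document_to_sequences(
    doc: AnnotatedDocument,
    segmenter: Segmenter,
    policy: str = "error",
) -> list[TaggedSequence]:
    """Split a document into sentences and produce gold-tagged sequences."""
    sequences = []
    for sent, offset in split_sentences(doc.text):
        tokens = tokenize(sent, segmenter)
        if not tokens:
            continue
        local = [
            EntityMention(e.id, e.type, e.start - offset, e.end - offset, e.text)
            for e in doc.entities
            if e.start >= offset and e.end <= offset + len(sent)
        ]
        tags = entities_to_bio(tokens, local, policy=policy)
        sequences.append(TaggedSequence(sent, tokens, tags, doc.doc_id, offset))
    return sequences


# ---------------------------------------------------------------------------
# vocabulary and batch encoding
# ---------------------------------------------------------------------------

def bio_tag_set(types: Iterable[EntityType] = EntityType) -> list[str]:
    """The full BIO tag inventory: O first, then B-/I- per type, sorted."""
    tags = ["O"]
    for t in sorted(types, key=lambda t: t.value):
        tags += [f"B-{t.value}", f"I-{t.value}"]
    return tags


@dataclass
class Vocab:
    """Word, character and tag index maps.  PAD is index 0, UNK index 1."""

    word_to_index: dict[str, int]
    char_to_index: dict[str, int]
    tag_to_index: dict[str, int]

    @classmethod
    def from_sequences(cls, sequences: Sequence[TaggedSequence]) -> "Vocab":
        words: set[str] = set()
        chars: set[str] = set()
        for seq in sequences:
            for token in seq.tokens:
                words.add(token.text)
                chars.update(token.text)
        word_to_index = {PAD: 0, UNK: 1}
        for w in sorted(words):
            word_to_index[w] = len(word_to_index)
        char_to_index = {PAD: 0, UNK: 1}
        for c in sorted(chars):
            char_to_index[c] = len(char_to_index)
        tag_to_index = {t: i for i, t in enumerate(bio_tag_set())}
        return cls(word_to_index, char_to_index, tag_to_index)

    @property
    def tags(self) -> list[str]:
        return [t for t, _ in sorted(self.tag_to_index.items(), key=lambda kv: kv[1])]

    def word_index(self, word: str) -> int:
        return self.word_to_index.get(word, self.word_to_index[UNK])

    def char_index(self, ch: str) -> int:
        return self.char_to_index.get(ch, self.char_to_index[UNK])

    # -- serialization: one symbol per line, index order -------------------
    def to_text(self) -> str:
        def block(mapping: dict[str, int]) -> str:
            return "\n".join(s for s, _ in sorted(mapping.items(), key=lambda kv: kv[1]))

        return (
            block(self.word_to_index)
            + "\n---\n"
            + block(self.char_to_index)
            + "\n---\n"
            + block(self.tag_to_index)
            + "\n"
        )

    @classmethod
    def from_text(cls, text: str) -> "Vocab":
        blocks = text.rstrip("\n").split("\n---\n")
        if len(blocks) != 3:
            raise ValueError("vocab text must contain word/char/tag blocks")
        maps = [{s: i for i, s in enumerate(b.split("\n"))} for b in blocks]
        return cls(*maps)


@dataclass
class EncodedBatch:
    """Index tensors for one batch of sentences, padded and masked.

    ``words`` is (batch, L); ``chars`` is (batch, L, C) with per-word padding
    appended at the end (C is at least 4 so every CNN kernel width fits);
    ``mask`` marks real tokens; ``tags`` is (batch, L).
    """

    words: np.ndarray
    chars: np.ndarray
    mask: np.ndarray
    tags: np.ndarray
    sequences: list[TaggedSequence] = field(default_factory=list)


def encode_batch(
    sequences: Sequence[TaggedSequence],
    vocab: Vocab,
    batch_size: int = 20,
    max_word_len: int | None = None,
) -> list[EncodedBatch]:
    """Group sequences into padded index batches of at most ``batch_size``.

    ``max_word_len`` optionally caps character padding; by default the
    longest word in each batch (floored at 4 for the CNN kernels) decides.
    """
    if not sequences:
        raise ValueError("encode_batch requires at least one sequence")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batches = []
    for lo in range(0, len(sequences), batch_size):
        chunk = list(sequences[lo : lo + batch_size])
        L = max(len(s.tokens) for s in chunk)
        C = max(
            (len(t.text) for s in chunk for t in s.tokens), default=1
        )
        if max_word_len is not None:
            C = min(C, max_word_len)
        C = max(C, 4)
        B = len(chunk)
        words = np.zeros((B, L), dtype=np.int64)
        chars = np.zeros((B, L, C), dtype=np.int64)
        mask = np.zeros((B, L), dtype=bool)
        tags = np.zeros((B, L), dtype=np.int64)
        for b, seq in enumerate(chunk):
            for j, (token, tag) in enumerate(zip(seq.tokens, seq.tags)):
                words[b, j] = vocab.word_index(token.text)
                for k, ch in enumerate(token.text[:C]):
                    chars[b, j, k] = vocab.char_index(ch)
                mask[b, j] = True
                tags[b, j] = vocab.tag_to_index[tag]
        batches.append(EncodedBatch(words, chars, mask, tags, chunk))
    return batches


# ---------------------------------------------------------------------------
# CoNLL two-column I/O
# ---------------------------------------------------------------------------

def write_conll(sequences: Iterable[TaggedSequence], path: str | Path) -> None:
    """Write ``token<TAB>tag`` lines with blank lines between sentences."""
    lines = []
    for seq in sequences:
        for token, tag in zip(seq.tokens, seq.tags):
            lines.append(f"{token.text}\t{tag}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_conll(path: str | Path) -> list[TaggedSequence]:
    """Read a two-column BIO file; offsets are rebuilt by concatenation."""
    sequences: list[TaggedSequence] = []
    tokens: list[Token] = []
    tags: list[str] = []
    pos = 0

    def flush() -> None:
        nonlocal tokens, tags, pos
        if tokens:
            text = "".join(t.text for t in tokens)
            sequences.append(TaggedSequence(text, tokens, tags))
        tokens, tags, pos = [], [], 0

    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'token<TAB>tag', got {line!r}")
        word, tag = parts
        tokens.append(Token(word, pos, pos + len(word)))
        tags.append(tag)
        pos += len(word)
    flush()
    return sequences
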