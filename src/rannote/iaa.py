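"""Inter-annotator agreement as precision / recall / F between two annotators.

One annotator (A) is taken as the reference.  For every entity type the
engine counts A's mentions, B's mentions, and the consistent pairs, then

    P = 100 * consistent / |B|
    R = 100 * consistent / |A|
    F = 2PR / (P + R)

P, R and F are kept at full precision internally; F is computed from the
unrounded P and R, and every figure is rounded to two decimals only for
display.  With both denominators equal to the counts, F reduces to
``200 * consistent / (|A| + |B|)``.

The default matching criterion is the strictest one: two mentions agree iff
start, end and type are all equal.  A relaxed criterion (same type, spans
overlap) is available behind a flag.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .schema import AnnotatedDocument, EntityMention, EntityType

TOTAL = "Total"


@dataclass(frozen=True)
class AgreementCounts:
    """Mention counts for one entity type (or the micro total)."""

    type: str
    n_a: int
    n_b: int
    n_consistent: int

    def __post_init__(self) -> None:
        if min(self.n_a, self.n_b, self.n_consistent) < 0:
            raise ValueError("agreement counts must be non-negative")
        if self.n_consistent > min(self.n_a, self.n_b):
            raise ValueError(
                f"consistent count {self.n_consistent} exceeds "
                f"min(|A|, |B|) = {min(self.n_a, self.n_b)}"
            )


@dataclass(frozen=True)
class PRF:
    """Precision / recall / F triple on the 0-100 percent scale, unrounded.

    ``_display`` optionally carries the two-decimal rendering computed in
    exact rational arithmetic, so that values falling precisely on a
    rounding tie (e.g. 15.625) are not at the mercy of binary float noise.
    """

    precision: float
    recall: float
    f1: float
    _display: tuple[float, float, float] | None = None

    def rounded(self) -> tuple[float, float, float]:
        if self._display is not None:
            return self._display
        return (round(self.precision, 2), round(self.recall, 2), round(self.f1, 2))


def f_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of already-computed P and R (percent scale)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def prf(counts: AgreementCounts) -> PRF:
    """P/R/F from raw counts; empty denominators give the defined zero.

    Internally exact: counts are integers, so P, R and F are rationals and
    are rounded for display once, at the very end.
    """
    from fractions import Fraction

    c = counts.n_consistent
    p = Fraction(100 * c, counts.n_b) if counts.n_b else Fraction(0)
    r = Fraction(100 * c, counts.n_a) if counts.n_a else Fraction(0)
    f = 2 * p * r / (p + r) if p + r else Fraction(0)
    display = tuple(float(round(v, 2)) for v in (p, r, f))
    return PRF(float(p), float(r), float(f), display)


def match_annotations(
    set_a: Sequence[EntityMention],
    set_b: Sequence[EntityMention],
    criterion: str = "exact",
) -> dict[str, AgreementCounts]:
    """Count per-type and total agreement between two mention sets.

    Both sets must come from the same document text.  Under ``"exact"`` a
    pair matches iff (start, end, type) coincide; since schema-clean
    annotation sets contain no overlapping spans, exact matches are unique
    and greedy counting is safe.  Under ``"overlap"`` mentions of the same
    type match if their spans intersect, each mention used at most once
    (greedy in span order).
    """
    if criterion not in ("exact", "overlap"):
        raise ValueError(f"unknown matching criterion {criterion!r}")

    per_type: dict[str, AgreementCounts] = {}
    for etype in EntityType:
        a = [m for m in set_a if m.type == etype]
        b = [m for m in set_b if m.type == etype]
        if criterion == "exact":
            spans_a = Counter((m.start, m.end) for m in a)
            spans_b = Counter((m.start, m.end) for m in b)
            consistent = sum((spans_a & spans_b).values())
        else:
            used = [False] * len(b)
            b_sorted = sorted(range(len(b)), key=lambda i: (b[i].start, b[i].end))
            consistent = 0
            for m in sorted(a, key=lambda m: (m.start, m.end)):
                for i in b_sorted:
                    if not used[i] and b[i].start < m.end and b[i].end > m.start:
                        used[i] = True
                        consistent += 1
                        break
        per_type[etype.value] = AgreementCounts(etype.value, len(a), len(b), consistent)

    per_type[TOTAL] = AgreementCounts(
        TOTAL,
        sum(c.n_a for t, c in per_type.items() if t != TOTAL),
        sum(c.n_b for t, c in per_type.items() if t != TOTAL),
        sum(c.n_consistent for t, c in per_type.items() if t != TOTAL),
    )
    return per_type


def match_documents(
    doc_a: AnnotatedDocument, doc_b: AnnotatedDocument, criterion: str = "exact"
) -> dict[str, AgreementCounts]:
    if doc_a.doc_id != doc_b.doc_id or doc_a.text != doc_b.text:
        raise ValueError(
            f"cannot mix annotations from different documents "
            f"({doc_a.doc_id!r} vs {doc_b.doc_id!r})"
        )
    return match_annotations(doc_a.entities, doc_b.entities, criterion)


def agreement_report(
    corpus_a: Sequence[AnnotatedDocument],
    corpus_b: Sequence[AnnotatedDocument],
    criterion: str = "exact",
) -> pd.DataFrame:
    """Per-type consistency table over two parallel corpora, plus a micro total.

    Rows carry the raw counts and P/R/F rounded to two decimals; the Total
    row pools counts over types (micro-average).  Raises if the two corpora
    do not cover the same doc_ids, listing the symmetric difference.
    """
    ids_a = {d.doc_id for d in corpus_a}
    ids_b = {d.doc_id for d in corpus_b}
    if ids_a != ids_b:
        raise ValueError(
            f"corpora cover different documents; symmetric difference: "
            f"{sorted(ids_a ^ ids_b)}"
        )
    by_id_b = {d.doc_id: d for d in corpus_b}

    totals: dict[str, list[int]] = {t.value: [0, 0, 0] for t in EntityType}
    for doc_a in corpus_a:
        counts = match_documents(doc_a, by_id_b[doc_a.doc_id], criterion)
        for t in EntityType:
            c = counts[t.value]
            acc = totals[t.value]
            acc[0] += c.n_a
            acc[1] += c.n_b
            acc[2] += c.n_consistent

    rows = []
    for label, (n_a, n_b, n_c) in totals.items():
        rows.append(_report_row(AgreementCounts(label, n_a, n_b, n_c)))
    rows.append(
        _report_row(
            AgreementCounts(
                TOTAL,
                sum(v[0] for v in totals.values()),
                sum(v[1] for v in totals.values()),
                sum(v[2] for v in totals.values()),
            )
        )
    )
    return pd.DataFrame(rows)


def _report_row(counts: AgreementCounts) -> dict:
    p, r, f = prf(counts).rounded()
    return {
        "type": counts.type,
        "n_A": counts.n_a,
        "n_B": counts.n_b,
        "n_consistent": counts.n_consistent,
        "P": p,
        "R": r,
        "F": f,
    }


def render_report(report: pd.DataFrame) -> str:
    """Aligned text rendering of an agreement (or evaluation) table."""
    return report.to_string(index=False, float_format=lambda v: f"{v:.2f}")
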