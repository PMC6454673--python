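"""Entity-level evaluation in the CoNLL-2003 shared-task style.

Entities are extracted from gold and predicted BIO tag sequences (predicted
sequences are repaired first: an I-X with no matching B is read as B-X,
matching conlleval's effective behaviour) and a prediction is correct only
on exact span *and* type.  Precision, recall and F are reported per type and
overall, with overall counts pooled over types (micro-average).  The
counting semantics are deliberately identical to the inter-annotator
agreement engine with gold as annotator A and the prediction as annotator B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .iaa import AgreementCounts, prf
from .pipeline import TaggedSequence, bio_to_entities
from .schema import EntityType

OVERALL = "Total"


@dataclass
class EvalReport:
    """Per-type and overall scoring rows."""

    frame: pd.DataFrame

    def row(self, label: str) -> dict:
        match = self.frame[self.frame["type"] == label]
        if match.empty:
            raise KeyError(label)
        return match.iloc[0].to_dict()

    @property
    def overall_f(self) -> float:
        return float(self.row(OVERALL)["F"])

    def to_string(self) -> str:
        return self.frame.to_string(index=False, float_format=lambda v: f"{v:.2f}")


def _extract(sequences: Sequence[TaggedSequence], seq_index: int, seq: TaggedSequence,
             tags: Sequence[str]) -> set[tuple]:
    # entity key: (sequence index, token start, token end, type)
    ents = bio_to_entities(seq.tokens, list(tags))
    return {(seq_index, e.start, e.end, e.type) for e in ents}


def conll_evaluate(
    gold: Sequence[TaggedSequence], pred: Sequence[TaggedSequence]
) -> EvalReport:
    """Score predicted sequences against gold, entity level, exact match."""
    if len(gold) != len(pred):
        raise ValueError(
            f"gold has {len(gold)} sequences but pred has {len(pred)}"
        )
    gold_ents: set[tuple] = set()
    pred_ents: set[tuple] = set()
    for i, (g, p) in enumerate(zip(gold, pred)):
        if len(g.tokens) != len(p.tokens):
            raise ValueError(f"sequence {i}: token count mismatch")
        gold_ents |= _extract(gold, i, g, g.tags)
        pred_ents |= _extract(pred, i, p, p.tags)

    rows = []
    total = [0, 0, 0]
    for etype in EntityType:
        g = {e for e in gold_ents if e[3] == etype}
        p = {e for e in pred_ents if e[3] == etype}
        correct = len(g & p)
        total[0] += len(g)
        total[1] += len(p)
        total[2] += correct
        rows.append(_eval_row(etype.value, len(g), len(p), correct))
    rows.append(_eval_row(OVERALL, *total))
    return EvalReport(pd.DataFrame(rows))


def _eval_row(label: str, n_gold: int, n_pred: int, n_correct: int) -> dict:
    # reuse the IAA arithmetic: gold plays annotator A, prediction annotator B
    p, r, f = prf(AgreementCounts(label, n_gold, n_pred, n_correct)).rounded()
    return {
        "type": label,
        "n_gold": n_gold,
        "n_pred": n_pred,
        "n_correct": n_correct,
        "P": p,
        "R": r,
        "F": f,
    }
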