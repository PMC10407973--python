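"""DrugProt-style scoring: micro and per-type precision/recall/F1,
confusion counts, and report-to-report differences.

Scoring is over relation tuples (pmid, arg1, arg2, type).  A predicted
tuple is a true positive iff an identical gold tuple exists; an unmatched
positive prediction is a false positive of its label; an unmatched gold
tuple is a false negative of its label.  NONE predictions never generate
false positives, and micro scores sum TP/FP/FN over the 13 positive types
only.  Division by an empty denominator reports 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats_io import POSITIVE_LABELS, RelationLabel

logger = logging.getLogger(__name__)

#: A scored relation tuple.
Tuple4 = tuple[str, str, str, RelationLabel]


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, _f1(p, r)


@dataclass
class EvalReport:
    """Precision/recall/F1 per relation type and micro-averaged, plus raw
    TP/FP/FN counts.  All rates are fractions in [0, 1]."""

    per_type: dict[RelationLabel, tuple[float, float, float]] = field(default_factory=dict)
    micro: tuple[float, float, float] = (0.0, 0.0, 0.0)
    counts: dict[RelationLabel, tuple[int, int, int]] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, counts: Mapping[RelationLabel, tuple[int, int, int]]
    ) -> "EvalReport":
        per_type = {lab: _prf(*counts[lab]) for lab in POSITIVE_LABELS}
        tp = sum(counts[lab][0] for lab in POSITIVE_LABELS)
        fp = sum(counts[lab][1] for lab in POSITIVE_LABELS)
        fn = sum(counts[lab][2] for lab in POSITIVE_LABELS)
        return cls(per_type=per_type, micro=_prf(tp, fp, fn), counts=dict(counts))

    @property
    def micro_f1(self) -> float:
        return self.micro[2]

    def to_text(self) -> str:
        rows = [f"{'Type':<24}{'Prec':>8}{'Recall':>8}{'F1':>8}"]
        for lab in POSITIVE_LABELS:
            p, r, f = self.per_type.get(lab, (0.0, 0.0, 0.0))
            rows.append(
                f"{lab.to_string():<24}{100*p:>8.2f}{100*r:>8.2f}{100*f:>8.2f}"
            )
        p, r, f = self.micro
        rows.append(f"{'Micro-average':<24}{100*p:>8.2f}{100*r:>8.2f}{100*f:>8.2f}")
        return "\n".join(rows)


def _dedup(tuples: Iterable[Tuple4], what: str) -> set[Tuple4]:
    seen: set[Tuple4] = set()
    n_dup = 0
    for t in tuples:
        if t in seen:
            n_dup += 1
        seen.add(t)
    if n_dup:
        logger.warning("%s: de-duplicated %d identical tuples", what, n_dup)
    return seen


def evaluate(gold: Iterable[Tuple4], predictions: Iterable[Tuple4]) -> EvalReport:
    """Score prediction tuples against gold tuples.

    Both inputs are (pmid, arg1, arg2, label) tuples; a pair may carry
    several gold types.  Duplicate identical tuples are de-duplicated with
    a warning.  Predictions labelled NONE are ignored (a NONE prediction is
    the absence of a prediction).
    """
    gold_set = _dedup(gold, "gold")
    pred_set = _dedup(
        (t for t in predictions if t[3] is not RelationLabel.NONE), "predictions"
    )
    for t in gold_set:
        if t[3] is RelationLabel.NONE:
            raise ValueError("gold tuples must not carry the NONE label")

    counts: dict[RelationLabel, list[int]] = {
        lab: [0, 0, 0] for lab in POSITIVE_LABELS
    }
    for t in pred_set:
        if t in gold_set:
            counts[t[3]][0] += 1  # TP
        else:
            counts[t[3]][1] += 1  # FP of the predicted label
    for t in gold_set:
        if t not in pred_set:
            counts[t[3]][2] += 1  # FN of the gold label
    return EvalReport.from_counts({k: tuple(v) for k, v in counts.items()})


def confusion_matrix(
    gold: Iterable[Tuple4],
    predictions: Iterable[Tuple4],
    omit_none_predictions: bool = False,
) -> dict[tuple[RelationLabel, RelationLabel], int]:
    """Per-pair-key confusion counts over (gold label, predicted label).

    A pair key with gold but no (positive) prediction counts in the
    (gold, NONE) cell; a positive prediction on an un-annotated pair counts
    in (NONE, predicted).  ``omit_none_predictions`` drops the NONE
    prediction column, the usual rendering for published matrices.
    """
    gold_by_pair: dict[tuple[str, str, str], set[RelationLabel]] = {}
    for pmid, a1, a2, lab in _dedup(gold, "gold"):
        gold_by_pair.setdefault((pmid, a1, a2), set()).add(lab)
    pred_by_pair: dict[tuple[str, str, str], set[RelationLabel]] = {}
    for pmid, a1, a2, lab in _dedup(predictions, "predictions"):
        pred_by_pair.setdefault((pmid, a1, a2), set()).add(lab)

    cells: dict[tuple[RelationLabel, RelationLabel], int] = {}
    for key in set(gold_by_pair) | set(pred_by_pair):
        gold_labels = gold_by_pair.get(key, {RelationLabel.NONE})
        pred_labels = pred_by_pair.get(key, {RelationLabel.NONE}) - {RelationLabel.NONE}
        if not pred_labels:
            pred_labels = {RelationLabel.NONE}
        for g in gold_labels:
            for p in pred_labels:
                cells[(g, p)] = cells.get((g, p), 0) + 1
    if omit_none_predictions:
        cells = {k: v for k, v in cells.items() if k[1] is not RelationLabel.NONE}
    return cells


def confusion_to_delimited(
    cells: Mapping[tuple[RelationLabel, RelationLabel], int], sep: str = "\t"
) -> str:
    """Render confusion counts as a delimited grid (gold rows, predicted
    columns) over the labels that occur."""
    labels = sorted(
        {g for g, _ in cells} | {p for _, p in cells}, key=int
    )
    lines = [sep.join(["gold\\pred"] + [lab.to_string() for lab in labels])]
    for g in labels:
        lines.append(
            sep.join([g.to_string()] + [str(cells.get((g, p), 0)) for p in labels])
        )
    return "\n".join(lines)


def diff_reports(
    report_a: EvalReport, report_b: EvalReport
) -> dict[str, tuple[float, float, float]]:
    """Per-metric differences (b - a) in percentage points, keyed by the
    relation-type string plus ``Micro-average``."""
    if set(report_a.per_type) != set(report_b.per_type):
        raise ValueError("reports cover different label sets")
    out: dict[str, tuple[float, float, float]] = {}
    for lab in report_a.per_type:
        pa, ra, fa = report_a.per_type[lab]
        pb, rb, fb = report_b.per_type[lab]
        out[lab.to_string()] = (100 * (pb - pa), 100 * (rb - ra), 100 * (fb - fa))
    pa, ra, fa = report_a.micro
    pb, rb, fb = report_b.micro
    out["Micro-average"] = (100 * (pb - pa), 100 * (rb - ra), 100 * (fb - fa))
    return out


def predictions_to_tuples(predictions) -> list[Tuple4]:
    """Lift PredictionRow / (pair_key, label) objects into scorer tuples."""
    out: list[Tuple4] = []
    for p in predictions:
        if hasattr(p, "pmid"):
            out.append((p.pmid, p.arg1, p.arg2, p.label))
        elif hasattr(p, "pair_key") and p.pair_key is not None:
            pmid, a1, a2 = p.pair_key
            out.append((pmid, a1, a2, p.label))
        else:
            raise ValueError(f"cannot convert {p!r} to a scorer tuple")
    return out


def gold_to_tuples(relations) -> list[Tuple4]:
    return [(r.pmid, r.arg1, r.arg2, r.rtype) for r in relations]
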