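"""Knowledge-base agreement filtering of weak (model-predicted) labels.

A chemical-gene knowledge base is indexed by pair presence only — no
relation-type mapping is attempted, because KB action vocabularies and
corpus label schemas differ.  A model prediction survives refinement iff it
agrees with the KB:

* a positive label is kept only when the (chemical id, gene id) pair is
  listed in the KB;
* a NONE label is kept only when the pair is absent.

Everything else is dropped.  Refinement never rewrites labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .formats_io import KBRecord, RelationLabel
from .preprocess import MarkedSequence

Normalizer = Callable[[str], str]


def default_normalizer(s: str) -> str:
    """Case-fold and collapse internal whitespace."""
    return " ".join(s.split()).casefold()


@dataclass
class KBIndex:
    """Pair-presence index over normalized (chem_id, gene_id) pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    pair_pmids: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    normalizer: Normalizer = default_normalizer

    @property
    def doc_pmids(self) -> set[str]:
        out: set[str] = set()
        for pmids in self.pair_pmids.values():
            out |= pmids
        return out

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.has_pair(*pair)

    def has_pair(self, chem_id: str | None, gene_id: str | None) -> bool:
        """Pure membership test; unset or empty ids are never present."""
        if not chem_id or not gene_id:
            return False
        return (self.normalizer(chem_id), self.normalizer(gene_id)) in self.pairs


def build_kb_index(
    records: Iterable[KBRecord], normalizer: Normalizer = default_normalizer
) -> KBIndex:
    """Merge KB records into a pair index; duplicate pairs union their
    supporting PMIDs."""
    index = KBIndex(normalizer=normalizer)
    for rec in records:
        key = (normalizer(rec.chem_id), normalizer(rec.gene_id))
        index.pairs.add(key)
        index.pair_pmids[key] = index.pair_pmids.get(key, frozenset()) | rec.pmids
    return index


def kb_has_pair(index: KBIndex, chem_id: str | None, gene_id: str | None) -> bool:
    return index.has_pair(chem_id, gene_id)


@dataclass(frozen=True)
class PairPrediction:
    """A model prediction for one candidate pair, carrying the KB-resolvable
    identifiers of its arguments.

    ``chem_id`` / ``gene_id`` are the normalized-entity identifiers when
    linking succeeded, else the surface forms (the index normalizer then
    matches them against KB name columns); empty/None means unlinked.
    """

    pair_key: tuple[str, str, str]  # (pmid, chem mention_id, gene mention_id)
    chem_id: str | None
    gene_id: str | None
    label: RelationLabel
    sequence: MarkedSequence | None = None


@dataclass(frozen=True)
class AugmentedExample:
    """A kept weak example: the model's label plus provenance."""

    sequence: MarkedSequence | None
    pair_key: tuple[str, str, str]
    label: RelationLabel
    model_label: RelationLabel
    kb_present: bool

    def __post_init__(self):
        assert self.label == self.model_label, "refinement never rewrites labels"


@dataclass
class RefineReport:
    """Bookkeeping for one refinement pass.

    ``breakdown`` counts predictions by (model positive/negative, KB pair
    present/absent); the kept cells are (positive, present) and
    (negative, absent).
    """

    n_input: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    n_unlinked: int = 0
    breakdown: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("positive", "kb_present"): 0,
            ("positive", "kb_absent"): 0,
            ("negative", "kb_present"): 0,
            ("negative", "kb_absent"): 0,
        }
    )

    def to_text(self) -> str:
        lines = [
            f"input        {self.n_input}",
            f"kept         {self.n_kept}",
            f"dropped      {self.n_dropped}",
            f"unlinked     {self.n_unlinked}",
        ]
        for (polarity, presence), n in sorted(self.breakdown.items()):
            lines.append(f"{polarity:<9}{presence:<12} {n}")
        return "\n".join(lines)


def refine(
    predictions: Sequence[PairPrediction], index: KBIndex
) -> tuple[list[AugmentedExample], RefineReport]:
    """Filter predictions by KB agreement.

    Keep iff (label != NONE and pair in KB) or (label == NONE and pair not
    in KB); drop otherwise.  Kept predictions become augmented examples
    carrying the model's label unchanged.
    """
    kept: list[AugmentedExample] = []
    report = RefineReport(n_input=len(predictions))
    for pred in predictions:
        linked = bool(pred.chem_id) and bool(pred.gene_id)
        if not linked:
            report.n_unlinked += 1
        present = index.has_pair(pred.chem_id, pred.gene_id)
        positive = pred.label is not RelationLabel.NONE
        report.breakdown[
            (
                "positive" if positive else "negative",
                "kb_present" if present else "kb_absent",
            )
        ] += 1
        if positive == present:
            kept.append(
                AugmentedExample(
                    sequence=pred.sequence,
                    pair_key=pred.pair_key,
                    label=pred.label,
                    model_label=pred.label,
                    kb_present=present,
                )
            )
    report.n_kept = len(kept)
    report.n_dropped = report.n_input - report.n_kept
    return kept, report


def exclude_dev_overlap(
    docs: Iterable, holdout_pmids: Iterable[str]
) -> tuple[list, int]:
    """Drop documents whose pmid appears in the held-out (development) set,
    preserving evaluation integrity of the weak-label pool."""
    holdout = set(holdout_pmids)
    docs_list = list(docs)
    kept = [d for d in docs_list if d.pmid not in holdout]
    return kept, len(docs_list) - len(kept)


def restrict_to_kb_documents(docs: Sequence, index: KBIndex) -> list:
    """Keep only documents cited as supporting evidence in the KB — the
    default source pool for weak labelling (disable by not calling)."""
    doc_pmids = index.doc_pmids
    return [d for d in docs if d.pmid in doc_pmids]
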