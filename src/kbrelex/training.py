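"""Three-phase training orchestration: weak pretrain, transfer, fine-tune;
plus the merged train+dev resplit strategy and checkpoint selection.

Phase 0 (not in this module's entry point) trains a seed model on the gold
data and predicts over an unlabelled pool; ``kb_refine`` filters those
predictions into the augmented set.  ``pretrain_finetune`` then fits a
fresh model on the augmented set, exports its parameters, and continues
training from them on the gold data.  Transfer preserves the parameter
space: before any fine-tuning step the transferred model reproduces the
pretrained model's predictions exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .classifier import ClassifierConfig, ReferenceClassifier, make_classifier
from .formats_io import DocumentSet, RelationLabel
from .kb_refine import AugmentedExample, KBIndex, PairPrediction, RefineReport, refine
from .preprocess import (
    CandidatePair,
    MarkedSequence,
    MarkingMethod,
    MarkerVocab,
    label_candidates,
    mark_entities,
    split_sentences,
    project_entities,
    enumerate_pairs,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Checkpoint:
    step: int
    params: Mapping[str, np.ndarray]
    dev_f1: float


def select_checkpoint(checkpoints: Sequence[Checkpoint]) -> Checkpoint:
    """Highest development micro-F1; ties resolve to the earliest step."""
    if not checkpoints:
        raise ValueError("no checkpoints to select from")
    return min(checkpoints, key=lambda c: (-c.dev_f1, c.step))


@dataclass(frozen=True)
class ResplitPlan:
    """Document-level k-fold resplit of the merged train+dev documents."""

    k: int
    pairs: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, dev) pmids
    seed: int


def resplit_train_dev(
    train_pmids: Sequence[str], dev_pmids: Sequence[str], k: int = 10, seed: int = 0
) -> ResplitPlan:
    """Merge the train and dev document ids and split them into ``k``
    disjoint partitions; pair i uses partition i as dev and the other k-1
    as train.  Partitioning is at document level so sentences from one
    abstract never straddle a train/dev boundary."""
    if k < 2:
        raise ValueError("k must be >= 2")
    merged = sorted(set(train_pmids) | set(dev_pmids))
    if len(merged) < k:
        raise ValueError(f"cannot split {len(merged)} documents into {k} partitions")
    rng = np.random.default_rng(seed)
    order = [merged[i] for i in rng.permutation(len(merged))]
    partitions: list[list[str]] = [order[i::k] for i in range(k)]
    pairs = []
    for i in range(k):
        dev = tuple(sorted(partitions[i]))
        train = tuple(sorted(p for j, part in enumerate(partitions) if j != i for p in part))
        pairs.append((train, dev))
    return ResplitPlan(k=k, pairs=tuple(pairs), seed=seed)


# ---------------------------------------------------------------------------
# Example construction
# ---------------------------------------------------------------------------


@dataclass
class ExampleSet:
    """Marked sequences + labels + candidate pairs for one document set."""

    pairs: list[CandidatePair]
    sequences: list[MarkedSequence]
    labels: list[RelationLabel]

    def __len__(self) -> int:
        return len(self.pairs)


def build_examples(
    docset: DocumentSet,
    method: MarkingMethod = MarkingMethod.WRAP_TYPE_SE,
    vocab: MarkerVocab = MarkerVocab(),
) -> ExampleSet:
    """Sentence-split every document, enumerate candidate pairs, mark each
    pair's sentence, and attach gold labels (NONE for unannotated pairs)."""
    pairs: list[CandidatePair] = []
    sequences: list[MarkedSequence] = []
    for doc in docset:
        windows = split_sentences(doc)
        project_entities(doc, windows)
        for w in windows:
            for pair in enumerate_pairs(w):
                pairs.append(pair)
                sequences.append(mark_entities(w, pair, method, vocab))
    labels = label_candidates(pairs, docset.relations)
    return ExampleSet(pairs=pairs, sequences=sequences, labels=labels)


def weak_label(
    model: ReferenceClassifier,
    pool: DocumentSet,
    index: KBIndex,
    method: MarkingMethod = MarkingMethod.WRAP_TYPE_SE,
    vocab: MarkerVocab = MarkerVocab(),
) -> tuple[list[AugmentedExample], RefineReport]:
    """Predict over an unlabelled pool and refine by KB agreement."""
    examples = build_examples(pool, method, vocab)
    preds = model.predict(examples.sequences, pair_keys=[p.pair_key for p in examples.pairs])
    pair_preds = [
        PairPrediction(
            pair_key=pair.pair_key,
            chem_id=pair.chem.norm_id or pair.chem.surface,
            gene_id=pair.gene.norm_id or pair.gene.surface,
            label=pred.label,
            sequence=seq,
        )
        for pair, seq, pred in zip(examples.pairs, examples.sequences, preds)
    ]
    return refine(pair_preds, index)


# ---------------------------------------------------------------------------
# Two-phase training
# ---------------------------------------------------------------------------


def pretrain_finetune(
    cfg: ClassifierConfig,
    augmented: Sequence[AugmentedExample],
    original_train: ExampleSet,
    pretrain_steps: int | None = None,
) -> ReferenceClassifier:
    """Phase 1: fit on the augmented (weakly labelled) set; phase 2:
    transfer the parameters and continue fitting on the gold data.

    An empty augmented set falls back to single-phase training with a
    warning.  ``pretrain_steps`` overrides ``cfg.max_steps`` for phase 1.
    """
    if len(original_train) == 0:
        raise ValueError("empty gold training set")
    if len(augmented) == 0:
        logger.warning("empty augmented set; falling back to single-phase training")
        model = make_classifier(cfg)
        model.fit(original_train.sequences, original_train.labels)
        return model

    phase1_cfg = cfg if pretrain_steps is None else replace(cfg, max_steps=pretrain_steps)
    pre = make_classifier(phase1_cfg)
    pre.fit(
        [ex.sequence for ex in augmented],
        [ex.label for ex in augmented],
    )
    logger.info("phase 1 (weak pretrain): %d examples, %d steps",
                len(augmented), phase1_cfg.max_steps)
    params = pre.export_params()

    fine = make_classifier(cfg)
    fine.fit(original_train.sequences, original_train.labels, init_params=params)
    logger.info("phase 2 (fine-tune): %d examples, %d steps",
                len(original_train), cfg.max_steps)
    return fine


# ---------------------------------------------------------------------------
# Desk-scale recovery experiment: labelled-only baseline vs two-phase
# ---------------------------------------------------------------------------


@dataclass
class RecoveryResult:
    """One seed of the weak-supervision recovery experiment."""

    seed: int
    baseline_f1: float
    two_phase_f1: float
    refine_report: RefineReport
    n_labelled: int
    n_weak: int
    n_test: int


def split_pmids(
    pmids: Sequence[str], seed: int, weak_to_labelled: int = 10
) -> tuple[list[str], list[str], list[str]]:
    """Document-level three-way split: a small labelled train set (the
    annotation-scarce regime weak supervision targets), a weak pool
    ``weak_to_labelled`` times larger, and the remainder held out for
    evaluation."""
    rng = np.random.default_rng(seed)
    order = [sorted(pmids)[i] for i in rng.permutation(len(pmids))]
    n_labelled = max(1, len(order) // 15)
    n_weak = weak_to_labelled * n_labelled
    labelled = order[:n_labelled]
    weak = order[n_labelled : n_labelled + n_weak]
    test = order[n_labelled + n_weak :]
    return labelled, weak, test


def _subset(docset: DocumentSet, pmids: Sequence[str]) -> DocumentSet:
    keep = set(pmids)
    out = DocumentSet(
        documents={p: docset.documents[p] for p in docset.documents if p in keep},
        relations=[r for r in docset.relations if r.pmid in keep],
    )
    return out


def run_recovery(
    bundle,
    cfg: ClassifierConfig,
    seed: int,
    pretrain_steps: int | None = 1500,
) -> RecoveryResult:
    """Compare labelled-only training against the full two-phase system on
    one synthetic bundle.

    The corpus splits into a small labelled set, a weak pool ten times its
    size, and a held-out test set.  The baseline trains on the labelled set
    alone; the system additionally weak-labels the pool with the baseline
    model, refines by KB agreement, pretrains on the kept examples and
    fine-tunes on the labelled set.  Both are scored on the same test gold.
    """
    from .evaluation import evaluate
    from .kb_refine import build_kb_index
    from .synthetic_fixtures import planted_truth

    labelled, weak, test = split_pmids(list(bundle.docset.documents), seed)
    cfg = replace(cfg, seed=seed)

    gold_train = build_examples(_subset(bundle.docset, labelled))
    test_set = _subset(bundle.docset, test)
    test_examples = build_examples(test_set)
    test_gold = [t for t in planted_truth(bundle) if t[0] in set(test)]

    def score(model) -> float:
        preds = model.predict(
            test_examples.sequences,
            pair_keys=[p.pair_key for p in test_examples.pairs],
        )
        tuples = [
            (p.pair_key[0], p.pair_key[1], p.pair_key[2], p.label) for p in preds
        ]
        return evaluate(test_gold, tuples).micro_f1

    baseline = make_classifier(cfg)
    baseline.fit(gold_train.sequences, gold_train.labels)
    baseline_f1 = score(baseline)

    index = build_kb_index(bundle.kb_records)
    augmented, report = weak_label(baseline, _subset(bundle.docset, weak), index)
    system = pretrain_finetune(cfg, augmented, gold_train, pretrain_steps=pretrain_steps)
    two_phase_f1 = score(system)

    return RecoveryResult(
        seed=seed,
        baseline_f1=baseline_f1,
        two_phase_f1=two_phase_f1,
        refine_report=report,
        n_labelled=len(labelled),
        n_weak=len(weak),
        n_test=len(test),
    )
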