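"""Relation classifier contract and desk-scale reference backbone.

The contract mirrors transformer-style sequence classification: a marked
sentence goes in, a score vector over the 14 labels (13 relation types +
NONE) comes out, and parameters can be exported and re-imported so a model
pretrained on weak labels can be transferred and fine-tuned on gold labels.

The reference backbone is a multinomial logistic regression over hashed
token n-gram features of the marked sequence, trained by mini-batch SGD
under the warmup/linear-decay learning-rate schedule.  Marker tokens are
atomic vocabulary items and participate as ordinary features, so their
(hashed) weights are trainable parameters exactly like learned marker
embeddings.  Transformer backbones attach through the same
fit/predict/export contract via an adapter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.utils.murmurhash import murmurhash3_32

from .formats_io import ALL_LABELS, RelationLabel
from .preprocess import MarkedSequence

PARAMS_FORMAT_VERSION = 1

_TOKEN_RE = re.compile(r"[A-Za-z0-9_\-\[\]]+")


@dataclass(frozen=True)
class ScheduleConfig:
    """Warmup + linear-decay learning-rate schedule.

    The rate rises linearly from 0 to ``peak_lr`` over the first
    ``warm_rate`` fraction of ``max_steps``, then decays linearly to 0 at
    the final step.
    """

    peak_lr: float = 2e-3
    max_steps: int = 1000
    warm_rate: float = 0.05

    def __post_init__(self):
        if not (0.0 < self.warm_rate < 1.0):
            raise ValueError("warm_rate must lie in (0, 1)")
        if self.peak_lr <= 0:
            raise ValueError("peak_lr must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def lr_schedule(step: int, cfg: ScheduleConfig) -> float:
    """Learning rate at ``step`` (0-based, inclusive of ``max_steps``).

    Piecewise linear: ``peak_lr * step / (w*T)`` during warmup, then
    ``peak_lr * (T - step) / ((1 - w)*T)`` down to 0 at ``T``.
    """
    T, w, eta = cfg.max_steps, cfg.warm_rate, cfg.peak_lr
    if step < 0 or step > T:
        raise ValueError(f"step {step} outside [0, {T}]")
    warm_steps = w * T
    if step <= warm_steps:
        return eta * step / warm_steps
    return eta * (T - step) / ((1.0 - w) * T)


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the reference backbone.

    ``marker_vocab`` tokens must survive tokenization as single units
    (asserted at model construction) so markers act as atomic features.
    """

    backbone: str = "reference"
    marker_vocab: tuple[str, ...] = ("CHEM-S", "CHEM-E", "GENE-S", "GENE-E")
    n_labels: int = len(ALL_LABELS)
    peak_lr: float = 0.5
    batch_size: int = 32
    max_steps: int = 400
    warm_rate: float = 0.05
    seed: int = 0
    n_features: int = 2**18
    ngram_range: tuple[int, int] = (1, 2)
    # character n-grams within tokens approximate subword vocabularies,
    # generalizing across morphological variants ("antagonist"/"antagonized")
    char_ngram_range: tuple[int, int] | None = (3, 5)
    l2: float = 1e-6

    def schedule(self) -> ScheduleConfig:
        return ScheduleConfig(
            peak_lr=self.peak_lr, max_steps=self.max_steps, warm_rate=self.warm_rate
        )


@dataclass(frozen=True)
class Prediction:
    pair_key: tuple[str, str, str] | None
    label: RelationLabel
    scores: tuple[float, ...]  # over ALL_LABELS, nonnegative, sums to 1


class NotFittedError(RuntimeError):
    pass


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


class ReferenceClassifier:
    """Hashed n-gram multinomial logistic regression (the reference
    backbone).

    Deterministic given (example order, config, seed): weights start at
    zero and mini-batch order is driven by a seeded generator.
    """

    def __init__(self, cfg: ClassifierConfig | None = None):
        self.cfg = cfg or ClassifierConfig()
        for tok in self.cfg.marker_vocab:
            if tokenize(tok) != [tok]:
                raise ValueError(
                    f"marker token {tok!r} does not tokenize as a single unit"
                )
        self.W: np.ndarray | None = None  # (n_features, n_labels)
        self.b: np.ndarray | None = None  # (n_labels,)

    # ---------------- feature hashing ----------------

    def _featurize(self, texts: Sequence[str]) -> sp.csr_matrix:
        n_feat = self.cfg.n_features
        lo, hi = self.cfg.ngram_range
        indptr = [0]
        indices: list[int] = []
        markers = set(self.cfg.marker_vocab)
        for text in texts:
            toks = tokenize(text)
            cols = set()
            for n in range(lo, hi + 1):
                for i in range(len(toks) - n + 1):
                    key = " ".join(toks[i : i + n])
                    cols.add(murmurhash3_32(key, positive=True) % n_feat)
            if self.cfg.char_ngram_range is not None:
                clo, chi = self.cfg.char_ngram_range
                for tok in toks:
                    if tok in markers:  # markers stay atomic
                        continue
                    padded = f"<{tok.lower()}>"
                    for n in range(clo, chi + 1):
                        for i in range(len(padded) - n + 1):
                            cols.add(
                                murmurhash3_32("c:" + padded[i : i + n], positive=True)
                                % n_feat
                            )
            indices.extend(sorted(cols))
            indptr.append(len(indices))
        data = np.ones(len(indices), dtype=np.float64)
        return sp.csr_matrix(
            (data, np.asarray(indices, dtype=np.int64), np.asarray(indptr, dtype=np.int64)),
            shape=(len(texts), n_feat),
        )

    @staticmethod
    def _texts(seqs: Sequence[MarkedSequence | str]) -> list[str]:
        return [s.text if isinstance(s, MarkedSequence) else s for s in seqs]

    # ---------------- training ----------------

    def fit(
        self,
        sequences: Sequence[MarkedSequence | str],
        labels: Sequence[RelationLabel],
        init_params: Mapping[str, np.ndarray] | None = None,
    ) -> "ReferenceClassifier":
        """Mini-batch SGD on softmax cross-entropy under the LR schedule.

        ``init_params`` (an exported parameter artifact) warm-starts the
        weights — the transfer mechanism between training phases.
        """
        if len(sequences) == 0:
            raise ValueError("empty training set")
        if len(sequences) != len(labels):
            raise ValueError("sequences and labels length mismatch")
        cfg = self.cfg
        X = self._featurize(self._texts(sequences))
        y = np.asarray([int(lab) for lab in labels], dtype=np.int64)
        n, k = X.shape[0], cfg.n_labels

        if init_params is not None:
            self.import_params(init_params)
            W, b = self.W.copy(), self.b.copy()  # type: ignore[union-attr]
        else:
            W = np.zeros((cfg.n_features, k))
            b = np.zeros(k)

        rng = np.random.default_rng(cfg.seed)
        # max_steps == 0 is a valid no-op fit (pure parameter transfer)
        sched = cfg.schedule() if cfg.max_steps > 0 else None
        order = rng.permutation(n)
        pos = 0
        for step in range(1, cfg.max_steps + 1):
            if pos + cfg.batch_size > n:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos : pos + cfg.batch_size]
            pos += cfg.batch_size
            Xb = X[idx]
            yb = y[idx]
            # restrict the update to features active in this batch (lazy L2)
            cols = np.unique(Xb.indices)
            Xa = Xb[:, cols].toarray()
            Wa = W[cols]
            logits = Xa @ Wa + b
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            probs[np.arange(len(idx)), yb] -= 1.0
            probs /= len(idx)
            lr = lr_schedule(step, sched)
            W[cols] = Wa * (1.0 - lr * cfg.l2) - lr * (Xa.T @ probs)
            b -= lr * probs.sum(axis=0)
        self.W, self.b = W, b
        return self

    # ---------------- inference ----------------

    def predict(
        self,
        sequences: Sequence[MarkedSequence | str],
        pair_keys: Sequence[tuple[str, str, str]] | None = None,
        batch_size: int = 1024,
    ) -> list[Prediction]:
        """Score sequences in batches, preserving input order.

        Ties at the argmax resolve to the lower enum index (``np.argmax``
        returns the first maximum over the canonically ordered labels).
        """
        if self.W is None or self.b is None:
            raise NotFittedError("classifier has not been fitted")
        if pair_keys is not None and len(pair_keys) != len(sequences):
            raise ValueError("pair_keys length mismatch")
        texts = self._texts(sequences)
        out: list[Prediction] = []
        for lo in range(0, len(texts), batch_size):
            chunk = texts[lo : lo + batch_size]
            X = self._featurize(chunk)
            logits = np.asarray(X @ self.W + self.b)
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            for j in range(len(chunk)):
                i = lo + j
                scores = probs[j]
                label = RelationLabel(int(np.argmax(scores)))
                out.append(
                    Prediction(
                        pair_key=pair_keys[i] if pair_keys is not None else None,
                        label=label,
                        scores=tuple(float(s) for s in scores),
                    )
                )
        return out

    # ---------------- parameter transfer ----------------

    def export_params(self) -> dict[str, np.ndarray]:
        """Versioned flat key-value parameter artifact."""
        if self.W is None or self.b is None:
            raise NotFittedError("classifier has not been fitted")
        return {
            "format_version": np.asarray(PARAMS_FORMAT_VERSION),
            "n_features": np.asarray(self.cfg.n_features),
            "n_labels": np.asarray(self.cfg.n_labels),
            "W": self.W.copy(),
            "b": self.b.copy(),
        }

    def import_params(self, params: Mapping[str, np.ndarray]) -> "ReferenceClassifier":
        if int(params["format_version"]) != PARAMS_FORMAT_VERSION:
            raise ValueError("unsupported parameter artifact version")
        if int(params["n_features"]) != self.cfg.n_features or int(
            params["n_labels"]
        ) != self.cfg.n_labels:
            raise ValueError("parameter artifact shape mismatch with config")
        self.W = np.asarray(params["W"], dtype=np.float64).copy()
        self.b = np.asarray(params["b"], dtype=np.float64).copy()
        return self

    def save_params(self, path) -> None:
        np.savez(path, **self.export_params())

    def load_params(self, path) -> "ReferenceClassifier":
        with np.load(path) as data:
            return self.import_params({k: data[k] for k in data.files})


def make_classifier(cfg: ClassifierConfig | None = None) -> ReferenceClassifier:
    """Factory for the configured backbone (only the reference backbone is
    built in; external backbones register via the adapter contract)."""
    cfg = cfg or ClassifierConfig()
    if cfg.backbone != "reference":
        raise ValueError(
            f"unknown backbone {cfg.backbone!r}; external backbones must be "
            "adapted to the fit/predict/export contract"
        )
    return ReferenceClassifier(cfg)


def with_seed(cfg: ClassifierConfig, seed: int) -> ClassifierConfig:
    return replace(cfg, seed=seed)
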