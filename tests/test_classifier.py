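import numpy as np
import pytest

from kbrelex.classifier import (
    ClassifierConfig,
    NotFittedError,
    Prediction,
    ReferenceClassifier,
    ScheduleConfig,
    lr_schedule,
    make_classifier,
)
from kbrelex.formats_io import ALL_LABELS, RelationLabel
from kbrelex import training
from kbrelex.evaluation import evaluate
from kbrelex.preprocess import MarkingMethod
from kbrelex.synthetic_fixtures import FixtureConfig, generate, planted_truth


class TestLrSchedule:
    def test_zero_at_start(self):
        cfg = ScheduleConfig(peak_lr=1.0, max_steps=100)
        assert lr_schedule(0, cfg) == 0.0

    def test_peak_at_warmup_end(self):
        cfg = ScheduleConfig(peak_lr=3e-4, max_steps=2000, warm_rate=0.05)
        assert lr_schedule(100, cfg) == pytest.approx(3e-4)

    def test_decay_midpoint_closed_form(self):
        # T=1000, w=0.05, eta=2e-5: step 525 is halfway down the decay leg
        cfg = ScheduleConfig(peak_lr=2e-5, max_steps=1000, warm_rate=0.05)
        assert lr_schedule(525, cfg) == pytest.approx(1e-5)

    def test_zero_at_end_and_error_beyond(self):
        cfg = ScheduleConfig(peak_lr=1.0, max_steps=100)
        assert lr_schedule(100, cfg) == 0.0
        with pytest.raises(ValueError):
            lr_schedule(101, cfg)

    def test_single_peak_and_continuity(self):
        cfg = ScheduleConfig(peak_lr=1.0, max_steps=400, warm_rate=0.05)
        rates = [lr_schedule(s, cfg) for s in range(401)]
        peak = int(np.argmax(rates))
        assert peak == 20  # 0.05 * 400
        assert all(rates[i] < rates[i + 1] for i in range(peak))
        assert all(rates[i] > rates[i + 1] for i in range(peak, 400))


@pytest.fixture(scope="module")
def fixture_examples():
    bundle = generate(FixtureConfig(n_docs=30, seed=11))
    return training.build_examples(bundle.docset)


class TestReferenceClassifier:
    def _cfg(self, **kw):
        kw.setdefault("max_steps", 200)
        kw.setdefault("seed", 0)
        return ClassifierConfig(**kw)

    def test_beats_majority_baseline_on_training_set(self, fixture_examples):
        ex = fixture_examples
        model = make_classifier(self._cfg())
        model.fit(ex.sequences[:200], ex.labels[:200])
        preds = model.predict(ex.sequences[:200])
        acc = np.mean([p.label == l for p, l in zip(preds, ex.labels[:200])])
        counts = {}
        for l in ex.labels[:200]:
            counts[l] = counts.get(l, 0) + 1
        majority = max(counts.values()) / 200
        assert acc > majority

    def test_deterministic_given_seed(self, fixture_examples):
        ex = fixture_examples
        params = []
        for _ in range(2):
            m = make_classifier(self._cfg(seed=5))
            m.fit(ex.sequences[:100], ex.labels[:100])
            params.append(m.export_params())
        assert np.array_equal(params[0]["W"], params[1]["W"])
        assert np.array_equal(params[0]["b"], params[1]["b"])

    def test_single_label_data_predicts_that_label(self):
        model = make_classifier(self._cfg())
        texts = [f"sentence number {i} with CHEM-S x CHEM-E" for i in range(40)]
        model.fit(texts, [RelationLabel.AGONIST] * 40)
        preds = model.predict(["a completely different sentence"])
        assert preds[0].label is RelationLabel.AGONIST

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            make_classifier(self._cfg()).fit([], [])

    def test_predict_preserves_order_and_normalization(self, fixture_examples):
        ex = fixture_examples
        model = make_classifier(self._cfg())
        model.fit(ex.sequences[:100], ex.labels[:100])
        keys = [p.pair_key for p in ex.pairs[:6]]
        preds = model.predict(ex.sequences[:6], pair_keys=keys, batch_size=2)
        assert [p.pair_key for p in preds] == keys
        for p in preds:
            assert len(p.scores) == len(ALL_LABELS)
            assert abs(sum(p.scores) - 1.0) < 1e-9
            assert p.label is ALL_LABELS[int(np.argmax(p.scores))]

    def test_untrained_predict_rejected(self):
        with pytest.raises(NotFittedError):
            make_classifier(self._cfg()).predict(["x"])

    def test_export_import_round_trip(self, fixture_examples, tmp_path):
        ex = fixture_examples
        model = make_classifier(self._cfg())
        model.fit(ex.sequences[:100], ex.labels[:100])
        model.save_params(tmp_path / "params.npz")
        clone = make_classifier(self._cfg()).load_params(tmp_path / "params.npz")
        p1 = model.predict(ex.sequences[100:140])
        p2 = clone.predict(ex.sequences[100:140])
        assert [p.label for p in p1] == [p.label for p in p2]
        assert all(a.scores == b.scores for a, b in zip(p1, p2))

    def test_import_shape_mismatch_rejected(self, fixture_examples):
        ex = fixture_examples
        model = make_classifier(self._cfg())
        model.fit(ex.sequences[:50], ex.labels[:50])
        other = make_classifier(self._cfg(n_features=2**10))
        with pytest.raises(ValueError):
            other.import_params(model.export_params())

    def test_non_atomic_marker_rejected(self):
        with pytest.raises(ValueError):
            ReferenceClassifier(self._cfg(marker_vocab=("CHEM S",)))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError):
            make_classifier(self._cfg(backbone="bert-large"))


def test_marking_ablation_direction():
    """Typed start/end markers should do at least as well as no marking,
    averaged over seeds: without markers, two pairs sharing a sentence get
    identical features and cannot be distinguished."""
    scores = {MarkingMethod.WRAP_TYPE_SE: [], MarkingMethod.NONE: []}
    for seed in range(10):
        bundle = generate(FixtureConfig(n_docs=60, seed=300 + seed))
        pmids = sorted(bundle.docset.documents)
        train_p, test_p = pmids[:40], pmids[40:]
        truth = [t for t in planted_truth(bundle) if t[0] in set(test_p)]
        for method in scores:
            train = training.build_examples(
                training._subset(bundle.docset, train_p), method
            )
            test = training.build_examples(
                training._subset(bundle.docset, test_p), method
            )
            model = make_classifier(ClassifierConfig(max_steps=300, seed=seed))
            model.fit(train.sequences, train.labels)
            preds = model.predict(
                test.sequences, pair_keys=[p.pair_key for p in test.pairs]
            )
            tuples = [(p.pair_key[0], p.pair_key[1], p.pair_key[2], p.label) for p in preds]
            scores[method].append(evaluate(truth, tuples).micro_f1)
    assert np.mean(scores[MarkingMethod.WRAP_TYPE_SE]) >= np.mean(
        scores[MarkingMethod.NONE]
    )
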