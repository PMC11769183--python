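"""Splitting, metrics, training determinism and the ablation harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fatiguecg import harness as h
from fatiguecg.errors import ConfigError, InvalidInputError
from fatiguecg.model import ModelConfig

from conftest import make_toy_examples


class TestSplit:
    def test_nine_to_one_counts(self):
        examples = make_toy_examples(100)
        train, test = h.split_dataset(examples, h.SplitSpec(seed=0))
        assert len(train) == 90 and len(test) == 10

    def test_deterministic_per_seed(self):
        examples = make_toy_examples(30)
        a = h.split_dataset(examples, h.SplitSpec(seed=5))
        b = h.split_dataset(examples, h.SplitSpec(seed=5))
        assert [id(x) for x in a[0]] == [id(x) for x in b[0]]

    def test_subject_grouped_never_splits_a_subject(self):
        examples = make_toy_examples(60)
        train, test = h.split_dataset(
            examples, h.SplitSpec(mode="subject-grouped", seed=1)
        )
        train_subjects = {ex.profile.subject_id for ex in train}
        test_subjects = {ex.profile.subject_id for ex in test}
        assert train_subjects and test_subjects
        assert not (train_subjects & test_subjects)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigError):
            h.SplitSpec(train_fraction=1.5)

    def test_too_few_examples_rejected(self):
        with pytest.raises(InvalidInputError):
            h.split_dataset(make_toy_examples(2)[:1])


class TestEvaluate:
    def test_perfect_predictions(self):
        labels = ["F", "N"] * 10
        result = h.evaluate(labels, labels)
        assert result.accuracy == 100.0 and result.f1 == 1.0

    def test_all_negative_predictor_on_balanced_set(self):
        labels = ["F", "N"] * 10
        result = h.evaluate(["N"] * 20, labels)
        assert result.accuracy == 50.0 and result.f1 == 0.0

    def test_hand_computed_confusion(self):
        # TP=45, FP=5, FN=5, TN=45 -> accuracy 90%, F1 0.9
        result = h.EvalResult(tp=45, fp=5, fn=5, tn=45)
        assert result.accuracy == pytest.approx(90.0)
        assert result.f1 == pytest.approx(0.9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            h.evaluate(["F"], ["F", "N"])

    def test_accepts_class_indices(self):
        result = h.evaluate(np.array([1, 0, 1]), ["F", "N", "N"])
        assert (result.tp, result.fp, result.fn, result.tn) == (1, 1, 0, 1)

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=100, deadline=None)
    def test_metric_identities(self, counts):
        tp, fp, fn, tn = counts
        result = h.EvalResult(tp=tp, fp=fp, fn=fn, tn=tn)
        assert result.accuracy == pytest.approx((tp + tn) / (tp + fp + fn + tn) * 100)
        expected_f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        assert result.f1 == pytest.approx(expected_f1)


FAST_OPT = h.OptimizerConfig(max_epochs=4, min_epochs=1, patience=2, seed=0)


class TestTrain:
    def test_single_class_rejected(self):
        examples = [ex for ex in make_toy_examples(12) if ex.label == "F"]
        with pytest.raises(InvalidInputError):
            h.train(examples, ModelConfig.small())

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            h.train([], ModelConfig.small())

    def test_same_seed_identical_final_weights(self):
        examples = make_toy_examples(12, seed=4)
        config = ModelConfig.small(seed=2)
        model_a, _ = h.train(examples, config, FAST_OPT)
        model_b, _ = h.train(examples, config, FAST_OPT)
        for pa, pb in zip(model_a.state_dict(), model_b.state_dict()):
            np.testing.assert_array_equal(pa, pb)

    def test_training_log_records_epochs(self):
        examples = make_toy_examples(12, seed=4)
        _, log = h.train(examples, ModelConfig.small(seed=0), FAST_OPT)
        assert 1 <= len(log.epoch_loss) <= 4
        assert log.best_epoch >= 0

    def test_learns_separable_toy(self):
        examples = make_toy_examples(30, seed=6)
        opt = h.OptimizerConfig(max_epochs=15, min_epochs=2, patience=3, seed=0)
        _, result, _ = h.train_and_evaluate(
            examples, ModelConfig.small(seed=1), opt, h.SplitSpec(train_fraction=0.8, seed=0)
        )
        assert result.accuracy >= 80.0


class TestAblation:
    def test_six_rows_in_canonical_order(self):
        examples = make_toy_examples(20, seed=8)
        table = h.run_ablation(
            examples,
            base_config=ModelConfig.small(seed=0),
            opt_config=h.OptimizerConfig(max_epochs=1, min_epochs=1, seed=0),
            split_spec=h.SplitSpec(seed=0),
        )
        assert list(table["Method"]) == ["S", "S + P", "T", "T + S", "T + P", "T + S + P"]
        assert {"F1 score", "Accuracy (%)"} <= set(table.columns)

    def test_disabled_modality_cannot_influence_result(self):
        """S-only results are bit-identical when the time series are randomized."""
        examples = make_toy_examples(20, seed=9)
        rng = np.random.default_rng(123)
        scrambled = []
        for ex in examples:
            import copy

            ex2 = copy.deepcopy(ex)
            for seg in ex2.group.segments:
                seg.samples[:] = rng.normal(size=seg.samples.shape)
            scrambled.append(ex2)
        config = ModelConfig.small(use_T=False, use_S=True, use_P=False, seed=3)
        opt = h.OptimizerConfig(max_epochs=2, min_epochs=1, seed=1)
        _, a, _ = h.train_and_evaluate(examples, config, opt, h.SplitSpec(seed=2))
        _, b, _ = h.train_and_evaluate(scrambled, config, opt, h.SplitSpec(seed=2))
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


def test_end_to_end_reproducibility():
    """simulate -> preprocess -> featurize -> train -> evaluate twice, same seed."""
    from fatiguecg import features as ft
    from fatiguecg import synthetic as syn

    results = []
    for _ in range(2):
        records = syn.generate_cohort(4, duration_s=30, seed=11)
        examples = ft.build_dataset(records)
        _, result, _ = h.train_and_evaluate(
            examples,
            ModelConfig.small(seed=1),
            h.OptimizerConfig(max_epochs=2, min_epochs=1, seed=1),
            h.SplitSpec(seed=1),
        )
        results.append((result.tp, result.fp, result.fn, result.tn, result.accuracy))
    assert results[0] == results[1]
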