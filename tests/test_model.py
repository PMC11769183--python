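"""Hybrid classifier: encoders, fusion, loss closed forms, learnability."""

import numpy as np
import pytest

from fatiguecg.errors import ConfigError, InvalidInputError
from fatiguecg.model import (
    HybridFatigueModel,
    ModelConfig,
    cross_entropy,
    cross_entropy_logits,
    labels_to_onehot,
    one_hot_age,
)
from fatiguecg.nn import Adam, Tensor


@pytest.fixture(scope="module")
def tiny_model() -> HybridFatigueModel:
    return HybridFatigueModel(ModelConfig.small(seed=0))


def make_batch(n=2, seed=0, ages=None):
    rng = np.random.default_rng(seed)
    return {
        "signal": rng.normal(size=(n, 1300)),
        "images": rng.normal(size=(n, 10, 17, 25)),
        "age": np.asarray(ages if ages is not None else [25] * n),
        "gender_idx": np.arange(n) % 2,
    }


class TestConfig:
    def test_all_branches_disabled_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(use_T=False, use_S=False, use_P=False)

    def test_heads_must_divide_d(self):
        with pytest.raises(ConfigError):
            ModelConfig(d_model=30, transformer_heads=4)

    def test_ablation_name(self):
        assert ModelConfig().ablation_name() == "T + S + P"
        assert ModelConfig(use_T=False).ablation_name() == "S + P"


class TestPhysioEncoding:
    def test_one_hot_places_single_one_at_age_index(self):
        v = one_hot_age(25)
        assert v.shape == (100,) and v.sum() == 1 and v[25] == 1

    @pytest.mark.parametrize("age", [-1, 100, 150])
    def test_out_of_range_age_rejected(self, age):
        with pytest.raises(InvalidInputError):
            one_hot_age(age)

    def test_physio_network_has_six_fc_layers(self, tiny_model):
        assert len(tiny_model.physio_branch.fc) == 6

    def test_gender_changes_token(self, tiny_model):
        a = tiny_model.encode_physio(np.array([25]), np.array([0])).data
        b = tiny_model.encode_physio(np.array([25]), np.array([1])).data
        assert not np.allclose(a, b)


class TestBranchEncoders:
    def test_zero_inputs_give_finite_tokens(self, tiny_model):
        t = tiny_model.encode_time(np.zeros((2, 1300))).data
        s = tiny_model.encode_spec(np.zeros((2, 10, 17, 25))).data
        assert np.all(np.isfinite(t)) and np.all(np.isfinite(s))
        assert t.shape == (2, 32) and s.shape == (2, 32)

    def test_deterministic_for_fixed_weights(self, tiny_model):
        batch = make_batch()
        a = tiny_model.encode_time(batch["signal"]).data
        b = tiny_model.encode_time(batch["signal"]).data
        np.testing.assert_array_equal(a, b)

    def test_small_perturbation_changes_time_token(self, tiny_model):
        signal = make_batch()["signal"]
        base = tiny_model.encode_time(signal).data
        signal2 = signal.copy()
        signal2[0, 600] += 1e-3
        assert not np.array_equal(tiny_model.encode_time(signal2).data, base)

    def test_image_order_sensitivity(self, tiny_model):
        images = make_batch()["images"]
        a = tiny_model.encode_spec(images).data
        b = tiny_model.encode_spec(images[:, ::-1].copy()).data
        assert not np.allclose(a, b)

    def test_wrong_image_count_rejected(self, tiny_model):
        with pytest.raises(InvalidInputError):
            tiny_model.encode_spec(np.zeros((2, 9, 17, 25)))

    def test_wrong_signal_length_rejected(self, tiny_model):
        with pytest.raises(InvalidInputError):
            tiny_model.encode_time(np.zeros((2, 1000)))


class TestFusion:
    def test_probabilities_sum_to_one(self, tiny_model):
        probs = tiny_model(make_batch(n=3)).data
        assert probs.shape == (3, 2)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_no_tokens_rejected(self, tiny_model):
        with pytest.raises(ConfigError):
            tiny_model.fuse_and_classify([])

    def test_ablation_isolation_age_has_no_effect_without_p(self):
        model = HybridFatigueModel(ModelConfig.small(use_P=False, seed=1))
        a = model(make_batch(ages=[20, 30])).data
        b = model(make_batch(ages=[60, 70])).data
        np.testing.assert_array_equal(a, b)

    def test_duplicated_tokens_permutation_invariant_without_types(self, tiny_model):
        tok = tiny_model.encode_physio(np.array([25, 30]), np.array([0, 1]))
        other = tiny_model.encode_time(make_batch()["signal"])
        p1 = tiny_model.fuse_and_classify([tok, other], use_type_embeddings=False).data
        p2 = tiny_model.fuse_and_classify([other, tok], use_type_embeddings=False).data
        np.testing.assert_allclose(p1, p2, atol=1e-10)

    def test_gradient_reaches_every_enabled_branch(self, tiny_model):
        batch = make_batch(n=4)
        onehot = labels_to_onehot(["F", "N", "F", "N"])
        tiny_model.zero_grad()
        cross_entropy_logits(tiny_model.logits(batch), onehot).backward()
        for branch in (tiny_model.time_branch, tiny_model.spec_branch, tiny_model.physio_branch):
            grads = [p.grad for p in branch.parameters()]
            assert any(g is not None and np.any(g != 0) for g in grads)


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy(np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]])) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_uniform_prediction_ln2(self):
        loss = cross_entropy(np.array([[0.5, 0.5]]), np.array([[1.0, 0.0]]))
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_two_sample_hand_computation(self):
        probs = np.array([[0.9, 0.1], [0.2, 0.8]])
        onehot = np.array([[1.0, 0.0], [0.0, 1.0]])
        expected = -(np.log(0.9) + np.log(0.8)) / 2  # 0.164252...
        assert cross_entropy(probs, onehot) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.164252, abs=1e-6)

    def test_nonnegative_and_clipped_at_zero_probability(self):
        loss = cross_entropy(np.array([[0.0, 1.0]]), np.array([[1.0, 0.0]]))
        assert np.isfinite(loss) and loss > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_entropy(np.ones((2, 2)) / 2, np.ones((3, 2)))

    def test_logit_form_matches_probability_form(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(5, 2))
        onehot = labels_to_onehot(["F", "N", "N", "F", "N"])
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert float(cross_entropy_logits(Tensor(logits), onehot).data) == pytest.approx(
            cross_entropy(probs, onehot), abs=1e-9
        )


def test_checkpoint_roundtrip(tmp_path):
    """Saved checkpoints restore both the config and the exact weights."""
    from fatiguecg.model import load_checkpoint, save_checkpoint

    model = HybridFatigueModel(ModelConfig.small(seed=4, use_P=False))
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path)
    assert restored.config == model.config
    batch = make_batch(n=2, seed=6)
    np.testing.assert_array_equal(restored(batch).data, model(batch).data)


def test_invalid_loss_inputs_rejected():
    with pytest.raises(InvalidInputError):
        cross_entropy(np.array([[0.7, 0.7]]), np.array([[1.0, 0.0]]))  # row sum != 1
    with pytest.raises(InvalidInputError):
        cross_entropy(np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]))  # not one-hot


def test_overfit_single_batch():
    """A seeded small model drives training loss below 0.05 on 8 examples."""
    config = ModelConfig.small(seed=3)
    model = HybridFatigueModel(config)
    batch = make_batch(n=8, seed=5)
    onehot = labels_to_onehot(["F", "N"] * 4)
    optimizer = Adam(model.parameters(), lr=3e-3)
    loss_val = np.inf
    for _ in range(200):
        loss = cross_entropy_logits(model.logits(batch), onehot)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step()
        loss_val = float(loss.data)
        if loss_val < 0.05:
            break
    assert loss_val < 0.05
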