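"""Hybrid multimodal fatigue classifier.

Three feature branches feed a transformer-encoder fusion stage:

* **T** — the 1300-sample (10 s) time series through a 1D ResNet (residual
  blocks of two convolutions each, ELU activations, stride-2 downsampling)
  followed by a bidirectional LSTM whose final states are projected to a
  d-dimensional token;
* **S** — the ten per-second spectrogram images through a 2D ResNet applied
  per image, global average pooling, then a BiLSTM over the length-10 image
  sequence, projected to d;
* **P** — physiological information: the subject's age as a 100-dimensional
  one-hot vector (index = age in years) concatenated with a learned gender
  embedding, through a 6-layer fully connected network to d.

The enabled tokens, plus learned branch-type embeddings, form the input
sequence of a transformer encoder; the encoder output is mean-pooled and
linearly mapped to two logits (softmax -> F/N probabilities).  Training
minimizes the mean cross-entropy  L = -(1/N) sum_q sum_r S_qr log P_qr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fatiguecg.errors import ConfigError, InvalidInputError
from fatiguecg.nn import (
    BiLSTMEncoder,
    Embedding,
    Linear,
    Module,
    Tensor,
    TransformerEncoderLayer,
    concat,
    no_grad,
)
from fatiguecg.nn.autodiff import softmax as softmax_op
from fatiguecg.nn.layers import ResidualBlock1d, ResidualBlock2d
from fatiguecg.synthetic import GENDERS, SubjectProfile

GROUP_SAMPLES = 1300
N_IMAGES = 10
AGE_DIM = 100
N_CLASSES = 2
#: Class index convention: F (fatigue, the positive class) = 1, N = 0.
CLASS_TO_INDEX = {"N": 0, "F": 1}

LOSS_EPS = 1e-12


@dataclass(frozen=True)
class ModelConfig:
    """All architecture sizes and the three ablation flags.

    Defaults are sized for CPU training on the synthetic benchmark while
    keeping the block structure of the full design: every knob is
    configurable.
    """

    # time branch: residual blocks (c_out, kernel, stride)
    time_blocks: tuple[tuple[int, int, int], ...] = (
        (16, 7, 2), (32, 3, 2), (64, 3, 2), (64, 3, 2),
    )
    # spectrogram branch: residual blocks (c_out, kernel, stride) applied per image
    spec_blocks: tuple[tuple[int, int, int], ...] = ((8, 3, 2), (16, 3, 2), (32, 3, 2))
    lstm_hidden: int = 64
    lstm_layers: int = 2
    d_model: int = 128
    transformer_layers: int = 2
    transformer_heads: int = 4
    transformer_ff: int = 256
    physio_widths: tuple[int, ...] = (128, 128, 128, 128, 128)  # hidden widths; 6 FC layers total
    gender_dim: int = 8
    dropout: float = 0.0
    use_T: bool = True
    use_S: bool = True
    use_P: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.use_T or self.use_S or self.use_P):
            raise ConfigError("at least one of the T/S/P branches must be enabled")
        if self.d_model % self.transformer_heads != 0:
            raise ConfigError("d_model must be divisible by transformer_heads")

    def branch_names(self) -> list[str]:
        return [n for n, on in (("T", self.use_T), ("S", self.use_S), ("P", self.use_P)) if on]

    def ablation_name(self) -> str:
        return " + ".join(self.branch_names())

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """Reduced-size config for quick benchmarks and tests."""
        defaults = dict(
            time_blocks=((8, 7, 4), (16, 3, 2), (16, 3, 2)),
            spec_blocks=((8, 3, 2), (16, 3, 2)),
            lstm_hidden=24,
            lstm_layers=1,
            d_model=32,
            transformer_layers=1,
            transformer_heads=4,
            transformer_ff=64,
            physio_widths=(32, 32, 32, 32, 32),
            gender_dim=4,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class PhysioVector:
    """Encoded physiological inputs: 100-dim age one-hot + gender index."""

    age_onehot: np.ndarray
    gender_index: int

    def __post_init__(self) -> None:
        if self.age_onehot.shape != (AGE_DIM,) or int(self.age_onehot.sum()) != 1:
            raise InvalidInputError("age one-hot must be 100-dim with exactly one 1")


def one_hot_age(age: int) -> np.ndarray:
    """Age encoded as a 100-dimensional one-hot vector (index = years)."""
    if not 0 <= int(age) <= AGE_DIM - 1:
        raise InvalidInputError(f"age {age} outside [0, {AGE_DIM - 1}]")
    v = np.zeros(AGE_DIM)
    v[int(age)] = 1.0
    return v


def encode_profile(profile: SubjectProfile) -> PhysioVector:
    if profile.gender not in GENDERS:
        raise InvalidInputError(f"unknown gender token {profile.gender!r}")
    return PhysioVector(one_hot_age(profile.age), GENDERS.index(profile.gender))


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = LOSS_EPS) -> float:
    """Mean cross-entropy over samples: -(1/N) sum_q sum_r S_qr log P_qr.

    Probabilities are clipped at ``eps`` before the log (the expression is
    undefined at exactly zero).
    """
    probs = np.asarray(probs, dtype=float)
    onehot = np.asarray(onehot, dtype=float)
    if probs.shape != onehot.shape:
        raise InvalidInputError(f"shape mismatch: {probs.shape} vs {onehot.shape}")
    if not np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6):
        raise InvalidInputError("each probability row must sum to 1 (within 1e-6)")
    if not (np.all((onehot == 0) | (onehot == 1)) and np.all(onehot.sum(axis=-1) == 1)):
        raise InvalidInputError("ground-truth rows must be one-hot indicators")
    logp = np.log(np.clip(probs, eps, None))
    return float(-(onehot * logp).sum() / probs.shape[0])


def cross_entropy_logits(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Differentiable mean cross-entropy from logits (stable log-softmax)."""
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    log_probs = z - z.exp().sum(axis=-1, keepdims=True).log()
    return -(Tensor(onehot) * log_probs).sum() * (1.0 / logits.shape[0])


class TimeBranch(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.blocks = []
        c_in = 1
        for c_out, kernel, stride in config.time_blocks:
            self.blocks.append(ResidualBlock1d(c_in, c_out, kernel, stride, rng))
            c_in = c_out
        self.encoder = BiLSTMEncoder(
            c_in, config.lstm_hidden, config.lstm_layers, config.d_model, rng
        )

    def forward(self, signal: Tensor) -> Tensor:
        x = signal.reshape(signal.shape[0], 1, signal.shape[1])
        for block in self.blocks:
            x = block(x)
        return self.encoder(x.transpose((0, 2, 1)))  # (B, T, C) -> token


class SpectrogramBranch(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.blocks = []
        c_in = 1
        for c_out, kernel, stride in config.spec_blocks:
            self.blocks.append(
                ResidualBlock2d(c_in, c_out, (kernel, kernel), (stride, stride), rng)
            )
            c_in = c_out
        self.encoder = BiLSTMEncoder(
            c_in, config.lstm_hidden, config.lstm_layers, config.d_model, rng
        )

    def forward(self, images: Tensor) -> Tensor:
        if images.ndim != 4 or images.shape[1] != N_IMAGES:
            raise InvalidInputError(
                f"expected (B, {N_IMAGES}, H, W) spectrogram stack, got {images.shape}"
            )
        b, n, h, w = images.shape
        x = images.reshape(b * n, 1, h, w)
        for block in self.blocks:
            x = block(x)
        pooled = x.mean(axis=(2, 3))                 # (B*N, C)
        seq = pooled.reshape(b, n, pooled.shape[-1])  # length-10 image sequence
        return self.encoder(seq)


class PhysioBranch(Module):
    """Age one-hot + gender embedding through 6 fully connected layers."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.gender_embedding = Embedding(len(GENDERS), config.gender_dim, rng)
        dims = [AGE_DIM + config.gender_dim, *config.physio_widths, config.d_model]
        self.fc = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]

    def forward(self, age_onehot: Tensor, gender_idx: np.ndarray) -> Tensor:
        x = concat([age_onehot, self.gender_embedding(gender_idx)], axis=-1)
        for i, layer in enumerate(self.fc):
            x = layer(x)
            if i < len(self.fc) - 1:
                x = x.elu()
        return x


class HybridFatigueModel(Module):
    """ResNet+BiLSTM branches with transformer-encoder fusion."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.time_branch = TimeBranch(config, rng) if config.use_T else None
        self.spec_branch = SpectrogramBranch(config, rng) if config.use_S else None
        self.physio_branch = PhysioBranch(config, rng) if config.use_P else None
        # learned branch-type embeddings stand in for positional encodings
        # over the (at most 3) fusion tokens
        self.type_embeddings = Embedding(3, config.d_model, rng)
        self.fusion = [
            TransformerEncoderLayer(
                config.d_model, config.transformer_heads, config.transformer_ff, rng
            )
            for _ in range(config.transformer_layers)
        ]
        self.head = Linear(config.d_model, N_CLASSES, rng)

    # -- branch encoders -----------------------------------------------------
    def encode_time(self, signal: np.ndarray | Tensor) -> Tensor:
        signal = signal if isinstance(signal, Tensor) else Tensor(signal)
        if signal.shape[-1] != GROUP_SAMPLES:
            raise InvalidInputError(
                f"time branch expects {GROUP_SAMPLES}-sample groups, got {signal.shape[-1]}"
            )
        return self.time_branch(signal)

    def encode_spec(self, images: np.ndarray | Tensor) -> Tensor:
        images = images if isinstance(images, Tensor) else Tensor(images)
        return self.spec_branch(images)

    def encode_physio(self, ages: np.ndarray, gender_idx: np.ndarray) -> Tensor:
        onehot = np.stack([one_hot_age(a) for a in np.atleast_1d(ages)])
        return self.physio_branch(Tensor(onehot), np.atleast_1d(gender_idx))

    # -- fusion --------------------------------------------------------------
    def fuse_and_classify(self, tokens: list[Tensor], use_type_embeddings: bool = True) -> Tensor:
        """Fuse branch tokens and return class probabilities (B, 2)."""
        if not tokens:
            raise ConfigError("fusion requires at least one branch token")
        if use_type_embeddings:
            tokens = [
                tok + self.type_embeddings(np.array([i])) for i, tok in enumerate(tokens)
            ]
        seq = concat([t.reshape(t.shape[0], 1, t.shape[1]) for t in tokens], axis=1)
        for layer in self.fusion:
            seq = layer(seq)
        pooled = seq.mean(axis=1)
        return softmax_op(self.head(pooled), axis=-1)

    def logits(self, batch: dict) -> Tensor:
        tokens = []
        if self.config.use_T:
            tokens.append(self.encode_time(batch["signal"]))
        if self.config.use_S:
            tokens.append(self.encode_spec(batch["images"]))
        if self.config.use_P:
            tokens.append(self.encode_physio(batch["age"], batch["gender_idx"]))
        tokens = [
            tok + self.type_embeddings(np.array([i])) for i, tok in enumerate(tokens)
        ]
        seq = concat([t.reshape(t.shape[0], 1, t.shape[1]) for t in tokens], axis=1)
        for layer in self.fusion:
            seq = layer(seq)
        return self.head(seq.mean(axis=1))

    def forward(self, batch: dict) -> Tensor:
        """Class probabilities (B, 2) for a batch dict of enabled modalities."""
        return softmax_op(self.logits(batch), axis=-1)

    def predict(self, batch: dict) -> np.ndarray:
        with no_grad():
            return self.forward(batch).data.argmax(axis=-1)


def save_checkpoint(model: HybridFatigueModel, path) -> None:
    """Persist weights with the full configuration embedded."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(dataclasses.asdict(model.config))
    arrays = {f"param_{i}": p for i, p in enumerate(model.state_dict())}
    np.savez(path, config=np.array(config_json), **arrays)


def load_checkpoint(path) -> HybridFatigueModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    data = np.load(path, allow_pickle=False)
    raw = json.loads(str(data["config"]))
    for key in ("time_blocks", "spec_blocks"):
        raw[key] = tuple(tuple(block) for block in raw[key])
    raw["physio_widths"] = tuple(raw["physio_widths"])
    model = HybridFatigueModel(ModelConfig(**raw))
    n_params = len(model.parameters())
    model.load_state_dict([data[f"param_{i}"] for i in range(n_params)])
    return model


def labels_to_onehot(labels: list[str] | np.ndarray) -> np.ndarray:
    idx = np.array([CLASS_TO_INDEX[l] for l in labels])
    onehot = np.zeros((len(idx), N_CLASSES))
    onehot[np.arange(len(idx)), idx] = 1.0
    return onehot
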