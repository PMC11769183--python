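"""Training/evaluation harness: splits, metrics, the training loop, ablation.

Accuracy and F1 treat fatigue (F) as the positive class:

    accuracy = (TP + TN) / (TP + FP + FN + TN) * 100
    F1       = 2 TP / (2 TP + FP + FN)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from fatiguecg.errors import ConfigError, InvalidInputError
from fatiguecg.features import Example
from fatiguecg.model import (
    CLASS_TO_INDEX,
    HybridFatigueModel,
    ModelConfig,
    cross_entropy_logits,
    labels_to_onehot,
)
from fatiguecg.nn import Adam, no_grad
from fatiguecg.synthetic import GENDERS

ABLATION_CONFIGS = ("S", "S + P", "T", "T + S", "T + P", "T + S + P")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    mode: str = "example-random"  # or "subject-grouped"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction <= 1.0:
            raise ConfigError("train_fraction must lie in (0, 1]")
        if self.mode not in ("example-random", "subject-grouped"):
            raise ConfigError(f"unknown split mode {self.mode!r}")


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int
    tn: int
    config_fingerprint: str = ""
    seed: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        """Accuracy in percent."""
        return (self.tp + self.tn) / self.n * 100.0

    @property
    def f1(self) -> float:
        """F1 with F as the positive class; 0 when there are no positives at all."""
        denom = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / denom if denom else 0.0

    @property
    def macro_f1(self) -> float:
        denom_pos = 2 * self.tp + self.fp + self.fn
        denom_neg = 2 * self.tn + self.fp + self.fn
        f1_pos = 2 * self.tp / denom_pos if denom_pos else 0.0
        f1_neg = 2 * self.tn / denom_neg if denom_neg else 0.0
        return 0.5 * (f1_pos + f1_neg)


def evaluate(predictions, labels, config_fingerprint: str = "", seed: int = 0) -> EvalResult:
    """Confusion counts + metrics from predicted and true F/N labels.

    Accepts label strings ("F"/"N") or class indices (1/0).
    """
    def to_idx(values):
        return np.array([CLASS_TO_INDEX[v] if isinstance(v, str) else int(v) for v in values])

    pred = to_idx(predictions)
    true = to_idx(labels)
    if pred.shape != true.shape:
        raise InvalidInputError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise InvalidInputError("cannot evaluate zero predictions")
    return EvalResult(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        config_fingerprint=config_fingerprint,
        seed=seed,
    )


def split_dataset(examples: list[Example], spec: SplitSpec | None = None) -> tuple[list[Example], list[Example]]:
    """9:1 (by default) train/test split, example-random or subject-grouped."""
    spec = spec or SplitSpec()
    n = len(examples)
    if n < 2:
        raise InvalidInputError("need at least 2 examples to split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * n))
    if spec.mode == "example-random":
        order = rng.permutation(n)
        train_idx, test_idx = order[:n_train], order[n_train:]
    else:
        subjects = sorted({ex.profile.subject_id for ex in examples})
        order = rng.permutation(len(subjects))
        counts = {s: sum(ex.profile.subject_id == s for ex in examples) for s in subjects}
        train_subjects: set[str] = set()
        total = 0
        for si in order:
            if total >= n_train:
                break
            train_subjects.add(subjects[si])
            total += counts[subjects[si]]
        if len(train_subjects) == len(subjects):  # keep the test side non-empty
            train_subjects.discard(subjects[order[-1]])
        train_idx = [i for i, ex in enumerate(examples) if ex.profile.subject_id in train_subjects]
        test_idx = [i for i, ex in enumerate(examples) if ex.profile.subject_id not in train_subjects]
    return [examples[i] for i in train_idx], [examples[i] for i in test_idx]


def examples_to_batch(examples: list[Example]) -> dict:
    """Stack a list of examples into the model's batch arrays."""
    return {
        "signal": np.stack([ex.signal for ex in examples]),
        "images": np.stack([ex.images for ex in examples]),
        "age": np.array([ex.profile.age for ex in examples]),
        "gender_idx": np.array([GENDERS.index(ex.profile.gender) for ex in examples]),
        "labels": [ex.label for ex in examples],
    }


@dataclass(frozen=True)
class OptimizerConfig:
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    val_fraction: float = 0.15
    min_epochs: int = 10
    seed: int = 0


@dataclass
class TrainLog:
    epoch_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


def _epoch_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _batch_loss(model: HybridFatigueModel, batch: dict, onehot: np.ndarray):
    logits = model.logits(batch)
    return cross_entropy_logits(logits, onehot)


def train(
    train_examples: list[Example],
    model_config: ModelConfig | None = None,
    opt_config: OptimizerConfig | None = None,
) -> tuple[HybridFatigueModel, TrainLog]:
    """Train the hybrid model with Adam, early-stopping on held-out loss.

    Fully deterministic for fixed configs: model initialization, batch order
    and the validation split all derive from the two config seeds.
    """
    model_config = model_config or ModelConfig()
    opt_config = opt_config or OptimizerConfig()
    labels = {ex.label for ex in train_examples}
    if len(train_examples) == 0 or len(labels) < 2:
        raise InvalidInputError("training requires a non-empty, two-class train set")

    rng = np.random.default_rng(opt_config.seed)
    n = len(train_examples)
    n_val = max(int(round(opt_config.val_fraction * n)), 0)
    order = rng.permutation(n)
    val_examples = [train_examples[i] for i in order[:n_val]]
    fit_examples = [train_examples[i] for i in order[n_val:]]
    if not fit_examples:
        raise InvalidInputError("validation split left no training examples")
    if len({ex.label for ex in fit_examples}) < 2:
        # degenerate holdout draw; fall back to training on everything
        fit_examples, val_examples = train_examples, []

    model = HybridFatigueModel(model_config)
    optimizer = Adam(model.parameters(), lr=opt_config.lr)
    log = TrainLog()
    batch_all = examples_to_batch(fit_examples)
    onehot_all = labels_to_onehot(batch_all["labels"])
    val_batch = examples_to_batch(val_examples) if val_examples else None
    val_onehot = labels_to_onehot(val_batch["labels"]) if val_batch else None

    best_state = model.state_dict()
    best_val = np.inf
    stale = 0
    for epoch in range(opt_config.max_epochs):
        losses = []
        for idx in _epoch_minibatches(len(fit_examples), opt_config.batch_size, rng):
            batch = {
                "signal": batch_all["signal"][idx],
                "images": batch_all["images"][idx],
                "age": batch_all["age"][idx],
                "gender_idx": batch_all["gender_idx"][idx],
            }
            loss = _batch_loss(model, batch, onehot_all[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        log.epoch_loss.append(float(np.mean(losses)))
        if val_batch is not None:
            with no_grad():
                val_logits = model.logits(val_batch)
                vloss = float(cross_entropy_logits(val_logits, val_onehot).data)
                vpred = val_logits.data.argmax(axis=-1)
            vacc = evaluate(vpred, val_batch["labels"]).accuracy
            log.val_loss.append(vloss)
            log.val_accuracy.append(vacc)
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_state = model.state_dict()
                log.best_epoch = epoch
                stale = 0
            else:
                stale += 1
            if epoch + 1 >= opt_config.min_epochs and stale >= opt_config.patience:
                break
        else:
            log.best_epoch = epoch
            best_state = model.state_dict()
            if log.epoch_loss[-1] < 1e-3:
                break
    model.load_state_dict(best_state)
    return model, log


def train_and_evaluate(
    examples: list[Example],
    model_config: ModelConfig | None = None,
    opt_config: OptimizerConfig | None = None,
    split_spec: SplitSpec | None = None,
) -> tuple[HybridFatigueModel, EvalResult, TrainLog]:
    split_spec = split_spec or SplitSpec()
    train_set, test_set = split_dataset(examples, split_spec)
    model, log = train(train_set, model_config, opt_config)
    test_batch = examples_to_batch(test_set)
    pred = model.predict(test_batch)
    result = evaluate(
        pred,
        test_batch["labels"],
        config_fingerprint=(model_config or ModelConfig()).ablation_name(),
        seed=split_spec.seed,
    )
    return model, result, log


def run_ablation(
    examples: list[Example],
    base_config: ModelConfig | None = None,
    opt_config: OptimizerConfig | None = None,
    split_spec: SplitSpec | None = None,
    configs: tuple[str, ...] = ABLATION_CONFIGS,
) -> pd.DataFrame:
    """Evaluate the six branch combinations on one shared split.

    Returns a table with one row per configuration (S, S+P, T, T+S, T+P,
    T+S+P), reporting F1 and accuracy like the comparison tables the model
    design is evaluated with.
    """
    base_config = base_config or ModelConfig()
    rows = []
    for name in configs:
        flags = set(name.replace(" ", "").split("+"))
        config = replace(
            base_config, use_T="T" in flags, use_S="S" in flags, use_P="P" in flags
        )
        _, result, _ = train_and_evaluate(examples, config, opt_config, split_spec)
        rows.append(
            {
                "Method": name,
                "F1 score": round(result.f1, 4),
                "Accuracy (%)": round(result.accuracy, 2),
                "TP": result.tp,
                "FP": result.fp,
                "FN": result.fn,
                "TN": result.tn,
            }
        )
    return pd.DataFrame(rows)
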