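"""Comparison models: SVM, random forest, CNN, LSTM and BiLSTM.

Classical models (SVM with C=0.1, gamma=10 and a sigmoid kernel; random
forest with 100 trees, random seed 40, maximum depth 100) consume the
flattened, 4x-decimated 10 s time series; the 18-layer CNN (3x3 kernels)
consumes the stacked spectrogram images; the recurrent baselines (depth 6,
input/hidden dimension 64, optionally bidirectional) consume the decimated
time series as a sequence.  All baselines run on the same splits as the
hybrid model so comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from fatiguecg.errors import InvalidInputError
from fatiguecg.features import Example
from fatiguecg.harness import EvalResult, evaluate
from fatiguecg.model import cross_entropy_logits, labels_to_onehot
from fatiguecg.nn import Adam, Conv2d, Linear, Module, Tensor, no_grad
from fatiguecg.nn.layers import LSTM

DECIMATION = 4


@dataclass(frozen=True)
class BaselineConfig:
    method: str = "svm"
    # SVM (printed hyperparameters)
    svm_c: float = 0.1
    svm_gamma: float = 10.0
    svm_kernel: str = "sigmoid"
    # Random forest (printed hyperparameters)
    rf_trees: int = 100
    rf_seed: int = 40
    rf_max_depth: int = 100
    # CNN
    cnn_layers: int = 18
    cnn_kernel: int = 3
    cnn_channels: int = 16
    # LSTM
    lstm_depth: int = 6
    lstm_dim: int = 64
    bidirectional: bool = False
    # neural training
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0


def time_features(examples: list[Example]) -> np.ndarray:
    """Flattened 4x-decimated group time series, (B, 325)."""
    return np.stack([ex.signal[::DECIMATION] for ex in examples])


def spectrogram_features(examples: list[Example]) -> np.ndarray:
    """Stacked spectrogram images, (B, 10, H, W)."""
    return np.stack([ex.images for ex in examples])


def _check_two_classes(labels: list[str]) -> None:
    if len(set(labels)) < 2:
        raise InvalidInputError("training set must contain both classes")


def _labels(examples: list[Example]) -> list[str]:
    return [ex.label for ex in examples]


def svm_baseline(
    train: list[Example], test: list[Example], config: BaselineConfig | None = None
) -> tuple[SVC, EvalResult]:
    config = config or BaselineConfig(method="svm")
    _check_two_classes(_labels(train))
    clf = SVC(C=config.svm_c, gamma=config.svm_gamma, kernel=config.svm_kernel)
    clf.fit(time_features(train), _labels(train))
    pred = clf.predict(time_features(test))
    return clf, evaluate(pred, _labels(test), config_fingerprint="svm", seed=config.seed)


def rf_baseline(
    train: list[Example], test: list[Example], config: BaselineConfig | None = None
) -> tuple[RandomForestClassifier, EvalResult]:
    config = config or BaselineConfig(method="rf")
    _check_two_classes(_labels(train))
    clf = RandomForestClassifier(
        n_estimators=config.rf_trees,
        random_state=config.rf_seed,
        max_depth=config.rf_max_depth,
    )
    clf.fit(time_features(train), _labels(train))
    pred = clf.predict(time_features(test))
    return clf, evaluate(pred, _labels(test), config_fingerprint="rf", seed=config.seed)


class CNN18(Module):
    """18 weighted layers: 17 convolutions (all 3x3) + one final linear.

    Stride-2 convolutions at regular intervals stand in for pooling; global
    average pooling feeds the classification layer.
    """

    def __init__(self, c_in: int, config: BaselineConfig):
        rng = np.random.default_rng(config.seed)
        k = (config.cnn_kernel, config.cnn_kernel)
        c = config.cnn_channels
        self.convs = []
        n_convs = config.cnn_layers - 1
        downsample_at = {0, n_convs // 3, 2 * n_convs // 3}
        for i in range(n_convs):
            stride = (2, 2) if i in downsample_at else (1, 1)
            self.convs.append(Conv2d(c_in if i == 0 else c, c, k, stride, rng))
        self.head = Linear(c, 2, rng)

    @property
    def n_weighted_layers(self) -> int:
        return len(self.convs) + 1

    def forward(self, images: Tensor) -> Tensor:
        x = images
        for conv in self.convs:
            x = conv(x).relu()
        return self.head(x.mean(axis=(2, 3)))


class RecurrentClassifier(Module):
    """Stacked (Bi)LSTM over the decimated time series + linear head."""

    def __init__(self, config: BaselineConfig):
        rng = np.random.default_rng(config.seed)
        self.lstm = LSTM(
            1, config.lstm_dim, config.lstm_depth, rng, bidirectional=config.bidirectional
        )
        dirs = 2 if config.bidirectional else 1
        self.head = Linear(config.lstm_dim * dirs, 2, rng)

    def forward(self, x: Tensor) -> Tensor:
        _, final = self.lstm(x)
        return self.head(final)


def _train_nn(
    model: Module, features: np.ndarray, labels: list[str], config: BaselineConfig
) -> Module:
    """Shared mini-batch Adam loop for the neural baselines."""
    _check_two_classes(labels)
    onehot = labels_to_onehot(labels)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.lr)
    n = features.shape[0]
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss = cross_entropy_logits(model(Tensor(features[idx])), onehot[idx])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        if np.mean(losses) < 5e-3:
            break
    return model


def _predict_nn(model: Module, features: np.ndarray) -> np.ndarray:
    with no_grad():
        return model(Tensor(features)).data.argmax(axis=-1)


def cnn_baseline(
    train: list[Example], test: list[Example], config: BaselineConfig | None = None
) -> tuple[CNN18, EvalResult]:
    config = config or BaselineConfig(method="cnn")
    feats = spectrogram_features(train)
    model = CNN18(feats.shape[1], config)
    _train_nn(model, feats, _labels(train), config)
    pred = _predict_nn(model, spectrogram_features(test))
    return model, evaluate(pred, _labels(test), config_fingerprint="cnn", seed=config.seed)


def lstm_baseline(
    train: list[Example],
    test: list[Example],
    config: BaselineConfig | None = None,
    bidirectional: bool | None = None,
) -> tuple[RecurrentClassifier, EvalResult]:
    config = config or BaselineConfig(method="lstm")
    if bidirectional is not None:
        config = BaselineConfig(**{**config.__dict__, "bidirectional": bidirectional})
    feats = time_features(train)[:, :, None]
    model = RecurrentClassifier(config)
    _train_nn(model, feats, _labels(train), config)
    pred = _predict_nn(model, time_features(test)[:, :, None])
    name = "bilstm" if config.bidirectional else "lstm"
    return model, evaluate(pred, _labels(test), config_fingerprint=name, seed=config.seed)


BASELINES = {
    "svm": svm_baseline,
    "rf": rf_baseline,
    "cnn": cnn_baseline,
    "lstm": lambda tr, te, cfg=None: lstm_baseline(tr, te, cfg, bidirectional=False),
    "bilstm": lambda tr, te, cfg=None: lstm_baseline(tr, te, cfg, bidirectional=True),
}


def run_baseline(
    method: str, train: list[Example], test: list[Example], config: BaselineConfig | None = None
) -> tuple[object, EvalResult]:
    if method not in BASELINES:
        raise InvalidInputError(f"unknown baseline {method!r}; choose from {sorted(BASELINES)}")
    return BASELINES[method](train, test, config)
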