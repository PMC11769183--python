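"""Neural layers built on the autodiff engine.

Initialization follows standard fan-in scaling (He for conv/dense feeding
ELU, Glorot for recurrent and attention weights), each layer drawing from a
``numpy.random.Generator`` passed in at construction so whole models are
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from fatiguecg.nn.autodiff import Tensor, concat, lstm_layer, softmax


class Module:
    """Base class: collects parameters from attributes, sub-modules and lists."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        def collect(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for p in obj.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    collect(item)
        for value in self.__dict__.values():
            collect(value)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(p_list := self.parameters(), state):
            p.data = s.copy()
        if len(p_list) != len(state):
            raise ValueError("state size mismatch")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """'Same'-style 1D convolution via unfold + matmul; input (B, C, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.kernel, self.stride = kernel, stride
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = Tensor(
            rng.normal(0, scale, size=(c_in * kernel, c_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        pad_total = self.kernel - 1
        lo, hi = pad_total // 2, pad_total - pad_total // 2
        x = x.pad(((0, 0), (0, 0), (lo, hi)))
        cols = x.unfold1d(self.kernel, self.stride)       # (B, L_out, C*K)
        out = cols @ self.weight + self.bias              # (B, L_out, C_out)
        return out.transpose((0, 2, 1))                   # (B, C_out, L_out)


class Conv2d(Module):
    """'Same'-style 2D convolution; input (B, C, H, W)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int],
        stride: tuple[int, int],
        rng: np.random.Generator,
    ):
        self.kernel, self.stride = kernel, stride
        fan_in = c_in * kernel[0] * kernel[1]
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(rng.normal(0, scale, size=(fan_in, c_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        (kh, kw), (sh, sw) = self.kernel, self.stride
        ph, pw = kh - 1, kw - 1
        x = x.pad(((0, 0), (0, 0), (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)))
        b, c, h, w = x.shape
        h_out = (h - kh) // sh + 1
        w_out = (w - kw) // sw + 1
        cols = x.unfold2d(self.kernel, self.stride)       # (B, Ho*Wo, C*kh*kw)
        out = cols @ self.weight + self.bias              # (B, Ho*Wo, C_out)
        return out.transpose((0, 2, 1)).reshape(b, -1, h_out, w_out)


class ResidualBlock1d(Module):
    """Two 1D convolutions with ELU and an identity/projection skip path."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv1d(c_in, c_out, kernel, stride, rng)
        self.conv2 = Conv1d(c_out, c_out, kernel, 1, rng)
        self.proj = (
            Conv1d(c_in, c_out, 1, stride, rng) if (c_in != c_out or stride != 1) else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).elu())
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).elu()


class ResidualBlock2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: tuple[int, int],
        stride: tuple[int, int],
        rng: np.random.Generator,
    ):
        self.conv1 = Conv2d(c_in, c_out, kernel, stride, rng)
        self.conv2 = Conv2d(c_out, c_out, kernel, (1, 1), rng)
        self.proj = (
            Conv2d(c_in, c_out, (1, 1), stride, rng)
            if (c_in != c_out or stride != (1, 1))
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv2(self.conv1(x).elu())
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).elu()


class LSTMCellParams(Module):
    """Gate parameters for one LSTM layer-direction (i, f, g, o stacked)."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / max(n_in + hidden, 1))
        self.w_x = Tensor(rng.normal(0, scale, size=(n_in, 4 * hidden)), requires_grad=True)
        self.w_h = Tensor(rng.normal(0, scale, size=(hidden, 4 * hidden)), requires_grad=True)
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0  # forget-gate bias, standard trick
        self.bias = Tensor(bias, requires_grad=True)
        self.hidden = hidden


class LSTM(Module):
    """Stacked (optionally bidirectional) LSTM over (B, T, F) sequences.

    Returns (outputs (B, T, H*dirs), final hidden (B, H*dirs) of the last
    layer).
    """

    def __init__(
        self,
        n_in: int,
        hidden: int,
        n_layers: int,
        rng: np.random.Generator,
        bidirectional: bool = True,
    ):
        self.hidden = hidden
        self.bidirectional = bidirectional
        self.layers: list[list[LSTMCellParams]] = []
        dirs = 2 if bidirectional else 1
        for layer in range(n_layers):
            d_in = n_in if layer == 0 else hidden * dirs
            self.layers.append([LSTMCellParams(d_in, hidden, rng) for _ in range(dirs)])

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        finals: list[Tensor] = []
        for cells in self.layers:
            fwd = lstm_layer(
                x, cells[0].w_x, cells[0].w_h, cells[0].bias, cells[0].hidden
            )
            if self.bidirectional:
                bwd = lstm_layer(
                    x, cells[1].w_x, cells[1].w_h, cells[1].bias, cells[1].hidden,
                    reverse=True,
                )
                x = concat([fwd, bwd], axis=-1)
                finals = [fwd[:, -1, :], bwd[:, 0, :]]
            else:
                x = fwd
                finals = [fwd[:, -1, :]]
        return x, concat(finals, axis=-1)


class BiLSTMEncoder(Module):
    """BiLSTM whose concatenated final states are projected to ``d_out``."""

    def __init__(self, n_in: int, hidden: int, n_layers: int, d_out: int, rng: np.random.Generator):
        self.lstm = LSTM(n_in, hidden, n_layers, rng, bidirectional=True)
        self.proj = Linear(2 * hidden, d_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        _, final = self.lstm(x)
        return self.proj(final)


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0, 1.0, size=(n_vocab, dim)), requires_grad=True)

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=int)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / ((var + self.eps) ** 0.5) * self.gain + self.bias


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention over (B, T, d)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.q = Linear(d_model, d_model, rng)
        self.k = Linear(d_model, d_model, rng)
        self.v = Linear(d_model, d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        return x.reshape(b, t, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def forward(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        q, k, v = self._split(self.q(x)), self._split(self.k(x)), self._split(self.v(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, t, d)
        return self.out(ctx)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder layer (attention + feed-forward)."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiheadSelfAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(self.ff1(self.norm2(x)).elu())
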