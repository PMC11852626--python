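"""The CLTNet network: CNN feature extractor, stacked LSTM, Transformer
encoder, and fully connected classifier, built on the NumPy autodiff engine.

Data flow for a trial batch of shape (B, C, T):

1. CNN stage — a temporal convolution shared across electrodes (F1 filters
   of length KC1, 'same' padding), a depthwise spatial convolution across
   the C electrodes (depth multiplier D, so F2 = F1*D maps of spatial extent
   one) with batch norm, ELU and average pooling (1, pool1), then a full
   temporal convolution (F2 filters of length KC2, 'same' padding) with
   batch norm, ELU and average pooling (1, P2). The result is reshaped to a
   feature sequence of TC = floor(floor(T/pool1)/P2) steps of width d = F2.
2. Two stacked LSTM layers (hidden width equal to d) return the full output
   sequence, preserving its length.
3. A Transformer encoder (multi-head scaled-dot-product self-attention with
   h heads of width d_k, residual + layer norm, position-wise feed-forward
   with exact GELU, residual + layer norm). No positional encoding is used.
4. The encoder output (optionally concatenated with the flattened LSTM
   output sequence) is flattened, passed through dropout and a linear map
   to N class logits.

Dropout is active only in training mode; evaluation-mode forwards are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from .autodiff import Tensor, cat

__all__ = ["ModelConfig", "CLTNet", "Module", "feature_sequence_length",
           "temporal_receptive_field_ms", "count_parameters",
           "save_checkpoint", "load_checkpoint"]


def feature_sequence_length(T: int, pool1: int, P2: int) -> int:
    """Post-CNN sequence length TC under floor division at both pooling stages."""
    return (T // pool1) // P2


def temporal_receptive_field_ms(kernel: int, rate_hz: float) -> float:
    """Time span covered by a temporal kernel at a given (post-pooling) rate."""
    return kernel * 1000.0 / rate_hz


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The defaults realize the reference 4-class configuration: F1=8 temporal
    filters with depth multiplier D=2 give F2=16 feature maps (the feature
    width d), kernels KC1=KC2=16, pooling 8 then P2=8 so a 1000-sample trial
    becomes a 15-step sequence, a two-layer LSTM with 16 hidden units, and a
    single encoder layer with h=2 heads of width d_k=16.
    """

    C: int = 22
    T: int = 1000
    F1: int = 8
    D: int = 2
    KC1: int = 16
    KC2: int = 16
    pool1: int = 8
    P2: int = 8
    dropout_cnn: float = 0.3
    lstm_layers: int = 2
    lstm_hidden: int = 16
    dropout_lstm: float = 0.5
    encoder_layers: int = 1
    h: int = 2
    d_k: int = 16
    ffn_hidden: int = 32
    dropout_ffn: float = 0.3
    dropout_cls: float = 0.5
    N: int = 4
    fusion: str = "concat"          # {"concat", "encoder_only"}
    use_lstm: bool = True
    use_transformer: bool = True
    spatial_mode: str = "depthwise"  # {"depthwise", "mean"} ("mean" = ablated spatial stage)

    @property
    def F2(self) -> int:
        return self.F1 * self.D

    @property
    def d(self) -> int:
        return self.F2

    @property
    def TC(self) -> int:
        return feature_sequence_length(self.T, self.pool1, self.P2)

    def __post_init__(self):
        for name in ("C", "T", "F1", "D", "KC1", "KC2", "pool1", "P2",
                     "lstm_layers", "lstm_hidden", "encoder_layers", "h",
                     "d_k", "ffn_hidden", "N"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.TC < 1:
            raise ValueError(f"config yields TC={self.TC} < 1 (T={self.T}, "
                             f"pool1={self.pool1}, P2={self.P2})")
        if self.use_lstm and self.lstm_hidden != self.d:
            raise ValueError("lstm_hidden must equal d (= F1*D) so the encoder "
                             "residual is well-typed")
        if self.fusion not in ("concat", "encoder_only"):
            raise ValueError("fusion must be 'concat' or 'encoder_only'")
        if self.spatial_mode not in ("depthwise", "mean"):
            raise ValueError("spatial_mode must be 'depthwise' or 'mean'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# -- module plumbing ---------------------------------------------------------

class Module:
    """Minimal parameter container with named parameter/buffer traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, np.ndarray):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_buffers(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, val in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = val
            else:
                params[key].data[...] = val


def _uniform(rng: np.random.Generator, shape, bound: float) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def dropout(x: Tensor, p: float, train: bool, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity in evaluation mode."""
    if not train or p <= 0:
        return x
    if rng is None:
        raise ValueError("training-mode dropout requires an RNG")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(n_in)
        self.W = _uniform(rng, (n_in, n_out), bound)
        self.b = _uniform(rng, (n_out,), bound) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out


class BatchNorm(Module):
    """Batch normalization over (batch, time) per feature map; input (B, F, L)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self._eps = eps
        self._momentum = momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2), keepdims=True)
            n = x.shape[0] * x.shape[2]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self._momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self._momentum * (unbiased - self.running_var)
            xhat = xc * ((var + self._eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, -1, 1)
            sd = np.sqrt(self.running_var + self._eps).reshape(1, -1, 1)
            xhat = (x - mu) * (1.0 / sd)
        F = self.gamma.shape[0]
        return xhat * self.gamma.reshape(1, F, 1) + self.beta.reshape(1, F, 1)


class LayerNorm(Module):
    """Layer normalization over the last axis, with affine rescaling."""

    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return (xc * ((var + self._eps) ** -0.5)) * self.gamma + self.beta


def avg_pool_last(x: Tensor, width: int) -> Tensor:
    """Non-overlapping average pooling along the last axis (floor division)."""
    L = x.shape[-1] // width
    if L < 1:
        raise ValueError(f"pooling width {width} exceeds axis length {x.shape[-1]}")
    trimmed = x[..., :L * width]
    return trimmed.reshape(x.shape[:-1] + (L, width)).mean(axis=-1)


def _same_pad(kernel: int) -> tuple[int, int]:
    return ((kernel - 1) // 2, kernel // 2)


class TemporalConv(Module):
    """F filters of shape (1, K) applied along time, shared across electrodes.

    Input (B, 1, C, T) -> output (B, F, C, T) under 'same' zero padding.
    """

    def __init__(self, F: int, K: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(K)
        self.W = _uniform(rng, (F, K), bound)
        self.b = _uniform(rng, (F,), bound) if bias else None
        self._K = K

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[-1]
        left, right = _same_pad(self._K)
        xp = x.pad_last(left, right)
        out = None
        for k in range(self._K):
            term = xp[..., k:k + T] * self.W[:, k].reshape(1, -1, 1, 1)
            out = term if out is None else out + term
        if self.b is not None:
            out = out + self.b.reshape(1, -1, 1, 1)
        return out


class DepthwiseSpatialConv(Module):
    """Depthwise filters of shape (C, 1): per temporal map, D spatial filters
    spanning all electrodes. Input (B, F1, C, T) -> output (B, F1*D, T).
    """

    def __init__(self, F1: int, D: int, C: int, rng: np.random.Generator):
        self.W = _uniform(rng, (F1, C, D), 1.0 / np.sqrt(C))

    def __call__(self, x: Tensor) -> Tensor:
        B, F1, C, T = x.shape
        # (B, F1, T, C) @ (F1, C, D) -> (B, F1, T, D) -> (B, F1*D, T)
        out = x.transpose(0, 1, 3, 2) @ self.W
        D = self.W.shape[-1]
        return out.transpose(0, 1, 3, 2).reshape(B, F1 * D, T)


class ChannelMeanCollapse(Module):
    """Ablated spatial stage: collapse electrodes by their mean, tiled to F1*D
    maps so downstream widths are unchanged."""

    def __init__(self, D: int):
        self._D = D

    def __call__(self, x: Tensor) -> Tensor:
        B, F1, C, T = x.shape
        m = x.mean(axis=2)              # (B, F1, T)
        tiled = cat([m.reshape(B, F1, 1, T)] * self._D, axis=2)
        return tiled.reshape(B, F1 * self._D, T)


class FeatureConv(Module):
    """Full temporal convolution across feature maps: F_out filters of shape
    (F_in, K). Input (B, F_in, L) -> output (B, F_out, L), 'same' padding."""

    def __init__(self, F_in: int, F_out: int, K: int, rng: np.random.Generator):
        self.W = _uniform(rng, (K, F_in, F_out), 1.0 / np.sqrt(F_in * K))
        self._K = K

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[-1]
        left, right = _same_pad(self._K)
        xp = x.pad_last(left, right)
        out = None
        for k in range(self._K):
            # (B, L, F_in) @ (F_in, F_out) -> (B, L, F_out)
            term = xp[..., k:k + L].transpose(0, 2, 1) @ self.W[k]
            out = term if out is None else out + term
        return out.transpose(0, 2, 1)


class LSTMLayer(Module):
    """One LSTM layer with separate per-gate weights (input, forget, output,
    candidate), zero initial state, returning the full output sequence."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(hidden)
        for gate in ("i", "f", "o", "c"):
            setattr(self, f"W_x{gate}", _uniform(rng, (n_in, hidden), bound))
            setattr(self, f"W_h{gate}", _uniform(rng, (hidden, hidden), bound))
            setattr(self, f"b_{gate}", _uniform(rng, (hidden,), bound))
        self._hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        h = Tensor(np.zeros((B, self._hidden)))
        c = Tensor(np.zeros((B, self._hidden)))
        outs = []
        for t in range(L):
            xt = x[:, t, :]
            i = (xt @ self.W_xi + h @ self.W_hi + self.b_i).sigmoid()
            f = (xt @ self.W_xf + h @ self.W_hf + self.b_f).sigmoid()
            o = (xt @ self.W_xo + h @ self.W_ho + self.b_o).sigmoid()
            cand = (xt @ self.W_xc + h @ self.W_hc + self.b_c).tanh()
            c = f * c + i * cand
            h = o * c.tanh()
            outs.append(h.reshape(B, 1, self._hidden))
        return cat(outs, axis=1)


class MultiHeadAttention(Module):
    """Scaled-dot-product self-attention with h heads of width d_k.

    Per head i: Q = S W_i^Q, K = S W_i^K, V = S W_i^V; the head output is
    softmax(Q K^T / sqrt(d_k)) V; heads are concatenated and projected by
    W^O in R^{h*d_k x d}. No projection biases (following the equations).
    """

    def __init__(self, d: int, h: int, d_k: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(d)
        self.W_q = _uniform(rng, (h, d, d_k), bound)
        self.W_k = _uniform(rng, (h, d, d_k), bound)
        self.W_v = _uniform(rng, (h, d, d_k), bound)
        self.W_o = _uniform(rng, (h * d_k, d), 1.0 / np.sqrt(h * d_k))
        self._h, self._d_k = h, d_k

    def __call__(self, S: Tensor) -> Tensor:
        B, L, d = S.shape
        S4 = S.reshape(B, 1, L, d)
        Q = S4 @ self.W_q                       # (B, h, L, d_k)
        K = S4 @ self.W_k
        V = S4 @ self.W_v
        scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self._d_k))
        A = scores.softmax(axis=-1)             # rows sum to 1
        Z = A @ V                               # (B, h, L, d_k)
        merged = Z.transpose(0, 2, 1, 3).reshape(B, L, self._h * self._d_k)
        return merged @ self.W_o

    def attention_weights(self, S: Tensor) -> np.ndarray:
        """Evaluation-mode attention maps (B, h, L, L), for inspection."""
        B, L, d = S.shape
        S4 = S.reshape(B, 1, L, d)
        Q = (S4 @ self.W_q).data
        K = (S4 @ self.W_k).data
        scores = (Q @ np.swapaxes(K, -1, -2)) / np.sqrt(self._d_k)
        z = scores - scores.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)


class EncoderLayer(Module):
    """Post-norm Transformer encoder block: O = LN(MHA(S) + S);
    E = LN(FFN(O) + O) with FFN = linear -> GELU -> dropout -> linear."""

    def __init__(self, d: int, h: int, d_k: int, ffn_hidden: int,
                 dropout_ffn: float, rng: np.random.Generator):
        self.mha = MultiHeadAttention(d, h, d_k, rng)
        self.ln1 = LayerNorm(d)
        self.ffn1 = Linear(d, ffn_hidden, rng)
        self.ffn2 = Linear(ffn_hidden, d, rng)
        self.ln2 = LayerNorm(d)
        self._p = dropout_ffn

    def __call__(self, S: Tensor, train: bool, rng) -> Tensor:
        O = self.ln1(self.mha(S) + S)
        hidden = dropout(self.ffn1(O).gelu(), self._p, train, rng)
        return self.ln2(self.ffn2(hidden) + O)


class CLTNet(Module):
    """The full hybrid network. Construct with a ModelConfig and an RNG for
    weight initialization; forward passes take an explicit training flag and
    (in training mode) an RNG for dropout."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        self.conv_t = TemporalConv(cfg.F1, cfg.KC1, rng)
        if cfg.spatial_mode == "depthwise":
            self.conv_s = DepthwiseSpatialConv(cfg.F1, cfg.D, cfg.C, rng)
        else:
            self.conv_s = ChannelMeanCollapse(cfg.D)
        self.bn1 = BatchNorm(cfg.F2)
        self.conv_f = FeatureConv(cfg.F2, cfg.F2, cfg.KC2, rng)
        self.bn2 = BatchNorm(cfg.F2)
        if cfg.use_lstm:
            self.lstm = [LSTMLayer(cfg.d if i == 0 else cfg.lstm_hidden,
                                   cfg.lstm_hidden, rng)
                         for i in range(cfg.lstm_layers)]
        else:
            self.lstm = []
        if cfg.use_transformer:
            self.encoder = [EncoderLayer(cfg.d, cfg.h, cfg.d_k, cfg.ffn_hidden,
                                         cfg.dropout_ffn, rng)
                            for _ in range(cfg.encoder_layers)]
        else:
            self.encoder = []
        n_flat = cfg.TC * cfg.d
        if cfg.fusion == "concat":
            n_flat += cfg.TC * (cfg.lstm_hidden if cfg.use_lstm else cfg.d)
        self.fc = Linear(n_flat, cfg.N, rng)

    # -- stages -----------------------------------------------------------
    def cnn_forward(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        """CNN stage: (B, C, T) -> feature sequence (B, TC, d)."""
        cfg = self.cfg
        B, C, T = x.shape
        if C != cfg.C or T != cfg.T:
            raise ValueError(f"input (C={C}, T={T}) does not match config "
                             f"(C={cfg.C}, T={cfg.T})")
        h = self.conv_t(x.reshape(B, 1, C, T))          # (B, F1, C, T)
        h = self.conv_s(h)                              # (B, F2, T)
        h = avg_pool_last(self.bn1(h, train).elu(), cfg.pool1)
        h = dropout(h, cfg.dropout_cnn, train, rng)
        h = self.conv_f(h)                              # (B, F2, T//pool1)
        h = avg_pool_last(self.bn2(h, train).elu(), cfg.P2)
        h = dropout(h, cfg.dropout_cnn, train, rng)
        return h.transpose(0, 2, 1)                     # (B, TC, d)

    def lstm_forward(self, s: Tensor, train: bool = False, rng=None) -> Tensor:
        """Stacked LSTM stage: (B, TC, d) -> (B, TC, lstm_hidden)."""
        out = s
        for layer in self.lstm:
            out = layer(out)
        return dropout(out, self.cfg.dropout_lstm, train, rng)

    def transformer_encode(self, s: Tensor, train: bool = False, rng=None) -> Tensor:
        out = s
        for layer in self.encoder:
            out = layer(out, train, rng)
        return out

    def forward_logits(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        cfg = self.cfg
        B = x.shape[0]
        feats = self.cnn_forward(x, train, rng)
        seq = self.lstm_forward(feats, train, rng) if cfg.use_lstm else feats
        enc = self.transformer_encode(seq, train, rng) if cfg.use_transformer else seq
        parts = [enc.reshape(B, -1)]
        if cfg.fusion == "concat":
            parts.append(seq.reshape(B, -1))
        z = parts[0] if len(parts) == 1 else cat(parts, axis=1)
        z = dropout(z, cfg.dropout_cls, train, rng)
        return self.fc(z)

    def __call__(self, x: Tensor, train: bool = False, rng=None) -> Tensor:
        """Full forward pass to class probabilities (softmax over N logits)."""
        return self.forward_logits(x, train, rng).softmax(axis=-1)

    def predict_proba(self, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode class probabilities for a (trials, C, T) array."""
        data = np.asarray(data, dtype=np.float64)
        outs = [self(Tensor(data[i:i + batch_size])).data
                for i in range(0, len(data), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict(self, data: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Predicted class labels (argmax; ties break toward the lowest index)."""
        return np.argmax(self.predict_proba(data, batch_size), axis=1)


def count_parameters(model_or_cfg) -> int:
    """Exact trainable parameter count of a model (or a config's model)."""
    model = model_or_cfg if isinstance(model_or_cfg, CLTNet) else CLTNet(model_or_cfg)
    return int(sum(p.size for p in model.parameters()))


# -- checkpoints --------------------------------------------------------------

def save_checkpoint(model: CLTNet, path) -> None:
    """Single-file weight archive with the embedded ModelConfig."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(model.cfg.to_dict())
        grp = f.create_group("state")
        for key, val in model.state_dict().items():
            grp.create_dataset(key, data=val)


def load_checkpoint(path) -> CLTNet:
    with h5py.File(path, "r") as f:
        if "config" not in f.attrs or "state" not in f:
            raise ValueError("checkpoint is missing 'config' or 'state'")
        cfg = ModelConfig.from_dict(json.loads(f.attrs["config"]))
        model = CLTNet(cfg)
        model.load_state_dict({k: f["state"][k][...] for k in f["state"]})
    return model
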