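"""Neural layers for the affinity model, built on the autograd engine.

Shapes follow the (batch, length, width) convention throughout; binary
validity masks are plain ``(batch, length)`` float arrays that travel
*outside* the autodiff graph (they are data, not parameters).
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat

# Large negative surrogate for -inf in additive attention masks.  After the
# max-shift inside softmax, exp(-NEG_INF) underflows to exactly 0.0, so masked
# keys receive exactly zero attention weight.
NEG_INF = 1e30


class Module:
    """Base class: tracks submodules/parameters, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data = np.asarray(state[p.name], dtype=np.float64).copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str):
        super().__init__()
        self.W = Parameter(_glorot(rng, n_in, n_out), name=f"{name}.W")
        self.b = Parameter(np.zeros(n_out), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, width: int, rng: np.random.Generator, name: str):
        super().__init__()
        self.table = Parameter(
            rng.normal(0.0, 0.1, size=(n_vocab, width)), name=f"{name}.table"
        )

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.table.take_rows(np.asarray(ids, dtype=np.intp))


class Conv1dSame(Module):
    """'Same'-padded 1D convolution as a sum of shifted matmuls.

    Input (B, L, h_in) -> output (B, L, h_out); zero padding at the borders,
    which coincides with masked (zeroed) padding positions so that batch and
    single-sample predictions agree exactly.
    """

    def __init__(
        self, h_in: int, h_out: int, kernel: int, rng: np.random.Generator, name: str
    ):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.kernel = kernel
        self.taps = [
            Parameter(_glorot(rng, h_in, h_out) / kernel, name=f"{name}.W{j}")
            for j in range(kernel)
        ]
        self.b = Parameter(np.zeros(h_out), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        half = self.kernel // 2
        L = x.shape[-2]
        padded = x.pad_axis(-2, half, half)  # (B, L + 2*half, h_in)
        out = None
        for j, W in enumerate(self.taps):
            shifted = padded[(slice(None),) * (x.ndim - 2) + (slice(j, j + L),)]
            term = shifted @ W
            out = term if out is None else out + term
        return out + self.b


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * mask


class MLP(Module):
    """Feed-forward regression head: hidden layers with ReLU + dropout, scalar out."""

    def __init__(
        self,
        n_in: int,
        hidden: tuple[int, ...],
        dropout: float,
        rng: np.random.Generator,
        name: str,
    ):
        super().__init__()
        widths = [n_in, *hidden]
        self.layers = [
            Linear(widths[i], widths[i + 1], rng, f"{name}.fc{i}")
            for i in range(len(hidden))
        ]
        self.out = Linear(widths[-1], 1, rng, f"{name}.out")
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = self.drop(layer(x).relu())
        return self.out(x)


def build_additive_mask(m_kv: np.ndarray, L_q: int) -> np.ndarray:
    """Additive attention mask: 0 for valid keys, -inf surrogate for padding.

    Returns an (L_q, L_kv) matrix of identical rows. Raises if no key is valid.
    """
    m_kv = np.asarray(m_kv, dtype=np.float64)
    if m_kv.ndim != 1:
        raise ValueError("key mask must be one-dimensional")
    if m_kv.sum() == 0:
        raise ValueError("additive mask requires at least one valid key")
    row = np.where(m_kv > 0, 0.0, -NEG_INF)
    return np.tile(row, (L_q, 1))


class MaskedMultiHeadAttention(Module):
    """Scaled dot-product cross-attention with additive key masking.

    softmax((Q Wq)(K Wk)^T / sqrt(d_k) + M)(V Wv), heads concatenated and
    projected by Wo.  Attention weight on masked keys is exactly zero (the
    -inf surrogate underflows in the stable softmax, and weights are
    additionally multiplied by the key mask).
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, name: str):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.Wq = Linear(d_model, d_model, rng, f"{name}.Wq")
        self.Wk = Linear(d_model, d_model, rng, f"{name}.Wk")
        self.Wv = Linear(d_model, d_model, rng, f"{name}.Wv")
        self.Wo = Linear(d_model, d_model, rng, f"{name}.Wo")
        self.capture_weights = False
        self.last_weights: np.ndarray | None = None  # (B, H, L_q, L_kv)

    def _split_heads(self, x: Tensor, B: int, L: int) -> Tensor:
        return x.reshape(B, L, self.n_heads, self.d_k).swapaxes(1, 2)

    def __call__(
        self, q_in: Tensor, k_in: Tensor, v_in: Tensor, key_mask: np.ndarray
    ) -> Tensor:
        B, L_q = q_in.shape[0], q_in.shape[1]
        L_kv = k_in.shape[1]
        key_mask = np.asarray(key_mask, dtype=np.float64)
        if np.any(key_mask.sum(axis=-1) == 0):
            raise ValueError("attention requires at least one valid key per sample")
        q = self._split_heads(self.Wq(q_in), B, L_q)  # (B,H,Lq,dk)
        k = self._split_heads(self.Wk(k_in), B, L_kv)
        v = self._split_heads(self.Wv(v_in), B, L_kv)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        additive = np.where(key_mask > 0, 0.0, -NEG_INF)[:, None, None, :]
        weights = (logits + additive).softmax(axis=-1)
        # exact-zero guarantee at masked keys (no-op numerically after underflow)
        weights = weights * key_mask[:, None, None, :]
        if self.capture_weights:
            self.last_weights = weights.data.copy()
        out = weights @ v  # (B,H,Lq,dk)
        out = out.swapaxes(1, 2).reshape(B, L_q, self.d_model)
        return self.Wo(out)


def masked_mean_pool(z: Tensor, mask: np.ndarray) -> Tensor:
    """Mean over valid positions only: sum(m_i * z_i) / sum(m_i)."""
    mask = np.asarray(mask, dtype=np.float64)
    denom = mask.sum(axis=-1)
    if np.any(denom == 0):
        raise ValueError("masked mean pooling requires at least one valid position")
    weighted = z * mask[..., None]
    return weighted.sum(axis=-2) / denom[..., None]


__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "Conv1dSame",
    "Dropout",
    "MLP",
    "MaskedMultiHeadAttention",
    "build_additive_mask",
    "masked_mean_pool",
    "concat",
    "NEG_INF",
]
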