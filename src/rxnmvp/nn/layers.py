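"""Neural network building blocks on top of the autodiff tensor.

Initialisation follows the usual uniform(-1/sqrt(fan_in), 1/sqrt(fan_in))
recipe for linear and recurrent layers and N(0, 1) for embeddings. Every
module draws its initial weights from an explicit seeded generator so whole
models are reproducible from a single integer.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = ["Module", "Linear", "Embedding", "Dropout", "MLP", "BiGRU"]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self._set_mode(True)
        return self

    def eval(self):
        self._set_mode(False)
        return self

    def _set_mode(self, flag: bool):
        self.training = flag
        for value in vars(self).values():
            if isinstance(value, Module):
                value._set_mode(flag)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={missing}, extra={extra}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _uniform(rng: np.random.Generator, shape, bound: float) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(np.float32),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        k = 1.0 / np.sqrt(in_dim)
        self.weight = _uniform(rng, (in_dim, out_dim), k)
        self.bias = _uniform(rng, (out_dim,), k) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 1.0, size=(num_embeddings, dim)).astype(np.float32),
                             requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        idx = np.asarray(idx)
        flat = self.weight.gather_rows(idx.reshape(-1))
        return flat.reshape(idx.shape + (self.weight.shape[1],))


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Randomness from an owned RNG."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask.astype(np.float32))


class MLP(Module):
    """Dense stack with a choice of nonlinearity between layers."""

    def __init__(self, dims: list[int], rng: np.random.Generator, activation: str = "relu",
                 dropout: float = 0.0):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2**31))) if dropout else None

    def __call__(self, x: Tensor) -> Tensor:
        last = len(self.layers) - 1
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i != last:
                x = getattr(x, self.activation)()
                if self.drop is not None:
                    x = self.drop(x)
        return x


class _GRUDirection(Module):
    """One direction of one GRU layer (gate order: reset, update, candidate)."""

    def __init__(self, input_size: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        k = 1.0 / np.sqrt(hidden)
        self.w_ih = _uniform(rng, (input_size, 3 * hidden), k)
        self.b_ih = _uniform(rng, (3 * hidden,), k)
        self.w_hh = _uniform(rng, (hidden, 3 * hidden), k)
        self.b_hh = _uniform(rng, (3 * hidden,), k)
        self.hidden = hidden

    def __call__(self, x: Tensor, lengths: np.ndarray, reverse: bool) -> tuple[list[Tensor], Tensor]:
        """Run over x of shape (T, B, D); returns per-step outputs and final state.

        Padded steps (t >= length) leave the hidden state untouched, so the
        final state is the state at each sequence's true last step.
        """
        T, B, D = x.shape
        H = self.hidden
        # one big input projection for all timesteps
        xw = (x.reshape(T * B, D) @ self.w_ih + self.b_ih).reshape(T, B, 3 * H)
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outputs: list[Tensor | None] = [None] * T
        for t in steps:
            gi = xw[t]
            gh = h @ self.w_hh + self.b_hh
            r = (gi[:, :H] + gh[:, :H]).sigmoid()
            z = (gi[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
            n = (gi[:, 2 * H :] + r * gh[:, 2 * H :]).tanh()
            h_new = (1.0 - z) * n + z * h
            mask = Tensor((t < lengths).astype(np.float32)[:, None])
            h = mask * h_new + (1.0 - mask) * h
            outputs[t] = h
        return outputs, h  # type: ignore[return-value]


class BiGRU(Module):
    """Multi-layer bidirectional GRU over padded (T, B, D) inputs.

    Returns the concatenated final hidden states of the last layer,
    forward direction first — a (B, 2*hidden) representation.
    """

    def __init__(self, input_size: int, hidden: int, num_layers: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.dirs = []
        for layer in range(num_layers):
            in_dim = input_size if layer == 0 else 2 * hidden
            self.dirs.append(_GRUDirection(in_dim, hidden, rng))  # forward
            self.dirs.append(_GRUDirection(in_dim, hidden, rng))  # backward
        self.num_layers = num_layers
        self.hidden = hidden
        self.drop = Dropout(dropout, np.random.default_rng(rng.integers(2**31))) if dropout else None

    def __call__(self, x: Tensor, lengths: np.ndarray) -> Tensor:
        lengths = np.asarray(lengths)
        if np.any(lengths < 1):
            raise ValueError("BiGRU requires every sequence length >= 1")
        B = x.shape[1]
        for layer in range(self.num_layers):
            if layer > 0 and self.drop is not None:
                x = self.drop(x)
            fwd, bwd = self.dirs[2 * layer], self.dirs[2 * layer + 1]
            out_f, h_f = fwd(x, lengths, reverse=False)
            out_b, h_b = bwd(x, lengths, reverse=True)
            if layer < self.num_layers - 1:
                steps = [
                    concat([out_f[t], out_b[t]], axis=1).reshape(1, B, 2 * self.hidden)
                    for t in range(x.shape[0])
                ]
                x = concat(steps, axis=0)
        return concat([h_f, h_b], axis=1)
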