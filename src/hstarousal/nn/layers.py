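"""Neural-network layers built on the autodiff engine.

Provides the building blocks of the arousal detector: same-length 1-D
convolution blocks (conv -> batch norm -> ReLU), inception and residual
assemblies, a unidirectional LSTM, and a linear head.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, batchnorm, bce_with_logits, concat, conv1d

__all__ = [
    "Module",
    "Conv1d",
    "BatchNorm1d",
    "ConvBlock",
    "LSTM",
    "Linear",
    "bce_with_logits",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state export."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # state = parameters + buffers (running batch-norm statistics)
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = state[name].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm1d):
                m.running_mean = state[f"__bn{i}.running_mean"].copy()
                m.running_var = state[f"__bn{i}.running_var"].copy()


class Conv1d(Module):
    """Same-length 1-D convolution; even kernels pad one extra on the left.

    ``bias=False`` is used when a batch normalization follows: a bias
    before BN is removed by the mean subtraction and would be a dead
    parameter.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        bias: bool = True,
        *,
        rng,
    ):
        super().__init__()
        scale = np.sqrt(2.0 / (in_ch * kernel))  # He initialization
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch, kernel)) * scale, requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=bias)
        self.stride = stride
        self.pad_left = kernel // 2
        self.pad_right = (kernel - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(
            x, self.weight, self.bias, self.stride, self.pad_left, self.pad_right
        )


class BatchNorm1d(Module):
    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )


class ConvBlock(Module):
    """Convolution -> batch normalization -> ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1, *, rng):
        super().__init__()
        self.conv = Conv1d(in_ch, out_ch, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm1d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, *, rng):
        super().__init__()
        scale = 1.0 / np.sqrt(in_dim)
        self.weight = Tensor(
            rng.uniform(-scale, scale, size=(in_dim, out_dim)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LSTM(Module):
    """Unidirectional single-layer LSTM over (N, T, F) sequences."""

    def __init__(self, in_dim: int, hidden: int, *, rng):
        super().__init__()
        s = 1.0 / np.sqrt(hidden)
        self.w_ih = Tensor(
            rng.uniform(-s, s, size=(in_dim, 4 * hidden)), requires_grad=True
        )
        self.w_hh = Tensor(
            rng.uniform(-s, s, size=(hidden, 4 * hidden)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(4 * hidden), requires_grad=True)
        self.hidden = hidden

    def __call__(
        self, x: Tensor, state: tuple[Tensor, Tensor] | None = None
    ) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        N, T, _ = x.shape
        H = self.hidden
        if state is None:
            h = Tensor(np.zeros((N, H)))
            c = Tensor(np.zeros((N, H)))
        else:
            h, c = state
        outs = []
        for t in range(T):
            xt = x[:, t, :]
            gates = xt @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0 * H : 1 * H].sigmoid()
            f = gates[:, 1 * H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H : 4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h.reshape(N, 1, H))
        return concat(outs, axis=1), (h, c)
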