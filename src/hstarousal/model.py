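"""The arousal detector: an inception/residual/LSTM sequence labeler.

The network consumes multichannel signals at 4 Hz and emits one arousal
probability per second.  Front end: an inception block of four parallel
convolution blocks with kernel sizes 5/33/65/129 capturing receptive
fields from ~1 s to ~32 s.  Two residual blocks follow, each made of two
components of two convolution blocks with skip connections; the second
component of each block downsamples by stride 2, so two blocks map
4 Hz -> 1 Hz.  Two unidirectional LSTM layers integrate context over the
1 Hz feature sequence, and a linear head with sigmoid activation yields
per-second probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autodiff import Tensor, concat
from .nn.layers import LSTM, BatchNorm1d, Conv1d, ConvBlock, Linear, Module

__all__ = ["ModelConfig", "ArousalDetector", "build_model"]

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The kernel-size lists and the two-residual-block depth are fixed by
    the 4 Hz -> 1 Hz design; widths are configurable and default small
    enough for CPU training on synthetic cohorts.
    """

    n_input_channels: int = 3
    inception_kernel_sizes: tuple[int, ...] = (5, 33, 65, 129)
    inception_filters_per_branch: int = 16
    residual_kernel_sizes: tuple[int, ...] = (1, 2, 7, 2)
    residual_channels: int = 64
    n_residual_blocks: int = 2
    lstm_hidden: int = 64
    lstm_layers: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_input_channels < 1:
            raise ValueError("n_input_channels must be >= 1")
        if self.n_residual_blocks != 2:
            raise ValueError(
                "n_residual_blocks must be 2: two stride-2 stages map 4 Hz to 1 Hz"
            )
        if len(self.inception_kernel_sizes) != 4:
            raise ValueError("inception block uses four parallel branches")
        if len(self.residual_kernel_sizes) != 4:
            raise ValueError("residual blocks use four kernel sizes")
        if self.lstm_layers < 1:
            raise ValueError("lstm_layers must be >= 1")


class _Inception(Module):
    """Four parallel conv blocks over the raw input, concatenated on channels."""

    def __init__(self, in_ch: int, filters: int, kernels: tuple[int, ...], *, rng):
        super().__init__()
        self.branches = [ConvBlock(in_ch, filters, k, rng=rng) for k in kernels]

    def __call__(self, x: Tensor) -> Tensor:
        return concat([b(x) for b in self.branches], axis=1)


class _ResidualComponent(Module):
    """Two conv blocks plus a skip connection; optional stride-2 downsampling.

    The kernel pair is (k1, k2); when ``stride`` is 2 the first
    convolution carries the stride and the skip path becomes a stride-2
    kernel-1 projection.  A kernel-1 projection is also used whenever the
    channel count changes; otherwise the skip is the identity.
    """

    def __init__(self, in_ch: int, out_ch: int, k1: int, k2: int, stride: int, *, rng):
        super().__init__()
        self.cb1 = ConvBlock(in_ch, out_ch, k1, stride=stride, rng=rng)
        self.cb2 = ConvBlock(out_ch, out_ch, k2, stride=1, rng=rng)
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv1d(in_ch, out_ch, 1, stride=stride, rng=rng)
        else:
            self.proj = None

    def __call__(self, x: Tensor) -> Tensor:
        y = self.cb2(self.cb1(x))
        skip = self.proj(x) if self.proj is not None else x
        return y + skip


class _ResidualBlock(Module):
    """Two components: same-length (kernels k[0], k[1]) then stride-2 (k[2], k[3])."""

    def __init__(self, in_ch: int, out_ch: int, kernels: tuple[int, ...], *, rng):
        super().__init__()
        k1, k2, k3, k4 = kernels
        self.comp1 = _ResidualComponent(in_ch, out_ch, k1, k2, stride=1, rng=rng)
        self.comp2 = _ResidualComponent(out_ch, out_ch, k3, k4, stride=2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.comp2(self.comp1(x))


class ArousalDetector(Module):
    """Per-second arousal-probability sequence labeler."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c0 = 4 * config.inception_filters_per_branch
        r = config.residual_channels
        self.inception = _Inception(
            config.n_input_channels,
            config.inception_filters_per_branch,
            config.inception_kernel_sizes,
            rng=rng,
        )
        self.res_blocks = [
            _ResidualBlock(
                c0 if i == 0 else r, r, config.residual_kernel_sizes, rng=rng
            )
            for i in range(config.n_residual_blocks)
        ]
        self.lstms = [
            LSTM(r if i == 0 else config.lstm_hidden, config.lstm_hidden, rng=rng)
            for i in range(config.lstm_layers)
        ]
        self.head = Linear(config.lstm_hidden, 1, rng=rng)

    # -- forward -------------------------------------------------------------
    def forward(
        self, x: Tensor, state: list[tuple[Tensor, Tensor]] | None = None
    ) -> tuple[Tensor, list[tuple[Tensor, Tensor]]]:
        """Map (N, C, 4T) input to (N, T) logits; carries LSTM state.

        ``state`` is a list of per-layer (h, c) tuples, used for truncated
        backpropagation through time; pass None to start from zeros.
        """
        if x.shape[1] != self.config.n_input_channels:
            raise ValueError(
                f"expected {self.config.n_input_channels} input channels, "
                f"got {x.shape[1]}"
            )
        if x.shape[2] % 4 != 0:
            raise ValueError("input length must be a multiple of 4 samples")
        h = self.inception(x)
        for block in self.res_blocks:
            h = block(h)
        h = h.transpose(0, 2, 1)  # (N, T, C)
        new_state = []
        for i, lstm in enumerate(self.lstms):
            h, st = lstm(h, None if state is None else state[i])
            new_state.append(st)
        logits = self.head(h)  # (N, T, 1)
        n, t = logits.shape[0], logits.shape[1]
        return logits.reshape(n, t), new_state

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Arousal probabilities, one per second of a (C, L) 4 Hz input.

        Inputs whose length is not a multiple of 4 are edge-padded to the
        next full second; output length is ``ceil(L / 4)``.
        """
        x = np.asarray(inputs, dtype=float)
        if x.ndim != 2:
            raise ValueError("predict expects a (channels, samples) array")
        pad = (-x.shape[1]) % 4
        if pad:
            x = np.pad(x, ((0, 0), (0, pad)), mode="edge")
        was_training = self.training
        self.eval()
        try:
            logits, _ = self.forward(Tensor(x[None]))
        finally:
            if was_training:
                self.train()
        z = np.clip(logits.data[0], -60, 60)
        return 1.0 / (1.0 + np.exp(-z))

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing --------------------------------------------------------
    def save(self, path):
        from dataclasses import asdict

        cfg = asdict(self.config)
        cfg["inception_kernel_sizes"] = list(cfg["inception_kernel_sizes"])
        cfg["residual_kernel_sizes"] = list(cfg["residual_kernel_sizes"])
        np.savez(
            path,
            __format_version=CHECKPOINT_FORMAT_VERSION,
            __config=np.array(repr(cfg)),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "ArousalDetector":
        import ast

        with np.load(path) as data:
            cfg = ast.literal_eval(str(data["__config"]))
            cfg["inception_kernel_sizes"] = tuple(cfg["inception_kernel_sizes"])
            cfg["residual_kernel_sizes"] = tuple(cfg["residual_kernel_sizes"])
            model = cls(ModelConfig(**cfg))
            state = {
                k: data[k]
                for k in data.files
                if k not in ("__format_version", "__config")
            }
            model.load_state_dict(state)
        return model


def build_model(config: ModelConfig) -> ArousalDetector:
    """Construct a seeded detector from ``config``."""
    return ArousalDetector(config)
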