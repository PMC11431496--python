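"""Training recipe for the arousal detector.

Per-second binary cross-entropy, truncated backpropagation through time
(segments of 90 output seconds = 360 input samples, LSTM state carried
across segments within a record and reset between records), Adam with
weight decay, plateau-driven learning-rate reduction, and selection of
the epoch with the best validation AUPRC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score

from .model import ArousalDetector
from .nn.autodiff import Tensor, bce_with_logits
from .preprocess import PreprocessedRecord

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "Adam",
    "PlateauScheduler",
    "train",
    "evaluate_epoch",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the training recipe)."""

    batch_size: int = 30
    tbptt_depth: int = 90  # output steps per truncated segment
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 1e-5
    lr_init: float = 1e-4
    lr_factor: float = 0.1
    lr_patience: int = 4
    max_epochs: int = 30
    mask_wake_in_loss: bool = False
    seed: int = 0


@dataclass
class TrainingHistory:
    """Per-epoch trace of the run."""

    train_loss: list[float] = field(default_factory=list)
    val_auprc: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """Index of the epoch with maximal validation AUPRC."""
        return int(np.argmax(self.val_auprc))


class Adam:
    """Adam with decoupled-style L2 weight decay added to the gradient."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, weight_decay=0.0, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = beta1, beta2
        self.weight_decay = weight_decay
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class PlateauScheduler:
    """Reduce the learning rate by ``factor`` after ``patience`` epochs
    without improvement of the monitored score (maximized)."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 4):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.best = -np.inf
        self.stale = 0

    def step(self, score: float):
        if score > self.best:
            self.best = score
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.optimizer.lr *= self.factor
                self.stale = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr


def _segment_record(
    rec: PreprocessedRecord, channel_names: list[str], depth: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inputs (C, 4T), labels (T,), loss mask (T,) for one record."""
    x = rec.input_matrix(channel_names)
    t = rec.n_seconds
    x = x[:, : 4 * t]
    y = rec.labels_1hz.astype(float)
    mask = np.ones(t)
    return x, y, mask


def evaluate_epoch(
    model: ArousalDetector,
    val_records: list[PreprocessedRecord],
    channel_names: list[str],
) -> float:
    """AUPRC over concatenated per-second predictions, sleep seconds only.

    Raises ``ValueError`` when the validation sleep seconds contain no
    positive labels (the area under precision–recall is undefined then).
    """
    probs, labels = [], []
    for rec in val_records:
        p = model.predict(rec.input_matrix(channel_names))
        keep = rec.sleep_mask_1hz.astype(bool)
        probs.append(p[keep])
        labels.append(rec.labels_1hz[keep])
    y = np.concatenate(labels)
    p = np.concatenate(probs)
    if y.sum() == 0:
        raise ValueError("validation set has no positive sleep seconds; AUPRC undefined")
    return float(average_precision_score(y, p))


def train(
    model: ArousalDetector,
    train_records: list[PreprocessedRecord],
    val_records: list[PreprocessedRecord],
    config: TrainConfig,
    channel_names: list[str] | None = None,
    log_fn=None,
) -> tuple[ArousalDetector, TrainingHistory]:
    """Train ``model`` and return it loaded with the best-validation weights.

    Records are grouped into batches of up to ``batch_size`` sequences;
    each batch advances through its records in lockstep segments of
    ``tbptt_depth`` output seconds, carrying LSTM state between segments
    (detached, so gradients stop at segment boundaries) and resetting it
    between batches.  Records shorter than the longest in their batch are
    masked out of the loss beyond their end.
    """
    if not train_records:
        raise ValueError("empty training set")
    if channel_names is None:
        channel_names = sorted(train_records[0].channels)
    rng = np.random.default_rng(config.seed)

    opt = Adam(
        model.parameters(),
        lr=config.lr_init,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
        weight_decay=config.weight_decay,
    )
    sched = PlateauScheduler(opt, factor=config.lr_factor, patience=config.lr_patience)
    history = TrainingHistory()
    best_state = None
    best_auprc = -np.inf

    prepared = [
        _segment_record(r, channel_names, config.tbptt_depth) for r in train_records
    ]
    depth = config.tbptt_depth

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(prepared))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            xs = [prepared[i] for i in batch_idx]
            t_max = max(x[1].shape[0] for x in xs)
            n = len(xs)
            c = len(channel_names)
            x_pad = np.zeros((n, c, 4 * t_max))
            y_pad = np.zeros((n, t_max))
            m_pad = np.zeros((n, t_max))
            for j, (x, y, m) in enumerate(xs):
                t = y.shape[0]
                x_pad[j, :, : 4 * t] = x
                y_pad[j, : t] = y
                m_pad[j, : t] = m
            if config.mask_wake_in_loss:
                for j, i in enumerate(batch_idx):
                    t = prepared[i][1].shape[0]
                    m_pad[j, :t] *= train_records[i].sleep_mask_1hz[:t]

            state = None
            for seg0 in range(0, t_max, depth):
                seg1 = min(seg0 + depth, t_max)
                m_seg = m_pad[:, seg0:seg1]
                if m_seg.sum() == 0:
                    break
                xb = Tensor(x_pad[:, :, 4 * seg0 : 4 * seg1])
                logits, state = model.forward(xb, state)
                state = [(h.detach(), cc.detach()) for h, cc in state]
                loss = bce_with_logits(logits, y_pad[:, seg0:seg1], m_seg)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))

        auprc = evaluate_epoch(model, val_records, channel_names)
        history.train_loss.append(float(np.mean(losses)))
        history.val_auprc.append(auprc)
        history.learning_rate.append(opt.lr)
        if log_fn is not None:
            log_fn(
                {
                    "epoch": epoch,
                    "train_loss": history.train_loss[-1],
                    "val_auprc": auprc,
                    "lr": opt.lr,
                }
            )
        if auprc > best_auprc:
            best_auprc = auprc
            best_state = model.state_dict()
        sched.step(auprc)

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history
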