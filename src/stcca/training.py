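"""Optimisation protocol: cross-entropy, Adam, step learning-rate decay.

Training follows the standard recipe for this architecture family:
shuffled mini-batches, Adam with default moments, and a step schedule
that halves the learning rate every 50 epochs over a 200-epoch run.
Everything is reproducible from the ``TrainConfig.seed``: weight
initialisation, batch shuffling and dropout noise all derive from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from . import nn
from .data import EEGTrialSet
from .model import ModelConfig, STCCANetwork


@dataclass
class TrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    lr_step: int = 50
    lr_gamma: float = 0.5
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("TrainConfig.epochs must be >= 1")
        if not 0 < self.lr_gamma <= 1:
            raise ValueError("TrainConfig.lr_gamma must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("TrainConfig.batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("TrainConfig.learning_rate must be positive")


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss, training accuracy and learning rate."""

    loss: list = field(default_factory=list)
    accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)


def cross_entropy_loss(logits, labels):
    """Mean −log softmax-probability of the true (1-based) class."""
    labels = np.asarray(labels)
    if labels.min() < 1:
        raise ValueError("labels must be 1-based class indices")
    return ag.cross_entropy(
        logits if isinstance(logits, ag.Tensor) else ag.Tensor(logits),
        labels - 1)


def build_model(config: ModelConfig, seed: int = 0) -> STCCANetwork:
    """Assemble the network for the requested variant and fusion strategy."""
    return STCCANetwork(config, seed=seed)


def train_model(model: STCCANetwork, train: EEGTrialSet,
                tc: TrainConfig) -> tuple[STCCANetwork, TrainingHistory]:
    """Seeded mini-batch optimisation of the cross-entropy objective."""
    if train.n_trials == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(np.random.SeedSequence([tc.seed, 7]))
    model.reseed_dropout(tc.seed)
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    history = TrainingHistory()
    n = train.n_trials
    labels0 = train.labels - 1

    for epoch in range(tc.epochs):
        lr = nn.step_lr(tc.learning_rate, epoch, tc.lr_step, tc.lr_gamma)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        total_loss, total_correct = 0.0, 0
        dtype = model.dtype
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            x = train.data[idx].astype(dtype, copy=False)
            y = labels0[idx]
            logits = model(x)
            loss = ag.cross_entropy(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * len(idx)
            total_correct += int((np.argmax(logits.data, axis=1) == y).sum())
        history.loss.append(total_loss / n)
        history.accuracy.append(total_correct / n)
        history.learning_rate.append(lr)
    model.eval()
    return model, history
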