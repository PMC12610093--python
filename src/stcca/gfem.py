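"""Global feature extraction and classification.

Multi-head self-attention over the fused sequence captures long-range
dependencies the convolutional receptive fields miss: the k-wide feature
axis is split into h heads of width k/h, scaled dot-product attention is
applied per head, the head outputs are concatenated and passed through
an output projection.  The classifier head flattens the 512 × k global
sequence and applies dropout → affine → ELU → dropout → affine to m
logits; the predicted label is the argmax (lowest index on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from . import nn
from ._autograd import Tensor
from .attention import scaled_dot_product_attention
from .lfem import SEQ_LEN, FeatureSequence


@dataclass
class GfemParams:
    """Head count, classifier width and regularisation of the global stage."""

    k: int = 32
    h: int = 4
    fc_hidden: int = 256
    n_classes: int = 4
    dropout: float = 0.3

    def __post_init__(self):
        if self.h < 1 or self.k % self.h != 0:
            raise ValueError(
                f"feature width k={self.k} must be divisible by head count h={self.h}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")


class MultiHeadSelfAttention(nn.Module):
    """h-head self-attention with per-head width k/h and output projection."""

    def __init__(self, p: GfemParams, rng):
        super().__init__()
        self.h = p.h
        self.head_width = p.k // p.h
        self.query = nn.Linear(p.k, p.k, rng)
        self.key = nn.Linear(p.k, p.k, rng)
        self.value = nn.Linear(p.k, p.k, rng)
        self.out = nn.Linear(p.k, p.k, rng)

    def __call__(self, f: FeatureSequence) -> FeatureSequence:
        if f.role != "fused":
            raise ValueError(f"expected a fused sequence, got role {f.role!r}")
        x = f.values
        batched = x.ndim == 3
        if not batched:
            x = ag.reshape(x, (1, *x.shape))
        B, L, k = x.shape
        dh = self.head_width

        def split(t):  # (B, L, k) -> (B, h, L, k/h)
            return ag.transpose(ag.reshape(t, (B, L, self.h, dh)), (0, 2, 1, 3))

        heads = scaled_dot_product_attention(
            split(self.query(x)), split(self.key(x)), split(self.value(x)), dh)
        merged = ag.reshape(ag.transpose(heads, (0, 2, 1, 3)), (B, L, k))
        y = self.out(merged)
        if not batched:
            y = ag.reshape(y, (L, k))
        return FeatureSequence(y, "global")


class ClassifierHead(nn.Module):
    """Flatten → dropout → affine → ELU → dropout → affine to m logits."""

    def __init__(self, p: GfemParams, rng, seq_len: int = SEQ_LEN):
        super().__init__()
        self.drop1 = nn.Dropout(p.dropout, rng)
        self.fc1 = nn.Linear(seq_len * p.k, p.fc_hidden, rng)
        self.drop2 = nn.Dropout(p.dropout, rng)
        self.fc2 = nn.Linear(p.fc_hidden, p.n_classes, rng)

    def __call__(self, f: FeatureSequence) -> Tensor:
        x = f.values
        batched = x.ndim == 3
        B = x.shape[0] if batched else 1
        flat = ag.reshape(x, (B, -1))
        return self.fc2(self.drop2(ag.elu(self.fc1(self.drop1(flat)))))


def classify(fg: FeatureSequence, head: ClassifierHead):
    """Logits and 1-based argmax labels (lowest index wins ties)."""
    logits = head(fg)
    labels = np.argmax(logits.data, axis=-1) + 1
    return logits, labels
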