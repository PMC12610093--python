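"""Local feature extraction: two convolutional pathways over each trial.

The temporal-first pathway convolves along time with a (1, ⌊fs/10⌋)
kernel and then across electrodes with a (⌊ch/2⌋, 1) kernel; the
spatial-first pathway applies the same two kernels in the opposite
order.  Each pathway is Conv→Conv→BatchNorm→ELU→AvgPool(4,4) with
valid convolutions, stride 1 and bias-free convs (the batch-norm absorbs
any bias).  The pooled k×H×W map is flattened position-wise and
area-resampled to a fixed 512-position feature sequence so downstream
attention sees the same shape for every montage and trial length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from . import nn
from ._autograd import Tensor

SEQ_LEN = 512

#: roles a feature sequence can play inside the network
ROLES = ("temporal", "spatial", "fused", "global")


@dataclass
class FeatureSequence:
    """A (batch ×) positions × features tensor with its pipeline role."""

    values: Tensor
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not np.isfinite(self.values.data).all():
            raise ValueError("feature sequence contains non-finite entries")

    @property
    def shape(self):
        return self.values.shape


def kernel_dims(ch: int, fs: float):
    """Temporal (1, ⌊fs/10⌋) and spatial (⌊ch/2⌋, 1) kernel sizes."""
    if ch < 2:
        raise ValueError(f"need at least 2 channels, got {ch}")
    if fs < 10:
        raise ValueError(f"need sampling rate >= 10 Hz, got {fs}")
    return (1, int(fs) // 10), (int(ch) // 2, 1)


def conv_output_shape(ch, t, fs, pool=(4, 4)):
    """(H, W) of the pooled feature map; raises if any stage collapses."""
    (_, kt), (kc, _) = kernel_dims(ch, fs)
    h, w = ch - kc + 1, t - kt + 1
    if h < 1 or w < 1:
        raise ValueError(
            f"convolution collapses the trial: {ch}x{t} with kernels "
            f"(1,{kt}) and ({kc},1)"
        )
    # a pooling window larger than the map shrinks to the map size
    ph, pw = h // min(pool[0], h), w // min(pool[1], w)
    return ph, pw


def to_sequence(featmap: Tensor, seq_len: int = SEQ_LEN,
                resample: np.ndarray | None = None) -> Tensor:
    """Flatten a (B, k, H, W) map to H·W positions × k features and
    area-resample the position axis to exactly ``seq_len``.

    The resampling is parameter-free and preserves the mean over
    positions exactly; when H·W == seq_len it is a pure rearrangement.
    """
    B, k, H, W = featmap.shape
    seq = ag.transpose(ag.reshape(featmap, (B, k, H * W)), (0, 2, 1))
    if H * W == seq_len:
        return seq
    if resample is None:
        resample = nn.resample_matrix(H * W, seq_len)
    return ag.matmul(Tensor(resample.astype(featmap.data.dtype, copy=False)), seq)


class _Pathway(nn.Module):
    """Conv→Conv→BN→ELU→AvgPool(4,4), then mapping to a 512 × k sequence."""

    def __init__(self, ch, t, fs, k, rng, order):
        super().__init__()
        temporal_k, spatial_k = kernel_dims(ch, fs)
        first, second = ((temporal_k, spatial_k) if order == "temporal"
                         else (spatial_k, temporal_k))
        self.role = order
        self.conv1 = nn.Conv2d(1, k, first, rng)
        self.conv2 = nn.Conv2d(k, k, second, rng)
        self.bn = nn.BatchNorm2d(k)
        h, w = conv_output_shape(ch, t, fs)
        conv_h = ch - spatial_k[0] + 1
        conv_w = t - temporal_k[1] + 1
        self._pool = (min(4, conv_h), min(4, conv_w))
        self._resample = (None if h * w == SEQ_LEN
                          else nn.resample_matrix(h * w, SEQ_LEN))

    def __call__(self, x: Tensor) -> FeatureSequence:
        B, ch, t = x.shape
        z = ag.reshape(x, (B, 1, ch, t))
        z = self.conv1(z)
        z = self.conv2(z)
        z = self.bn(z)
        z = ag.elu(z)
        z = ag.avg_pool2d(z, self._pool)
        return FeatureSequence(to_sequence(z, SEQ_LEN, self._resample), self.role)


class TemporalPathway(_Pathway):
    """Temporal-then-spatial convolution producing ft."""

    def __init__(self, ch, t, fs, k, rng):
        super().__init__(ch, t, fs, k, rng, "temporal")


class SpatialPathway(_Pathway):
    """Spatial-then-temporal convolution producing fs."""

    def __init__(self, ch, t, fs, k, rng):
        super().__init__(ch, t, fs, k, rng, "spatial")
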