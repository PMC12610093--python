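"""Coupled cross-attention fusion of the temporal and spatial streams.

Scaled dot-product attention is applied in both directions between the
two local feature sequences — the temporal stream queries the spatial
one (fts) and vice versa (fst) — and the two results are combined with
learnable unconstrained scalar weights followed by layer normalisation:

    ffusion = LN(α·fts + β·fst)

Each direction has its own query/key/value projections (affine, k → k).
No positional encoding is used anywhere, so attention is invariant to
permutations of the key/value positions.  The standard fusion baselines
(summation, concatenation + re-projection, softmax-gated convex
combination) live here too for ablation runs.
"""

from __future__ import annotations

import math

import numpy as np

from . import _autograd as ag
from . import nn
from ._autograd import Tensor
from .lfem import FeatureSequence

FUSION_STRATEGIES = ("cca", "sum", "cat", "atten")


def scaled_dot_product_attention(Q, K, V, dk: int) -> Tensor:
    """softmax(Q·Kᵀ/√dk)·V with row-stochastic weights.

    Accepts arrays or tensors of shape (..., positions, features).
    """
    Q, K, V = (t if isinstance(t, Tensor) else Tensor(t) for t in (Q, K, V))
    if dk <= 0:
        raise ValueError(f"dk must be positive, got {dk}")
    for name, t in (("Q", Q), ("K", K), ("V", V)):
        if not np.isfinite(t.data).all():
            raise ValueError(f"{name} contains non-finite entries")
    if Q.shape[-1] != K.shape[-1] or K.shape[-2] != V.shape[-2]:
        raise ValueError("Q/K feature widths and K/V lengths must match")
    return ag.attention(Q, K, V, dk)


def attention_weights(Q, K, dk: int) -> np.ndarray:
    """The row-stochastic attention weight matrix (no gradient)."""
    Q = Q.data if isinstance(Q, Tensor) else np.asarray(Q, dtype=float)
    K = K.data if isinstance(K, Tensor) else np.asarray(K, dtype=float)
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(dk)
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _swap_last(ndim):
    axes = list(range(ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return axes


class AttentionProjections(nn.Module):
    """Affine query/key/value maps (k → k) for one attention direction."""

    def __init__(self, k, rng):
        super().__init__()
        self.query_map = nn.Linear(k, k, rng)
        self.key_map = nn.Linear(k, k, rng)
        self.value_map = nn.Linear(k, k, rng)
        self.dk = k


def cross_attention_ts(ft: FeatureSequence, fs: FeatureSequence,
                       proj: AttentionProjections) -> FeatureSequence:
    """Temporal stream queries the spatial stream: fts = Atten(ft, fs, fs)."""
    if ft.role != "temporal" or fs.role != "spatial":
        raise ValueError(f"expected (temporal, spatial) roles, got "
                         f"({ft.role}, {fs.role})")
    out = scaled_dot_product_attention(
        proj.query_map(ft.values), proj.key_map(fs.values),
        proj.value_map(fs.values), proj.dk)
    return FeatureSequence(out, "temporal")


def cross_attention_st(fs: FeatureSequence, ft: FeatureSequence,
                       proj: AttentionProjections) -> FeatureSequence:
    """Spatial stream queries the temporal stream: fst = Atten(fs, ft, ft)."""
    if fs.role != "spatial" or ft.role != "temporal":
        raise ValueError(f"expected (spatial, temporal) roles, got "
                         f"({fs.role}, {ft.role})")
    out = scaled_dot_product_attention(
        proj.query_map(fs.values), proj.key_map(ft.values),
        proj.value_map(ft.values), proj.dk)
    return FeatureSequence(out, "spatial")


class FusionWeights(nn.Module):
    """Learnable scalar stream weights α, β plus the fusion layer norm."""

    def __init__(self, k, alpha=1.0, beta=1.0):
        super().__init__()
        self.alpha = nn.Parameter(np.asarray(alpha, dtype=float))
        self.beta = nn.Parameter(np.asarray(beta, dtype=float))
        self.layer_norm = nn.LayerNorm(k)


def fuse(fts: FeatureSequence, fst: FeatureSequence,
         w: FusionWeights) -> FeatureSequence:
    """ffusion = LN(α·fts + β·fst), normalised over the feature axis."""
    if fts.shape != fst.shape:
        raise ValueError(f"shape mismatch: {fts.shape} vs {fst.shape}")
    mixed = ag.add(ag.mul(fts.values, w.alpha), ag.mul(fst.values, w.beta))
    return FeatureSequence(w.layer_norm(mixed), "fused")


class CoupledCrossAttention(nn.Module):
    """Bidirectional cross-attention between ft and fs with weighted fusion."""

    def __init__(self, k, rng):
        super().__init__()
        self.proj_ts = AttentionProjections(k, rng)
        self.proj_st = AttentionProjections(k, rng)
        self.weights = FusionWeights(k)

    def __call__(self, ft: FeatureSequence, fs: FeatureSequence) -> FeatureSequence:
        fts = cross_attention_ts(ft, fs, self.proj_ts)
        fst = cross_attention_st(fs, ft, self.proj_st)
        return fuse(fts, fst, self.weights)


class SumFusion(nn.Module):
    """Baseline: elementwise sum of the two streams."""

    def __init__(self, k, rng):
        super().__init__()

    def __call__(self, ft, fs):
        return FeatureSequence(ag.add(ft.values, fs.values), "fused")


class CatFusion(nn.Module):
    """Baseline: feature-axis concatenation, re-projected 2k → k so the
    downstream global module is unchanged across ablations."""

    def __init__(self, k, rng):
        super().__init__()
        self.reproject = nn.Linear(2 * k, k, rng)

    def __call__(self, ft, fs):
        cat = ag.concat([ft.values, fs.values], axis=-1)
        return FeatureSequence(self.reproject(cat), "fused")


class AttenFusion(nn.Module):
    """Baseline: softmax-normalised scalar gates from a linear projection
    of the pooled pair, applied as a convex combination of the streams."""

    def __init__(self, k, rng):
        super().__init__()
        self.gate = nn.Linear(2 * k, 2, rng)

    def __call__(self, ft, fs):
        pooled = ag.concat([ag.mean(ft.values, axis=-2),
                            ag.mean(fs.values, axis=-2)], axis=-1)
        w = ag.softmax(self.gate(pooled), axis=-1)  # (..., 2)
        wt = ag.reshape(w, (*w.shape[:-1], 1, 1, 2))
        stack = ag.concat([
            ag.reshape(ft.values, (*ft.values.shape, 1)),
            ag.reshape(fs.values, (*fs.values.shape, 1)),
        ], axis=-1)
        return FeatureSequence(
            ag.mean(ag.mul(stack, ag.scale(wt, 2.0)), axis=-1), "fused")


def make_fusion(strategy: str, k, rng) -> nn.Module:
    """Fusion module by name: cca (the coupled mechanism) or a baseline."""
    table = {"cca": CoupledCrossAttention, "sum": SumFusion,
             "cat": CatFusion, "atten": AttenFusion}
    if strategy not in table:
        raise ValueError(f"unknown fusion strategy {strategy!r}; "
                         f"valid options: {', '.join(FUSION_STRATEGIES)}")
    return table[strategy](k, rng)


def fusion_baseline(ft: FeatureSequence, fs: FeatureSequence,
                    strategy: str, module: nn.Module | None = None,
                    rng=None) -> FeatureSequence:
    """Apply a named baseline fusion; builds a fresh module if none given."""
    if module is None:
        if strategy == "cca":
            raise ValueError("cca is the coupled mechanism, not a baseline")
        module = make_fusion(strategy, ft.shape[-1],
                             rng if rng is not None else np.random.default_rng(0))
    return module(ft, fs)
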