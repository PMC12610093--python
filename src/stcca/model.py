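"""Model assembly and the fit/results user API.

:class:`STCCANetwork` wires the pipeline stages in order — local
convolutional pathways, coupled cross-attention fusion, multi-head
self-attention, classifier — and supports the two ablation variants
(``no_lfem``: the raw trial is mapped into the two 512 × k streams by
fixed area pooling plus a learned width projection; ``no_gfem``: the
fused sequence goes straight to the classifier) and the four fusion
strategies.

:class:`STCCAModel` is the statsmodels-style entry point: construct it
from an :class:`~stcca.data.EEGTrialSet` (plus configuration overrides),
call :meth:`~STCCAModel.fit`, and work with the returned
:class:`STCCAResults` (predictions, training history, summary table,
checkpointing).
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _autograd as ag
from . import nn
from ._autograd import Tensor
from .attention import FUSION_STRATEGIES, make_fusion
from .data import EEGTrialSet
from .gfem import ClassifierHead, GfemParams, MultiHeadSelfAttention
from .lfem import SEQ_LEN, FeatureSequence, SpatialPathway, TemporalPathway

VARIANTS = ("full", "no_lfem", "no_gfem")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    k is the feature width of every convolution and attention stage
    (default 32), h the self-attention head count (default 4); the
    fixed internal sequence length is 512 positions.
    """

    n_classes: int
    channels: int
    timepoints: int
    sampling_rate: float
    k: int = 32
    h: int = 4
    seq_len: int = SEQ_LEN
    fusion: str = "cca"
    variant: str = "full"
    fc_hidden: int = 256
    dropout: float = 0.3

    def __post_init__(self):
        for name in ("n_classes", "channels", "timepoints", "k", "h",
                     "fc_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"ModelConfig.{name} must be positive")
        if self.n_classes < 2:
            raise ValueError("ModelConfig.n_classes must be >= 2")
        if self.k % self.h != 0:
            raise ValueError(f"k={self.k} must be divisible by h={self.h}")
        if self.fusion not in FUSION_STRATEGIES:
            raise ValueError(f"unknown fusion {self.fusion!r}; "
                             f"valid: {', '.join(FUSION_STRATEGIES)}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"valid: {', '.join(VARIANTS)}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


class RawStreams(nn.Module):
    """no_lfem stand-in: fixed pooling of the raw trial to 512 positions
    plus a learned 1 → k width projection per stream.  The temporal
    stream flattens time-major, the spatial stream channel-major, so the
    two streams present the trial in complementary orders while leaving
    the fusion stage's input contract untouched."""

    def __init__(self, ch, t, k, rng):
        super().__init__()
        self._R = nn.resample_matrix(ch * t, SEQ_LEN)
        self.proj_t = nn.Linear(1, k, rng)
        self.proj_s = nn.Linear(1, k, rng)

    def __call__(self, x: Tensor):
        B, ch, t = x.shape
        time_major = ag.reshape(ag.transpose(x, (0, 2, 1)), (B, ch * t, 1))
        chan_major = ag.reshape(x, (B, ch * t, 1))
        R = Tensor(self._R.astype(x.data.dtype, copy=False))
        ft = FeatureSequence(self.proj_t(ag.matmul(R, time_major)), "temporal")
        fs = FeatureSequence(self.proj_s(ag.matmul(R, chan_major)), "spatial")
        return ft, fs


class STCCANetwork(nn.Module):
    """The assembled network: LFEM → fusion → GFEM → classifier."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2024]))
        ch, t, fs_hz, k = (config.channels, config.timepoints,
                           config.sampling_rate, config.k)
        if config.variant == "no_lfem":
            self.streams = RawStreams(ch, t, k, rng)
        else:
            self.temporal = TemporalPathway(ch, t, fs_hz, k, rng)
            self.spatial = SpatialPathway(ch, t, fs_hz, k, rng)
        self.fusion = make_fusion(config.fusion, k, rng)
        gp = GfemParams(k=k, h=config.h, fc_hidden=config.fc_hidden,
                        n_classes=config.n_classes, dropout=config.dropout)
        if config.variant != "no_gfem":
            self.mha = MultiHeadSelfAttention(gp, rng)
        self.head = ClassifierHead(gp, rng, seq_len=config.seq_len)
        # dropout noise comes from its own stream, reseedable per run
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = self._dropout_rng

    def reseed_dropout(self, seed: int):
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
        for m in self.modules():
            if isinstance(m, nn.Dropout):
                m.rng = self._dropout_rng

    @property
    def dtype(self):
        """The parameter dtype (set at construction from nn.default_dtype)."""
        return self.head.fc1.weight.data.dtype

    def __call__(self, x) -> Tensor:
        """Logits for a (B, channels, timepoints) batch (or one trial)."""
        arr = x if isinstance(x, Tensor) else Tensor(
            np.asarray(x).astype(self.dtype, copy=False))
        if arr.ndim == 2:
            arr = ag.reshape(arr, (1, *arr.shape))
        if self.config.variant == "no_lfem":
            ft, fs = self.streams(arr)
        else:
            ft = self.temporal(arr)
            fs = self.spatial(arr)
        fused = self.fusion(ft, fs)
        if self.config.variant != "no_gfem":
            fused = self.mha(fused)
        return self.head(fused)

    def predict(self, x) -> np.ndarray:
        """1-based predicted labels (evaluation mode, deterministic)."""
        was_training = self.training
        self.eval()
        logits = self(x).data
        self.train(was_training)
        return np.argmax(logits, axis=-1) + 1


class STCCAModel:
    """A network specification bound to a trial set, statsmodels-style.

    >>> model = STCCAModel(trialset, k=16)
    >>> res = model.fit(epochs=30, seed=1)
    >>> res.summary()
    """

    def __init__(self, trialset: EEGTrialSet, config: ModelConfig = None,
                 **overrides):
        self.trialset = trialset
        if config is None:
            config = ModelConfig(
                n_classes=int(trialset.labels.max()),
                channels=trialset.n_channels,
                timepoints=trialset.n_timepoints,
                sampling_rate=trialset.sampling_rate,
                **overrides,
            )
        elif overrides:
            config = ModelConfig(**{**asdict(config), **overrides})
        self.config = config

    def fit(self, train_config=None, **overrides) -> "STCCAResults":
        from .training import TrainConfig, train_model

        if train_config is None:
            train_config = TrainConfig(**overrides)
        elif overrides:
            train_config = TrainConfig(**{**asdict(train_config), **overrides})
        network = STCCANetwork(self.config, seed=train_config.seed)
        network, history = train_model(network, self.trialset, train_config)
        return STCCAResults(self, network, history, train_config)


class STCCAResults:
    """Fitted network plus its training history and diagnostics."""

    def __init__(self, model: STCCAModel, network: STCCANetwork, history,
                 train_config):
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config

    def predict(self, ts_or_array) -> np.ndarray:
        x = ts_or_array.data if isinstance(ts_or_array, EEGTrialSet) else ts_or_array
        return self.network.predict(x)

    def predict_logits(self, ts_or_array) -> np.ndarray:
        x = ts_or_array.data if isinstance(ts_or_array, EEGTrialSet) else ts_or_array
        was_training = self.network.training
        self.network.eval()
        logits = self.network(x).data
        self.network.train(was_training)
        return logits

    def score(self, ts: EEGTrialSet) -> float:
        """Accuracy on a labelled trial set, as a fraction."""
        return float(np.mean(self.predict(ts) == ts.labels))

    @property
    def n_parameters(self):
        return self.network.num_parameters()

    def summary(self) -> str:
        cfg = self.model.config
        h = self.history
        buf = io.StringIO()
        w = buf.write
        w("        Spatial-Temporal Coupled Cross-Attention Classifier\n")
        w("=" * 68 + "\n")
        rows = [
            ("Variant / fusion", f"{cfg.variant} / {cfg.fusion}"),
            ("Classes (m)", cfg.n_classes),
            ("Input (channels x time)", f"{cfg.channels} x {cfg.timepoints}"),
            ("Feature width k / heads h", f"{cfg.k} / {cfg.h}"),
            ("Sequence length", cfg.seq_len),
            ("Learnable parameters", f"{self.n_parameters:,}"),
            ("Epochs trained", len(h.loss)),
            ("Final training loss", f"{h.loss[-1]:.4f}"),
            ("Final training accuracy", f"{100 * h.accuracy[-1]:.2f}%"),
            ("Final learning rate", f"{h.learning_rate[-1]:.2e}"),
        ]
        for name, val in rows:
            w(f"{name:<32s}{val}\n")
        w("=" * 68 + "\n")
        return buf.getvalue()

    def save(self, path):
        """Single-file checkpoint: config + weights + running statistics."""
        state = self.network.state_dict()
        meta = json.dumps({"config": asdict(self.model.config),
                           "train_config": asdict(self.train_config),
                           "seed": self.network.seed})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @staticmethod
    def load(path, trialset: EEGTrialSet):
        from .training import TrainConfig, TrainingHistory

        with np.load(path) as f:
            meta = json.loads(bytes(f["__meta__"]).decode())
            state = {k: f[k] for k in f.files if k != "__meta__"}
        config = ModelConfig(**meta["config"])
        model = STCCAModel(trialset, config)
        network = STCCANetwork(config, seed=meta["seed"])
        network.load_state_dict(state)
        return STCCAResults(model, network, TrainingHistory([], [], []),
                            TrainConfig(**meta["train_config"]))
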