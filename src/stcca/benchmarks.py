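"""Synthetic benchmark protocols for the full pipeline.

These are the package's reference experiments on the synthetic
class-conditioned generator: a class-recovery run on highly separable
data (four classes, 50 trials each, SNR 10, fully coupled
spatio-temporal structure), its permuted-label chance control, the
fusion-strategy comparison (coupled cross-attention vs. summation), and
an exhaustive variant × fusion smoke grid.  Training is scaled down
relative to a full 200-epoch protocol — the feature width is halved to
k = 16 and runs last roughly a dozen epochs, which is past convergence
on this benchmark — so the whole suite runs on a laptop CPU.
"""

from __future__ import annotations

import numpy as np

from .data import permute_labels
from .evaluation import MetricsReport, cross_validate, stratified_kfold
from .model import ModelConfig
from .preprocessing import PreprocessConfig, apply_chain
from .synthetic import SynthConfig, generate_trialset
from .training import TrainConfig

#: benchmark signal conditions: four-class, 8-channel, 1 s at 256 Hz,
#: SNR 10, fully coupled class structure
BENCH_SYNTH = dict(n_classes=4, n_channels=8, n_timepoints=256,
                   sampling_rate=256.0, snr=10.0, coupling=1.0)
#: reduced network width for desk-scale runs
BENCH_K = 16


def _prepare(seed, trials_per_class, permute_seed=None):
    ts = generate_trialset(SynthConfig(trials_per_class=trials_per_class,
                                       seed=seed, **BENCH_SYNTH))
    if permute_seed is not None:
        ts = permute_labels(ts, permute_seed)
    return apply_chain(ts, PreprocessConfig())


def _model_config(clean, fusion="cca", variant="full"):
    return ModelConfig(n_classes=4, channels=clean.n_channels,
                       timepoints=clean.n_timepoints,
                       sampling_rate=clean.sampling_rate,
                       k=BENCH_K, h=4, fusion=fusion, variant=variant)


def recovery_benchmark(seed: int = 1, epochs: int = 12,
                       permuted: bool = False,
                       robustness_fractions=(0.05, 0.10)) -> MetricsReport:
    """Five-fold class recovery on the separable benchmark (200 trials).

    With intact labels the network should recover the four classes
    nearly perfectly; with ``permuted=True`` labels are shuffled first
    and held-out accuracy must sit at the 25% chance level.
    """
    clean = _prepare(seed, trials_per_class=50,
                     permute_seed=seed + 1 if permuted else None)
    plan = stratified_kfold(clean.labels, 5, seed=seed)
    tc = TrainConfig(epochs=epochs, seed=seed)
    return cross_validate(clean, _model_config(clean), tc, plan,
                          robustness_fractions=robustness_fractions,
                          robustness_seed=seed)


def chance_control_benchmark(seed: int = 1, epochs: int = 5) -> MetricsReport:
    """The permuted-label null run (shorter: there is nothing to learn)."""
    return recovery_benchmark(seed=seed, epochs=epochs, permuted=True,
                              robustness_fractions=())


def fusion_margin_benchmark(seeds=(0, 1, 2), epochs: int = 10,
                            trials_per_class: int = 25,
                            strategies=("cca", "sum")) -> dict:
    """Mean two-fold accuracy per fusion strategy, averaged over seeds.

    Mirrors the ablation comparison between the coupled cross-attention
    fusion and the summation baseline on the fully coupled benchmark,
    where only the joint spatio-temporal pattern identifies the class.
    """
    means = {s: [] for s in strategies}
    for seed in seeds:
        clean = _prepare(seed, trials_per_class=trials_per_class)
        plan = stratified_kfold(clean.labels, 2, seed=seed)
        tc = TrainConfig(epochs=epochs, seed=seed)
        for strat in strategies:
            report = cross_validate(clean, _model_config(clean, fusion=strat),
                                    tc, plan)
            means[strat].append(report.mean)
    return {s: float(np.mean(v)) for s, v in means.items()}


def variant_grid_smoke(seed: int = 0, epochs: int = 1,
                       trials_per_class: int = 5,
                       n_timepoints: int = 64) -> dict:
    """Build, briefly train and evaluate every variant × fusion combination.

    Returns {(variant, fusion): held-out accuracy in percent}; raises if
    any combination fails to build or run.
    """
    synth = dict(BENCH_SYNTH)
    synth["n_timepoints"] = n_timepoints
    ts = generate_trialset(SynthConfig(trials_per_class=trials_per_class,
                                       seed=seed, **synth))
    clean = apply_chain(ts, PreprocessConfig())
    plan = stratified_kfold(clean.labels, 2, seed=seed)
    plan.folds = plan.folds[:1]
    tc = TrainConfig(epochs=epochs, seed=seed, batch_size=8)
    results = {}
    for variant in ("full", "no_lfem", "no_gfem"):
        for fusion in ("cca", "sum", "cat", "atten"):
            mc = _model_config(clean, fusion=fusion, variant=variant)
            report = cross_validate(clean, mc, tc, plan)
            results[(variant, fusion)] = report.mean
    return results
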