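"""Evaluation protocol: cross-validation, metrics, significance, robustness.

Subject-wise stratified five-fold cross-validation is the primary
protocol: all trials of a subject are pooled, split into five
class-balanced folds (4:1 train:test), and accuracy is reported as
mean ± standard deviation over folds, with σ using the population
divisor (the fold count).  Leave-one-subject-out (LOSO) splitting probes
cross-subject generalisation.  Per-channel z-score statistics are fitted
inside each training fold only — a leakage guard makes violations loud.

Also here: macro-F1 and confusion matrices, the Wilcoxon signed-rank
test (exact null distribution for n ≤ 25, tie-corrected normal
approximation beyond), channel-dropout robustness, and parameter/FLOP
accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.model_selection import StratifiedKFold

from .data import EEGTrialSet, LeakageError
from .preprocessing import zscore_apply, zscore_fit

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    """Train/test index partition for one cross-validation scheme."""

    folds: list  # list of (train_indices, test_indices)
    scheme: str  # "stratified_kfold" | "loso"
    seed: int | None = None
    fold_names: list | None = None

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


@dataclass
class MetricsReport:
    """Per-fold accuracies (in percent) with aggregate diagnostics."""

    per_fold_accuracy: list
    mean: float
    std: float
    f1: float
    confusion: np.ndarray
    robustness: dict = field(default_factory=dict)
    scheme: str = "stratified_kfold"
    f1_averaging: str = "macro"
    pairing_unit: str = "per-fold accuracies"

    def summary(self) -> str:
        lines = [
            f"Cross-validation scheme: {self.scheme}",
            f"Per-fold accuracy (%): "
            + ", ".join(f"{a:.2f}" for a in self.per_fold_accuracy),
            f"Accuracy: {self.mean:.2f} +/- {self.std:.2f} %",
            f"F1 score ({self.f1_averaging}): {self.f1:.4f}",
            "Confusion matrix (rows = true class):",
        ]
        lines += ["  " + " ".join(f"{int(v):5d}" for v in row)
                  for row in self.confusion]
        for frac, acc in sorted(self.robustness.items()):
            lines.append(f"Accuracy with {100 * frac:.0f}% channels dropped: "
                         f"{acc:.2f} %")
        return "\n".join(lines)


def stratified_kfold(labels, n_folds: int, seed: int) -> FoldPlan:
    """Shuffled, class-stratified k-fold partition (4:1 at k = 5)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    for c, n in zip(classes, counts):
        if n < n_folds:
            raise ValueError(
                f"class {c} has only {n} trials, fewer than {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]
    return FoldPlan(folds=folds, scheme="stratified_kfold", seed=seed)


def loso_split(subject_ids) -> FoldPlan:
    """One fold per subject: that subject's trials are the test set."""
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    idx = np.arange(len(subject_ids))
    folds = [(idx[subject_ids != s], idx[subject_ids == s]) for s in subjects]
    return FoldPlan(folds=folds, scheme="loso",
                    fold_names=[str(s) for s in subjects])


def accuracy_summary(per_fold):
    """Mean and population standard deviation (divisor = fold count)."""
    per_fold = np.asarray(per_fold, dtype=float)
    if per_fold.size == 0:
        raise ValueError("no fold accuracies given")
    mu = per_fold.mean()
    sigma = np.sqrt(np.mean((per_fold - mu) ** 2))
    return float(mu), float(sigma)


def confusion_and_f1(true, pred, m: int):
    """m × m confusion counts (rows = true) and macro-averaged F1.

    Classes absent from both ``true`` and ``pred`` contribute an F1 of 0
    to the macro average, with a warning.
    """
    true = np.asarray(true)
    pred = np.asarray(pred)
    if true.shape != pred.shape:
        raise ValueError(f"length mismatch: {true.shape} vs {pred.shape}")
    labels = np.arange(1, m + 1)
    cm = _sk_confusion(true, pred, labels=labels)
    support = cm.sum(axis=1)
    if (support == 0).any():
        logger.warning("classes with no support contribute F1 = 0: %s",
                       labels[support == 0].tolist())
    f1 = _sk_f1(true, pred, labels=labels, average="macro", zero_division=0)
    return cm, float(f1)


def n_dropout_channels(fraction: float, n_channels: int) -> int:
    """Channels to drop: round-half-even of fraction × ch, at least 1."""
    if fraction >= 1.0:
        raise ValueError("dropout fraction must be < 1")
    if fraction <= 0.0:
        return 0
    return max(1, round(fraction * n_channels))


def channel_dropout_eval(predict_fn, test: EEGTrialSet, fraction: float,
                         seed: int) -> float:
    """Accuracy (fraction) after zero-filling a random channel subset.

    Channels are zeroed rather than removed so the spatial kernel
    geometry fixed at build time stays valid.
    """
    n_drop = n_dropout_channels(fraction, test.n_channels)
    data = test.data.copy()
    if n_drop:
        rng = np.random.default_rng(seed)
        drop = rng.choice(test.n_channels, size=n_drop, replace=False)
        data[:, drop, :] = 0.0
    pred = predict_fn(data)
    return float(np.mean(pred == test.labels))


def _wilcoxon_exact_sf_cdf(ranks2, w2):
    """P(W ≤ w) and P(W ≥ w) for the sum of positive (doubled, integer)
    ranks under random sign assignment, by dynamic programming."""
    total = int(sum(ranks2))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return cdf, sf


def wilcoxon_signed_rank(a, b) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired scores.

    Zero differences are dropped; |differences| are midranked.  For
    n ≤ 25 the exact permutation null over all 2^n sign assignments is
    used (computed by convolution); beyond that, the normal
    approximation with the standard tie correction (no continuity
    correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("no discriminative pairs: all differences are zero")
    if n < 5:
        raise ValueError(f"need >= 5 non-zero differences, got {n}")
    ranks = sstats.rankdata(np.abs(d))  # midranks
    w_plus = ranks[d > 0].sum()
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        cdf, sf = _wilcoxon_exact_sf_cdf(ranks2, w2)
        return float(min(1.0, 2.0 * min(cdf, sf)))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * sstats.norm.sf(abs(z)))


def count_parameters(model) -> int:
    """Total learnable scalar count of a network."""
    return model.num_parameters()


def count_flops(config) -> int:
    """Rough forward multiply-accumulate count for one trial.

    Counts convolution, affine and attention MACs only; counting
    conventions for FLOPs vary widely, so treat this as an internal
    relative measure.
    """
    from .lfem import SEQ_LEN, conv_output_shape, kernel_dims

    ch, t, fs_hz, k = (config.channels, config.timepoints,
                       config.sampling_rate, config.k)
    L = SEQ_LEN
    macs = 0
    if config.variant != "no_lfem":
        (_, kt), (kc, _) = kernel_dims(ch, fs_hz)
        w1 = t - kt + 1
        macs += 2 * (k * ch * w1 * kt            # temporal conv 1
                     + k * (ch - kc + 1) * w1 * k * kc)   # conv 2
        macs += 2 * (k * (ch - kc + 1) * t * kc
                     + k * (ch - kc + 1) * w1 * k * kt)
    else:
        macs += 2 * L * k
    if config.fusion == "cca":
        macs += 2 * (3 * L * k * k + 2 * L * L * k)
    elif config.fusion == "cat":
        macs += L * 2 * k * k
    elif config.fusion == "atten":
        macs += 2 * k * 2
    if config.variant != "no_gfem":
        macs += 4 * L * k * k + 2 * L * L * k
    macs += L * k * config.fc_hidden + config.fc_hidden * config.n_classes
    return int(macs)


def fit_fold_zscore(ts: EEGTrialSet, train_idx, test_idx):
    """Fit z-score statistics on the training indices of a fold.

    Raises :class:`LeakageError` if any test index reaches the fit.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    overlap = np.intersect1d(train_idx, test_idx)
    if overlap.size:
        raise LeakageError(
            f"test indices {overlap[:5].tolist()}... reached z-score fitting")
    return zscore_fit(ts.subset(train_idx))


def cross_validate(ts: EEGTrialSet, model_config, train_config, plan: FoldPlan,
                   robustness_fractions=(), robustness_seed=0) -> MetricsReport:
    """Train and evaluate the network over a fold plan.

    Per fold: z-score statistics are fitted on the training split only,
    applied to both splits, a fresh network is trained (fold index mixed
    into the seed) and scored on the held-out split.
    """
    from .model import STCCAModel

    accs, all_true, all_pred = [], [], []
    robustness_accs = {f: [] for f in robustness_fractions}
    for fold_i, (train_idx, test_idx) in enumerate(plan):
        stats = fit_fold_zscore(ts, train_idx, test_idx)
        train = zscore_apply(ts.subset(train_idx), stats)
        test = zscore_apply(ts.subset(test_idx), stats)
        tc_seed = (train_config.seed + 1000 * fold_i) % (2 ** 31)
        res = STCCAModel(train, config=model_config).fit(train_config,
                                                         seed=tc_seed)
        pred = res.predict(test)
        accs.append(100.0 * float(np.mean(pred == test.labels)))
        all_true.append(test.labels)
        all_pred.append(pred)
        for frac in robustness_fractions:
            acc = channel_dropout_eval(res.network.predict, test, frac,
                                       seed=robustness_seed + fold_i)
            robustness_accs[frac].append(100.0 * acc)
    mu, sigma = accuracy_summary(accs)
    m = model_config.n_classes
    cm, f1 = confusion_and_f1(np.concatenate(all_true),
                              np.concatenate(all_pred), m)
    return MetricsReport(
        per_fold_accuracy=accs, mean=mu, std=sigma, f1=f1, confusion=cm,
        robustness={f: float(np.mean(v)) for f, v in robustness_accs.items()},
        scheme=plan.scheme,
    )

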