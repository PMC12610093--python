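"""Class-conditioned synthetic EEG generator.

Each class is a rank-1 spatio-temporal template: a unit-norm spatial
mixing vector (which electrodes see the source) times an oscillatory
burst (a Hann-windowed sinusoid with class-specific frequency and
latency).  Trials are the template scaled to a target signal-to-noise
ratio plus 1/f ("pink") background noise with a small channel-correlated
common-mode component, mimicking real EEG background so that band-pass
and notch filtering have realistic work to do.

The ``coupling`` knob controls whether class identity lives in the
marginal spatial or temporal pattern (coupling = 0: every class has its
own topography AND its own waveform, either alone suffices) or only in
their joint combination (coupling = 1: topographies are shared between
class pairs and waveforms between the complementary pairs, so neither
marginal alone identifies the class).  This is a stand-in signal model —
no real acquisition is simulated — but it lets tests probe exactly the
regime where coupled spatio-temporal fusion should pay off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EEGTrialSet

#: peak template amplitude before noise, microvolts
TEMPLATE_PEAK_UV = 10.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic class-conditioned EEG signal model.

    Defaults mirror a small four-class inner-speech-style benchmark:
    8 electrodes, 1-second trials at 256 Hz, high SNR, fully coupled
    spatio-temporal class structure.
    """

    n_classes: int = 4
    n_channels: int = 8
    n_timepoints: int = 256
    sampling_rate: float = 256.0
    trials_per_class: int = 25
    snr: float = 10.0
    coupling: float = 1.0
    seed: int = 0

    def __post_init__(self):
        checks = [
            ("n_classes", self.n_classes >= 2, "must be >= 2"),
            ("trials_per_class", self.trials_per_class >= 1, "must be >= 1"),
            ("n_channels", self.n_channels >= 2, "must be >= 2"),
            ("n_timepoints", self.n_timepoints >= 16, "must be >= 16"),
            ("sampling_rate", self.sampling_rate > 0, "must be positive"),
            ("snr", self.snr > 0, "must be positive"),
            ("coupling", 0.0 <= self.coupling <= 1.0, "must be in [0, 1]"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValueError(f"SynthConfig.{name} {msg} "
                                 f"(got {getattr(self, name)!r})")


def _pink_noise(rng, shape, n_time):
    """1/f-amplitude-shaped Gaussian noise along the last axis, unit power."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_time)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spec * shaping, n=n_time, axis=-1)
    power = (noise ** 2).mean(axis=-1, keepdims=True)
    return noise / np.sqrt(np.maximum(power, 1e-30))


def _class_frequencies(n, lo=5.0, hi=29.0):
    """n burst frequencies spaced >= 2 Hz apart inside the 4-30 Hz band."""
    if n == 1:
        return np.array([(lo + hi) / 2])
    step = max(2.0, (hi - lo) / (n - 1))
    return lo + step * np.arange(n)


def _burst(freq, latency_frac, width_frac, t, fs):
    """Hann-windowed sinusoid burst; unit peak amplitude."""
    n = len(t)
    width = max(int(round(width_frac * n)), 8)
    start = int(round(latency_frac * (n - width)))
    wave = np.zeros(n)
    seg = np.arange(width)
    window = 0.5 * (1 - np.cos(2 * np.pi * seg / (width - 1)))
    wave[start:start + width] = window * np.sin(
        2 * np.pi * freq * seg / fs
    )
    return wave


def class_templates(config: SynthConfig):
    """Per-class (spatial vector, temporal waveform) pairs.

    Spatial vectors are unit-norm Gaussian draws; waveforms are unit-norm
    oscillatory bursts.  With coupling -> 1 the spatial bank collapses to
    one vector per class PAIR and the temporal bank to one waveform per
    complementary pair, so only the joint pattern is class-specific.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    m, ch = config.n_classes, config.n_channels
    t = np.arange(config.n_timepoints)

    # independent banks: one topography and one waveform per class
    uniq_spatial = rng.standard_normal((m, ch))
    uniq_spatial /= np.linalg.norm(uniq_spatial, axis=1, keepdims=True)
    uniq_freqs = _class_frequencies(m)
    uniq_temporal = np.stack([
        _burst(uniq_freqs[c], latency_frac=(c + 0.5) / m, width_frac=0.5,
               t=t, fs=config.sampling_rate) for c in range(m)
    ])

    # shared banks: class c = (spatial group c//2, temporal parity c%2)
    n_sgroups = (m + 1) // 2
    shared_spatial_bank = rng.standard_normal((n_sgroups, ch))
    shared_spatial_bank /= np.linalg.norm(shared_spatial_bank, axis=1,
                                          keepdims=True)
    shared_freqs = _class_frequencies(2, lo=8.0, hi=24.0)
    shared_temporal_bank = np.stack([
        _burst(shared_freqs[p], latency_frac=0.25 + 0.5 * p, width_frac=0.5,
               t=t, fs=config.sampling_rate) for p in range(2)
    ])

    lam = config.coupling
    spatial, temporal = [], []
    for c in range(m):
        s = (1 - lam) * uniq_spatial[c] + lam * shared_spatial_bank[c // 2]
        w = (1 - lam) * uniq_temporal[c] + lam * shared_temporal_bank[c % 2]
        s = s / max(np.linalg.norm(s), 1e-12)
        w = w / max(np.linalg.norm(w), 1e-12)
        spatial.append(s)
        temporal.append(w)
    spatial = np.stack(spatial)
    temporal = np.stack(temporal)
    # scale waveforms so the rank-1 template peaks near TEMPLATE_PEAK_UV
    peak = np.abs(spatial[:, :, None] * temporal[:, None, :]).max(
        axis=(1, 2), keepdims=False)
    temporal = temporal * (TEMPLATE_PEAK_UV / peak)[:, None]
    return spatial, temporal


def generate_trialset(config: SynthConfig) -> EEGTrialSet:
    """Generate a class-balanced synthetic trial set.

    Each trial is ``outer(spatial_c, temporal_c) * gain + noise`` with the
    global gain calibrated so the realised mean signal-to-noise power
    ratio matches ``config.snr``; fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    m, ch, nt = config.n_classes, config.n_channels, config.n_timepoints
    n = m * config.trials_per_class
    spatial, temporal = class_templates(config)

    labels = np.repeat(np.arange(1, m + 1), config.trials_per_class)
    # per-channel pink noise plus a channel-correlated common-mode drift
    noise = _pink_noise(rng, (n, ch, nt), nt)
    common = _pink_noise(rng, (n, 1, nt), nt)
    noise = noise + 0.3 * common
    noise_power = (noise ** 2).mean()

    templates = np.einsum("mc,mt->mct", spatial, temporal)
    signal = templates[labels - 1]
    signal_power = (signal ** 2).mean()
    gain = np.sqrt(config.snr * noise_power / signal_power)
    data = signal * gain + noise

    order = rng.permutation(n)
    return EEGTrialSet(data[order], labels[order], config.sampling_rate,
                       subject_id="synthetic")


def generate_multisubject(config: SynthConfig, n_subjects: int) -> EEGTrialSet:
    """Concatenate per-subject sets (distinct seeds) with per-trial subject ids."""
    sets = []
    ids = []
    for s in range(n_subjects):
        cfg = SynthConfig(**{**config.__dict__, "seed": config.seed + 1000 * (s + 1)})
        ts = generate_trialset(cfg)
        sets.append(ts)
        ids.extend([f"S{s + 1:02d}"] * ts.n_trials)
    data = np.concatenate([ts.data for ts in sets])
    labels = np.concatenate([ts.labels for ts in sets])
    return EEGTrialSet(data, labels, config.sampling_rate,
                       subject_id=np.asarray(ids))
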