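"""Labelled EEG trial containers and array-container (HDF5) I/O.

The :class:`EEGTrialSet` is the currency passed between every pipeline
stage: a ``(trials, channels, timepoints)`` float array with one 1-based
class label per trial plus sampling metadata.  Trial sets round-trip
losslessly through HDF5 files; continuous EDF/BDF recordings can be
epoched into trial sets when ``mne`` is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np


class LeakageError(RuntimeError):
    """Raised when test-set indices reach a train-only fitting step."""


@dataclass
class EEGTrialSet:
    """A set of fixed-length EEG trials with per-trial class labels.

    data : (n_trials, n_channels, n_timepoints) array, microvolt scale
    labels : (n_trials,) integer class labels in 1..m
    sampling_rate : Hz
    subject_id : optional per-set identifier, or per-trial array for
        multi-subject sets (used by leave-one-subject-out splitting)
    """

    data: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    subject_id: object = None
    channel_names: list | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, timepoints)")
        if self.labels.ndim != 1 or len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one entry per trial")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite entries")
        if len(self.labels) and self.labels.min() < 1:
            raise ValueError("labels must be 1-based class indices")

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def n_timepoints(self):
        return self.data.shape[2]

    @property
    def n_classes(self):
        return int(self.labels.max()) if len(self.labels) else 0

    def with_data(self, data, sampling_rate=None):
        """Copy of this set with new data (labels/metadata preserved)."""
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       sampling_rate=self.sampling_rate
                       if sampling_rate is None else sampling_rate)

    def subset(self, indices):
        idx = np.asarray(indices)
        subj = self.subject_id
        if isinstance(subj, np.ndarray):
            subj = subj[idx]
        return EEGTrialSet(self.data[idx], self.labels[idx],
                           self.sampling_rate, subj, self.channel_names)


def permute_labels(ts: EEGTrialSet, seed: int) -> EEGTrialSet:
    """Null-control: uniformly permute labels, leaving the data untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ts.n_trials)
    return replace(ts, labels=ts.labels[perm])


def write_trialset(ts: EEGTrialSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ts.data)
        f.create_dataset("labels", data=ts.labels)
        f.attrs["sampling_rate"] = float(ts.sampling_rate)
        if isinstance(ts.subject_id, np.ndarray):
            f.create_dataset("subject_id", data=np.asarray(ts.subject_id, dtype="S"))
        elif ts.subject_id is not None:
            f.attrs["subject_id"] = str(ts.subject_id)
        if ts.channel_names is not None:
            f.create_dataset("channel_names",
                             data=np.asarray(ts.channel_names, dtype="S"))


def read_trialset(path) -> EEGTrialSet:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: missing 'data' dataset")
        if "labels" not in f:
            raise ValueError(f"{path}: missing 'labels' dataset")
        if "sampling_rate" not in f.attrs:
            raise ValueError(f"{path}: missing 'sampling_rate' attribute")
        data = f["data"][()]
        labels = f["labels"][()]
        rate = float(f.attrs["sampling_rate"])
        subject = None
        if "subject_id" in f:
            subject = f["subject_id"][()].astype(str)
        elif "subject_id" in f.attrs:
            subject = str(f.attrs["subject_id"])
        names = None
        if "channel_names" in f:
            names = [n.decode() for n in f["channel_names"][()]]
    return EEGTrialSet(data, labels, rate, subject, names)


def read_edf_epochs(path, onsets_s, window_s, labels, subject_id=None):
    """Epoch a continuous EDF/BDF recording into an EEGTrialSet.

    onsets_s : event onset times in seconds; window_s : epoch length in
    seconds; labels : 1-based class label per onset.  Requires ``mne``.
    """
    import mne

    raw = mne.io.read_raw(path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    sig = raw.get_data()
    n = int(round(window_s * fs))
    trials = []
    for t0 in onsets_s:
        i0 = int(round(t0 * fs))
        if i0 + n > sig.shape[1]:
            raise ValueError(f"epoch at {t0}s runs past end of recording")
        trials.append(sig[:, i0:i0 + n])
    return EEGTrialSet(np.stack(trials) * 1e6, np.asarray(labels), fs,
                       subject_id, list(raw.ch_names))
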