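"""Trial containers, GDF loading, epoching, normalisation and data splits.

The evaluation protocols mirror standard MI-BCI practice: a
subject-dependent 8:1:1 stratified split within one subject, and
leave-one-subject-out (LOSO) transfer where the held-out subject's labels are
never available to training.  Epochs are cut 0.5-4.5 s after cue onset
(1000 samples at 250 Hz) and z-scored per channel with statistics fitted on
the training portion only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

__all__ = [
    "EEGTrialSet",
    "NormStats",
    "SplitSpec",
    "load_gdf_dataset",
    "epoch_trials",
    "zscore_fit_apply",
    "split_subject_dependent",
    "split_loso",
]

SIGMA_FLOOR = 1e-8

# Cue annotation codes of the Graz competition recordings.
GDF_EVENT_CLASSES = {
    "2a": {"769": 0, "770": 1, "771": 2, "772": 3},  # left, right, feet, tongue
    "2b": {"769": 0, "770": 1},  # left, right
}


@dataclasses.dataclass
class EEGTrialSet:
    """Labelled multi-subject trial collection (n_trials, n_channels, n_samples)."""

    trials: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    fs: float
    channel_names: list[str] | None = None

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subjects = np.asarray(self.subjects, dtype=np.int64)
        if self.trials.ndim != 3:
            raise ValueError("trials must be (n_trials, n_channels, n_samples)")
        n = self.trials.shape[0]
        if self.labels.shape != (n,) or self.subjects.shape != (n,):
            raise ValueError("labels/subjects must have length n_trials")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.isfinite(self.trials).all():
            raise ValueError("trials contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_trials else 0

    def subset(self, indices) -> "EEGTrialSet":
        idx = np.asarray(indices, dtype=np.int64)
        return EEGTrialSet(
            trials=self.trials[idx],
            labels=self.labels[idx],
            subjects=self.subjects[idx],
            fs=self.fs,
            channel_names=self.channel_names,
        )


@dataclasses.dataclass
class NormStats:
    """Per-channel z-score statistics (sigma floored at 1e-8)."""

    mu: np.ndarray
    sigma: np.ndarray


@dataclasses.dataclass
class SplitSpec:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    mode: str  # "subject_dependent" | "cross_subject"
    test_subject: int | None = None

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=np.int64)
        self.val = np.asarray(self.val, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)
        parts = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split index lists overlap")
        if self.mode not in ("subject_dependent", "cross_subject"):
            raise ValueError(f"unknown split mode {self.mode!r}")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train": self.train.tolist(),
                    "val": self.val.tolist(),
                    "test": self.test.tolist(),
                    "mode": self.mode,
                    "test_subject": self.test_subject,
                }
            )
        )

    @staticmethod
    def from_json(path) -> "SplitSpec":
        d = json.loads(Path(path).read_text())
        return SplitSpec(d["train"], d["val"], d["test"], d["mode"], d["test_subject"])


def load_gdf_dataset(paths, dataset_id: str):
    """Read Graz competition GDF recordings.

    Returns a list of ``(signals, fs, events)`` per session, where ``signals``
    is (n_channels, n_samples) from the EEG channels only and ``events`` is an
    (n_events, 2) array of (cue onset sample, class id).  For the two-class
    three-channel dataset only the last three (feedback) sessions of the
    sorted file list are retained.
    """
    if dataset_id not in GDF_EVENT_CLASSES:
        raise ValueError(f"unknown dataset_id {dataset_id!r}; expected '2a' or '2b'")
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"GDF file not found: {p}")
    if dataset_id == "2b":
        paths = sorted(paths)[-3:]

    import mne

    code_map = GDF_EVENT_CLASSES[dataset_id]
    sessions = []
    for p in paths:
        raw = mne.io.read_raw_gdf(str(p), preload=True, verbose="error")
        raw.pick(picks="eeg", verbose="error")
        fs = float(raw.info["sfreq"])
        events = []
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            if desc in code_map:
                events.append((int(round(onset * fs)), code_map[desc]))
        sessions.append((raw.get_data(), fs, np.asarray(events, dtype=np.int64).reshape(-1, 2)))
    return sessions


def epoch_trials(
    continuous: np.ndarray,
    events: np.ndarray,
    fs: float,
    window: tuple[float, float] = (0.5, 4.5),
    subject: int = 0,
) -> EEGTrialSet:
    """Cut half-open sample windows ``[onset + w0*fs, onset + w1*fs)`` per cue.

    0-based indexing; at 250 Hz the default window yields exactly 1000
    samples.  No overlap augmentation is applied.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    events = np.asarray(events, dtype=np.int64).reshape(-1, 2)
    start_off = int(round(window[0] * fs))
    stop_off = int(round(window[1] * fs))
    n_total = continuous.shape[-1]
    bad = [int(on) for on, _ in events if on + stop_off > n_total or on + start_off < 0]
    if bad:
        raise ValueError(f"epoch window exceeds recording bounds for cue onsets {bad}")
    trials = np.stack([continuous[:, on + start_off : on + stop_off] for on, _ in events])
    return EEGTrialSet(
        trials=trials,
        labels=events[:, 1],
        subjects=np.full(len(events), subject, dtype=np.int64),
        fs=fs,
    )


def zscore_fit_apply(train: EEGTrialSet, others: list[EEGTrialSet] | None = None):
    """Fit per-channel mean/sd on the training set and apply to all sets."""
    if train.n_trials == 0:
        raise ValueError("training set is empty")
    mu = train.trials.mean(axis=(0, 2))
    sigma = np.maximum(train.trials.std(axis=(0, 2)), SIGMA_FLOOR)
    stats = NormStats(mu=mu, sigma=sigma)

    def apply(ts: EEGTrialSet) -> EEGTrialSet:
        return EEGTrialSet(
            trials=(ts.trials - mu[None, :, None]) / sigma[None, :, None],
            labels=ts.labels,
            subjects=ts.subjects,
            fs=ts.fs,
            channel_names=ts.channel_names,
        )

    normalized_others = [apply(o) for o in (others or [])]
    return apply(train), normalized_others, stats


def _stratified_indices(labels: np.ndarray, fractions, rng) -> list[np.ndarray]:
    """Split index space per class by ``fractions`` (largest share gets the
    rounding remainder)."""
    parts: list[list[int]] = [[] for _ in fractions]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        counts = [int(np.floor(f * len(idx))) for f in fractions]
        counts[int(np.argmax(fractions))] += len(idx) - sum(counts)
        pos = 0
        for part, c in zip(parts, counts):
            part.extend(idx[pos : pos + c])
            pos += c
    return [np.sort(np.asarray(p, dtype=np.int64)) for p in parts]


def split_subject_dependent(trial_set: EEGTrialSet, ratios=(8, 1, 1), seed: int = 0) -> SplitSpec:
    """Stratified train/val/test split of a single subject's trials."""
    if len(np.unique(trial_set.subjects)) != 1:
        raise ValueError("subject-dependent split expects a single-subject set")
    if trial_set.n_trials < trial_set.n_classes:
        raise ValueError("fewer trials than classes")
    total = float(sum(ratios))
    fractions = [r / total for r in ratios]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    train, val, test = _stratified_indices(trial_set.labels, fractions, rng)
    return SplitSpec(train=train, val=val, test=test, mode="subject_dependent")


def split_loso(
    trial_set: EEGTrialSet, test_subject: int, val_fraction: float = 0.1, seed: int = 0
) -> SplitSpec:
    """Leave-one-subject-out split: the held-out subject is the whole test set."""
    subjects = np.unique(trial_set.subjects)
    if len(subjects) < 2:
        raise ValueError("LOSO requires at least two subjects")
    if test_subject not in subjects:
        raise ValueError(f"unknown subject id {test_subject}")
    test = np.flatnonzero(trial_set.subjects == test_subject)
    source = np.flatnonzero(trial_set.subjects != test_subject)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3, int(test_subject))))
    val_part, train_part = _stratified_indices(
        trial_set.labels[source], [val_fraction, 1.0 - val_fraction], rng
    )
    return SplitSpec(
        train=source[train_part],
        val=source[val_part],
        test=test,
        mode="cross_subject",
        test_subject=int(test_subject),
    )
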