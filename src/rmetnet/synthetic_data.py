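"""Seeded multi-subject motor-imagery EEG simulator.

Emulates the statistical structure that MI decoders exploit: every channel
carries a 1/f (pink) background plus narrowband oscillations in the mu
(8-12 Hz) and beta (13-30 Hz) sensorimotor bands, and the imagined class
expresses itself as event-related desynchronization (ERD) — an attenuation of
mu power on the channel group assigned to that class.  Inter-subject
distribution shift is produced by a subject-specific linear mixing matrix
``M_s = I + shift * G_s`` and per-channel log-normal gains, which is the kind
of spatial/gain variability that makes cross-subject transfer hard.

Randomness is counter-based: one global seed expands into independent
per-subject and per-trial streams through ``numpy`` ``SeedSequence`` keys, so
the output is identical regardless of generation order.

Not modelled: volume-conduction forward physics, ocular/muscular artifacts,
and non-stationarity within a trial.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .eeg_io import EEGTrialSet

__all__ = ["SynthConfig", "generate_subjects", "band_power", "save_h5", "load_h5"]

MU_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)
_MU_AMP = 1.0
_BETA_AMP = 0.5


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Generator settings; identical configs give byte-identical data."""

    n_subjects: int = 4
    trials_per_class: int = 40
    n_classes: int = 2
    n_channels: int = 6
    n_samples: int = 250
    fs: float = 250.0
    erd_depth: float = 0.8
    subject_shift: float = 0.3
    snr_db: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "trials_per_class", "n_channels", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_classes not in (2, 4):
            raise ValueError("n_classes must be 2 or 4")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.subject_shift < 0:
            raise ValueError("subject_shift must be non-negative")
        if self.fs <= 2.0 * BETA_BAND[1]:
            raise ValueError(
                f"fs={self.fs} too low: need fs > {2 * BETA_BAND[1]} Hz "
                "(twice the highest synthesized band edge)"
            )
        if self.n_channels < self.n_classes:
            raise ValueError(
                "need at least one channel per class group: "
                f"n_channels={self.n_channels} < n_classes={self.n_classes}"
            )

    def channel_group(self, cls: int) -> np.ndarray:
        """Disjoint contiguous channel group assigned to ``cls`` (in order)."""
        size = self.n_channels // self.n_classes
        return np.arange(cls * size, (cls + 1) * size)


def _pink_background(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float) -> np.ndarray:
    """Unit-variance noise with a 1/sqrt(f) amplitude spectrum (flat < 1 Hz)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec = rng.normal(size=(n_channels, freqs.size)) + 1j * rng.normal(size=(n_channels, freqs.size))
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.maximum(sd, 1e-30)


def _oscillation(rng: np.random.Generator, n_channels: int, n_samples: int, fs: float, band) -> np.ndarray:
    """Per-channel sinusoid with trial-specific frequency and phase."""
    t = np.arange(n_samples) / fs
    f = rng.uniform(band[0], band[1], size=(n_channels, 1))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, 1))
    return np.sin(2.0 * np.pi * f * t[None, :] + phi)


def generate_subjects(cfg: SynthConfig) -> EEGTrialSet:
    """Simulate ``n_subjects * n_classes * trials_per_class`` labelled trials."""
    n_trials = cfg.n_subjects * cfg.n_classes * cfg.trials_per_class
    trials = np.empty((n_trials, cfg.n_channels, cfg.n_samples))
    labels = np.empty(n_trials, dtype=np.int64)
    subjects = np.empty(n_trials, dtype=np.int64)

    # white-noise floor set by the nominal mu oscillation power (amp^2/2)
    noise_sd = np.sqrt((_MU_AMP**2 / 2.0) / 10.0 ** (cfg.snr_db / 10.0))

    idx = 0
    for s in range(cfg.n_subjects):
        srng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0, s)))
        mixing = np.eye(cfg.n_channels) + cfg.subject_shift * srng.normal(
            size=(cfg.n_channels, cfg.n_channels)
        )
        # gain spread scales with subject_shift so that shift = 0 means
        # identically distributed subjects
        gains = np.exp(0.2 * cfg.subject_shift * srng.normal(size=(cfg.n_channels, 1)))
        for cls in range(cfg.n_classes):
            group = cfg.channel_group(cls)
            for _ in range(cfg.trials_per_class):
                trng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1, idx)))
                bg = _pink_background(trng, cfg.n_channels, cfg.n_samples, cfg.fs)
                mu = _MU_AMP * _oscillation(trng, cfg.n_channels, cfg.n_samples, cfg.fs, MU_BAND)
                beta = _BETA_AMP * _oscillation(trng, cfg.n_channels, cfg.n_samples, cfg.fs, BETA_BAND)
                amp = np.ones((cfg.n_channels, 1))
                amp[group] = 1.0 - cfg.erd_depth  # ERD on the class-matched group
                source = bg + amp * mu + beta
                white = noise_sd * trng.normal(size=(cfg.n_channels, cfg.n_samples))
                trials[idx] = gains * (mixing @ source) + white
                labels[idx] = cls
                subjects[idx] = s
                idx += 1
    return EEGTrialSet(
        trials=trials,
        labels=labels,
        subjects=subjects,
        fs=cfg.fs,
        channel_names=[f"ch{i}" for i in range(cfg.n_channels)],
    )


def band_power(trial: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Per-channel power integrated over ``[f_lo, f_hi)`` from a periodogram.

    Normalised so that summing over a partition of [0, fs/2) recovers the
    signal's total variance about zero (Parseval), and a unit sinusoid whose
    frequency sits in the band contributes ~1/2.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    f_lo, f_hi = band
    if not (0.0 <= f_lo < f_hi <= fs / 2.0):
        raise ValueError(f"band {band} must satisfy 0 <= f_lo < f_hi <= fs/2")
    n = trial.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.fft.rfft(trial, axis=-1)
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    pxx = scale * np.abs(spec) ** 2 / n**2
    sel = (freqs >= f_lo) & (freqs < f_hi)
    if f_hi == fs / 2.0:  # closed upper edge so a partition of [0, fs/2] is exact
        sel |= freqs == f_hi
    if not sel.any():
        raise ValueError(f"band {band} contains no frequency bins at n={n}, fs={fs}")
    return pxx[:, sel].sum(axis=-1)


def save_h5(path, trial_set: EEGTrialSet, config: SynthConfig | None = None) -> None:
    """Write the named-array HDF5 container (deterministic byte layout)."""
    import h5py

    with h5py.File(path, "w") as f:
        for name, data in (
            ("trials", trial_set.trials.astype(np.float32)),
            ("labels", trial_set.labels),
            ("subjects", trial_set.subjects),
        ):
            f.create_dataset(name, data=data, track_times=False)
        f.attrs["fs"] = trial_set.fs
        f.attrs["channel_names"] = json.dumps(trial_set.channel_names)
        if config is not None:
            f.attrs["config_json"] = json.dumps(dataclasses.asdict(config))


def load_h5(path) -> EEGTrialSet:
    import h5py

    with h5py.File(path, "r") as f:
        names = json.loads(f.attrs.get("channel_names", "null"))
        return EEGTrialSet(
            trials=np.asarray(f["trials"], dtype=np.float64),
            labels=np.asarray(f["labels"], dtype=np.int64),
            subjects=np.asarray(f["subjects"], dtype=np.int64),
            fs=float(f.attrs["fs"]),
            channel_names=names,
        )
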