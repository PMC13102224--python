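"""SPD covariance geometry: estimation, means, distances and alignment.

EEG trial covariances live on the manifold of symmetric positive-definite
(SPD) matrices.  Aligning each domain's covariances at a common reference —
whitening by the inverse square root of the domain's geometric mean, then
(optionally) taking the matrix logarithm — removes a large part of the
inter-subject shift before any learning happens, and produces the inputs of
the decoder's Riemannian branch.

All matrix functions go through symmetric eigendecompositions with an
eigenvalue floor for numerical safety.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .eeg_io import EEGTrialSet

__all__ = [
    "SPDSet",
    "trial_covariance",
    "geometric_mean",
    "riemannian_distance",
    "align_to_reference",
    "build_riemannian_inputs",
]

EIG_FLOOR = 1e-10
DEFAULT_SHRINKAGE = 1e-3


@dataclasses.dataclass
class SPDSet:
    """A stack of SPD matrices plus alignment book-keeping."""

    matrices: np.ndarray  # (n, C, C)
    reference: np.ndarray | None = None
    aligned: bool = False
    log_mapped: bool = False

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n, C, C)")
        asym = np.abs(self.matrices - np.swapaxes(self.matrices, 1, 2)).max()
        if asym > 1e-8:
            raise ValueError(f"matrices not symmetric (max asymmetry {asym:.2e})")

    def __len__(self):
        return self.matrices.shape[0]


def _check_spd(mat: np.ndarray, name: str = "matrix") -> np.ndarray:
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if np.abs(mat - mat.T).max() > 1e-8:
        raise ValueError(f"{name} is not symmetric")
    if np.linalg.eigvalsh(mat).min() <= 0:
        raise np.linalg.LinAlgError(f"{name} is not positive definite")
    return mat


def _sym_fun(mat: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of symmetric ``mat``."""
    w, v = np.linalg.eigh(mat)
    w = np.maximum(w, EIG_FLOOR)
    return (v * fun(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def logm(mat: np.ndarray) -> np.ndarray:
    return _sym_fun(mat, np.log)


def expm(mat: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mat)  # no floor: any symmetric matrix has an exp
    return (v * np.exp(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def invsqrtm(mat: np.ndarray) -> np.ndarray:
    return _sym_fun(mat, lambda w: 1.0 / np.sqrt(w))


def sqrtm(mat: np.ndarray) -> np.ndarray:
    return _sym_fun(mat, np.sqrt)


def trial_covariance(trial_set: EEGTrialSet, shrinkage: float = DEFAULT_SHRINKAGE) -> SPDSet:
    """Per-trial channel covariance with trace-normalised shrinkage.

    ``Cov = (1/N) sum_t (x_t - mu)(x_t - mu)^T`` over the trial's N time
    samples, then ``(1-s) Cov + s (tr(Cov)/C) I``.  Shrinkage keeps
    low-channel or degenerate trials invertible.
    """
    if trial_set.n_samples < 2:
        raise ValueError("need at least 2 time samples per trial")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    x = trial_set.trials
    xc = x - x.mean(axis=2, keepdims=True)
    covs = np.einsum("nct,ndt->ncd", xc, xc) / trial_set.n_samples
    c = trial_set.n_channels
    if shrinkage > 0:
        tr = np.trace(covs, axis1=1, axis2=2) / c
        covs = (1.0 - shrinkage) * covs + shrinkage * tr[:, None, None] * np.eye(c)
    else:
        min_eig = np.linalg.eigvalsh(covs)[:, 0].min()
        if min_eig <= 0:
            raise np.linalg.LinAlgError(
                "singular trial covariance with shrinkage 0; increase shrinkage"
            )
    return SPDSet(matrices=covs)


def geometric_mean(
    spd: SPDSet | np.ndarray,
    method: str = "log_euclidean",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Geometric mean of an SPD set.

    ``log_euclidean``: exp of the average matrix log (closed form).
    ``karcher``: affine-invariant Frechet mean by fixed-point iteration.
    """
    mats = spd.matrices if isinstance(spd, SPDSet) else np.asarray(spd, dtype=np.float64)
    if mats.shape[0] == 0:
        raise ValueError("empty SPD set")
    if method == "log_euclidean":
        return expm(logm(mats).mean(axis=0))
    if method != "karcher":
        raise ValueError(f"unknown mean method {method!r}")
    g = mats.mean(axis=0)
    last = g
    for _ in range(max_iter):
        g_isqrt = invsqrtm(g)
        g_sqrt = sqrtm(g)
        tangent = logm(g_isqrt @ mats @ g_isqrt).mean(axis=0)
        g = g_sqrt @ expm(tangent) @ g_sqrt
        last = g
        if np.linalg.norm(tangent) < tol:
            return g
    err = RuntimeError(f"Karcher mean did not converge in {max_iter} iterations")
    err.last_iterate = last
    raise err


def riemannian_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Log-Euclidean distance ``||log(A) - log(B)||_F`` between SPD matrices."""
    a = _check_spd(a, "A")
    b = _check_spd(b, "B")
    return float(np.linalg.norm(logm(a) - logm(b)))


def align_to_reference(spd: SPDSet, ref: np.ndarray, apply_log: bool = True) -> SPDSet:
    """Congruence-whiten every matrix by ``ref^(-1/2)``, optionally log-map.

    With ``apply_log`` the result is the tangent-space coordinate at the
    identity; without, it is the whitened SPD matrix itself.
    """
    ref = _check_spd(ref, "reference")
    w = invsqrtm(ref)
    aligned = w @ spd.matrices @ w
    aligned = 0.5 * (aligned + np.swapaxes(aligned, 1, 2))  # kill rounding asymmetry
    if apply_log:
        aligned = logm(aligned)
    return SPDSet(matrices=aligned, reference=ref, aligned=True, log_mapped=apply_log)


def build_riemannian_inputs(
    source: EEGTrialSet,
    target: EEGTrialSet | None = None,
    shrinkage: float = DEFAULT_SHRINKAGE,
    policy: str = "per_domain",
    apply_log: bool = True,
    mean_method: str = "log_euclidean",
) -> tuple[SPDSet, SPDSet | None]:
    """Produce aligned covariance features for the source (and target) domain.

    ``per_domain`` whitens each domain by its own geometric mean — fully
    unsupervised, so it may be applied transductively to an unlabelled test
    subject.  ``source_reference`` whitens every domain by the source mean.
    """
    if target is not None and target.n_channels != source.n_channels:
        raise ValueError("channel count mismatch between source and target")
    if policy not in ("per_domain", "source_reference"):
        raise ValueError(f"unknown alignment policy {policy!r}")
    src_cov = trial_covariance(source, shrinkage)
    src_mean = geometric_mean(src_cov, method=mean_method)
    src_aligned = align_to_reference(src_cov, src_mean, apply_log)
    if target is None:
        return src_aligned, None
    tgt_cov = trial_covariance(target, shrinkage)
    if policy == "per_domain":
        tgt_mean = geometric_mean(tgt_cov, method=mean_method)
    else:
        tgt_mean = src_mean
    tgt_aligned = align_to_reference(tgt_cov, tgt_mean, apply_log)
    return src_aligned, tgt_aligned
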