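"""Maximum mean discrepancy and the combined training objective.

The cross-subject trainer aligns source- and target-domain penultimate
features by adding a kernel MMD penalty to the classification loss:
``total = L_cls + lambda * MMD^2``.  MMD^2 is the biased V-statistic

    mean(K_ss) + mean(K_tt) - 2 mean(K_st)

averaged over a bank of RBF kernels whose bandwidths come from the median
heuristic (median pairwise distance of the pooled batch, scaled by
0.25/0.5/1/2/4).  It is non-negative, zero iff the two sample multisets
coincide under every kernel in the bank, and invariant to within-domain
permutations.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "KernelSpec",
    "DomainBatch",
    "LossBundle",
    "median_heuristic_bandwidths",
    "mmd_squared",
    "mmd_loss",
    "cross_entropy",
    "combined_loss",
]

MEDIAN_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)
LOG_EPS = 1e-12


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """RBF kernel bank; ``bandwidths=None`` requests the median heuristic."""

    kind: str = "rbf"
    bandwidths: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.kind != "rbf":
            raise ValueError(f"unsupported kernel kind {self.kind!r}")
        if self.bandwidths is not None:
            bw = tuple(float(b) for b in self.bandwidths)
            if not bw or any(b <= 0 for b in bw):
                raise ValueError("bandwidths must be a non-empty list of positive reals")
            object.__setattr__(self, "bandwidths", bw)


@dataclasses.dataclass
class DomainBatch:
    """Paired source/target feature batches; target labels do not exist here."""

    source_feats: np.ndarray
    target_feats: np.ndarray
    source_labels: np.ndarray | None = None

    def __post_init__(self):
        self.source_feats = np.atleast_2d(np.asarray(self.source_feats, dtype=np.float64))
        self.target_feats = np.atleast_2d(np.asarray(self.target_feats, dtype=np.float64))
        if self.source_feats.shape[0] == 0 or self.target_feats.shape[0] == 0:
            raise ValueError("both domains need at least one sample")
        if self.source_feats.shape[1] != self.target_feats.shape[1]:
            raise ValueError("feature dimension mismatch between domains")


@dataclasses.dataclass
class LossBundle:
    cls: float
    mmd: float
    lam: float

    @property
    def total(self) -> float:
        return self.cls + self.lam * self.mmd


def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = a[:, None, :] - b[None, :, :]
    return np.einsum("ijk,ijk->ij", d, d)


def median_heuristic_bandwidths(x: np.ndarray, y: np.ndarray,
                                multipliers=MEDIAN_MULTIPLIERS) -> tuple[float, ...]:
    """Bandwidth bank from the pooled pairwise squared distances.

    Base bandwidth ``sigma0 = sqrt(median(d^2) / 2)`` so that the kernel value
    at the median distance is ``exp(-1)``; the bank scales sigma0 by the
    multipliers.
    """
    pooled = np.vstack([x, y])
    d2 = _pairwise_sq(pooled, pooled)
    med = np.median(d2[np.triu_indices_from(d2, k=1)]) if pooled.shape[0] > 1 else 1.0
    sigma0 = np.sqrt(max(med, 1e-12) / 2.0)
    return tuple(float(sigma0 * m) for m in multipliers)


def mmd_squared(batch: DomainBatch, kernel: KernelSpec = KernelSpec()) -> float:
    """Biased multi-kernel MMD^2 between the two feature batches."""
    x, y = batch.source_feats, batch.target_feats
    bws = kernel.bandwidths or median_heuristic_bandwidths(x, y)
    dxx, dyy, dxy = _pairwise_sq(x, x), _pairwise_sq(y, y), _pairwise_sq(x, y)
    total = 0.0
    for sigma in bws:
        g = 1.0 / (2.0 * sigma**2)
        total += (
            np.exp(-g * dxx).mean() + np.exp(-g * dyy).mean() - 2.0 * np.exp(-g * dxy).mean()
        )
    return float(max(total / len(bws), 0.0))


def _pairwise_sq_t(a: Tensor, b: Tensor) -> Tensor:
    an = (a**2).sum(axis=1, keepdims=True)  # (m,1)
    bn = (b**2).sum(axis=1, keepdims=True)  # (n,1)
    cross = a @ b.transpose(1, 0)
    return an + bn.transpose(1, 0) - 2.0 * cross


def mmd_loss(source: Tensor, target: Tensor, kernel: KernelSpec = KernelSpec()) -> Tensor:
    """Differentiable MMD^2 on penultimate-feature tensors (training path).

    The median-heuristic bandwidths are treated as constants of the batch
    (no gradient through the bandwidth selection).
    """
    bws = kernel.bandwidths or median_heuristic_bandwidths(source.data, target.data)
    dxx = _pairwise_sq_t(source, source)
    dyy = _pairwise_sq_t(target, target)
    dxy = _pairwise_sq_t(source, target)
    total = None
    for sigma in bws:
        g = 1.0 / (2.0 * sigma**2)
        term = (dxx * -g).exp().mean() + (dyy * -g).exp().mean() - 2.0 * (dxy * -g).exp().mean()
        total = term if total is None else total + term
    return total * (1.0 / len(bws))


def cross_entropy(probs, labels) -> float:
    """Mean negative log-likelihood of one-hot labels under ``probs``."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    k = probs.shape[1]
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    p_true = probs[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p_true, LOG_EPS))))


def cross_entropy_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Differentiable cross-entropy on probability tensors (training path)."""
    labels = np.asarray(labels, dtype=np.int64)
    n, k = probs.shape
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    return -(probs.clamp_min(LOG_EPS).log() * Tensor(onehot)).sum() * (1.0 / n)


def combined_loss(probs, labels, batch: DomainBatch | None, lam: float,
                  kernel: KernelSpec = KernelSpec()) -> LossBundle:
    """Bundle ``L_cls + lam * MMD^2`` with all components reported."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    cls = cross_entropy(probs, labels)
    mmd = mmd_squared(batch, kernel) if batch is not None else 0.0
    return LossBundle(cls=cls, mmd=mmd, lam=lam)
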