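"""Full decoder: temporal branch, spatio-temporal convolutions, multi-scale
Riemannian branch, fusion classifier, and analytic complexity profiling.

Architecture summary (defaults follow the published structural table):

* TSLANet temporal stack (3 residual ASB+ICB layers, shape-preserving).
* Spatio-temporal branch: two same-padded temporal convolutions (F1=12,
  F2=24, kernel length 30), a full spatial collapse over channels, square
  activation, average pooling, log, dropout and batch normalisation — the
  square/log band-power trick of shallow EEG ConvNets.
* Riemannian branch: parallel 2-D convolutions (F3=4 filters each, kernel
  sizes 1x1/3x3/5x5 for 22-channel data, 1x1/2x2 for 3-channel) over the
  aligned covariance matrix, fused into a compact |kernels|*F3 projection.
* Classifier: fused features -> 128 -> ReLU -> dropout -> K-way softmax;
  the post-ReLU 128-d activations are the features the MMD loss aligns.

Several structural details are under-determined by the published table
(pool stride 15 vs an output length of T/75, the spectral-filter scope, the
ICB convolution type, how the Riemannian maps are flattened).  These are
explicit dials in :class:`ModelConfig`; :func:`reconcile_complexity` sweeps
the discrete dial grid against the published parameter/FLOP counts and the
winning grid point is the pinned default.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .autodiff import Tensor, concat
from . import nn
from .tslanet import TslanetNet

__all__ = [
    "ModelConfig",
    "FusedFeatures",
    "RMETNet",
    "count_parameters",
    "count_flops",
    "reconcile_complexity",
    "PUBLISHED_COMPLEXITY",
]

LOG_CLAMP = 1e-7

# Printed complexity of the reference architecture (M params / M FLOPs) used
# as the objective of the dial-reconciliation sweep.
PUBLISHED_COMPLEXITY = {
    "bciciv2a": {"params_m": 0.198, "flops_m": 421.681},
    "bciciv2b": {"params_m": 0.159, "flops_m": 57.752},
}


@dataclasses.dataclass
class ModelConfig:
    """All architecture hyperparameters, including the reconciliation dials."""

    C: int = 22
    T: int = 1000
    K: int = 4
    F1: int = 12
    F2: int = 24
    F3: int = 4
    K_E: int = 30
    pool_kernel: int = 75
    pool_stride: int = 75  # dial: 15 or 75; pinned by the sweep
    tslanet_layers: int = 3
    icb_kernels: tuple[int, int, int] = (2, 8, 4)
    icb_conv_type: str = "depthwise"  # dial: depthwise | full
    asb_filter_scope: str = "per_channel"  # dial: per_channel | scalar_per_bin
    d_model: int | None = None  # None => identity embedding, d_model = C
    riemannian_kernels: tuple[int, ...] | None = None  # None => by channel count
    riem_feature_mode: str = "pooled"  # dial: pooled (|k|*F3) | full_flatten
    riem_projection_width: int | None = None  # None => |kernels| * F3
    hidden_width: int = 128
    dropout: float = 0.5
    maxnorm: float = 2.0
    apply_log_alignment: bool = True

    def __post_init__(self):
        if self.riemannian_kernels is None:
            self.riemannian_kernels = (1, 3, 5) if self.C >= 8 else (1, 2)
        self.riemannian_kernels = tuple(self.riemannian_kernels)
        if self.K_E > self.T:
            raise ValueError("temporal kernel K_E exceeds T")
        if self.pool_kernel > self.T:
            raise ValueError("pool kernel exceeds T")
        if not self.riemannian_kernels:
            raise ValueError("riemannian_kernels must be non-empty")
        if max(self.riemannian_kernels) > self.C:
            raise ValueError("riemannian kernel larger than channel count")
        for name in ("C", "T", "K", "F1", "F2", "F3", "K_E", "pool_stride", "hidden_width"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def dm(self) -> int:
        return self.d_model or self.C

    @property
    def l_pool(self) -> int:
        return (self.T - self.pool_kernel) // self.pool_stride + 1

    @property
    def riem_width(self) -> int:
        return self.riem_projection_width or len(self.riemannian_kernels) * self.F3

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=list)

    @staticmethod
    def from_json(s: str) -> "ModelConfig":
        d = json.loads(s)
        d["icb_kernels"] = tuple(d["icb_kernels"])
        if d.get("riemannian_kernels") is not None:
            d["riemannian_kernels"] = tuple(d["riemannian_kernels"])
        return ModelConfig(**d)


def preset(name: str) -> ModelConfig:
    """Named architecture presets."""
    if name == "bciciv2a":
        return ModelConfig(C=22, T=1000, K=4)
    if name == "bciciv2b":
        return ModelConfig(C=3, T=1000, K=2, riemannian_kernels=(1, 2))
    if name == "synthetic-small":
        return ModelConfig(
            C=6, T=250, K=2, F1=6, F2=12, K_E=15, pool_kernel=25, pool_stride=25,
            tslanet_layers=1, hidden_width=64, riemannian_kernels=(1, 2),
        )
    raise ValueError(f"unknown preset {name!r}")


@dataclasses.dataclass
class FusedFeatures:
    """Forward-pass outputs: branch features, penultimate activations, probs."""

    st_features: np.ndarray
    riem_features: np.ndarray | None
    fused: Tensor  # post-ReLU penultimate activations (kept in the graph)
    logits: Tensor
    probs: Tensor


class SpatioTemporalBranch(nn.Module):
    """Temporal convs -> spatial collapse -> square -> pool -> log -> BN."""

    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.conv_t1 = nn.Conv2d(1, cfg.F1, (1, cfg.K_E), padding="same", rng=rng)
        self.conv_t2 = nn.Conv2d(cfg.F1, cfg.F2, (1, cfg.K_E), padding="same", rng=rng)
        self.conv_s = nn.Conv2d(cfg.F2, cfg.F2, (cfg.dm, 1), padding="valid", rng=rng)
        self.drop = nn.Dropout(cfg.dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.bn = nn.BatchNorm(cfg.F2)

    def __call__(self, x1d: Tensor) -> Tensor:
        b = x1d.shape[0]
        x = x1d.reshape(b, 1, x1d.shape[1], x1d.shape[2])
        x = self.conv_t2(self.conv_t1(x))
        x = self.conv_s(x)  # (b, F2, 1, T)
        x = x.reshape(b, self.cfg.F2, self.cfg.T) ** 2.0
        x = nn.avg_pool_last(x, self.cfg.pool_kernel, self.cfg.pool_stride)
        x = x.clamp_min(LOG_CLAMP).log()
        x = self.bn(self.drop(x))
        return x.reshape(b, self.cfg.F2 * self.cfg.l_pool)


class RiemannianBranch(nn.Module):
    """Multi-scale convolutions over the aligned covariance matrix.

    Parallel branches with F3 filters each (same padding for all but the
    last, which is valid).  In the pinned ``pooled`` mode each map is
    global-average-pooled to one value per filter before concatenation, so
    the concatenated width is |kernels|*F3; ``full_flatten`` keeps entire
    maps.  Either way a linear layer projects to ``riem_width``.
    """

    def __init__(self, cfg: ModelConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        ks = cfg.riemannian_kernels
        self.convs = [
            nn.Conv2d(1, cfg.F3, (k, k),
                      padding="same" if i < len(ks) - 1 else "valid", rng=rng)
            for i, k in enumerate(ks)
        ]
        self.proj = nn.Linear(self._flat_width(), cfg.riem_width, rng=rng)

    def _flat_width(self) -> int:
        cfg = self.cfg
        if cfg.riem_feature_mode == "pooled":
            return len(cfg.riemannian_kernels) * cfg.F3
        total = 0
        for i, k in enumerate(cfg.riemannian_kernels):
            side = cfg.C if i < len(cfg.riemannian_kernels) - 1 else cfg.C - k + 1
            total += cfg.F3 * side * side
        return total

    def __call__(self, covs: Tensor) -> Tensor:
        b = covs.shape[0]
        x = covs.reshape(b, 1, self.cfg.C, self.cfg.C)
        feats = []
        for conv in self.convs:
            m = conv(x)
            if self.cfg.riem_feature_mode == "pooled":
                feats.append(m.mean(axis=(2, 3)))
            else:
                feats.append(m.reshape(b, -1))
        return self.proj(concat(feats, axis=1))


class RMETNet(nn.Module):
    """The full two-branch decoder with a fusion classifier."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence((seed, 10)))
        self.cfg = cfg
        self.tslanet = TslanetNet(
            cfg.C, cfg.T, cfg.tslanet_layers, cfg.d_model, cfg.icb_kernels,
            cfg.asb_filter_scope, cfg.icb_conv_type, cfg.dropout, rng=rng,
        )
        self.st_branch = SpatioTemporalBranch(cfg, rng=rng)
        self.riem_branch = RiemannianBranch(cfg, rng=rng)
        fused_in = cfg.F2 * cfg.l_pool + cfg.riem_width
        base_in = cfg.F2 * cfg.l_pool
        self.fc_full = nn.Linear(fused_in, cfg.hidden_width, rng=rng)
        self.fc_base = nn.Linear(base_in, cfg.hidden_width, rng=rng)
        self.drop = nn.Dropout(cfg.dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.head = nn.Linear(cfg.hidden_width, cfg.K, rng=rng)

    def __call__(self, eeg, riem=None, mode: str = "full") -> FusedFeatures:
        if mode not in ("full", "base"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "full" and riem is None:
            raise ValueError("mode='full' requires aligned covariance inputs")
        x = Tensor.as_tensor(eeg)
        st = self.st_branch(self.tslanet(x))
        if mode == "full":
            rf = self.riem_branch(Tensor.as_tensor(riem))
            fused_in = concat([st, rf], axis=1)
            pre = self.fc_full(fused_in)
        else:
            rf = None
            pre = self.fc_base(st)
        fused = pre.relu()
        logits = self.head(self.drop(fused))
        probs = nn.softmax(logits)
        return FusedFeatures(
            st_features=st.data,
            riem_features=None if rf is None else rf.data,
            fused=fused,
            logits=logits,
            probs=probs,
        )

    def trainable_parameters(self, mode: str = "full"):
        """Parameters that receive gradients in the given mode."""
        skip = self.fc_base if mode == "full" else self.fc_full
        skip_ids = {id(p) for _, p in skip.named_parameters()}
        riem_ids = (
            {id(p) for _, p in self.riem_branch.named_parameters()} if mode == "base" else set()
        )
        return [p for p in self.parameters() if id(p) not in skip_ids | riem_ids]


# ---------------------------------------------------------------------------
# analytic complexity accounting


def count_parameters(cfg: ModelConfig, mode: str = "full") -> int:
    """Exact trainable-scalar count of the instantiated model.

    Complex spectral filters count two scalars per entry (stored as separate
    real/imaginary parts).  ``mode='full'`` counts the cross-subject model
    (fusion classifier + Riemannian branch); 'base' the subject-dependent one.
    """
    model = RMETNet(cfg)
    return sum(p.data.size for p in model.trainable_parameters(mode))


def conv2d_macs(cout: int, cin: int, kh: int, kw: int, ho: int, wo: int) -> int:
    """Multiply-accumulates of one stride-1 convolution from output shape."""
    return cout * cin * kh * kw * ho * wo


def linear_macs(d_in: int, d_out: int) -> int:
    return d_in * d_out


def count_flops(cfg: ModelConfig, convention: str = "mac_is_2",
                include_fft: bool = False, mode: str = "full") -> int:
    """Per-trial forward operation count, summed analytically from shapes.

    Counts multiply-accumulates of every convolution and linear layer (a MAC
    is 1 or 2 FLOPs per ``convention``); optionally adds ``5 n log2 n`` real
    operations per length-``n`` FFT/IFFT of the spectral blocks.
    """
    if convention not in ("mac_is_1", "mac_is_2"):
        raise ValueError(f"unknown convention {convention!r}")
    macs = 0
    d, t = cfg.dm, cfg.T
    # embedding (if any)
    if cfg.d_model is not None and cfg.d_model != cfg.C:
        macs += conv2d_macs(d, cfg.C, 1, 1, 1, t)
    # ICB convolutions per layer
    cin = 1 if cfg.icb_conv_type == "depthwise" else d
    for k in cfg.icb_kernels:
        macs += cfg.tslanet_layers * conv2d_macs(d, cin, 1, k, 1, t)
    # spatio-temporal branch
    macs += conv2d_macs(cfg.F1, 1, 1, cfg.K_E, d, t)
    macs += conv2d_macs(cfg.F2, cfg.F1, 1, cfg.K_E, d, t)
    macs += conv2d_macs(cfg.F2, cfg.F2, d, 1, 1, t)
    # riemannian branch
    ks = cfg.riemannian_kernels
    for i, k in enumerate(ks):
        side = cfg.C if i < len(ks) - 1 else cfg.C - k + 1
        macs += conv2d_macs(cfg.F3, 1, k, k, side, side)
    flat = RiemannianBranch(cfg)._flat_width()
    macs += linear_macs(flat, cfg.riem_width)
    # classifier
    macs += linear_macs(cfg.F2 * cfg.l_pool + cfg.riem_width, cfg.hidden_width)
    macs += linear_macs(cfg.hidden_width, cfg.K)
    flops = macs * (2 if convention == "mac_is_2" else 1)
    if include_fft:
        n_transforms = 2 * d * cfg.tslanet_layers  # forward + inverse per channel
        flops += int(n_transforms * 5 * t * np.log2(t))
    return int(flops)


def _dial_grid():
    for stride in (75, 15):
        for scope in ("per_channel", "scalar_per_bin"):
            for icb in ("depthwise", "full"):
                for riem in ("pooled", "full_flatten"):
                    yield {"pool_stride": stride, "asb_filter_scope": scope,
                           "icb_conv_type": icb, "riem_feature_mode": riem}


def reconcile_complexity() -> dict:
    """Sweep the discrete dial grid against the published complexity figures.

    For every grid point the 22-channel/4-class and 3-channel/2-class models
    are instantiated and their exact parameter counts compared with the
    published 0.198 M / 0.159 M.  Selection is lexicographic: a grid point is
    ranked first by how many published figures it *reproduces* at the printed
    precision (three decimals in millions) and only then by summed relative
    error — the sweep's purpose is reproduction, so an exact hit on one
    figure outranks any compromise that matches none.  The winning dials then
    fix the FLOP convention by the same rule over {MAC=1, MAC=2} x
    {FFT in/out} against 421.681 M / 57.752 M.  Returns the full sweep
    report; the selected point is asserted to be the module's pinned default.
    """

    def _score(values, published):
        hits = sum(round(v / 1e6, 3) == p for v, p in zip(values, published))
        rel = sum(abs(v / 1e6 - p) / p for v, p in zip(values, published))
        return (-hits, rel)

    pub_p = [PUBLISHED_COMPLEXITY["bciciv2a"]["params_m"],
             PUBLISHED_COMPLEXITY["bciciv2b"]["params_m"]]
    rows = []
    for dials in _dial_grid():
        p2a = count_parameters(ModelConfig(C=22, T=1000, K=4, **dials))
        p2b = count_parameters(ModelConfig(C=3, T=1000, K=2, riemannian_kernels=(1, 2), **dials))
        hits, rel = _score([p2a, p2b], pub_p)
        rows.append({**dials, "params_2a": p2a, "params_2b": p2b,
                     "exact_hits": -hits, "param_rel_err": rel})
    best = min(rows, key=lambda r: (-r["exact_hits"], r["param_rel_err"]))
    dials = {k: best[k] for k in ("pool_stride", "asb_filter_scope", "icb_conv_type",
                                  "riem_feature_mode")}
    pub_f = [PUBLISHED_COMPLEXITY["bciciv2a"]["flops_m"],
             PUBLISHED_COMPLEXITY["bciciv2b"]["flops_m"]]
    flop_rows = []
    for convention in ("mac_is_2", "mac_is_1"):
        for include_fft in (False, True):
            f2a = count_flops(ModelConfig(C=22, T=1000, K=4, **dials), convention, include_fft)
            f2b = count_flops(
                ModelConfig(C=3, T=1000, K=2, riemannian_kernels=(1, 2), **dials),
                convention, include_fft,
            )
            hits, rel = _score([f2a, f2b], pub_f)
            flop_rows.append({"convention": convention, "include_fft": include_fft,
                              "flops_2a": f2a, "flops_2b": f2b,
                              "exact_hits": -hits, "flop_rel_err": rel})
    best_flops = min(flop_rows, key=lambda r: (-r["exact_hits"], r["flop_rel_err"]))
    return {
        "grid": rows,
        "selected_dials": dials,
        "flop_grid": flop_rows,
        "selected_flop_convention": {k: best_flops[k] for k in ("convention", "include_fft")},
        "selected": {
            "params_2a": best["params_2a"],
            "params_2b": best["params_2b"],
            "flops_2a": best_flops["flops_2a"],
            "flops_2b": best_flops["flops_2b"],
        },
    }
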