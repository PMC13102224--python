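"""Temporal branch: residual layers of adaptive spectral filtering (ASB) and
gated interactive convolutions (ICB).

The ASB moves each feature channel to the frequency domain, gates spectral
bins by comparing the max-normalised power spectral density against a
learnable threshold theta (trained through a straight-through sigmoid
surrogate), applies learnable complex global/local filters to the raw and
gated spectra, and reconstructs a same-length time-domain signal.  The ICB
couples a short-kernel and a long-kernel convolution through GELU gating.
Each layer is wrapped in a residual connection, so a zeroed block is an exact
identity.

The forward/inverse real FFTs are expressed as fixed DFT matrix products so
gradients flow through the spectral filters with no special casing.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, ste_mask
from . import nn

__all__ = ["AdaptiveSpectralBlock", "InteractiveConvBlock", "TslanetLayer", "TslanetNet"]

_DFT_CACHE: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}


def dft_matrices(n: int):
    """Real-FFT analysis/synthesis matrices for length-``n`` signals.

    Returns (C, S, A, B) with F_re = x @ C, F_im = x @ S and
    x = F_re @ A + F_im @ B; exact inverses of one another.
    """
    if n not in _DFT_CACHE:
        k = np.arange(n // 2 + 1)
        t = np.arange(n)
        ang = 2.0 * np.pi * np.outer(t, k) / n
        cmat = np.cos(ang)  # (n, nf)
        smat = -np.sin(ang)
        alpha = np.full(k.size, 2.0)
        alpha[0] = 1.0
        if n % 2 == 0:
            alpha[-1] = 1.0
        amat = (alpha[:, None] * np.cos(ang.T)) / n  # (nf, n)
        bmat = (-alpha[:, None] * np.sin(ang.T)) / n
        _DFT_CACHE[n] = (cmat, smat, amat, bmat)
    return _DFT_CACHE[n]


class AdaptiveSpectralBlock(nn.Module):
    """FFT-domain filtering with a learnable threshold and dual complex filters.

    ``filter_scope``: 'per_channel' learns one complex weight per
    (channel, frequency bin); 'scalar_per_bin' shares weights across channels.
    Initialisation is near-identity: W_G = 1+0i, W_L = 0, theta ~ 0
    (all-pass mask), so an untrained block passes signals through unchanged.
    """

    def __init__(self, d_model: int, n_samples: int, filter_scope: str = "per_channel",
                 tau: float = 0.02):
        super().__init__()
        if filter_scope not in ("per_channel", "scalar_per_bin"):
            raise ValueError(f"unknown filter_scope {filter_scope!r}")
        nf = n_samples // 2 + 1
        shape = (d_model, nf) if filter_scope == "per_channel" else (1, nf)
        self.wg_re = nn.Parameter(np.ones(shape))
        self.wg_im = nn.Parameter(np.zeros(shape))
        self.wl_re = nn.Parameter(np.zeros(shape))
        self.wl_im = nn.Parameter(np.zeros(shape))
        self.theta_raw = nn.Parameter(np.array(-6.0))  # sigmoid(-6) ~ 0.0025
        self.n_samples = n_samples
        self.filter_scope = filter_scope
        self.tau = tau

    @property
    def theta(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.theta_raw.data)))

    def __call__(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite input to adaptive spectral block")
        if x.shape[-1] != self.n_samples:
            raise ValueError(
                f"sequence length {x.shape[-1]} does not match configured {self.n_samples}"
            )
        cmat, smat, amat, bmat = dft_matrices(self.n_samples)
        f_re = x @ Tensor(cmat)
        f_im = x @ Tensor(smat)
        psd = f_re**2 + f_im**2
        # scale-free threshold: normalise PSD by its per-sample maximum
        peak = psd.data.max(axis=(1, 2), keepdims=True)
        p_norm = psd * Tensor(1.0 / np.maximum(peak, 1e-300))
        theta = (1.0 + (-self.theta_raw).exp()) ** -1.0
        mask = ste_mask(p_norm, theta, tau=self.tau)
        ff_re = f_re * mask
        ff_im = f_im * mask
        # complex products W_G . F + W_L . F_filtered
        fi_re = self.wg_re * f_re - self.wg_im * f_im + self.wl_re * ff_re - self.wl_im * ff_im
        fi_im = self.wg_re * f_im + self.wg_im * f_re + self.wl_re * ff_im + self.wl_im * ff_re
        return fi_re @ Tensor(amat) + fi_im @ Tensor(bmat)


class InteractiveConvBlock(nn.Module):
    """Two gated parallel convolutions fused by a third.

    ``A1 = GELU(conv1(x)) * conv2(x)``, ``A2 = GELU(conv2(x)) * conv1(x)``,
    output ``conv3(dropout(A1 + A2))``; same-length padding throughout.
    ``conv_type='depthwise'`` uses per-channel kernels (the pinned default of
    the complexity reconciliation); 'full' mixes channels.
    """

    def __init__(self, d_model: int, kernels=(2, 8, 4), conv_type: str = "depthwise",
                 dropout: float = 0.5, n_samples: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if n_samples is not None and max(kernels) > n_samples:
            raise ValueError(f"ICB kernel {max(kernels)} longer than sequence {n_samples}")
        rng = rng or np.random.default_rng(0)
        if conv_type == "depthwise":
            make = lambda k: nn.DepthwiseConv1d(d_model, k, rng=rng)
        elif conv_type == "full":
            make = lambda k: _FullConv1d(d_model, d_model, k, rng=rng)
        else:
            raise ValueError(f"unknown conv_type {conv_type!r}")
        k1, k2, k3 = kernels
        self.conv1 = make(k1)
        self.conv2 = make(k2)
        self.conv3 = make(k3)
        self.drop = nn.Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def __call__(self, x: Tensor) -> Tensor:
        c1 = self.conv1(x)
        c2 = self.conv2(x)
        gated = c1.gelu() * c2 + c2.gelu() * c1
        return self.conv3(self.drop(gated))


class _FullConv1d(nn.Module):
    """Channel-mixing 1-D convolution along time (same padding)."""

    def __init__(self, in_ch, out_ch, kernel, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, (1, kernel), padding="same", rng=rng)

    @property
    def weight(self):
        return self.conv.weight

    @property
    def bias(self):
        return self.conv.bias

    def __call__(self, x: Tensor) -> Tensor:
        y = x.reshape(x.shape[0], x.shape[1], 1, x.shape[2])
        y = self.conv(y)
        return y.reshape(y.shape[0], y.shape[1], y.shape[3])


class TslanetLayer(nn.Module):
    """Residual layer: ``x + LN(ICB(LN(ASB(x))))``."""

    def __init__(self, d_model, n_samples, icb_kernels=(2, 8, 4),
                 filter_scope="per_channel", icb_conv_type="depthwise",
                 dropout=0.5, rng=None):
        super().__init__()
        self.asb = AdaptiveSpectralBlock(d_model, n_samples, filter_scope)
        self.norm1 = nn.LayerNorm(d_model)
        self.icb = InteractiveConvBlock(
            d_model, icb_kernels, icb_conv_type, dropout, n_samples, rng=rng
        )
        self.norm2 = nn.LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        return x + self.norm2(self.icb(self.norm1(self.asb(x))))


class TslanetNet(nn.Module):
    """Stack of residual ASB+ICB layers with an optional pointwise embedding.

    By default ``d_model`` equals the channel count and the embedding is the
    identity, so the stack preserves the (batch, C, T) layout end to end.
    """

    def __init__(self, n_channels, n_samples, n_layers=3, d_model=None,
                 icb_kernels=(2, 8, 4), filter_scope="per_channel",
                 icb_conv_type="depthwise", dropout=0.5, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.d_model = d_model or n_channels
        self.embed = None
        if self.d_model != n_channels:
            self.embed = _FullConv1d(n_channels, self.d_model, 1, rng=rng)
        self.layers = [
            TslanetLayer(self.d_model, n_samples, icb_kernels, filter_scope,
                         icb_conv_type, dropout, rng=rng)
            for _ in range(n_layers)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        if self.embed is not None:
            x = self.embed(x)
        for layer in self.layers:
            x = layer(x)
        return x
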