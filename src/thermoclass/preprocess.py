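"""Image conditioning chain for thermograms.

Four stages, applied in order before feature extraction:

1. histogram statistics and plain histogram equalization — each pixel is
   remapped to the cumulative distribution value of its intensity bin,
   p_i = n_i / N,  cdf(i) = sum_{j<=i} p_j;
2. double-exponential histogram equalization (DEHE) — the equalized value
   is pushed through a symmetric double-exponential curve that stretches
   both the dark and the bright ends of the range;
3. anisotropic (Perona–Malik) diffusion — iterative PDE smoothing
   dI/dt = div(c(|∇I|) ∇I) with conductance c(g) = exp(−g²/k²), so flat
   regions are denoised while strong edges are preserved;
4. proportionate adaptive filtering — a range-weighted neighborhood
   average W(u,v) = exp(−(I(u,v)−I(x,y))²/(2σ²)) that sharpens local
   structure without smearing hotspot boundaries.

All operations take and return :class:`~thermoclass.image.Thermogram`
objects with intensities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import Thermogram


# --------------------------------------------------------------------------
# histogram statistics and equalization

@dataclass
class HistogramStats:
    """Normalized intensity histogram of a thermogram.

    ``p`` are per-bin probabilities n_i/N over ``n_bins`` equal-width bins
    on [0, 1]; ``cdf`` is their running sum (non-decreasing, ending at 1).
    """

    counts: np.ndarray
    p: np.ndarray
    cdf: np.ndarray
    n_bins: int
    n_pixels: int

    def __post_init__(self) -> None:
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")
        if np.any(np.diff(self.cdf) < -1e-12):
            raise ValueError("cdf must be non-decreasing")
        if abs(self.cdf[-1] - 1.0) > 1e-9:
            raise ValueError("cdf must end at 1")


def _bin_index(pixels: np.ndarray, n_bins: int) -> np.ndarray:
    """Bin assignment on [0,1]; the value 1.0 belongs to the last bin."""
    idx = np.floor(pixels * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def intensity_histogram(img: Thermogram, n_bins: int = 256) -> HistogramStats:
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if img.pixels.size == 0:
        raise ValueError("empty image")
    counts = np.bincount(_bin_index(img.pixels, n_bins).ravel(), minlength=n_bins)
    n = img.pixels.size
    p = counts / n
    return HistogramStats(counts=counts, p=p, cdf=np.cumsum(p), n_bins=n_bins, n_pixels=n)


def equalize_histogram(img: Thermogram, n_bins: int = 256) -> Thermogram:
    """Map each pixel to the cdf of its intensity bin.

    Spreads intensities toward a uniform distribution; rank order of
    distinct values is preserved because the cdf is non-decreasing.
    """
    stats = intensity_histogram(img, n_bins)
    out = stats.cdf[_bin_index(img.pixels, n_bins)]
    return img.with_pixels(np.clip(out, 0.0, 1.0))


def double_exponential_remap(u: np.ndarray, alpha: float) -> np.ndarray:
    """Symmetric double-exponential contrast curve on [0, 1].

    g(u) = (1 − exp(−2 α u)) / (2 (1 − exp(−α)))   for u ≤ 1/2,
    g(u) = 1 − g(1 − u)                            for u > 1/2.

    Anchored at g(0)=0, g(1/2)=1/2, g(1)=1 and monotone for any α>0; the
    steep initial slope on each half stretches both dark and bright tails.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    u = np.asarray(u, dtype=np.float64)
    lower = 0.5 * (1.0 - np.exp(-2.0 * alpha * np.minimum(u, 0.5))) / (1.0 - np.exp(-alpha))
    upper = 1.0 - 0.5 * (1.0 - np.exp(-2.0 * alpha * np.minimum(1.0 - u, 0.5))) / (1.0 - np.exp(-alpha))
    return np.where(u <= 0.5, lower, upper)


def double_exponential_equalize(img: Thermogram, alpha: float = 2.0,
                                n_bins: int = 256) -> Thermogram:
    """Histogram equalization followed by the double-exponential remap (DEHE)."""
    stats = intensity_histogram(img, n_bins)
    u = stats.cdf[_bin_index(img.pixels, n_bins)]
    return img.with_pixels(np.clip(double_exponential_remap(u, alpha), 0.0, 1.0))


# --------------------------------------------------------------------------
# anisotropic diffusion

@dataclass(frozen=True)
class DiffusionConfig:
    """Perona–Malik parameters.

    ``k`` is the edge-sensitivity scale in normalized intensity units:
    gradients well below k diffuse freely, gradients above k are treated
    as edges and preserved.  ``dt`` must satisfy the explicit-scheme
    stability bound dt ≤ 1/4 for a 4-neighbor stencil.
    """

    k: float = 0.1
    n_iterations: int = 15
    dt: float = 0.2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be non-negative")
        if not (0.0 < self.dt <= 0.25):
            raise ValueError("dt must lie in (0, 0.25] for stability")


def diffusion_coefficient(grad_mag: np.ndarray | float, k: float) -> np.ndarray | float:
    """Edge-stopping conductance c(g) = exp(−g²/k²) ∈ (0, 1]."""
    if k <= 0:
        raise ValueError("k must be positive")
    g = np.asarray(grad_mag, dtype=np.float64)
    out = np.exp(-(g * g) / (k * k))
    return out if out.ndim else float(out)


def anisotropic_diffusion(img: Thermogram, cfg: DiffusionConfig = DiffusionConfig()) -> Thermogram:
    """Explicit 4-neighbor Perona–Malik iteration with reflecting borders.

    Per step each pixel receives dt · Σ_d c(|δ_d|) δ_d over the four
    directional differences δ_d.  The conductance is symmetric in the pair
    of neighbors, so total intensity is conserved exactly, and with
    dt ≤ 1/4 the update is a convex combination: the global maximum cannot
    increase nor the minimum decrease.
    """
    I = img.pixels.copy()
    k = cfg.k
    for _ in range(cfg.n_iterations):
        # directional differences with Neumann (zero-flux) borders
        dN = np.zeros_like(I); dN[1:, :] = I[:-1, :] - I[1:, :]
        dS = np.zeros_like(I); dS[:-1, :] = I[1:, :] - I[:-1, :]
        dW = np.zeros_like(I); dW[:, 1:] = I[:, :-1] - I[:, 1:]
        dE = np.zeros_like(I); dE[:, :-1] = I[:, 1:] - I[:, :-1]
        flux = (diffusion_coefficient(np.abs(dN), k) * dN
                + diffusion_coefficient(np.abs(dS), k) * dS
                + diffusion_coefficient(np.abs(dW), k) * dW
                + diffusion_coefficient(np.abs(dE), k) * dE)
        I = I + cfg.dt * flux
    return img.with_pixels(np.clip(I, 0.0, 1.0))


# --------------------------------------------------------------------------
# proportionate adaptive (range-bilateral) filtering

@dataclass(frozen=True)
class AdaptiveFilterConfig:
    """Range-filter parameters: σ is the intensity-difference scale, radius
    the neighborhood half-width (window side = 2·radius + 1)."""

    sigma: float = 0.1
    radius: int = 1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.radius < 1:
            raise ValueError("radius must be at least 1")


def proportionate_adaptive_filter(img: Thermogram,
                                  cfg: AdaptiveFilterConfig = AdaptiveFilterConfig()) -> Thermogram:
    """Weighted neighborhood average with intensity-similarity weights.

    Output(x,y) = Σ W(u,v) I(u,v) / Σ W(u,v) over the (2r+1)² reflected
    window, with W(u,v) = exp(−(I(u,v)−I(x,y))²/(2σ²)).  The center pixel
    always carries weight 1, so Σ W > 0 and every output value is a convex
    combination of its neighborhood.
    """
    I = img.pixels
    r = cfg.radius
    padded = np.pad(I, r, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (2 * r + 1, 2 * r + 1))
    diff = windows - I[:, :, None, None]
    W = np.exp(-(diff * diff) / (2.0 * cfg.sigma ** 2))
    out = (W * windows).sum(axis=(2, 3)) / W.sum(axis=(2, 3))
    return img.with_pixels(np.clip(out, 0.0, 1.0))


# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    """End-to-end conditioning configuration."""

    equalization: str = "dehe"  # "none" | "histogram" | "dehe"
    dehe_alpha: float = 2.0
    n_bins: int = 256
    diffusion: DiffusionConfig = DiffusionConfig()
    adaptive: AdaptiveFilterConfig = AdaptiveFilterConfig()


def preprocess(img: Thermogram, cfg: PreprocessConfig = PreprocessConfig()) -> Thermogram:
    """Run the full chain: equalize → diffuse → adaptive filter."""
    out = img
    if cfg.equalization == "histogram":
        out = equalize_histogram(out, cfg.n_bins)
    elif cfg.equalization == "dehe":
        out = double_exponential_equalize(out, cfg.dehe_alpha, cfg.n_bins)
    elif cfg.equalization != "none":
        raise ValueError(f"unknown equalization mode {cfg.equalization!r}")
    out = anisotropic_diffusion(out, cfg.diffusion)
    out = proportionate_adaptive_filter(out, cfg.adaptive)
    return out
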