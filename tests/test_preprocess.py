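"""Conditioning chain: histogram stats, DEHE, diffusion, adaptive filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoclass.image import Thermogram, to_grayscale
from thermoclass.preprocess import (AdaptiveFilterConfig, DiffusionConfig,
                                    anisotropic_diffusion, diffusion_coefficient,
                                    double_exponential_equalize,
                                    double_exponential_remap, equalize_histogram,
                                    intensity_histogram,
                                    proportionate_adaptive_filter)


# --------------------------------------------------------------------------
# grayscale

def test_grayscale_constant_and_zero_passthrough():
    v = 0.42
    rgb = np.full((4, 5, 3), v)
    assert np.allclose(to_grayscale(rgb).pixels, v)
    assert np.allclose(to_grayscale(np.zeros((3, 3, 3))).pixels, 0.0)


def test_grayscale_green_weight():
    rgb = np.zeros((1, 1, 3))
    rgb[0, 0, 1] = 1.0
    assert to_grayscale(rgb).pixels[0, 0] == pytest.approx(0.587)


def test_grayscale_rejects_wrong_channel_count():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 4, 2)))


# --------------------------------------------------------------------------
# histogram statistics and equalization

def test_histogram_counting_oracle():
    img = Thermogram(np.array([[0.0, 0.0], [0.5, 1.0]]))
    stats = intensity_histogram(img, n_bins=4)
    assert np.allclose(stats.p, [0.5, 0.0, 0.25, 0.25])
    assert np.allclose(stats.cdf, [0.5, 0.5, 0.75, 1.0])
    assert stats.n_pixels == 4


def test_histogram_constant_image_single_bin():
    stats = intensity_histogram(Thermogram(np.full((5, 5), 0.3)), n_bins=10)
    assert stats.p[3] == 1.0 and stats.p.sum() == 1.0


@settings(deadline=None, max_examples=100)
@given(st.integers(0, 10_000))
def test_histogram_normalization_property(seed):
    g = np.random.default_rng(seed)
    img = Thermogram(g.random((8, 8)))
    stats = intensity_histogram(img, n_bins=16)
    assert abs(stats.p.sum() - 1.0) < 1e-9
    assert np.all(np.diff(stats.cdf) >= -1e-12)
    assert abs(stats.cdf[-1] - 1.0) < 1e-9


def test_equalize_counting_oracle():
    img = Thermogram(np.array([[0.0, 0.0], [0.5, 1.0]]))
    out = equalize_histogram(img, n_bins=4)
    assert np.allclose(out.pixels, [[0.5, 0.5], [0.75, 1.0]])


def test_equalize_constant_image_maps_to_one():
    out = equalize_histogram(Thermogram(np.full((4, 4), 0.2)), n_bins=8)
    assert np.allclose(out.pixels, 1.0)


def test_equalize_preserves_rank_order(random_image):
    out = equalize_histogram(random_image, 64)
    a = random_image.pixels.ravel()
    b = out.pixels.ravel()
    order = np.argsort(a, kind="stable")
    assert np.all(np.diff(b[order]) >= -1e-12)


def test_equalize_idempotent_up_to_quantization(random_image):
    n_bins = 64
    once = equalize_histogram(random_image, n_bins)
    twice = equalize_histogram(once, n_bins)
    assert np.max(np.abs(twice.pixels - once.pixels)) <= 1.0 / n_bins + 1e-12


# --------------------------------------------------------------------------
# DEHE

@pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0, 5.0])
def test_dehe_remap_anchors_and_midpoint(alpha):
    g = double_exponential_remap(np.array([0.0, 0.5, 1.0]), alpha)
    assert g[0] == pytest.approx(0.0, abs=1e-12)
    assert g[1] == pytest.approx(0.5, abs=1e-12)
    assert g[2] == pytest.approx(1.0, abs=1e-12)


def test_dehe_remap_monotone():
    u = np.linspace(0, 1, 201)
    g = double_exponential_remap(u, 2.0)
    assert np.all(np.diff(g) >= -1e-12)


def test_dehe_monotone_ramp_stays_monotone():
    ramp = np.tile(np.linspace(0, 1, 32), (4, 1))
    out = double_exponential_equalize(Thermogram(ramp), alpha=2.0, n_bins=32)
    assert np.all(np.diff(out.pixels[0]) >= -1e-12)


def test_dehe_rejects_nonpositive_alpha():
    with pytest.raises(ValueError):
        double_exponential_remap(np.array([0.5]), 0.0)


# --------------------------------------------------------------------------
# anisotropic diffusion

def test_conductance_analytic_values():
    assert diffusion_coefficient(0.0, k=0.1) == pytest.approx(1.0)
    assert diffusion_coefficient(0.1, k=0.1) == pytest.approx(np.exp(-1.0))
    g = np.linspace(0, 1, 50)
    c = diffusion_coefficient(g, k=0.2)
    assert np.all(np.diff(c) < 0)
    with pytest.raises(ValueError):
        diffusion_coefficient(0.5, k=0.0)


def test_diffusion_constant_image_unchanged():
    img = Thermogram(np.full((8, 8), 0.6))
    out = anisotropic_diffusion(img, DiffusionConfig(k=0.1, n_iterations=10, dt=0.2))
    assert np.allclose(out.pixels, 0.6)


def test_diffusion_zero_iterations_is_identity(random_image):
    out = anisotropic_diffusion(random_image, DiffusionConfig(n_iterations=0))
    assert np.array_equal(out.pixels, random_image.pixels)


def diffusion_step_oracle(I, k, dt):
    """Straight-loop single Perona-Malik step with zero-flux borders."""
    h, w = I.shape
    out = I.copy()
    for r in range(h):
        for c in range(w):
            flux = 0.0
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    d = I[rr, cc] - I[r, c]
                    flux += np.exp(-(d / k) ** 2) * d
            out[r, c] = I[r, c] + dt * flux
    return out


def test_diffusion_single_step_matches_loop_oracle():
    I = np.zeros((3, 3))
    I[1, 1] = 0.8
    cfg = DiffusionConfig(k=0.3, n_iterations=1, dt=0.2)
    out = anisotropic_diffusion(Thermogram(I), cfg)
    assert np.allclose(out.pixels, diffusion_step_oracle(I, 0.3, 0.2), atol=1e-12)


def test_diffusion_extremum_principle_and_conservation(rng):
    cfg = DiffusionConfig(k=0.1, n_iterations=1, dt=0.25)
    for _ in range(20):
        I = rng.random((16, 16))
        total0 = I.sum()
        cur = Thermogram(I)
        prev_max, prev_min = I.max(), I.min()
        for _ in range(10):
            cur = anisotropic_diffusion(cur, cfg)
            assert cur.pixels.max() <= prev_max + 1e-12
            assert cur.pixels.min() >= prev_min - 1e-12
            prev_max, prev_min = cur.pixels.max(), cur.pixels.min()
        assert abs(cur.pixels.sum() - total0) / total0 < 1e-6


def test_diffusion_rejects_unstable_dt():
    with pytest.raises(ValueError):
        DiffusionConfig(dt=0.3)


# --------------------------------------------------------------------------
# proportionate adaptive filter

def test_adaptive_filter_constant_unchanged():
    img = Thermogram(np.full((6, 6), 0.4))
    out = proportionate_adaptive_filter(img, AdaptiveFilterConfig(sigma=0.1, radius=2))
    assert np.allclose(out.pixels, 0.4)


def adaptive_filter_oracle(I, sigma, radius):
    """Direct double-loop weighted average with reflect padding."""
    P = np.pad(I, radius, mode="reflect")
    out = np.zeros_like(I)
    h, w = I.shape
    for r in range(h):
        for c in range(w):
            num = den = 0.0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    v = P[r + radius + dr, c + radius + dc]
                    wgt = np.exp(-((v - I[r, c]) ** 2) / (2 * sigma ** 2))
                    num += wgt * v
                    den += wgt
            out[r, c] = num / den
    return out


def test_adaptive_filter_matches_loop_oracle(rng):
    I = rng.random((3, 3))
    cfg = AdaptiveFilterConfig(sigma=0.1, radius=1)
    out = proportionate_adaptive_filter(Thermogram(I), cfg)
    assert np.allclose(out.pixels, adaptive_filter_oracle(I, 0.1, 1), atol=1e-12)


def test_adaptive_filter_is_convex_combination(rng):
    I = rng.random((12, 12))
    r = 2
    out = proportionate_adaptive_filter(Thermogram(I), AdaptiveFilterConfig(sigma=0.05, radius=r))
    P = np.pad(I, r, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(P, (2 * r + 1, 2 * r + 1))
    assert np.all(out.pixels >= win.min(axis=(2, 3)) - 1e-12)
    assert np.all(out.pixels <= win.max(axis=(2, 3)) + 1e-12)


def test_adaptive_filter_config_validation():
    with pytest.raises(ValueError):
        AdaptiveFilterConfig(sigma=0.0)
    with pytest.raises(ValueError):
        AdaptiveFilterConfig(radius=0)
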