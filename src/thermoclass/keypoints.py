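"""Scale-space keypoint detection and local descriptors.

Keypoints are extrema of a difference-of-Gaussians (DoG) pyramid — image
locations that stand out from their surroundings at some blur scale, e.g.
the center of a warm focal spot in a thermogram.  Two descriptor kinds are
provided for the patch around a keypoint:

* ``histogram`` — gradient-orientation histograms over a grid of
  subregions of the orientation-aligned patch, concatenated and
  L2-normalized (the classic SIFT construction, here with a configurable
  subregion layout defaulting to 8 subregions);
* ``binary`` — an integer code Σ 2^i · [I(p_i) > I(q_i)] assembled from
  intensity comparisons at fixed offset pairs around the keypoint
  (a BRIEF-style binary test pattern).

Both are deterministic functions of the image and keypoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Thermogram


@dataclass(frozen=True)
class Keypoint:
    """A scale-space interest point.

    ``x``/``y`` are sub-pixel column/row coordinates in the original image,
    ``scale`` the blur sigma (pixels) at which the DoG extremum occurred,
    ``orientation`` the dominant local gradient direction in radians, and
    ``response`` the absolute DoG value (extremum strength).
    """

    x: float
    y: float
    scale: float
    orientation: float = 0.0
    response: float = 0.0


@dataclass
class Descriptor:
    """Local appearance summary of a keypoint neighborhood."""

    values: np.ndarray | None  # histogram kind: unit-norm float vector
    code: int | None = None    # binary kind: integer in [0, 2^n)
    kind: str = "histogram"
    degenerate: bool = False


# --------------------------------------------------------------------------
# detection

def detect_keypoints(img: Thermogram, n_octaves: int = 3, n_scales: int = 3,
                     contrast_threshold: float = 0.02,
                     edge_ratio: float = 10.0, base_sigma: float = 1.6) -> list[Keypoint]:
    """Find DoG extrema with sub-pixel refinement.

    Per octave, a stack of progressively blurred images is differenced and
    each interior voxel is compared against its 26 scale-space neighbors;
    surviving extrema must exceed ``contrast_threshold`` in absolute DoG
    value and pass the principal-curvature (edge) ratio test.  A quadratic
    fit to the local DoG refines the spatial position.
    """
    if img.pixels.shape[0] < 16 or img.pixels.shape[1] < 16:
        raise ValueError("image must be at least 16x16 for keypoint detection")
    base = img.pixels
    if min(base.shape) // (2 ** (n_octaves - 1)) < 8:
        raise ValueError("image too small for the requested number of octaves")

    keypoints: list[Keypoint] = []
    octave_img = base
    for octave in range(n_octaves):
        sigmas = [base_sigma * 2.0 ** (i / n_scales) for i in range(n_scales + 2)]
        gauss = [ndimage.gaussian_filter(octave_img, s, mode="reflect") for s in sigmas]
        dog = np.stack([gauss[i + 1] - gauss[i] for i in range(len(gauss) - 1)])

        maxf = ndimage.maximum_filter(dog, size=3, mode="nearest")
        minf = ndimage.minimum_filter(dog, size=3, mode="nearest")
        interior = np.zeros_like(dog, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        is_ext = interior & (np.abs(dog) > contrast_threshold) & ((dog == maxf) | (dog == minf))

        for s_idx, r, c in zip(*np.nonzero(is_ext)):
            patch = dog[s_idx]
            # principal-curvature ratio test on the 2-D Hessian
            dxx = patch[r, c + 1] + patch[r, c - 1] - 2 * patch[r, c]
            dyy = patch[r + 1, c] + patch[r - 1, c] - 2 * patch[r, c]
            dxy = 0.25 * (patch[r + 1, c + 1] - patch[r + 1, c - 1]
                          - patch[r - 1, c + 1] + patch[r - 1, c - 1])
            tr, det = dxx + dyy, dxx * dyy - dxy * dxy
            if det <= 0 or tr * tr / det >= (edge_ratio + 1) ** 2 / edge_ratio:
                continue
            # sub-pixel offset from the quadratic model (spatial only)
            gx = 0.5 * (patch[r, c + 1] - patch[r, c - 1])
            gy = 0.5 * (patch[r + 1, c] - patch[r - 1, c])
            denom = dxx * dyy - dxy * dxy
            off_x = -(dyy * gx - dxy * gy) / denom
            off_y = -(dxx * gy - dxy * gx) / denom
            if abs(off_x) > 1.0 or abs(off_y) > 1.0:
                off_x = off_y = 0.0
            scale = sigmas[s_idx] * (2.0 ** octave)
            kx = (c + off_x) * (2.0 ** octave)
            ky = (r + off_y) * (2.0 ** octave)
            if not (0 <= kx <= base.shape[1] - 1 and 0 <= ky <= base.shape[0] - 1):
                continue
            ori = _dominant_orientation(gauss[s_idx], r, c, sigmas[s_idx])
            keypoints.append(Keypoint(x=kx, y=ky, scale=scale,
                                      orientation=ori,
                                      response=float(abs(patch[r, c]))))
        octave_img = gauss[n_scales][::2, ::2]

    keypoints.sort(key=lambda k: (-k.response, k.y, k.x))
    return keypoints


def _dominant_orientation(gauss: np.ndarray, r: int, c: int, sigma: float,
                          n_bins: int = 36) -> float:
    """Peak of the Gaussian-weighted gradient-orientation histogram."""
    rad = max(int(round(3 * sigma)), 2)
    r0, r1 = max(r - rad, 1), min(r + rad + 1, gauss.shape[0] - 1)
    c0, c1 = max(c - rad, 1), min(c + rad + 1, gauss.shape[1] - 1)
    region = gauss[r0 - 1:r1 + 1, c0 - 1:c1 + 1]
    gy, gx = np.gradient(region)
    gy, gx = gy[1:-1, 1:-1], gx[1:-1, 1:-1]
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % (2 * np.pi)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    w = np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * (1.5 * sigma) ** 2))
    hist = np.zeros(n_bins)
    bins = np.minimum((ang / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    np.add.at(hist, bins.ravel(), (mag * w).ravel())
    if hist.sum() == 0:
        return 0.0
    return (np.argmax(hist) + 0.5) * 2 * np.pi / n_bins


# --------------------------------------------------------------------------
# histogram (SIFT-style) descriptor

def _sample_rotated_patch(pixels: np.ndarray, kp: Keypoint, grid: int,
                          spacing: float) -> np.ndarray:
    """Bilinear sample of a grid×grid patch rotated by the keypoint orientation."""
    half = (grid - 1) / 2.0
    u = (np.arange(grid) - half) * spacing
    uu, vv = np.meshgrid(u, u, indexing="xy")  # vv rows, uu cols in patch frame
    ct, st = math.cos(kp.orientation), math.sin(kp.orientation)
    xs = kp.x + ct * uu - st * vv
    ys = kp.y + st * uu + ct * vv
    return ndimage.map_coordinates(pixels, [ys, xs], order=1, mode="reflect")


def sift_descriptor(img: Thermogram, kp: Keypoint, n_subregions: int = 8,
                    n_orientation_bins: int = 8, grid: int = 16,
                    spacing_factor: float = 1.0) -> Descriptor:
    """Orientation-compensated gradient-orientation-histogram descriptor.

    The patch around the keypoint is resampled on a grid rotated by the
    keypoint orientation (sample spacing proportional to scale), gradients
    are computed in the rotated frame, and per-subregion orientation
    histograms are concatenated and L2-normalized.  ``n_subregions`` must
    be 8 (2×4 layout) or a perfect square (e.g. 16 → 4×4).
    """
    if n_subregions == 8:
        rows, cols = 2, 4
    else:
        side = int(round(math.sqrt(n_subregions)))
        if side * side != n_subregions:
            raise ValueError("n_subregions must be 8 or a perfect square")
        rows = cols = side
    if grid % rows or grid % cols:
        raise ValueError("grid size must be divisible by the subregion layout")

    patch = _sample_rotated_patch(img.pixels, kp, grid, spacing_factor * max(kp.scale, 1.0))
    gy, gx = np.gradient(patch)
    mag = np.hypot(gx, gy)
    ang = np.arctan2(gy, gx) % (2 * np.pi)
    bins = np.minimum((ang / (2 * np.pi) * n_orientation_bins).astype(int),
                      n_orientation_bins - 1)

    desc = np.zeros(rows * cols * n_orientation_bins)
    rh, cw = grid // rows, grid // cols
    for i in range(rows):
        for j in range(cols):
            sub = slice(i * rh, (i + 1) * rh), slice(j * cw, (j + 1) * cw)
            np.add.at(desc, (i * cols + j) * n_orientation_bins + bins[sub].ravel(),
                      mag[sub].ravel())
    norm = np.linalg.norm(desc)
    if norm < 1e-12:
        return Descriptor(values=desc, kind="histogram", degenerate=True)
    return Descriptor(values=desc / norm, kind="histogram")


# --------------------------------------------------------------------------
# binary-test descriptor

def radial_offsets(n: int, radius: float = 4.0) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """n test pairs comparing a point at angle 2πi/n, distance ``radius``,
    against the keypoint center."""
    out = []
    for i in range(n):
        theta = 2 * np.pi * i / n
        out.append(((radius * math.sin(theta), radius * math.cos(theta)), (0.0, 0.0)))
    return out


def binary_descriptor(img: Thermogram, kp: Keypoint, n: int,
                      offsets: list[tuple[tuple[float, float], tuple[float, float]]] | None = None,
                      ) -> Descriptor:
    """Integer code from pairwise intensity tests: bit i set iff the first
    point of pair i is strictly brighter than the second.

    Offsets are (dy, dx) pairs relative to the keypoint; points falling
    outside the image are reflected at the border.
    """
    if n > 30:
        raise ValueError("binary descriptor supports at most 30 tests")
    if offsets is None:
        offsets = radial_offsets(n)
    if len(offsets) != n:
        raise ValueError("offsets length must equal n")

    h, w = img.pixels.shape

    def sample(dy: float, dx: float) -> float:
        r = int(round(kp.y + dy))
        c = int(round(kp.x + dx))
        # reflect out-of-range indices back into the image
        r = int(np.abs(r)) if r < 0 else r
        c = int(np.abs(c)) if c < 0 else c
        if r >= h:
            r = 2 * (h - 1) - r
        if c >= w:
            c = 2 * (w - 1) - c
        return float(img.pixels[np.clip(r, 0, h - 1), np.clip(c, 0, w - 1)])

    code = 0
    for i, ((dy1, dx1), (dy2, dx2)) in enumerate(offsets):
        if sample(dy1, dx1) > sample(dy2, dx2):
            code |= 1 << i
    return Descriptor(values=None, code=code, kind="binary")
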