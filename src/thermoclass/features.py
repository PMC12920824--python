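"""First-order statistics, co-occurrence texture, and per-image feature vectors.

The per-image feature vector concatenates:

* eight first-order statistics of the intensity distribution (mean,
  variance, standard deviation, max, min, histogram entropy, excess
  kurtosis, skewness);
* the gray-level co-occurrence matrix (GLCM) correlation, averaged over
  the four standard offsets — how strongly a pixel's quantized intensity
  predicts its neighbor's;
* the number of scale-space keypoints and the mean of their histogram
  descriptors.

Degenerate quantities (e.g. skewness of a constant image, correlation of
a single-level GLCM) are flagged, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix

from .image import Thermogram
from .keypoints import detect_keypoints, sift_descriptor
from .preprocess import intensity_histogram

#: Default GLCM offsets: distance 1 at the four standard angles.
DEFAULT_GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


# --------------------------------------------------------------------------
# GLCM

@dataclass
class GLCMatrix:
    """Normalized co-occurrence probabilities p(i, j) over quantized levels."""

    p: np.ndarray
    n_levels: int
    distance: int
    angle: float
    symmetric: bool

    def __post_init__(self) -> None:
        if np.any(self.p < 0):
            raise ValueError("GLCM entries must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("normalized GLCM must sum to 1")


def quantize(img: Thermogram, n_levels: int) -> np.ndarray:
    """Uniform quantization of [0,1] intensities to integer levels."""
    levels = np.floor(img.pixels * n_levels).astype(np.uint8 if n_levels <= 256 else np.int64)
    return np.minimum(levels, n_levels - 1)


def compute_glcm(img: Thermogram, distance: int = 1, angle: float = 0.0,
                 n_levels: int = 32, symmetric: bool = True) -> GLCMatrix:
    """Co-occurrence counts of quantized levels at the given offset,
    optionally symmetrized, normalized to probabilities."""
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if distance >= max(img.pixels.shape):
        raise ValueError("offset distance exceeds image extent")
    q = quantize(img, n_levels)
    counts = graycomatrix(q, distances=[distance], angles=[angle],
                          levels=n_levels, symmetric=symmetric, normed=False)
    counts = counts[:, :, 0, 0].astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("offset produced no co-occurring pairs")
    return GLCMatrix(p=counts / total, n_levels=n_levels,
                     distance=distance, angle=angle, symmetric=symmetric)


def glcm_correlation(glcm: GLCMatrix) -> float | None:
    """Correlation of the level pair (i, j) under p(i, j):

        (Σ_{ij} i·j·p(i,j) − μ_x μ_y) / (σ_x σ_y)

    with means/SDs from the GLCM marginals.  Returns None (degenerate)
    when either marginal variance vanishes, e.g. for a constant image.
    """
    p = glcm.p
    i = np.arange(p.shape[0], dtype=np.float64)
    px, py = p.sum(axis=1), p.sum(axis=0)
    mu_x, mu_y = (i * px).sum(), (i * py).sum()
    var_x = ((i - mu_x) ** 2 * px).sum()
    var_y = ((i - mu_y) ** 2 * py).sum()
    if var_x < 1e-15 or var_y < 1e-15:
        return None
    num = (np.outer(i, i) * p).sum() - mu_x * mu_y
    return float(num / np.sqrt(var_x * var_y))


def mean_glcm_correlation(img: Thermogram, distance: int = 1,
                          angles: tuple[float, ...] = DEFAULT_GLCM_ANGLES,
                          n_levels: int = 32) -> float | None:
    """GLCM correlation averaged over offsets; None if all are degenerate."""
    vals = [glcm_correlation(compute_glcm(img, distance, a, n_levels))
            for a in angles]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else None


# --------------------------------------------------------------------------
# first-order statistics

@dataclass
class FirstOrderStats:
    mean: float
    variance: float
    std_dev: float
    max: float
    min: float
    entropy: float
    kurtosis: float | None  # excess; None when variance is 0
    skewness: float | None


def first_order_stats(img: Thermogram, n_bins: int = 256) -> FirstOrderStats:
    """Pixel-distribution summary.

    Variance is the population variance over all pixels; entropy is the
    Shannon entropy (bits) of the ``n_bins`` intensity histogram; kurtosis
    is the excess kurtosis (0 for a Gaussian) and skewness the third
    standardized moment, both undefined for constant images.
    """
    x = img.pixels.ravel()
    var = float(np.var(x))
    p = intensity_histogram(img, n_bins).p
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    if var < 1e-18:
        kurt: float | None = None
        skew: float | None = None
    else:
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
        skew = float(sps.skew(x, bias=True))
    return FirstOrderStats(mean=float(np.mean(x)), variance=var,
                           std_dev=float(np.sqrt(var)), max=float(np.max(x)),
                           min=float(np.min(x)), entropy=entropy,
                           kurtosis=kurt, skewness=skew)


# --------------------------------------------------------------------------
# assembled feature vector

@dataclass(frozen=True)
class FeatureConfig:
    n_bins: int = 256
    glcm_levels: int = 32
    glcm_distance: int = 1
    glcm_angles: tuple[float, ...] = DEFAULT_GLCM_ANGLES
    n_octaves: int = 3
    n_scales: int = 3
    contrast_threshold: float = 0.02
    n_subregions: int = 8
    n_orientation_bins: int = 8
    max_keypoints: int = 25  # strongest keypoints used for the descriptor mean


@dataclass
class FeatureVector:
    """Ordered numeric summary of one image, matching the CSV schema."""

    stats: FirstOrderStats
    glcm_correlation: float | None
    n_keypoints: int
    descriptor_mean: np.ndarray
    degenerate_flags: list[str] = field(default_factory=list)

    SCALAR_FIELDS = ("mean", "variance", "std_dev", "max", "min",
                     "entropy", "kurtosis", "skewness")

    def to_row(self) -> list[float]:
        """Flat numeric row; degenerate entries encoded as NaN (and named
        in ``degenerate_flags``)."""
        row = [getattr(self.stats, f) for f in self.SCALAR_FIELDS]
        row = [np.nan if v is None else v for v in row]
        row.append(np.nan if self.glcm_correlation is None else self.glcm_correlation)
        row.append(float(self.n_keypoints))
        row.extend(self.descriptor_mean.tolist())
        return row

    @staticmethod
    def header(descriptor_len: int) -> list[str]:
        return (list(FeatureVector.SCALAR_FIELDS) + ["glcm_correlation", "n_keypoints"]
                + [f"desc_{i}" for i in range(descriptor_len)])


def extract_features(img: Thermogram, cfg: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Assemble the per-image feature vector (deterministic)."""
    stats = first_order_stats(img, cfg.n_bins)
    corr = mean_glcm_correlation(img, cfg.glcm_distance, cfg.glcm_angles, cfg.glcm_levels)

    flags: list[str] = []
    if stats.kurtosis is None:
        flags.append("kurtosis")
    if stats.skewness is None:
        flags.append("skewness")
    if corr is None:
        flags.append("glcm_correlation")

    desc_len = cfg.n_subregions * cfg.n_orientation_bins
    kps = detect_keypoints(img, cfg.n_octaves, cfg.n_scales, cfg.contrast_threshold)
    descs = []
    for kp in kps[: cfg.max_keypoints]:
        d = sift_descriptor(img, kp, cfg.n_subregions, cfg.n_orientation_bins)
        if not d.degenerate:
            descs.append(d.values)
    if descs:
        desc_mean = np.mean(descs, axis=0)
    else:
        desc_mean = np.zeros(desc_len)
        flags.append("descriptor_mean")

    return FeatureVector(stats=stats, glcm_correlation=corr,
                         n_keypoints=len(kps), descriptor_mean=desc_mean,
                         degenerate_flags=flags)


def feature_table(images: list[Thermogram], names: list[str],
                  cfg: FeatureConfig = FeatureConfig()):
    """Feature DataFrame for a batch of images, one row per sample."""
    import pandas as pd

    rows = [extract_features(img, cfg).to_row() for img in images]
    desc_len = cfg.n_subregions * cfg.n_orientation_bins
    df = pd.DataFrame(rows, columns=FeatureVector.header(desc_len))
    df.insert(0, "sample", names)
    return df
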