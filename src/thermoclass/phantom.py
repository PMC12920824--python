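"""Synthetic thermogram phantoms with ground truth.

Clinical breast thermograms show a smooth background temperature field with
localized warm anomalies over vascularized lesions.  The phantom generator
emulates exactly that structure — a linear background gradient, radially
symmetric Gaussian hot spots, and i.i.d. Gaussian pixel noise — so every
downstream stage (enhancement, texture features, classification) can be
exercised against known ground truth at desk scale.

Class separability is encoded by giving each of the four lesion classes its
own prior over hotspot count, radius and intensity elevation.  These priors
are an artifact of the generator, not a claim about real lesion-class
thermal signatures; see docs/methods.md.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .image import CLASS_LABELS, Thermogram, save_image

#: Fraction of a hotspot's peak elevation defining its ground-truth core mask.
MASK_LEVEL = 0.75

#: Per-class priors: (n_hotspots range, radius range [px], delta range).
#: Counts are inclusive integer ranges; radius/delta uniform continuous.
CLASS_PRIORS: dict[str, dict] = {
    "DCIS": {"n_hotspots": (1, 1), "radius": (4.0, 6.0), "delta": (0.18, 0.26)},
    "ILC": {"n_hotspots": (3, 4), "radius": (3.0, 4.5), "delta": (0.28, 0.36)},
    "Angiosarcoma": {"n_hotspots": (2, 3), "radius": (10.0, 14.0), "delta": (0.40, 0.48)},
    "PhyllodesTumor": {"n_hotspots": (7, 9), "radius": (2.0, 3.0), "delta": (0.50, 0.60)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom thermogram.

    ``hotspot_radius_px`` and ``hotspot_delta`` are (low, high) ranges
    sampled uniformly per hotspot; ``background_gradient`` is the
    edge-to-edge intensity span of the linear background ramp.  The same
    spec (seed included) always yields a bit-identical image.
    """

    height: int = 128
    width: int = 128
    class_label: str | None = None
    n_hotspots: int = 3
    hotspot_radius_px: tuple[float, float] = (3.0, 6.0)
    hotspot_delta: tuple[float, float] = (0.2, 0.4)
    background_gradient: float = 0.1
    noise_sd: float = 0.01
    baseline: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be at least 32x32")
        if self.n_hotspots < 0:
            raise ValueError("n_hotspots must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_hotspots > 0 and self.hotspot_delta[0] <= 0:
            raise ValueError("hotspot_delta must be positive when hotspots are present")
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")


def spec_for_class(label: str, *, height: int = 128, width: int = 128,
                   noise_sd: float = 0.01, background_gradient: float = 0.1,
                   seed: int = 0) -> PhantomSpec:
    """Build a :class:`PhantomSpec` with the class's hotspot priors filled in."""
    prior = CLASS_PRIORS[label]
    lo, hi = prior["n_hotspots"]
    # hotspot count drawn here so the spec is fully explicit and hashable
    rng = np.random.default_rng(np.random.SeedSequence([seed, CLASS_LABELS.index(label)]))
    n = int(rng.integers(lo, hi + 1))
    return PhantomSpec(
        height=height, width=width, class_label=label, n_hotspots=n,
        hotspot_radius_px=prior["radius"], hotspot_delta=prior["delta"],
        background_gradient=background_gradient, noise_sd=noise_sd, seed=seed,
    )


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Linear ramp of span ``background_gradient`` in a seeded direction.

    Drawn first from the RNG stream, so a spec differing only in
    ``n_hotspots``/``noise_sd`` reproduces the identical background field.
    """
    theta = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0: spec.height, 0: spec.width]
    u = (np.cos(theta) * xx / max(spec.width - 1, 1)
         + np.sin(theta) * yy / max(spec.height - 1, 1))
    if u.max() > u.min():
        u = (u - u.min()) / (u.max() - u.min())
    return spec.baseline + spec.background_gradient * u


def generate_phantom(spec: PhantomSpec) -> tuple[Thermogram, np.ndarray]:
    """Generate one phantom and its ground-truth hotspot core mask.

    Returns
    -------
    thermogram : Thermogram
        background + Gaussian bumps + noise, clipped to [0, 1].
    mask : ndarray of bool, shape (H, W)
        True where some hotspot's elevation exceeds ``MASK_LEVEL`` of its
        peak delta (the hotspot "core").
    """
    rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    mask = np.zeros((spec.height, spec.width), dtype=bool)

    yy, xx = np.mgrid[0: spec.height, 0: spec.width]
    for _ in range(spec.n_hotspots):
        r = rng.uniform(*spec.hotspot_radius_px)
        delta = rng.uniform(*spec.hotspot_delta)
        # keep centers away from the border by one radius
        cy = rng.uniform(r, spec.height - 1 - r)
        cx = rng.uniform(r, spec.width - 1 - r)
        bump = delta * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * r * r))
        img = img + bump
        mask |= bump >= MASK_LEVEL * delta

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return Thermogram(img, source_bit_depth=8, label=spec.class_label), mask


def generate_thermogram(spec: PhantomSpec) -> Thermogram:
    """Phantom image only (see :func:`generate_phantom` for the mask too)."""
    return generate_phantom(spec)[0]


def generate_labeled_set(n_per_class: int, *, height: int = 128, width: int = 128,
                         noise_sd: float = 0.01, background_gradient: float = 0.1,
                         seed: int = 0) -> tuple[list[Thermogram], list[str]]:
    """In-memory labeled phantom set (same per-image seeding as
    :func:`generate_dataset`, no files written)."""
    images: list[Thermogram] = []
    labels: list[str] = []
    idx = 0
    for label in CLASS_LABELS:
        prior = CLASS_PRIORS[label]
        for _ in range(n_per_class):
            child = int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2 ** 31))
            rng = np.random.default_rng(child)
            n = int(rng.integers(prior["n_hotspots"][0], prior["n_hotspots"][1] + 1))
            spec = PhantomSpec(
                height=height, width=width, class_label=label, n_hotspots=n,
                hotspot_radius_px=prior["radius"], hotspot_delta=prior["delta"],
                background_gradient=background_gradient, noise_sd=noise_sd,
                seed=child + 1)
            images.append(generate_thermogram(spec))
            labels.append(label)
            idx += 1
    return images, labels


@dataclass
class DatasetManifest:
    """Rows of (file_path, class_label, partition) describing a dataset on disk."""

    records: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        paths = [r[0] for r in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest file paths must be unique")
        for _, label, _ in self.records:
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown class label {label!r}")

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label", "partition"])
            writer.writerows(self.records)

    @classmethod
    def read_csv(cls, path: str | Path) -> "DatasetManifest":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header != ["path", "label", "partition"]:
                raise IOError(f"unexpected manifest header {header} in {path}")
            return cls([tuple(row) for row in reader])

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label, _ in self.records:
            counts[label] = counts.get(label, 0) + 1
        return counts


def generate_dataset(class_counts: dict[str, int], out_dir: str | Path,
                     *, seed: int = 0, height: int = 128, width: int = 128,
                     noise_sd: float = 0.01, background_gradient: float = 0.1,
                     write_masks: bool = True) -> DatasetManifest:
    """Write a labeled phantom dataset and its manifest.

    One 8-bit PNG per record (plus a ``.mask.png`` ground-truth mask),
    ``manifest.csv`` listing them with partition left unassigned.  Per-image
    seeds are spawned deterministically from the master seed, so the same
    call reproduces identical bytes.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc
    for label, count in class_counts.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if count < 0:
            raise ValueError("class counts must be non-negative")

    records: list[tuple[str, str, str]] = []
    idx = 0
    for label in CLASS_LABELS:  # fixed enum order for determinism
        for j in range(class_counts.get(label, 0)):
            child = np.random.SeedSequence([int(seed), idx]).generate_state(1)[0]
            child = int(child % (2 ** 31))
            prior = CLASS_PRIORS[label]
            rng = np.random.default_rng(child)
            n = int(rng.integers(prior["n_hotspots"][0], prior["n_hotspots"][1] + 1))
            spec = PhantomSpec(
                height=height, width=width, class_label=label, n_hotspots=n,
                hotspot_radius_px=prior["radius"], hotspot_delta=prior["delta"],
                background_gradient=background_gradient, noise_sd=noise_sd,
                seed=child + 1,
            )
            tg, mask = generate_phantom(spec)
            name = f"{label}_{j:04d}.png"
            save_image(tg, out_dir / name)
            if write_masks:
                iio.imwrite(out_dir / f"{label}_{j:04d}.mask.png",
                            (mask.astype(np.uint8) * 255))
            records.append((name, label, "unassigned"))
            idx += 1

    manifest = DatasetManifest(records)
    manifest.write_csv(out_dir / "manifest.csv")
    return manifest
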