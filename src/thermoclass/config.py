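"""JSON run configuration with strict validation.

Unknown keys are rejected (typos fail loudly) and a round-trip through
``to_json``/``from_json`` is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .features import FeatureConfig
from .network import NetworkConfig, TrainConfig
from .pipeline import PipelineConfig
from .preprocess import AdaptiveFilterConfig, DiffusionConfig, PreprocessConfig
from .svm import KernelSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    n_per_class: int = 40
    height: int = 128
    width: int = 128
    noise_sd: float = 0.01
    background_gradient: float = 0.1
    write_masks: bool = True


class PreprocessSection(_Strict):
    equalization: str = "none"  # classification default; "dehe" for enhancement
    dehe_alpha: float = 2.0
    n_bins: int = 256
    diffusion_k: float = 0.1
    diffusion_iterations: int = 15
    diffusion_dt: float = 0.2
    adaptive_sigma: float = 0.1
    adaptive_radius: int = 1

    def build(self) -> PreprocessConfig:
        return PreprocessConfig(
            equalization=self.equalization, dehe_alpha=self.dehe_alpha,
            n_bins=self.n_bins,
            diffusion=DiffusionConfig(k=self.diffusion_k,
                                      n_iterations=self.diffusion_iterations,
                                      dt=self.diffusion_dt),
            adaptive=AdaptiveFilterConfig(sigma=self.adaptive_sigma,
                                          radius=self.adaptive_radius))


class FeatureSection(_Strict):
    n_bins: int = 256
    glcm_levels: int = 32
    glcm_distance: int = 1
    n_octaves: int = 3
    n_scales: int = 3
    contrast_threshold: float = 0.02
    n_subregions: int = 8
    n_orientation_bins: int = 8

    def build(self) -> FeatureConfig:
        return FeatureConfig(n_bins=self.n_bins, glcm_levels=self.glcm_levels,
                             glcm_distance=self.glcm_distance,
                             n_octaves=self.n_octaves, n_scales=self.n_scales,
                             contrast_threshold=self.contrast_threshold,
                             n_subregions=self.n_subregions,
                             n_orientation_bins=self.n_orientation_bins)


class ModelSection(_Strict):
    mode: str = "network"
    pool_size: int = 16
    prn_widths: tuple[int, ...] = (8, 12, 16)
    backbone_widths: tuple[int, ...] = (8, 8, 16, 16)
    blocks_per_stage: int = 2
    fusion: str = "concatenate"
    svm_kernel: str = "rbf"
    svm_gamma: float | None = None
    svm_c: float = 10.0
    augment: bool = True


class OptimizerSection(_Strict):
    epochs: int = 60
    lr: float = 0.01
    weight_decay: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def build(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, lr=self.lr,
                           weight_decay=self.weight_decay, beta1=self.beta1,
                           beta2=self.beta2, eps=self.eps)


class EvaluationSection(_Strict):
    k: int = 5
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)


class RunConfig(_Strict):
    """Top-level configuration for the end-to-end pipeline."""

    seed: int = 0
    verbosity: str = "info"
    simulate: SimulateSection = SimulateSection()
    preprocessing: PreprocessSection = PreprocessSection()
    features: FeatureSection = FeatureSection()
    model: ModelSection = ModelSection()
    optimizer: OptimizerSection = OptimizerSection()
    evaluation: EvaluationSection = EvaluationSection()

    def to_pipeline_config(self) -> PipelineConfig:
        net = None
        if self.model.mode == "network":
            net = NetworkConfig(kind="conv", input_hw=self.model.pool_size,
                                input_dim=self.model.pool_size ** 2,
                                prn_widths=tuple(self.model.prn_widths),
                                backbone_widths=tuple(self.model.backbone_widths),
                                blocks_per_stage=self.model.blocks_per_stage,
                                fusion=self.model.fusion)
        return PipelineConfig(mode=self.model.mode, pool_size=self.model.pool_size,
                              preprocess=self.preprocessing.build(),
                              features=self.features.build(), network=net,
                              train=self.optimizer.build(),
                              kernel=KernelSpec(kind=self.model.svm_kernel,
                                                gamma=self.model.svm_gamma),
                              svm_c=self.model.svm_c,
                              augment=self.model.augment)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "RunConfig":
        p = Path(str(text_or_path))
        if p.suffix == ".json" and p.exists():
            text = p.read_text()
        else:
            text = str(text_or_path)
        return cls.model_validate(json.loads(text))
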