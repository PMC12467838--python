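"""Pipeline configuration: one nested, file-round-trippable config object.

Every stage of the pipeline reads its parameters from a section of
:class:`PipelineConfig`. A single global ``seed`` fans out to per-stage
derived seeds (via ``numpy.random.SeedSequence(seed, stage_index)``) so each
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import yaml

from .features import VMDConfig, WelchConfig

#: Fixed stage indices for seed derivation (order is part of the contract).
STAGE_IDS = {
    "simulate": 0,
    "split": 1,
    "train": 2,
    "model_init": 3,
    "assist": 4,
}


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed below 2^31, deterministic in (seed, stage)."""
    ss = np.random.SeedSequence([int(seed), STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PreprocessConfig:
    wavelet: str = "db2"
    levels: int = 4
    threshold_rule: str = "universal"
    band: Tuple[float, float] = (10.0, 100.0)
    order: int = 4


@dataclass
class SegmentConfig:
    window_n: int = 128            # MAS window, samples (~128 ms at 1 kHz)
    threshold: Optional[float] = None   # None: mean + 3 SD of rest baseline
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.2
    source: str = "rectified"


@dataclass
class GAFConfig:
    size: int = 64
    kind: str = "GASF"
    rescale_mode: str = "symmetric"    # "unit" for the [0, 1] compat mode


@dataclass
class FeatureConfig:
    window_len: float = 0.25
    stride: float = 0.125
    vmd: VMDConfig = field(default_factory=VMDConfig)
    welch: WelchConfig = field(default_factory=WelchConfig)


@dataclass
class ModelConfig:
    """Architecture of the dual-branch fusion classifier.

    ``conv_widths`` gives the channel width of each of the five VGG16
    convolution blocks (the canonical full-capacity layout is
    ``[64, 128, 256, 512, 512]``); ``conv_depths`` is the fixed VGG16 block
    structure. The reduced profile keeps the topology but shrinks widths so
    the model trains at desk scale.
    """

    image_size: int = 64
    n_input_planes: int = 6
    conv_widths: List[int] = field(default_factory=lambda: [64, 128, 256, 512, 512])
    conv_depths: List[int] = field(default_factory=lambda: [2, 2, 3, 3, 3])
    fc_dims: List[int] = field(default_factory=lambda: [4096, 4096])
    d_model: int = 128
    n_heads: int = 4
    lstm_hidden: int = 128
    n_classes: int = 5
    frim_tokens: str = "triple"    # "triple" or "single"
    forest_trees: int = 100

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    @classmethod
    def reduced(cls, image_size: int = 32) -> "ModelConfig":
        """Reduced-width test profile: same topology, desk-scale capacity."""
        return cls(
            image_size=image_size,
            conv_widths=[4, 8, 16, 32, 32],
            fc_dims=[32, 32],
            d_model=32,
            n_heads=4,
            lstm_hidden=32,
        )


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_decay_factor: float = 0.1
    lr_decay_step: int = 10
    max_epochs: int = 50
    batch_size: int = 40
    dropout: float = 0.5
    val_fraction: float = 0.2      # carved from the training set for checkpointing
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("lr", "lr_decay_factor", "lr_decay_step", "max_epochs",
                     "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulateConfig:
    fs: float = 1000.0
    n_per_class: int = 20
    split: float = 0.8
    separation: float = 1.0        # scales class-profile contrast


@dataclass
class AssistConfig:
    rms_window_s: float = 0.1
    two_sided: bool = True
    n_subjects: int = 8
    mean_reduction: float = 0.40
    sd_reduction: float = 0.05


@dataclass
class PipelineConfig:
    seed: int = 0
    verbosity: str = "info"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    gaf: GAFConfig = field(default_factory=GAFConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    assist: AssistConfig = field(default_factory=AssistConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_dict(cls, d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """YAML-safe plain types (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        ftype = f.type if not isinstance(f.type, str) else None
        target = _DATACLASS_FIELDS.get((cls.__name__, f.name))
        if target is not None and isinstance(v, dict):
            kwargs[f.name] = _from_dict(target, v)
        elif f.name == "band" and isinstance(v, list):
            kwargs[f.name] = tuple(v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


_DATACLASS_FIELDS = {
    ("PipelineConfig", "preprocess"): PreprocessConfig,
    ("PipelineConfig", "segment"): SegmentConfig,
    ("PipelineConfig", "gaf"): GAFConfig,
    ("PipelineConfig", "features"): FeatureConfig,
    ("PipelineConfig", "model"): ModelConfig,
    ("PipelineConfig", "train"): TrainConfig,
    ("PipelineConfig", "simulate"): SimulateConfig,
    ("PipelineConfig", "assist"): AssistConfig,
    ("FeatureConfig", "vmd"): VMDConfig,
    ("FeatureConfig", "welch"): WelchConfig,
}
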