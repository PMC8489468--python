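"""Pipeline configuration: YAML round-trip and profile enforcement.

Two profiles gate the compute budget:

* ``paper`` — the full-scale training recipe (batch 36, 15 epochs,
  learning rate 0.001, full-size images);
* ``desk`` — a CPU-sized schedule capped at 128x128 images and 5 epochs,
  used by the test suite and the acceptance experiments.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ..acquisition import AcquisitionProtocol
from ..dnif import ModelConfig, TrainConfig

__all__ = ["PhantomSetConfig", "PipelineConfig", "load_config", "save_config", "stage_seed"]

# Per-stage seed offsets: stages can be re-run in isolation reproducibly.
_STAGE_OFFSETS = {
    "phantom": 10_000,
    "acquire": 20_000,
    "train": 30_000,
    "evaluate": 40_000,
}


def stage_seed(global_seed: int, stage: str, index: int = 0) -> int:
    """Derive the seed of one stochastic stage from the global seed."""
    return global_seed + _STAGE_OFFSETS[stage] + index


@dataclass(frozen=True)
class PhantomSetConfig:
    """How many random phantoms to draw and with what geometry."""

    n_train: int = 30
    n_val: int = 20
    grid_shape: tuple[int, int] = (64, 64)
    lesion_adc: float = 0.7e-3
    lesion_radius: float = 4.0
    lesion_s0_range: tuple[float, float] = (1500.0, 3000.0)
    background_s0: float = 60.0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_val < 1:
            raise ValueError("need at least one training and one validation phantom")


@dataclass(frozen=True)
class PipelineConfig:
    phantoms: PhantomSetConfig = field(default_factory=PhantomSetConfig)
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(base_channels=8))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(batch_size=16, epochs=5))
    profile: str = "desk"
    output_dir: str = "quickdwi_out"
    global_seed: int = 0
    train_acquisition_subset: int = 1  # acquisitions per (b, direction) used as inputs

    def __post_init__(self) -> None:
        if self.profile not in ("paper", "desk"):
            raise ValueError("profile must be 'paper' or 'desk'")
        if self.profile == "desk":
            r, c = self.phantoms.grid_shape
            if r > 128 or c > 128:
                raise ValueError("desk profile caps image size at 128x128")
            if self.train.epochs > 5:
                raise ValueError("desk profile caps training at 5 epochs")
        else:
            if (
                self.train.batch_size != 36
                or self.train.epochs != 15
                or self.train.learning_rate != 0.001
            ):
                raise ValueError(
                    "paper profile pins batch_size=36, epochs=15, learning_rate=0.001"
                )


def _to_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["phantoms"]["grid_shape"] = list(cfg.phantoms.grid_shape)
    d["phantoms"]["lesion_s0_range"] = list(cfg.phantoms.lesion_s0_range)
    d["protocol"]["b_values"] = list(cfg.protocol.b_values)
    d["model"]["input_shape"] = list(cfg.model.input_shape)
    return d


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))
    return path


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Read a YAML pipeline config; keyword overrides win over the file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    raw.update(overrides)
    kwargs: dict = {}
    if "phantoms" in raw:
        p = dict(raw.pop("phantoms"))
        if "grid_shape" in p:
            p["grid_shape"] = tuple(p["grid_shape"])
        if "lesion_s0_range" in p:
            p["lesion_s0_range"] = tuple(p["lesion_s0_range"])
        kwargs["phantoms"] = PhantomSetConfig(**p)
    if "protocol" in raw:
        p = dict(raw.pop("protocol"))
        if "b_values" in p:
            p["b_values"] = tuple(p["b_values"])
        kwargs["protocol"] = AcquisitionProtocol(**p)
    if "model" in raw:
        p = dict(raw.pop("model"))
        if "input_shape" in p:
            p["input_shape"] = tuple(p["input_shape"])
        kwargs["model"] = ModelConfig(**p)
    if "train" in raw:
        kwargs["train"] = TrainConfig(**raw.pop("train"))
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
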