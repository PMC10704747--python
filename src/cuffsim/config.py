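"""Pipeline configuration: schema, defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
import pathlib

import pydantic
import yaml


class ConfigError(ValueError):
    """Configuration file violates the schema."""


class _Section(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class GeometryConfig(_Section):
    seed: int = 1
    n_fascicles: int = 17
    pixel_pitch: float = 0.15  # mm/px of the rasterized cross-section
    epineurium_semi_axes: tuple[float, float] = (4.5, 2.0)
    fascicle_radius_range: tuple[float, float] = (0.15, 0.45)
    min_centroid_separation: float = 1.0
    perineurium_fraction: float = 0.03
    axial_length: float = 24.0  # mm
    axial_pitch: float = 0.75  # mm
    saline_diameter: float = 11.0


class ForwardConfig(_Section):
    tolerance: float = 1e-6
    insulator_cutoff: float = 1e-6
    reference_contact: int = 0


class SimulateConfig(_Section):
    waveform_seed: int = 0
    n_templates: int = 1000
    n_samples: int = 100
    sampling_rate: float = 30000.0
    amplitude_jitter: float = 0.1
    offset_jitter: float = 3.0
    conduction_velocity: float = 60.0  # m/s
    node_spacing: float = 1.0  # mm
    noise_mode: str = "amplitude"


class ModelConfig(_Section):
    backbone: str = "escape"
    width_mult: float = 1.0 / 16.0
    dropout: float = 0.5
    learning_rate: float = 1e-3
    lr_decay: float = 1e-6
    momentum: float = 1e-9
    # desk-profile batch/epoch budget: small batches give the small stated
    # learning rate enough update steps to converge on 6k-sample datasets
    batch_size: int = 48
    max_epochs: int = 12
    patience: int | None = None  # None: 15 for escape, 40 otherwise
    val_fraction: float = 0.2


class SweepConfig(_Section):
    class_counts: list[int] = [3, 5, 7, 10]
    noise_ratios: list[float] = [0.05, 0.10, 0.15]
    repetitions: int = 3
    folds: int = 3
    dataset_size: int = 6000


class PipelineConfig(_Section):
    """Nested configuration for the full simulation/benchmark pipeline.

    The ``desk`` profile (default) uses the single-CPU problem sizes:
    6,000-sample datasets, 3 repetitions, a 1/16-width network and a
    coarse solver grid.  The ``full`` profile restores the benchmark-scale
    design: 30,000 samples, 10 repetitions, full-width networks.
    """

    profile: str = "desk"
    master_seed: int = 0
    geometry: GeometryConfig = GeometryConfig()
    forward: ForwardConfig = ForwardConfig()
    simulate: SimulateConfig = SimulateConfig()
    model: ModelConfig = ModelConfig()
    sweep: SweepConfig = SweepConfig()

    @classmethod
    def full_profile(cls, **overrides) -> "PipelineConfig":
        cfg = cls(**overrides)
        return cfg.model_copy(
            update={
                "profile": "full",
                "model": cfg.model.model_copy(
                    update={"width_mult": 1.0, "max_epochs": 50, "batch_size": 128}
                ),
                "sweep": cfg.sweep.model_copy(
                    update={"repetitions": 10, "dataset_size": 30000}
                ),
            }
        )


def load_config(path: str | pathlib.Path) -> PipelineConfig:
    """Load a YAML config; omitted keys take defaults, unknown keys fail."""
    path = pathlib.Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    try:
        return PipelineConfig(**raw)
    except pydantic.ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"invalid config key {loc!r}: {first['msg']}") from exc


def save_config(config: PipelineConfig, path: str | pathlib.Path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    )


def config_hash(config: PipelineConfig, *sections: str) -> str:
    """Stable hash of the whole config or of named sections."""
    payload = config.model_dump(mode="json")
    if sections:
        payload = {k: payload[k] for k in sections}
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
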