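"""Schema-validated run configuration.

A single YAML file drives the full pipeline.  Defaults are the standard
therapeutic operating point: -1.5 V, 60 us, 130 Hz monopolar cathodic pulses,
42% interface voltage drop, 0.128 S/m encapsulation, 3.3 uF interface
capacitance, 1000 Ohm impedance, probtrackX-style tracking (0.5 mm steps,
+/-80 degrees, 2000 steps, 100 samples/seed, 11^3 seed cube of 2 mm voxels),
1 mm heat-map cells and the 5.7 um / 0.5 mm internodal axon parameter set.
Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ElectrodeConfig(_Strict):
    position_mm: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    active_contact: int = Field(0, ge=0, le=3)


class StimulusConfig(_Strict):
    amplitude_v: float = -1.5
    pulse_width_us: float = Field(60.0, gt=0)
    frequency_hz: float = Field(130.0, gt=0)
    voltage_drop: float = Field(0.42, ge=0, lt=1)
    interface_capacitance_uf: float = Field(3.3, gt=0)
    impedance_ohm: float = Field(1000.0, gt=0)
    encapsulation_s_per_m: float = Field(0.128, gt=0)
    encapsulation_mm: float = Field(0.5, ge=0)
    tuch_scale: float = Field(0.844, gt=0)
    waveform_mode: str = "square"

    @field_validator("waveform_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("square", "rc_filtered"):
            raise ValueError("waveform_mode must be 'square' or 'rc_filtered'")
        return v


class TrackingConfig(_Strict):
    step_mm: float = Field(0.5, gt=0)
    curvature_deg: float = Field(80.0, gt=0, lt=180)
    max_steps: int = Field(2000, ge=1)
    samples_per_seed: int = Field(100, ge=1)
    seed_cube_edge_voxels: int = Field(11, ge=1)
    seed_cube_voxel_mm: float = Field(2.0, gt=0)
    loop_check: bool = True


class SimulationSection(_Strict):
    dt_us: float = Field(2.0, gt=0)
    duration_us: float = Field(3000.0, gt=0)
    detection_threshold_mv: float = 0.0
    min_nodes: int = Field(21, ge=2)
    membrane_parameters: str = "mrg_5p7um_v1"


class HeatmapConfig(_Strict):
    cell_mm: float = Field(1.0, gt=0)
    pad_mm: float = Field(2.0, ge=0)


class RegionsConfig(_Strict):
    percentage_policy: str = "region_reaching"
    top_k: int = Field(5, ge=1)

    @field_validator("percentage_policy")
    @classmethod
    def _policy(cls, v: str) -> str:
        if v not in ("region_reaching", "all_active"):
            raise ValueError("policy must be 'region_reaching' or 'all_active'")
        return v


class InputPaths(_Strict):
    orientation_dir: str
    tensors: str
    csf_mask: str | None = None
    atlas: str | None = None
    region_table: str | None = None


class RunConfig(_Strict):
    """Full pipeline configuration (see module docstring for defaults)."""

    inputs: InputPaths
    electrodes: list[ElectrodeConfig]
    out_dir: str = "stimdense_out"
    rng_seed: int = 0
    stimulus: StimulusConfig = StimulusConfig()
    tracking: TrackingConfig = TrackingConfig()
    simulation: SimulationSection = SimulationSection()
    heatmap: HeatmapConfig = HeatmapConfig()
    regions: RegionsConfig = RegionsConfig()

    def resolve_paths(self, base: Path) -> None:
        """Check input paths exist (relative to ``base``), raising ConfigError."""
        for key in ("orientation_dir", "tensors", "csf_mask", "atlas", "region_table"):
            val = getattr(self.inputs, key)
            if val is None:
                continue
            p = Path(val)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"inputs.{key}: path does not exist: {p}")


def load_config(path) -> RunConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    cfg.resolve_paths(path.parent)
    return cfg
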