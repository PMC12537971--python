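"""Validated run configuration for the pipeline CLI.

A ``RunConfig`` mirrors the core dataclasses (optics, mirror, acquisition
plan, noise, reconstruction) as nested, schema-validated sections; unknown
keys are rejected with field paths.  The master seed fully determines
every child seed used downstream.
"""

from __future__ import annotations

from typing import Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .optics import MirrorConfig, OpticalConfig
from .phantoms import AcquisitionPlan, NoiseModel
from .reconstruction import ReconConfig

__all__ = [
    "OpticsSection", "MirrorSection", "PlanSection", "NoiseSection",
    "PhantomSection", "ReconSection", "MetricsSection", "RunConfig",
    "derive_seeds",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Section):
    wavelength_exc: float = 488.0
    wavelength_em: float = 520.0
    numerical_aperture: float = 1.49
    n_immersion: float = 1.518
    n_sample: float = 1.33
    lateral_spacing: float = 40.0
    axial_spacing: float = 20.0
    grid_shape: Tuple[int, int, int] = (96, 128, 128)

    def build(self) -> OpticalConfig:
        return OpticalConfig(**self.model_dump())


class MirrorSection(_Section):
    enabled: bool = True
    gap_distance: float = 100_000.0
    reflectance: float = 0.97
    tilt_deg: float = 0.0

    def build(self) -> MirrorConfig:
        return MirrorConfig(**self.model_dump())


class PlanSection(_Section):
    frames_per_layer: int = 50
    z_step: float = 25.0
    n_layers: int = 1
    frame_interval: float = 0.02
    drift_per_frame: Optional[Tuple[float, float]] = None

    def build(self) -> AcquisitionPlan:
        return AcquisitionPlan(**self.model_dump())


class NoiseSection(_Section):
    enabled: bool = True
    photons_at_peak: float = 500.0
    em_gain: float = 30.0
    read_noise_sd: float = 2.0
    offset: float = 100.0
    excess_noise: bool = True

    def build(self) -> NoiseModel | None:
        if not self.enabled:
            return None
        d = self.model_dump()
        d.pop("enabled")
        return NoiseModel(**d)


class PhantomSection(_Section):
    kind: Literal["beads", "filaments", "hollow_shells"] = "beads"
    n: int = Field(default=5, ge=0)
    size: float = 100.0          # bead diameter / filament thickness /
                                 # shell diameter, nm
    brightness: float = 1.0
    min_spacing: Optional[float] = None
    margin_nm: float = 0.0
    shell_thickness: float = 100.0   # hollow shells only


class ReconSection(_Section):
    order: int = 3
    lag: int = 0
    rl_iters_2d: int = 10
    rl_iters_3d: int | Literal["auto"] = "auto"
    max_rl_iters_3d: int = 40
    linearize_iters: int = 5
    upsample_factor: int = 2
    linearize_brightness: bool = True
    z_flatten: bool = True
    epsilon_scale: float = 1e-9
    dsi_mean_subtracted: bool = False

    def build(self) -> ReconConfig:
        return ReconConfig(**self.model_dump())


class MetricsSection(_Section):
    decorr_n_radii: int = 50
    decorr_n_filters: int = 10
    bead_profile_width: int = 3


class RunConfig(_Section):
    """Top-level pipeline configuration (YAML/JSON mapping)."""

    seed: int = 0
    out_dir: str = "axisim_out"
    stages: Tuple[str, ...] = ("simulate", "preprocess", "reconstruct",
                               "evaluate")
    apodization: Literal["aplanatic", "none"] = "aplanatic"
    register_frames: bool = True
    optics: OpticsSection = OpticsSection()
    mirror: MirrorSection = MirrorSection()
    plan: PlanSection = PlanSection()
    noise: NoiseSection = NoiseSection()
    phantom: PhantomSection = PhantomSection()
    recon: ReconSection = ReconSection()
    metrics: MetricsSection = MetricsSection()

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        return cls.model_validate(mapping)


def derive_seeds(master_seed: int, n: int, label: str = "") -> list[int]:
    """Deterministic child seeds from a master seed; an optional label
    decorrelates seed streams used for different purposes."""
    entropy = [master_seed] + [ord(c) for c in label]
    ss = np.random.SeedSequence(entropy)
    return [int(s) for s in ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF]
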