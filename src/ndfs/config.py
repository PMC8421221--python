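"""Run configuration: one flat record of every tunable physical parameter.

Defaults are the constants of the measured system: kBT at 298 K, 61 nm
arms, a 249 bp / 85 nm sample with lp = 50 nm, 5-degree angle bins, 3 bp
unwrapping bins, a 0.001 per-degree density cutoff, 2 nm coupling-grid
spacing, and 50 bootstrap replicates. Every output of the pipeline is
stamped with a hash of the configuration so runs are attributable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .coupling import HingeGeometry
from .exceptions import InputError
from .nucleosome import NucleosomeSpec, PiecewiseAdhesionModel
from .polymer import (
    GaussianChainSpec,
    KBT_PN_NM,
    RISE_PER_BP_NM,
    ThermalScale,
    WLCSpec,
    contour_length,
)


@dataclass
class RunConfig:
    # thermal / geometry
    kBT: float = KBT_PN_NM
    arm_length: float = 61.0
    attachment_radius: float = None
    radial_min: float = 11.0
    radial_max: float = 61.0
    # polymers
    linker_n: float = 4.0
    linker_b: float = 1.5
    sample_bp: int = 249
    sample_lp: float = 50.0
    rise_per_bp: float = RISE_PER_BP_NM
    grid_spacing: float = 2.0
    # nucleosome
    wrapped_bp: int = 147
    nucleosome_linker_bp: int = 51
    superhelix_radius: float = 4.18
    superhelix_turns: float = 1.67
    superhelix_pitch: float = 2.39
    adhesion_outer_bp: int = 35
    adhesion_gamma_outer: float = 0.15
    adhesion_gamma_inner: float = 1.0
    nucleosome_geometry_backend: str = "planar"
    # binning / estimation
    angle_bin: float = 5.0
    unwrap_bin: int = 3
    density_cutoff: float = 0.001
    spline_smoothing: float = None
    # bootstrap
    bootstrap_replicates: int = 50
    seed: int = 0

    # --- derived model objects -------------------------------------------
    def thermal(self) -> ThermalScale:
        return ThermalScale(self.kBT)

    def geometry(self) -> HingeGeometry:
        return HingeGeometry(self.arm_length, self.attachment_radius)

    def linker(self) -> GaussianChainSpec:
        return GaussianChainSpec(self.linker_n, self.linker_b)

    def sample_wlc(self) -> WLCSpec:
        return WLCSpec(contour_length(self.sample_bp, self.rise_per_bp), self.sample_lp)

    def nucleosome_spec(self) -> NucleosomeSpec:
        return NucleosomeSpec(
            total_bp=self.sample_bp,
            wrapped_bp=self.wrapped_bp,
            linker_bp=self.nucleosome_linker_bp,
            superhelix_radius=self.superhelix_radius,
            superhelix_turns=self.superhelix_turns,
            superhelix_pitch=self.superhelix_pitch,
            rise_per_bp=self.rise_per_bp,
            energy_model=PiecewiseAdhesionModel(
                outer_bp=self.adhesion_outer_bp,
                gamma_outer=self.adhesion_gamma_outer,
                gamma_inner=self.adhesion_gamma_inner,
            ),
            angle_bin=self.angle_bin,
            unwrap_bin=self.unwrap_bin,
            geometry_backend=self.nucleosome_geometry_backend,
        )

    # --- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"configuration file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
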