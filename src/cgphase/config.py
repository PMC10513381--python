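"""Validated key-value run configurations (YAML).

A config describes a full protocol: molecule source, force field,
electrostatics, box construction, thermostat/barostat settings, the
optional slab protocol (compress -> elongate -> anneal -> production),
the REMD ladder, and the analysis windows. Unknown keys are rejected;
every default is materialized on load so a dumped config is explicit and
``dump(load(x))`` is idempotent.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MoleculeConfig(_Strict):
    sequence: Optional[str] = None
    fasta: Optional[str] = None
    pdb: Optional[str] = None
    kind: Literal["protein", "dna", "rna"] = "protein"
    n_bp: Optional[int] = None  # dsDNA builder

    @model_validator(mode="after")
    def _one_source(self):
        sources = [self.sequence, self.fasta, self.pdb, self.n_bp]
        if sum(x is not None for x in sources) != 1:
            raise ValueError(
                "exactly one of sequence/fasta/pdb/n_bp must be given")
        return self


class ForceFieldConfig(_Strict):
    family: Literal["hps", "mpipi", "moff", "mrg_dna"] = "hps"
    scale: Literal["KR", "Urry"] = "Urry"
    mu: float = 1.0
    delta: Optional[float] = None
    rescaled: bool = False


class ElectrostaticsConfig(_Strict):
    dielectric: float = Field(80.0, gt=0)
    salt_mM: float = Field(100.0, gt=0)
    temperature_K: float = Field(300.0, gt=0)
    cutoff_nm: float = Field(3.5, gt=0)


class BoxConfig(_Strict):
    length_nm: float = Field(75.0, gt=0)
    n_copies: int = Field(1, ge=1)
    min_dist_nm: float = Field(0.7, gt=0)


class ThermostatConfig(_Strict):
    kind: Literal["langevin_middle", "nose_hoover"] = "langevin_middle"
    temperature_K: float = Field(300.0, gt=0)
    friction_per_ps: float = Field(1.0, ge=0)
    timestep_ps: float = Field(0.01, gt=0)


class BarostatConfig(_Strict):
    pressure_bar: float = Field(1.0, gt=0)
    move_interval: int = Field(25, ge=1)
    max_log_volume_step: float = Field(0.02, gt=0)


class SlabProtocolConfig(_Strict):
    """Compress at low T / 1 bar, elongate z, anneal, then production."""

    compress_steps: int = Field(5_000_000, ge=0)
    compress_temperature_K: float = Field(150.0, gt=0)
    elongate_z_nm: float = Field(400.0, gt=0)
    anneal_steps: int = Field(100_000, ge=0)
    anneal_from_K: float = Field(150.0, gt=0)
    production_steps: int = Field(200_000_000, ge=0)
    production_temperatures_K: list[float] = Field(default_factory=lambda: [300.0])


class RemdConfig(_Strict):
    ladder_K: list[float] = Field(
        default_factory=lambda: [300.0, 315.79, 333.33, 352.94, 375.00, 400.0])
    exchange_interval: int = Field(1000, ge=1)

    @model_validator(mode="after")
    def _increasing(self):
        if any(b <= a for a, b in zip(self.ladder_K, self.ladder_K[1:])):
            raise ValueError("REMD ladder must be strictly increasing")
        return self


class AnalysisConfig(_Strict):
    bin_width_nm: float = Field(1.0, gt=0)
    cluster_cutoff_nm: float = Field(5.0, gt=0)
    dense_halfwidth_nm: float = Field(5.0, gt=0)
    dilute_min_z_nm: float = Field(50.0, gt=0)
    persistence_fit_range: tuple[int, int] = (2, 20)


class RunConfig(_Strict):
    molecule: MoleculeConfig
    force_field: ForceFieldConfig = ForceFieldConfig()
    electrostatics: ElectrostaticsConfig = ElectrostaticsConfig()
    box: BoxConfig = BoxConfig()
    thermostat: ThermostatConfig = ThermostatConfig()
    barostat: BarostatConfig = BarostatConfig()
    slab: Optional[SlabProtocolConfig] = None
    remd: Optional[RemdConfig] = None
    analysis: AnalysisConfig = AnalysisConfig()
    n_steps: int = Field(10_000, ge=0)
    traj_stride: int = Field(10_000, ge=0)
    energy_stride: int = Field(1_000, ge=0)
    seed: int = 0

    def build_force_field(self):
        from . import forcefields as ff
        es = ff.ElectrostaticsSpec(
            dielectric=self.electrostatics.dielectric,
            salt_mM=self.electrostatics.salt_mM,
            temperature_K=self.electrostatics.temperature_K,
            cutoff=self.electrostatics.cutoff_nm)
        f = self.force_field
        if f.family == "hps":
            return ff.load_hps(f.scale, f.mu, f.delta, electrostatics=es)
        if f.family == "mpipi":
            return ff.load_mpipi(electrostatics=es)
        if f.family == "moff":
            return ff.load_moff(electrostatics=es)
        return ff.load_mrg_dna(rescaled=f.rescaled, electrostatics=es)

    def force_field_tag(self) -> str:
        return {"hps": "HPS", "mpipi": "Mpipi", "moff": "MOFF",
                "mrg_dna": "MRG-CG"}[self.force_field.family]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a key-value mapping")
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig) -> str:
    return yaml.safe_dump(config.model_dump(), sort_keys=True)
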