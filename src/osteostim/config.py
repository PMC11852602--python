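"""Run-configuration schema (YAML) for the simulator.

Every block maps 1:1 onto a domain dataclass; unknown keys are rejected so
typos fail loudly before any mesh is built.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .fixtures import FemurFixtureParams
from .materials import MaterialMapping
from .elasticity import LoadCase, DEFAULT_LOAD_CASES
from .electrostatics import DielectricParams, StimulationProtocol
from .remodeling import RemodelingParams, BMUClassParams


class ConfigError(ValueError):
    pass


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FixtureConfig(_Block):
    shaft_length: float = 80.0
    shaft_outer_radius: float = 14.0
    shaft_inner_radius: float = 7.0
    neck_length: float = 40.0
    neck_radius: float = 11.0
    neck_angle_deg: float = 55.0
    head_radius: float = 17.0
    target_element_count: int = 9000
    implant_stem_radius: float = 6.0
    implant_stem_length: float = 60.0
    implant_ball_radius: float = 10.0
    jitter: float = 0.0

    def to_params(self, implanted: bool, seed: int) -> FemurFixtureParams:
        return FemurFixtureParams(implanted=implanted, seed=seed,
                                  **self.model_dump())


class MaterialConfig(_Block):
    rho_a: float = 0.1
    rho_b: float = 1.8
    rho_0: float = 1.8
    hu_min: float = 0.0
    hu_max: float = 1700.0
    nu: float = 0.3
    n_bins: int = 50
    cortical_threshold: float = 1.3
    implant_E: float = 110_000.0
    implant_nu: float = 0.3

    def to_mapping(self) -> MaterialMapping:
        return MaterialMapping(**self.model_dump())


class LoadCaseConfig(_Block):
    name: str
    cycles: int
    joint_force_N: float
    joint_angle_deg: float
    muscle_force_N: float
    muscle_angle_deg: float

    def to_load_case(self, joint_patch: str) -> LoadCase:
        return LoadCase(joint_patch=joint_patch, **self.model_dump())


class DielectricConfig(_Block):
    beta11: float = 88.54e-12
    beta33: float = 106.248e-12

    def to_params(self) -> DielectricParams:
        return DielectricParams(beta11=self.beta11, beta33=self.beta33)


class StimulationConfig(_Block):
    voltage_V: float = 32.0
    amplitude: float = 0.0
    start_day: int = 101
    duration_days: int = 100
    electrode_set: str = "neck_electrode"
    ground_set: str = "base"

    def to_protocol(self) -> StimulationProtocol:
        return StimulationProtocol(
            electrode_voltage=self.voltage_V, amplitude=self.amplitude,
            start_day=self.start_day, duration_days=self.duration_days,
            electrode_set=self.electrode_set, ground_set=self.ground_set,
        )


class RemodelingConfig(_Block):
    m: float = 4.0
    kappa_d1: float = 0.5
    kappa_d2: float = 0.1
    fa_max: float = 0.1
    t_r_cortical: int = 24
    t_i_cortical: int = 8
    t_f_cortical: int = 64
    t_r_cancellous: int = 60
    t_i_cancellous: int = 57
    t_f_cancellous: int = 197
    v: float = 0.01
    d_bmu: float = 0.65
    d_e: float = 0.05
    d_o: float = 0.2
    dt_days: float = 1.0
    total_days: int = 300
    fe_update_interval: int = 1

    def to_params(self) -> RemodelingParams:
        d = self.model_dump()
        cort = BMUClassParams(d.pop("t_r_cortical"), d.pop("t_i_cortical"),
                              d.pop("t_f_cortical"))
        canc = BMUClassParams(d.pop("t_r_cancellous"), d.pop("t_i_cancellous"),
                              d.pop("t_f_cancellous"))
        return RemodelingParams(cortical=cort, cancellous=canc, **d)


class OutputConfig(_Block):
    directory: str = "results"
    snapshot_days: list[int] = []


class RunConfig(_Block):
    seed: int = 0
    log_level: str = "INFO"
    hu_noise_sd: float = 0.0
    fixture: FixtureConfig = FixtureConfig()
    material: MaterialConfig = MaterialConfig()
    load_cases: list[LoadCaseConfig] | None = None
    dielectric: DielectricConfig = DielectricConfig()
    stimulation: StimulationConfig = StimulationConfig()
    remodeling: RemodelingConfig = RemodelingConfig()
    output: OutputConfig = OutputConfig()

    def load_case_list(self, joint_patch: str) -> list[LoadCase]:
        if self.load_cases is None:
            return [
                LoadCase(n, c, jf, ja, mf, ma, joint_patch=joint_patch)
                for n, c, jf, ja, mf, ma in DEFAULT_LOAD_CASES
            ]
        return [lc.to_load_case(joint_patch) for lc in self.load_cases]


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        keys = sorted({".".join(str(p) for p in e["loc"]) for e in exc.errors()})
        raise ConfigError(f"invalid config keys: {', '.join(keys)}") from exc
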