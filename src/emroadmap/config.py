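"""Structured run configuration.

One YAML file drives the whole pipeline; every block is validated strictly
(unknown keys are rejected) and round-trips losslessly.  Units throughout:
millimetres, degrees, N·mm² for bending stiffness, MPa for moduli.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomBlock(_Strict):
    trunk_length: float = 120.0
    trunk_radius: float = 9.0
    aneurysm_amplitude: float = 9.0
    aneurysm_center_frac: float = 0.45
    aneurysm_extent: float = 22.0
    iliac_length: float = 160.0
    iliac_radius: float = 6.0
    branch_half_angle_deg: float = 25.0
    tortuosity_amplitude: float = 10.0
    tortuosity_wavelength: float = 100.0
    point_spacing: float = 2.0
    seed: int = 0
    circumferential_resolution: int = 16


class MechanicsBlock(_Strict):
    wall_e_eff: float = 0.05          # MPa
    wall_thickness: float = 2.0       # mm
    foundation_factor: float = 0.01
    laplacian_factor: float = 4.0
    contact_penalty: float = 60.0     # N/mm
    increment: float = 5.0            # mm
    tol_energy: float = 2e-4
    max_outer: int = 250


class ToolBlock(_Strict):
    ei: float = 6000.0                # N*mm^2, assembled tool
    h: float = 3.0                    # mm, rod discretization
    floppy_tip_length: float = 30.0   # mm
    floppy_ei_factor: float = 0.01
    sensor_offsets: tuple[float, float, float] = (5.0, 105.0, 175.0)

    @field_validator("sensor_offsets")
    @classmethod
    def _increasing(cls, v):
        if not (v[0] < v[1] < v[2]):
            raise ValueError("sensor_offsets must be strictly increasing")
        return v


class ScheduleBlock(_Strict):
    names: list[str] = Field(default_factory=lambda: ["Pos1", "Pos2"])
    # depths in mm of inserted arc length; None = derive from phantom geometry
    # (Pos1 just past the aortic bifurcation, Pos2 near full insertion)
    depths: list[float] | None = None


class AngleEntry(_Strict):
    label: str
    theta_f: float
    theta_s: float


class NoiseBlock(_Strict):
    sigma: float = 0.5                # mm, isotropic EM noise per coordinate
    fiducial_sigma: float = 0.0       # mm, landmark sampling noise
    seed: int = 0


class TransformBlock(_Strict):
    axis: tuple[float, float, float] = (0.3, 0.5, 0.8)
    angle_deg: float = 35.0
    translation: tuple[float, float, float] = (120.0, -40.0, 25.0)


class ExperimentBlock(_Strict):
    truth_label: str = "alpha"
    transform: TransformBlock = Field(default_factory=TransformBlock)


class EvaluationBlock(_Strict):
    spacing: float = 1.0              # mm, label-map voxel size
    sample_density: float = 1.0       # samples per mm^2 for surface distances


class OutputBlock(_Strict):
    directory: str = "runs/default"


class RunConfig(_Strict):
    """Full pipeline configuration with the default study conditions."""

    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    mechanics: MechanicsBlock = Field(default_factory=MechanicsBlock)
    tool: ToolBlock = Field(default_factory=ToolBlock)
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    angles: list[AngleEntry] = Field(default_factory=lambda: [
        AngleEntry(label="alpha", theta_f=4.0, theta_s=13.0),
        AngleEntry(label="beta", theta_f=4.0, theta_s=38.0),
        AngleEntry(label="gamma", theta_f=23.0, theta_s=30.0),
    ])
    noise: NoiseBlock = Field(default_factory=NoiseBlock)
    experiment: ExperimentBlock = Field(default_factory=ExperimentBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(data)
        except Exception as err:
            raise ValidationError(f"invalid run configuration: {err}") from err

    def to_yaml(self, path=None) -> str:
        import yaml

        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
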