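"""Study configuration: agents, eye geometry, and the VEGF-challenge design.

The shipped defaults describe the head-to-head rabbit comparison of
aflibercept, brolucizumab, and ranibizumab: rabbit-scaled intravitreal
doses (1000 / 3000 / 250 µg in 25 µL), KinExA solution affinities
(171.9 fM / 1.3 pM / 21.8 pM), and the intravitreal VEGF-A165 challenge
schedule (500 ng at days 5, 26, 33, 40, 54, 68; leakage read out 47 h
after each challenge; 7 animals per group per time point).

Molecular weights and eye geometry are literature-sourced defaults (they
are not part of the assay readouts) and can be overridden in the config
file. All fields carry explicit units in their names or docstrings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .units import mass_to_molar


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AgentSpec(_StrictModel):
    """Molecular and dosing parameters of one anti-VEGF agent.

    ``kd_assay`` is the solution equilibrium dissociation constant in mol/L
    at assay temperature (23 °C); ``kd_temp_factor`` is a dimensionless
    multiplier converting it to body temperature (default 1.0 = no
    correction; a documented hook, since published corrections vary).
    ``binding_sites_per_drug`` counts VEGF-binding sites per drug molecule
    and ``sites_per_vegf`` counts drug-binding sites per VEGF-A165 dimer:
    a trap that sequesters the whole dimer has (1, 1); a Fab or scFv that
    occupies one epitope of the homodimer has (1, 2).
    """

    name: str
    molecular_weight: float = Field(gt=0, description="kDa")
    dose_mass: float = Field(gt=0, description="µg per intravitreal injection")
    injection_volume: float = Field(gt=0, description="µL")
    kd_assay: float = Field(gt=0, description="mol/L at 23 °C")
    kd_temp_factor: float = Field(default=1.0, gt=0)
    binding_sites_per_drug: Literal[1, 2] = 1
    sites_per_vegf: Literal[1, 2] = 2

    @model_validator(mode="after")
    def _finite_kd(self):
        if not (self.kd_assay > 0 and self.kd_assay < float("inf")):
            raise ValueError("kd_assay must be finite and positive")
        return self

    @property
    def kd_body(self) -> float:
        """Body-temperature K_D in mol/L."""
        return self.kd_assay * self.kd_temp_factor

    def initial_site_concentration_nm(self, vitreous_volume_ml: float) -> float:
        """Binding-site concentration (nM) right after injection, assuming
        instantaneous distribution into the vitreous volume."""
        molar = mass_to_molar(self.dose_mass, self.molecular_weight, vitreous_volume_ml)
        return molar * self.binding_sites_per_drug * 1e9


class EyeGeometry(_StrictModel):
    """Rabbit eye geometry for the anterior-route elimination model.

    Defaults are literature-plausible rabbit values, not measured here:
    vitreous 1.5 mL (typical range 1.15–1.7 mL), aqueous chamber 0.3 mL
    turning over at ~3 µL/min, a ~0.9 cm effective diffusion path, and
    vitreous viscosity close to water at body temperature.
    """

    vitreous_volume: float = Field(default=1.5, gt=0, description="mL")
    aqueous_volume: float = Field(default=0.3, gt=0, description="mL")
    aqueous_outflow: float = Field(default=3.0, gt=0, description="µL/min")
    diffusion_path_length: float = Field(default=0.9, gt=0, description="cm")
    temperature: float = Field(default=310.15, gt=0, description="K")
    vitreous_viscosity: float = Field(default=7.0e-4, gt=0, description="Pa·s")

    @model_validator(mode="after")
    def _plausible_vitreous(self):
        if not (0.5 <= self.vitreous_volume <= 3.0):
            raise ValueError(
                f"vitreous_volume {self.vitreous_volume} mL is outside the "
                "plausible rabbit range"
            )
        return self


class ChallengeDesign(_StrictModel):
    """Intravitreal VEGF challenge schedule and cohort structure."""

    vegf_dose_mass: float = Field(default=500.0, gt=0, description="ng")
    vegf_injection_volume: float = Field(default=50.0, gt=0, description="µL")
    vegf_molecular_weight: float = Field(default=38.2, gt=0, description="kDa (dimer)")
    challenge_days: list[float] = Field(default=[5, 26, 33, 40, 54, 68])
    observation_lag: float = Field(default=47.0, gt=0, description="hours")
    animals_per_group: int = Field(default=7, gt=0)

    @model_validator(mode="after")
    def _days_increasing(self):
        days = self.challenge_days
        if len(days) == 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("challenge_days must be non-empty and strictly increasing")
        return self

    def vegf_site_concentration_nm(self, vitreous_volume_ml: float) -> float:
        """VEGF binding-site concentration (nM) after a challenge injection
        distributes into the vitreous; the A165 dimer carries two epitopes."""
        molar = mass_to_molar(
            self.vegf_dose_mass * 1e-3, self.vegf_molecular_weight, vitreous_volume_ml
        )
        return molar * 2 * 1e9


class StudyConfig(_StrictModel):
    agents: list[AgentSpec]
    geometry: EyeGeometry = EyeGeometry()
    design: ChallengeDesign = ChallengeDesign()

    def agent(self, name: str) -> AgentSpec:
        for a in self.agents:
            if a.name == name:
                return a
        raise ConfigError(f"no agent named {name!r} in config")


#: Literature-sourced defaults; overridable via config file. Doses and
#: affinities are the rabbit study values; molecular weights are nominal
#: (aflibercept 115 kDa trap, ranibizumab 48 kDa Fab, brolucizumab 26 kDa
#: scFv, VEGF-A165 dimer 38.2 kDa protein core).
DEFAULT_AGENTS = [
    AgentSpec(name="aflibercept", molecular_weight=115.0, dose_mass=1000.0,
              injection_volume=25.0, kd_assay=171.9e-15,
              binding_sites_per_drug=1, sites_per_vegf=1),
    AgentSpec(name="brolucizumab", molecular_weight=26.0, dose_mass=3000.0,
              injection_volume=25.0, kd_assay=1.3e-12,
              binding_sites_per_drug=1, sites_per_vegf=2),
    AgentSpec(name="ranibizumab", molecular_weight=48.0, dose_mass=250.0,
              injection_volume=25.0, kd_assay=21.8e-12,
              binding_sites_per_drug=1, sites_per_vegf=2),
]

#: Observed vitreal half-lives (days) from the rabbit NCA; used wherever a
#: measured half-life should drive the simulation instead of the size-scaling
#: prediction.
OBSERVED_HALF_LIVES_DAYS = {"aflibercept": 5.63, "brolucizumab": 3.10, "ranibizumab": 3.15}

#: Bioanalytical lower limits of quantification, µg/mL, per assay.
ASSAY_LLOQ_UG_PER_ML = {"aflibercept": 6.25e-3, "brolucizumab": 20.0e-3, "ranibizumab": 3.0e-3}


def default_study_config() -> StudyConfig:
    return StudyConfig(agents=[a.model_copy(deep=True) for a in DEFAULT_AGENTS])


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_study_config(path) -> StudyConfig:
    """Read a YAML study configuration.

    Unknown keys are rejected with a message naming the key; missing
    mandatory fields and out-of-range values raise :class:`ConfigError`
    naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    try:
        return StudyConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {_format_validation_error(exc)}") from exc


def save_study_config(config: StudyConfig, path) -> None:
    """Write a config back to YAML; round-trips through load_study_config."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False))
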