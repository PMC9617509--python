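"""Synthetic study generator.

Produces every input the analysis pipeline consumes, with the statistical
structure the analysis assumes, so the whole chain runs and is testable
without external data:

* duplicate KinExA titration curves at each agent's published concentration
  design, with multiplicative signal noise (default 2% CV);
* sparse destructive-sampling vitreous concentration profiles (7 animals per
  termination day) with lognormal inter-animal variability (default 15% CV)
  and assay-specific LLOQ censoring;
* binary leakage outcomes on the actual cohort schedule: 7 animals per
  group per challenge day, challenges at days 5/26/33/40/54/68, observation
  47 ± 3 h post-challenge, animals limited to two VEGF exposures via
  (first, final) challenge-day pairs, plus a vehicle arm at 100% free VEGF;
* triplicate calcium-mobilization inhibition curves per agent for the 4PL
  potency stage.

Every generator is fully deterministic under the spec seed; independent
substreams are derived per dataset so adding one generator never perturbs
another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import BindingCurve, kinexa_signal
from .challenge import drug_sites_at_day, kinetics_params_for_agent, percent_free_vegf
from .config import (
    ASSAY_LLOQ_UG_PER_ML,
    OBSERVED_HALF_LIVES_DAYS,
    AgentSpec,
    ChallengeDesign,
    EyeGeometry,
    default_study_config,
)
from .errors import ConfigError
from .leakage import LeakageLogisticModel
from .pk import simulate_profile
from .potency import InhibitionCurve, four_pl

__all__ = [
    "SyntheticStudySpec",
    "KINEXA_DESIGNS",
    "generate_kinexa_dataset",
    "generate_vitreous_pk_dataset",
    "generate_leakage_dataset",
    "generate_potency_dataset",
]

#: Published KinExA concentration designs, mol/L:
#: (constant inhibitor concentrations, (titration low, titration high)).
KINEXA_DESIGNS = {
    "aflibercept": ([2.5e-12, 5.0e-12, 50.0e-12], (48.8e-15, 1.0e-9)),
    "brolucizumab": ([25e-12, 50e-12, 400e-12], (0.12e-12, 4.0e-9)),
    "ranibizumab": ([50e-12, 400e-12], (1.46e-12, 10.0e-9)),
}

#: In vitro potency truths (nM) used by the synthetic calcium-mobilization
#: generator; the reported HUVEC assay IC50s.
IC50_TRUTHS_NM = {"aflibercept": 2.42, "brolucizumab": 5.74, "ranibizumab": 10.82}

_TWO31 = 2 ** 31


def _substream(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible substream per (seed, dataset tag); the tag
    is hashed with CRC32 so streams are stable across interpreter runs."""
    tag_int = zlib.crc32(tag.encode()) % _TWO31
    return np.random.default_rng(np.random.SeedSequence([seed % _TWO31, tag_int]))


@dataclass
class SyntheticStudySpec:
    """Study conditions for the generators; defaults are the rabbit study's."""

    seed: int = 0
    agents: list[AgentSpec] = field(default_factory=lambda: default_study_config().agents)
    geometry: EyeGeometry = field(default_factory=EyeGeometry)
    design: ChallengeDesign = field(default_factory=ChallengeDesign)
    noise_cv_pk: float = 0.15
    noise_cv_binding: float = 0.02
    noise_sd_potency: float = 0.05
    leakage_truth: tuple[float, float] = (70.0, 24.0 / np.log(4.0))
    animals_per_group: int = 7
    observation_jitter_hours: float = 3.0
    pk_sampling_days: tuple = (5, 26, 33, 40, 54, 56)
    satellite_animals_per_agent: int = 4

    def agent(self, name: str) -> AgentSpec:
        for a in self.agents:
            if a.name == name:
                return a
        raise ConfigError(f"no agent named {name!r}")


def _titration_series(low: float, high: float) -> np.ndarray:
    """Approximately 3-fold dilution series with exact endpoints."""
    n = int(round(np.log(high / low) / np.log(3.0))) + 1
    return np.geomspace(low, high, max(n, 5))


def generate_kinexa_dataset(spec: SyntheticStudySpec, agent_name: str,
                            kd_truth: float | None = None) -> list[BindingCurve]:
    """Duplicate equilibrium titration curves at the agent's published
    design, generated from the one-site model at ``kd_truth`` (default: the
    agent's configured K_D) with multiplicative Gaussian signal noise."""
    if agent_name not in KINEXA_DESIGNS:
        raise ConfigError(f"no KinExA design for {agent_name!r}")
    agent = spec.agent(agent_name)
    kd = kd_truth if kd_truth is not None else agent.kd_assay
    constants, (low, high) = KINEXA_DESIGNS[agent_name]
    titrant = _titration_series(low, high)
    rng = _substream(spec.seed, f"kinexa:{agent_name}")
    curves = []
    for const in constants:
        for rep in (1, 2):
            clean = kinexa_signal(const, titrant, kd, amplitude=1.0, background=0.05)
            noisy = clean * (1.0 + spec.noise_cv_binding * rng.standard_normal(len(titrant)))
            curves.append(BindingCurve(
                constant_conc=const, titrant_concs=titrant, signals=noisy,
                replicate_id=f"{agent_name}_c{const:.3g}_r{rep}",
            ))
    return curves


def generate_vitreous_pk_dataset(spec: SyntheticStudySpec,
                                 t_halves: dict | None = None) -> pd.DataFrame:
    """Destructive-sampling vitreous concentrations for every agent.

    ``animals_per_group`` eyes are terminated at each sampling day; each
    contributes one sample with lognormal inter-animal noise; values below
    the agent's assay LLOQ are flagged. Returns a tidy frame with columns
    animal_id, agent, day, conc_ug_per_ml, below_lloq.
    """
    t_halves = t_halves or OBSERVED_HALF_LIVES_DAYS
    rows = []
    for agent in spec.agents:
        th = t_halves.get(agent.name)
        if th is None:
            raise ConfigError(f"no half-life for {agent.name!r}")
        lloq = ASSAY_LLOQ_UG_PER_ML.get(agent.name, 0.0)
        schedule = np.repeat(np.asarray(spec.pk_sampling_days, dtype=float),
                             spec.animals_per_group)
        rng = _substream(spec.seed, f"pk:{agent.name}")
        prof = simulate_profile(agent, th, schedule, noise_cv=spec.noise_cv_pk,
                                lloq=lloq, seed=rng,
                                volume_ml=spec.geometry.vitreous_volume)
        for k, (day, conc, flag) in enumerate(zip(prof.times, prof.concentrations,
                                                  prof.below_lloq_flags)):
            animal = f"{agent.name[:3]}-d{int(day)}-{k % spec.animals_per_group + 1}"
            rows.append((animal, agent.name, day, conc, bool(flag)))
    return pd.DataFrame(rows, columns=["animal_id", "agent", "day",
                                       "conc_ug_per_ml", "below_lloq"])


def _challenge_pairs(days) -> list[tuple]:
    """(first, final) challenge-day pairs limiting each animal to two VEGF
    exposures: the first half of the schedule is paired with the second."""
    days = list(days)
    half = len(days) // 2
    pairs = [(days[i], days[half + i]) for i in range(half)]
    if len(days) % 2:
        pairs.append((days[-1],))
    return pairs


def generate_leakage_dataset(spec: SyntheticStudySpec,
                             t_halves: dict | None = None,
                             mode: str = "quasi_equilibrium") -> pd.DataFrame:
    """Leakage observations for every arm (agents + vehicle) on the cohort
    schedule.

    For each animal and challenge, the free-VEGF percentage is computed at
    the animal's actual observation lag (47 h jittered uniformly by ±3 h)
    and the binary outcome drawn Bernoulli from the logistic truth; the
    recorded ``percent_free`` is the model-assigned value at the nominal
    47 h lag, as an analyst would assign it. Ordinal scores are synthesized
    as 0/1 (no/mild leakage) or 3 (moderate-to-severe), consistent with the
    score ≥ 2 dichotomization.
    """
    t_halves = t_halves or OBSERVED_HALF_LIVES_DAYS
    truth = LeakageLogisticModel(x50=spec.leakage_truth[0], slope=spec.leakage_truth[1])
    design, geometry = spec.design, spec.geometry
    rng = _substream(spec.seed, "leakage")
    arms = [a.name for a in spec.agents] + ["vehicle"]

    # nominal and jitter-resolved percent free per (arm, day)
    nominal: dict[tuple, float] = {}
    params_by_agent = {}
    for arm in arms:
        for day in design.challenge_days:
            if arm == "vehicle":
                nominal[(arm, day)] = 100.0
            else:
                agent = spec.agent(arm)
                th = t_halves[arm]
                params = params_by_agent.setdefault(
                    arm, kinetics_params_for_agent(agent, design, drug_t_half_days=th))
                drug_nm = drug_sites_at_day(agent, day, th, geometry)
                res = percent_free_vegf(agent, drug_nm, design, params, geometry,
                                        mode=mode)
                nominal[(arm, day)] = res.percent_free

    rows = []
    pairs = _challenge_pairs(design.challenge_days)
    for arm in arms:
        for p_idx, pair in enumerate(pairs):
            for k in range(spec.animals_per_group):
                animal = f"{arm[:3]}-p{p_idx + 1}-{k + 1}"
                for day in pair:
                    lag = design.observation_lag + rng.uniform(
                        -spec.observation_jitter_hours, spec.observation_jitter_hours)
                    if arm == "vehicle":
                        pf_true = 100.0
                    else:
                        agent = spec.agent(arm)
                        th = t_halves[arm]
                        drug_nm = drug_sites_at_day(agent, day, th, geometry)
                        pf_true = percent_free_vegf(
                            agent, drug_nm, design, params_by_agent[arm], geometry,
                            mode=mode, observation_lag_hours=lag).percent_free
                    leak = int(rng.random() < truth.predict(pf_true))
                    score = 3 if leak else int(rng.integers(0, 2))
                    rows.append((animal, arm, day, score, nominal[(arm, day)]))
    return pd.DataFrame(rows, columns=["animal_id", "agent", "challenge_day",
                                       "score", "percent_free"])


def generate_potency_dataset(spec: SyntheticStudySpec, n_replicates: int = 3,
                             ic50_truths: dict | None = None,
                             n_conc: int = 8) -> list[InhibitionCurve]:
    """Replicate 4PL inhibition curves per agent: ``n_conc`` three-fold
    spaced concentrations bracketing the IC50 truth (hill 1, top 1,
    bottom 0) with additive Gaussian response noise."""
    ic50_truths = ic50_truths or IC50_TRUTHS_NM
    curves = []
    for agent in spec.agents:
        truth = ic50_truths.get(agent.name)
        if truth is None:
            continue
        rng = _substream(spec.seed, f"potency:{agent.name}")
        half = (n_conc - 1) / 2.0
        concs = truth * 3.0 ** (np.arange(n_conc) - half)
        for rep in range(n_replicates):
            clean = four_pl(concs, truth, 1.0, 1.0, 0.0)
            noisy = clean + spec.noise_sd_potency * rng.standard_normal(n_conc)
            curves.append(InhibitionCurve(
                inhibitor_concs=concs, responses=noisy,
                replicate_id=f"{agent.name}_rep{rep + 1}",
            ))
    return curves
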