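"""Ocular pharmacokinetics: anterior-route half-life prediction, vitreous
concentration-time simulation, and noncompartmental analysis (NCA).

The minimal physiology-based model assumes biologics leave the eye
predominantly by the anterior route: diffusion through the vitreous followed
by clearance from the anterior chamber via aqueous humor turnover. The
vitreous-to-aqueous transfer rate scales with the molecule's diffusivity,
which by Stokes-Einstein is inversely proportional to its hydrodynamic
radius; with compact-globule scaling r_h ∝ MW^(1/3), the anterior-dominated
vitreal half-life is therefore proportional to MW^(1/3). A single geometry
factor calibrates the absolute scale, anchored to one reference agent's
half-life.

NCA follows standard practice: linear-up/log-down trapezoidal AUC,
terminal slope λz from the best adjusted-R² log-linear window, C0
back-extrapolated from the first two points, CL = dose/AUC_inf and
Vss = CL × MRT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants

from .config import AgentSpec, EyeGeometry
from .errors import ConfigError, NCAError
from .units import per_minute_to_per_day

__all__ = [
    "ConcentrationProfile",
    "NCAResult",
    "PkModelParams",
    "hydrodynamic_radius",
    "predict_vitreal_half_life",
    "simulate_profile",
    "nca",
    "pool_profiles",
    "read_concentration_data",
    "write_concentration_data",
]

#: Globular-protein Stokes-radius prefactor, nm per kDa^(1/3)
#: (empirical compact-globule scaling; configurable).
DEFAULT_RH_PREFACTOR_NM = 0.66
DEFAULT_RH_EXPONENT = 1.0 / 3.0


@dataclass
class ConcentrationProfile:
    """Vitreous concentration-time observations for one agent.

    Times in days (nonnegative, sorted, repeats allowed for destructive
    sampling); concentrations in µg/mL. Points below the assay LLOQ are
    flagged rather than imputed.
    """

    times: np.ndarray
    concentrations: np.ndarray
    lloq: float = 0.0
    below_lloq_flags: np.ndarray | None = None
    agent: str = ""
    source: str = "observed"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if np.any(self.times < 0):
            raise ConfigError("times must be nonnegative")
        if np.any(np.diff(self.times) < 0):
            raise ConfigError("times must be sorted ascending")
        if np.any(self.concentrations < 0):
            raise ConfigError("concentrations must be nonnegative")
        if len(self.times) != len(self.concentrations):
            raise ConfigError("times and concentrations must have equal length")
        if self.below_lloq_flags is None:
            self.below_lloq_flags = self.concentrations < self.lloq
        else:
            self.below_lloq_flags = np.asarray(self.below_lloq_flags, dtype=bool)
            if len(self.below_lloq_flags) != len(self.times):
                raise ConfigError("below_lloq_flags length mismatch")

    def quantifiable(self) -> "ConcentrationProfile":
        """Profile truncated at the first below-LLOQ point (that point
        marks the t_last boundary and is excluded)."""
        flags = self.below_lloq_flags
        if flags.any():
            cut = int(np.argmax(flags))
        else:
            cut = len(self.times)
        return ConcentrationProfile(
            times=self.times[:cut], concentrations=self.concentrations[:cut],
            lloq=self.lloq, below_lloq_flags=np.zeros(cut, dtype=bool),
            agent=self.agent, source=self.source,
        )


@dataclass
class NCAResult:
    """Noncompartmental summary of one vitreous profile (canonical units:
    days, mL, µg)."""

    auc: float        # day·µg/mL, extrapolated to infinity
    aumc: float       # day²·µg/mL, extrapolated to infinity
    c0: float         # µg/mL, back-extrapolated
    lambda_z: float   # 1/day
    t_half: float     # days
    cl: float         # mL/day
    vss: float        # mL
    t_last: float     # day
    c_last: float     # µg/mL
    auc_last: float = np.nan
    lambda_z_points: int = 0
    lambda_z_adj_r2: float = np.nan
    agent: str = ""

    def to_dict(self) -> dict:
        """Report keyed by the conventional NCA parameter names."""
        return {
            "agent": self.agent,
            "AUC": self.auc, "AUMC": self.aumc, "C_0": self.c0,
            "lambda_z": self.lambda_z, "t_1/2": self.t_half,
            "CL": self.cl, "V_ss": self.vss,
            "T_last": self.t_last, "C_last": self.c_last,
            "AUC_last": self.auc_last,
            "lambda_z_points": self.lambda_z_points,
            "lambda_z_adj_r2": self.lambda_z_adj_r2,
        }


@dataclass
class PkModelParams:
    """Parameters of the two-compartment anterior-elimination model.

    Either supply an absolute vitreous→aqueous transfer rate, or a
    geometry_factor (dimensionless multiplier on the Stokes-Einstein
    transfer rate D/L²), or let the caller calibrate via an anchor agent.
    """

    hydrodynamic_radius: float | None = None       # nm, overrides MW scaling
    transfer_rate_vit_to_aq: float | None = None   # 1/day, absolute
    aqueous_elimination_rate: float | None = None  # 1/day; default from geometry
    geometry_factor: float | None = None
    rh_prefactor: float = DEFAULT_RH_PREFACTOR_NM
    rh_exponent: float = DEFAULT_RH_EXPONENT


def hydrodynamic_radius(molecular_weight_kda: float,
                        prefactor: float = DEFAULT_RH_PREFACTOR_NM,
                        exponent: float = DEFAULT_RH_EXPONENT) -> float:
    """Hydrodynamic (Stokes) radius in nm from molecular weight in kDa,
    r_h = prefactor × MW^exponent (compact-globule default exponent 1/3)."""
    if molecular_weight_kda <= 0:
        raise ConfigError("molecular_weight must be positive")
    if prefactor <= 0:
        raise ConfigError("prefactor must be positive")
    return prefactor * molecular_weight_kda ** exponent


def _stokes_einstein_diffusivity_cm2_per_day(radius_nm: float, geometry: EyeGeometry) -> float:
    """D = kB·T / (6π η r), converted to cm²/day."""
    d_m2_s = constants.k * geometry.temperature / (
        6.0 * np.pi * geometry.vitreous_viscosity * radius_nm * 1e-9)
    return d_m2_s * 1e4 * 86400.0


def aqueous_elimination_rate(geometry: EyeGeometry) -> float:
    """First-order anterior-chamber clearance rate (1/day) from aqueous
    humor turnover: outflow / aqueous volume."""
    outflow_ml_per_day = per_minute_to_per_day(geometry.aqueous_outflow) / 1e3
    return float(outflow_ml_per_day / geometry.aqueous_volume)


def predict_vitreal_half_life(agent: AgentSpec, geometry: EyeGeometry,
                              params: PkModelParams | None = None,
                              anchor: tuple[float, float] | None = None) -> float:
    """Predicted vitreal half-life (days) from the two-compartment
    anterior-elimination model.

    The linear system (vitreous → aqueous → outflow) has rate constants
    k_vt (vitreous→aqueous transfer, size-dependent) and k_aq (aqueous
    turnover); the terminal half-life is ln2 over the slowest eigenvalue.
    In the usual anterior-dominated regime (k_vt ≪ k_aq) the half-life is
    proportional to the hydrodynamic radius.

    ``anchor = (reference_mw_kda, reference_half_life_days)`` calibrates the
    geometry factor so the reference molecule's predicted half-life matches;
    alternatively pass absolute rates via ``params``. One of the two is
    required.
    """
    params = params or PkModelParams()
    r_agent = params.hydrodynamic_radius or hydrodynamic_radius(
        agent.molecular_weight, params.rh_prefactor, params.rh_exponent)
    k_aq = params.aqueous_elimination_rate or aqueous_elimination_rate(geometry)

    if params.transfer_rate_vit_to_aq is not None:
        k_vt = params.transfer_rate_vit_to_aq
    else:
        d_agent = _stokes_einstein_diffusivity_cm2_per_day(r_agent, geometry)
        base_rate = d_agent / geometry.diffusion_path_length ** 2
        if anchor is not None:
            ref_mw, ref_t_half = anchor
            if ref_t_half <= 0 or ref_mw <= 0:
                raise ConfigError("anchor must have positive MW and half-life")
            r_ref = hydrodynamic_radius(ref_mw, params.rh_prefactor, params.rh_exponent)
            d_ref = _stokes_einstein_diffusivity_cm2_per_day(r_ref, geometry)
            k_vt_ref = np.log(2.0) / ref_t_half
            gf = k_vt_ref * geometry.diffusion_path_length ** 2 / d_ref
            k_vt = gf * base_rate
        elif params.geometry_factor is not None:
            k_vt = params.geometry_factor * base_rate
        else:
            raise ConfigError(
                "predict_vitreal_half_life needs a calibration anchor, an "
                "absolute transfer rate, or a geometry_factor")

    # vitreous/aqueous amounts: dAv/dt = -k_vt Av ; dAa/dt = k_vt Av - k_aq Aa
    system = np.array([[-k_vt, 0.0], [k_vt, -k_aq]])
    eig = np.linalg.eigvals(system).real
    slowest = np.min(np.abs(eig))
    if slowest <= 0:
        raise ConfigError("degenerate elimination system")
    return float(np.log(2.0) / slowest)


def simulate_profile(agent: AgentSpec, t_half: float, schedule, noise_cv: float = 0.0,
                     lloq: float = 0.0, seed=None, volume_ml: float = 1.5,
                     t_half_dist: float | None = None, frac_dist: float = 0.0,
                     c0_ug_per_ml: float | None = None) -> ConcentrationProfile:
    """Simulate a vitreous concentration-time profile.

    Monoexponential decay from C0 = dose/volume (or an explicit
    ``c0_ug_per_ml``, e.g. a back-extrapolated observed value) by default;
    an optional
    faster distribution phase (``t_half_dist``, fraction ``frac_dist``)
    makes it biexponential. Noise is multiplicative lognormal with median 1
    (geometric CV ``noise_cv``), emulating inter-animal variability in
    destructive sampling; repeat a day in ``schedule`` once per animal.
    Points below ``lloq`` are flagged. Fully reproducible under ``seed``.
    """
    if t_half <= 0:
        raise ConfigError("t_half must be positive")
    times = np.sort(np.asarray(schedule, dtype=float))
    c0 = c0_ug_per_ml if c0_ug_per_ml is not None else agent.dose_mass / volume_ml
    lam = np.log(2.0) / t_half
    conc = c0 * np.exp(-lam * times)
    if t_half_dist is not None and frac_dist > 0:
        lam_d = np.log(2.0) / t_half_dist
        conc = c0 * (frac_dist * np.exp(-lam_d * times)
                     + (1.0 - frac_dist) * np.exp(-lam * times))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        conc = conc * rng.lognormal(mean=0.0, sigma=sigma, size=len(times))
    return ConcentrationProfile(
        times=times, concentrations=conc, lloq=lloq,
        agent=agent.name, source="simulated",
    )


def pool_profiles(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Pool repeated samples per nominal day by geometric mean of the
    quantifiable concentrations (destructive-sampling profiles are pooled
    before NCA). The first day on which at least half the samples fall
    below the LLOQ ends the profile: censored values are never imputed, and
    a majority-censored day cannot give an unbiased pooled value, so it is
    treated as the t_last boundary."""
    days, concs = [], []
    for day in np.unique(profile.times):
        at_day = profile.times == day
        flagged = profile.below_lloq_flags[at_day]
        if flagged.sum() * 2 >= len(flagged):
            break
        mask = at_day & ~profile.below_lloq_flags
        days.append(day)
        concs.append(float(np.exp(np.mean(np.log(profile.concentrations[mask])))))
    return ConcentrationProfile(
        times=np.array(days), concentrations=np.array(concs), lloq=profile.lloq,
        below_lloq_flags=np.zeros(len(days), dtype=bool),
        agent=profile.agent, source=profile.source,
    )


def _best_lambda_z_window(times, concs):
    """Log-linear terminal regression over the adjusted-R²-maximizing suffix
    of ≥3 points strictly after the observed peak (the peak itself is
    excluded). Returns (lambda_z, n_points, adj_r2)."""
    i_max = int(np.argmax(concs))
    cand_t = times[i_max + 1:]
    cand_c = concs[i_max + 1:]
    n = len(cand_t)
    if n < 3:
        raise NCAError(
            f"terminal phase needs ≥3 post-peak points, have {n} "
            f"(usable times: {list(times)})")
    best = None
    for start in range(0, n - 2):
        t_w = cand_t[start:]
        c_w = cand_c[start:]
        m = len(t_w)
        slope, intercept = np.polyfit(t_w, np.log(c_w), 1)
        pred = intercept + slope * t_w
        ss_res = float(np.sum((np.log(c_w) - pred) ** 2))
        ss_tot = float(np.sum((np.log(c_w) - np.mean(np.log(c_w))) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        adj = 1.0 - (1.0 - r2) * (m - 1) / (m - 2)
        if slope >= 0:
            continue
        # prefer higher adjusted R²; ties (within 1e-4) go to more points
        if best is None or adj > best[2] + 1e-4:
            best = (-slope, m, adj)
    if best is None:
        raise NCAError(
            f"no declining terminal window found (usable times: {list(times)})")
    return best


def _auc_aumc_segment(t1, t2, c1, c2):
    """Linear-up/log-down trapezoid for one segment: linear when the
    concentration rises or is flat, log-trapezoidal (exact for exponential
    decay) when it falls."""
    dt = t2 - t1
    if c2 >= c1 or c1 <= 0 or c2 <= 0:
        auc = dt * (c1 + c2) / 2.0
        aumc = dt * (t1 * c1 + t2 * c2) / 2.0
    else:
        k = np.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
    return auc, aumc


def nca(profile: ConcentrationProfile, dose_ug: float) -> NCAResult:
    """Noncompartmental analysis of a vitreous profile.

    Below-LLOQ points are excluded (first below-LLOQ sets the t_last
    boundary); λz comes from the best adjusted-R² log-linear suffix of
    ≥3 post-peak points; AUC/AUMC use linear-up/log-down trapezoids with a
    c_last/λz (and c_last(t_last/λz + 1/λz²)) tail; C0 is back-extrapolated
    log-linearly from the first two points; CL = dose/AUC_inf and
    Vss = CL × AUMC_inf/AUC_inf.
    """
    if dose_ug <= 0:
        raise ConfigError("dose must be positive")
    if len(profile.times) >= 2 and len(np.unique(profile.times)) != len(profile.times):
        # repeated sampling days (destructive design): pool before analysis
        q = pool_profiles(profile)
    else:
        q = profile.quantifiable()
    times, concs = q.times, q.concentrations
    if len(times) < 3:
        raise NCAError(
            f"need ≥3 quantifiable points, have {len(times)} "
            f"(usable times: {list(times)})")
    if np.any(concs <= 0):
        raise NCAError("quantifiable concentrations must be positive")

    lambda_z, n_lz, adj_r2 = _best_lambda_z_window(times, concs)
    t_half = float(np.log(2.0) / lambda_z)

    # back-extrapolated C0 from the first two points (falls back to the
    # first observation if the profile does not decline there)
    if concs[1] < concs[0] and times[1] > times[0]:
        slope0 = (np.log(concs[1]) - np.log(concs[0])) / (times[1] - times[0])
        c0 = float(np.exp(np.log(concs[0]) - slope0 * times[0]))
    else:
        c0 = float(concs[0])

    if times[0] > 0:
        t_grid = np.concatenate([[0.0], times])
        c_grid = np.concatenate([[c0], concs])
    else:
        t_grid, c_grid = times, concs

    auc_last = aumc_last = 0.0
    for i in range(len(t_grid) - 1):
        a, m = _auc_aumc_segment(t_grid[i], t_grid[i + 1], c_grid[i], c_grid[i + 1])
        auc_last += a
        aumc_last += m

    t_last, c_last = float(times[-1]), float(concs[-1])
    auc_inf = auc_last + c_last / lambda_z
    aumc_inf = aumc_last + c_last * (t_last / lambda_z + 1.0 / lambda_z ** 2)

    cl = dose_ug / auc_inf
    vss = cl * aumc_inf / auc_inf
    return NCAResult(
        auc=float(auc_inf), aumc=float(aumc_inf), c0=c0, lambda_z=float(lambda_z),
        t_half=t_half, cl=float(cl), vss=float(vss), t_last=t_last, c_last=c_last,
        auc_last=float(auc_last), lambda_z_points=int(n_lz),
        lambda_z_adj_r2=float(adj_r2), agent=profile.agent,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_PK_COLUMNS = ["animal_id", "agent", "day", "conc_ug_per_ml", "below_lloq"]


def read_concentration_data(path, sep=",") -> pd.DataFrame:
    """Read vitreous concentration data (animal_id, agent, day,
    conc_ug_per_ml, below_lloq) from delimited text."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _PK_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"concentration file {path} missing columns: {missing}")
    return df


def write_concentration_data(df: pd.DataFrame, path, sep=",") -> None:
    df.to_csv(path, sep=sep, index=False, columns=_PK_COLUMNS)


def profile_from_frame(df: pd.DataFrame, agent: str, lloq: float = 0.0) -> ConcentrationProfile:
    """Assemble one agent's ConcentrationProfile from a tidy frame."""
    sub = df[df["agent"] == agent].sort_values("day")
    if sub.empty:
        raise ConfigError(f"no rows for agent {agent!r}")
    return ConcentrationProfile(
        times=sub["day"].to_numpy(dtype=float),
        concentrations=sub["conc_ug_per_ml"].to_numpy(dtype=float),
        lloq=lloq,
        below_lloq_flags=sub["below_lloq"].to_numpy(dtype=bool),
        agent=agent,
    )
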