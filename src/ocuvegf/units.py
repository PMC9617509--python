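"""Unit conversions used across the package.

Canonical internal units are days (time), mL (volume), nM (concentration)
and µg (mass). Everything converts at the boundary; molar quantities are
occasionally carried in mol/L (M) where assay conventions demand it
(equilibrium dissociation constants are quoted in M, fM, pM).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError

HOURS_PER_DAY = 24.0
MINUTES_PER_DAY = 1440.0


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ConfigError(f"{name} must be positive and finite, got {value!r}")


def mass_to_molar(mass_ug: float, molecular_weight_kda: float, volume_ml: float) -> float:
    """Concentration in mol/L of `mass_ug` µg of a `molecular_weight_kda` kDa
    species dissolved in `volume_ml` mL.

    1 µg / (1 kDa · 1 mL) = 1 µM, so the result is mass/(MW·V) × 1e-6 M.
    """
    _require_positive(mass_ug=mass_ug, molecular_weight_kda=molecular_weight_kda,
                      volume_ml=volume_ml)
    return mass_ug / (molecular_weight_kda * volume_ml) * 1e-6


def molar_to_mass(conc_molar: float, molecular_weight_kda: float, volume_ml: float) -> float:
    """Inverse of :func:`mass_to_molar`; returns µg."""
    _require_positive(conc_molar=conc_molar, molecular_weight_kda=molecular_weight_kda,
                      volume_ml=volume_ml)
    return conc_molar * molecular_weight_kda * volume_ml * 1e6


def molar_to_nm(conc_molar):
    return np.asarray(conc_molar, dtype=float) * 1e9


def nm_to_molar(conc_nm):
    return np.asarray(conc_nm, dtype=float) * 1e-9


def ug_per_ml_to_nm(conc_ug_per_ml, molecular_weight_kda: float):
    """µg/mL → nM. 1 µg/mL of a 1 kDa species is 1 µM = 1000 nM."""
    _require_positive(molecular_weight_kda=molecular_weight_kda)
    return np.asarray(conc_ug_per_ml, dtype=float) / molecular_weight_kda * 1e3


def nm_to_ug_per_ml(conc_nm, molecular_weight_kda: float):
    _require_positive(molecular_weight_kda=molecular_weight_kda)
    return np.asarray(conc_nm, dtype=float) * molecular_weight_kda * 1e-3


def hours_to_days(hours):
    return np.asarray(hours, dtype=float) / HOURS_PER_DAY


def days_to_hours(days):
    return np.asarray(days, dtype=float) * HOURS_PER_DAY


def ul_to_ml(volume_ul):
    return np.asarray(volume_ul, dtype=float) / 1e3


def per_minute_to_per_day(rate_per_min):
    return np.asarray(rate_per_min, dtype=float) * MINUTES_PER_DAY
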