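"""Solution-equilibrium (kinetic exclusion) affinity analysis.

A KinExA experiment equilibrates a fixed ("constant") concentration of the
VEGF inhibitor with a titration series of VEGF-A165 and measures a signal
proportional to the *free* inhibitor fraction at equilibrium. Because the
bead contact is brief, the measurement does not perturb the equilibrium, so
the signal follows the one-site homogeneous binding model: the free fraction
solves the 1:1 site mass balance exactly (a quadratic).

Several curves at different constant concentrations are fitted globally —
one shared K_D, per-curve amplitude and background (and optionally a linear
signal drift in injection order). The K_D confidence interval is computed by
profile likelihood with an F-statistic threshold.

Concentrations throughout this module are *binding-site* concentrations in
mol/L; converting molecule concentrations to site concentrations (drug
valency, two epitopes per VEGF dimer) is the caller's job (see
:mod:`ocuvegf.config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, FitError

__all__ = [
    "BindingCurve",
    "AffinityFit",
    "equilibrium_free_fraction",
    "kinexa_signal",
    "fit_ncurve",
    "kd_confidence_interval",
    "read_binding_curves",
    "write_binding_curves",
]


@dataclass
class BindingCurve:
    """One equilibrium titration curve.

    constant_conc : mol/L of inhibitor binding sites held fixed.
    titrant_concs : mol/L of VEGF binding sites, strictly positive, sorted
        ascending (injection order is assumed to follow titration order).
    signals : measured free-inhibitor signal, arbitrary units.
    """

    constant_conc: float
    titrant_concs: np.ndarray
    signals: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self):
        self.titrant_concs = np.asarray(self.titrant_concs, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.constant_conc <= 0:
            raise ConfigError("constant_conc must be positive")
        if self.titrant_concs.ndim != 1 or len(self.titrant_concs) == 0:
            raise ConfigError("titrant_concs must be a non-empty 1-D array")
        if np.any(self.titrant_concs <= 0):
            raise ConfigError("titrant_concs must be strictly positive")
        if np.any(np.diff(self.titrant_concs) <= 0):
            raise ConfigError("titrant_concs must be strictly increasing")
        if len(self.signals) != len(self.titrant_concs):
            raise ConfigError("signals and titrant_concs must have equal length")


@dataclass
class AffinityFit:
    """Result of a global N-curve fit: shared K_D plus per-curve nuisances."""

    kd: float
    kd_ci_low: float
    kd_ci_high: float
    per_curve_amplitude: list = field(default_factory=list)
    per_curve_background: list = field(default_factory=list)
    per_curve_drift: list = field(default_factory=list)
    residual_sum: float = np.nan
    n_obs: int = 0
    ci_level: float = 0.95
    ci_open_low: bool = False
    ci_open_high: bool = False

    def to_dict(self) -> dict:
        return {
            "kd_molar": self.kd,
            "kd_ci_low_molar": self.kd_ci_low,
            "kd_ci_high_molar": self.kd_ci_high,
            "ci_level": self.ci_level,
            "ci_open_low": self.ci_open_low,
            "ci_open_high": self.ci_open_high,
            "per_curve_amplitude": list(self.per_curve_amplitude),
            "per_curve_background": list(self.per_curve_background),
            "per_curve_drift": list(self.per_curve_drift),
            "residual_sum": self.residual_sum,
            "n_obs": self.n_obs,
        }


def equilibrium_free_fraction(inhibitor_total, ligand_total, kd):
    """Free fraction of inhibitor sites at 1:1 site-binding equilibrium.

    Solves the mass balance for free inhibitor F given total inhibitor
    sites I, total ligand sites L and dissociation constant K:

        F = ½ [ (I − L − K) + sqrt((I − L − K)² + 4 K I) ]

    and returns F / I ∈ (0, 1]. Vectorized over ``ligand_total``.
    A numerically stable conjugate form is used where I − L − K < 0 to
    avoid catastrophic cancellation at tight binding.
    """
    inhibitor_total = np.asarray(inhibitor_total, dtype=float)
    ligand_total = np.asarray(ligand_total, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(inhibitor_total <= 0):
        raise ConfigError("inhibitor_total must be positive")
    if np.any(ligand_total < 0):
        raise ConfigError("ligand_total must be nonnegative")
    if np.any(kd <= 0):
        raise ConfigError("kd must be positive")

    b = inhibitor_total - ligand_total - kd
    disc = np.sqrt(b * b + 4.0 * kd * inhibitor_total)
    # b >= 0: direct root is stable; b < 0: rationalized form avoids
    # subtracting nearly equal magnitudes.
    free = np.where(
        b >= 0,
        0.5 * (b + disc),
        2.0 * kd * inhibitor_total / (disc - b),
    )
    return free / inhibitor_total


def kinexa_signal(constant_conc, titrant_concs, kd, amplitude=1.0, background=0.0,
                  drift=0.0):
    """Predicted KinExA signals for one curve.

    signal_i = background + amplitude × free_fraction(constant, titrant_i, K_D),
    optionally scaled by a per-curve linear drift term in injection order:
    the i-th point (0-based, of n) is multiplied by (1 + drift · i/(n−1)).
    drift = 0 reduces exactly to the no-drift model.
    """
    titrant_concs = np.asarray(titrant_concs, dtype=float)
    ff = equilibrium_free_fraction(constant_conc, titrant_concs, kd)
    sig = background + amplitude * ff
    if drift != 0.0:
        n = len(titrant_concs)
        order = np.arange(n) / max(n - 1, 1)
        sig = sig * (1.0 + drift * order)
    return sig


# ---------------------------------------------------------------------------
# Global N-curve fitting: variable projection over log10(K_D)
# ---------------------------------------------------------------------------

_LOG10_KD_GRID = (-16.0, -9.0)
_N_STARTS = 15


def _solve_curve_linear(curve: BindingCurve, kd: float):
    """For fixed K_D the no-drift model is linear in (background, amplitude):
    solve per curve by least squares. Returns (background, amplitude, ssr)."""
    ff = equilibrium_free_fraction(curve.constant_conc, curve.titrant_concs, kd)
    X = np.column_stack([np.ones_like(ff), ff])
    coef, _, _, _ = np.linalg.lstsq(X, curve.signals, rcond=None)
    resid = curve.signals - X @ coef
    return coef[0], coef[1], float(resid @ resid)


def _solve_curve_drift(curve: BindingCurve, kd: float):
    """Per-curve (background, amplitude, drift) at fixed K_D: small nonlinear
    least squares seeded from the no-drift linear solution."""
    b0, a0, _ = _solve_curve_linear(curve, kd)
    ff = equilibrium_free_fraction(curve.constant_conc, curve.titrant_concs, kd)
    n = len(ff)
    order = np.arange(n) / max(n - 1, 1)

    def resid(p):
        b, a, d = p
        return (b + a * ff) * (1.0 + d * order) - curve.signals

    sol = optimize.least_squares(resid, x0=[b0, a0, 0.0], method="lm", xtol=1e-14)
    r = sol.fun
    return sol.x[0], sol.x[1], sol.x[2], float(r @ r)


def _global_ssr(log10_kd: float, curves, use_drift: bool) -> float:
    kd = 10.0 ** log10_kd
    total = 0.0
    for c in curves:
        if use_drift:
            total += _solve_curve_drift(c, kd)[3]
        else:
            total += _solve_curve_linear(c, kd)[2]
    return total


def _n_params(curves, use_drift: bool) -> int:
    per_curve = 3 if use_drift else 2
    return 1 + per_curve * len(curves)


def fit_ncurve(curves, use_drift: bool = False, ci_level: float = 0.95,
               compute_ci: bool = True) -> AffinityFit:
    """Global fit of one shared K_D across all curves.

    The shared K_D is profiled on a fixed multi-start grid in log10(K_D)
    over [−16, −9] (mol/L) and refined by bounded scalar minimization around
    the best start; the per-curve amplitude/background (and drift, if
    enabled) are re-solved exactly at every K_D, which makes the procedure
    deterministic and fast. Ties between starts are broken toward the
    smallest K_D.

    Raises :class:`FitError` when the data carry no binding signal (the
    binding model does not beat a per-curve constant) or when the optimum
    pins to the grid boundary.
    """
    curves = list(curves)
    if len(curves) == 0:
        raise ConfigError("at least one curve is required")
    for c in curves:
        if len(c.titrant_concs) < 5:
            raise ConfigError("each curve needs at least 5 titration points")

    n_obs = sum(len(c.signals) for c in curves)
    if n_obs <= _n_params(curves, use_drift):
        raise ConfigError("not enough points to identify the model")

    lo, hi = _LOG10_KD_GRID
    starts = np.linspace(lo, hi, _N_STARTS)
    ssrs = np.array([_global_ssr(s, curves, use_drift) for s in starts])
    # ties broken toward smallest kd: argmin returns the first (smallest) index
    best = int(np.argmin(ssrs))
    step = starts[1] - starts[0]
    bl = max(lo, starts[best] - step)
    bh = min(hi, starts[best] + step)
    res = optimize.minimize_scalar(
        _global_ssr, args=(curves, use_drift), bounds=(bl, bh), method="bounded",
        options={"xatol": 1e-10},
    )
    log10_kd = float(res.x)
    ssr = float(res.fun)
    kd = 10.0 ** log10_kd

    # identifiability: the binding model must beat per-curve constants
    ssr_const = 0.0
    for c in curves:
        resid = c.signals - c.signals.mean()
        ssr_const += float(resid @ resid)
    if ssr_const <= 0 or 1.0 - ssr / ssr_const < 0.5:
        raise FitError(
            "no identifiable binding signal: curves are flat or noise-dominated",
            best_params={"kd": kd},
            diagnostics={"ssr": ssr, "ssr_constant_model": ssr_const},
        )
    if log10_kd - lo < 1e-3 or hi - log10_kd < 1e-3:
        raise FitError(
            "K_D pinned to the search boundary; data do not bracket the affinity",
            best_params={"kd": kd},
            diagnostics={"log10_kd": log10_kd, "bounds": (lo, hi)},
        )

    amps, bgs, drifts = [], [], []
    for c in curves:
        if use_drift:
            b, a, d, _ = _solve_curve_drift(c, kd)
        else:
            b, a, _ = _solve_curve_linear(c, kd)
            d = 0.0
        bgs.append(float(b))
        amps.append(float(a))
        drifts.append(float(d))

    fit = AffinityFit(
        kd=kd, kd_ci_low=kd, kd_ci_high=kd,
        per_curve_amplitude=amps, per_curve_background=bgs,
        per_curve_drift=drifts, residual_sum=ssr, n_obs=n_obs,
        ci_level=ci_level,
    )
    if compute_ci:
        low, high, open_low, open_high = kd_confidence_interval(
            fit, curves, level=ci_level, use_drift=use_drift, _return_flags=True
        )
        fit.kd_ci_low, fit.kd_ci_high = low, high
        fit.ci_open_low, fit.ci_open_high = open_low, open_high
    return fit


def kd_confidence_interval(fit: AffinityFit, curves, level: float = 0.95,
                           use_drift: bool = False, _return_flags: bool = False):
    """Profile-likelihood interval for the shared K_D.

    K_D is scanned on a log grid with all nuisance parameters re-optimized
    at each value; the interval is bounded where the profiled residual sum
    crosses SSR_min · (1 + F(1, n−p; level)/(n−p)). If the profile never
    crosses within the search range on one side, that side is flagged open
    and the search-range edge is reported rather than a fabricated bound.
    """
    curves = list(curves)
    n_obs = sum(len(c.signals) for c in curves)
    dof = n_obs - _n_params(curves, use_drift)
    if dof <= 0:
        raise FitError("no residual degrees of freedom for a confidence interval")

    log10_hat = np.log10(fit.kd)
    ssr_min = _global_ssr(log10_hat, curves, use_drift)
    threshold = ssr_min * (1.0 + stats.f.ppf(level, 1, dof) / dof)
    # guard against an exactly-zero noiseless optimum
    threshold = max(threshold, ssr_min + 1e-300)

    lo, hi = _LOG10_KD_GRID

    def g(x):
        return _global_ssr(x, curves, use_drift) - threshold

    def scan(direction):
        """Walk away from the optimum until the profile crosses, then bisect."""
        step = 0.05
        x_prev = log10_hat
        x = log10_hat + direction * step
        edge = hi if direction > 0 else lo
        while (x - edge) * direction < 0:
            if g(x) > 0:
                root = optimize.brentq(g, min(x_prev, x), max(x_prev, x),
                                       xtol=1e-9)
                return root, False
            x_prev = x
            x = x + direction * step
        return edge, g(edge) <= 0  # open if never crossed within range

    low_log, open_low = scan(-1.0)
    high_log, open_high = scan(+1.0)
    low, high = 10.0 ** low_log, 10.0 ** high_log
    if _return_flags:
        return low, high, open_low, open_high
    return low, high


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ["curve_id", "constant_conc_molar", "titrant_conc_molar", "signal"]


def read_binding_curves(path, sep=",") -> list[BindingCurve]:
    """Read titration curves from delimited text with columns
    curve_id, constant_conc_molar, titrant_conc_molar, signal."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"binding-curve file {path} missing columns: {missing}")
    curves = []
    for cid, grp in df.groupby("curve_id", sort=True):
        grp = grp.sort_values("titrant_conc_molar")
        const = grp["constant_conc_molar"].unique()
        if len(const) != 1:
            raise ConfigError(f"curve {cid!r} has multiple constant concentrations")
        curves.append(BindingCurve(
            constant_conc=float(const[0]),
            titrant_concs=grp["titrant_conc_molar"].to_numpy(),
            signals=grp["signal"].to_numpy(),
            replicate_id=str(cid),
        ))
    return curves


def write_binding_curves(curves, path, sep=",") -> None:
    rows = []
    for c in curves:
        for t, s in zip(c.titrant_concs, c.signals):
            rows.append((c.replicate_id, c.constant_conc, t, s))
    pd.DataFrame(rows, columns=_CURVE_COLUMNS).to_csv(path, sep=sep, index=False)
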