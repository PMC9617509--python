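"""Four-parameter logistic (4PL) IC50 fitting for the VEGF-induced calcium
mobilization assay, and Tukey-style all-pairs comparison of log-IC50s.

Responses are assumed pre-normalized peak responses (1 = uninhibited VEGF
response, 0 = complete inhibition); the raw fluorescence kinetics are out of
scope. The fitted model is

    response(c) = bottom + (top − bottom) / (1 + (c / IC50)^hill)

with the Hill slope constrained to [0.3, 5] to avoid pathological fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, FitError

__all__ = [
    "InhibitionCurve",
    "PotencyFit",
    "fit_4pl",
    "compare_potencies",
    "read_inhibition_curves",
]

_HILL_BOUNDS = (0.3, 5.0)


@dataclass
class InhibitionCurve:
    """Inhibitor concentrations (nM, ascending) and normalized responses."""

    inhibitor_concs: np.ndarray
    responses: np.ndarray
    replicate_id: str = "rep1"

    def __post_init__(self):
        self.inhibitor_concs = np.asarray(self.inhibitor_concs, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if np.any(self.inhibitor_concs <= 0):
            raise ConfigError("inhibitor_concs must be positive")
        if np.any(np.diff(self.inhibitor_concs) <= 0):
            raise ConfigError("inhibitor_concs must be strictly increasing")
        if len(self.responses) != len(self.inhibitor_concs):
            raise ConfigError("responses and inhibitor_concs must have equal length")


@dataclass
class PotencyFit:
    ic50: float            # nM
    hill: float
    top: float
    bottom: float
    se_log_ic50: float     # standard error of log10(IC50)
    df_resid: int = 0
    label: str = ""

    def to_dict(self) -> dict:
        return {"ic50_nM": self.ic50, "hill": self.hill, "top": self.top,
                "bottom": self.bottom, "se_log_ic50": self.se_log_ic50,
                "df_resid": self.df_resid, "label": self.label}


def four_pl(conc, ic50, hill, top, bottom):
    """Descending 4PL: top at c → 0, bottom at c → ∞."""
    conc = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (conc / ic50) ** hill)


def fit_4pl(curve: InhibitionCurve, label: str = "") -> PotencyFit:
    """Least-squares 4PL fit with deterministic initialization.

    The IC50 start is the concentration whose response is nearest the
    half-range midpoint; hill starts at 1, top/bottom at the observed
    extremes. Data that do not descend through an inflection (monotone
    non-inhibiting responses, or a response span too small to identify the
    midpoint) raise :class:`FitError` with diagnostics.
    """
    c, y = curve.inhibitor_concs, curve.responses
    if len(np.unique(c)) < 5:
        raise ConfigError("need at least 5 distinct concentrations")

    span = y.max() - y.min()
    rho = stats.spearmanr(c, y).statistic if span > 0 else 0.0
    if span < 0.1 or not (rho < 0):
        raise FitError(
            "no inhibition detected: responses do not descend across the "
            "concentration range",
            diagnostics={"response_span": float(span), "spearman_rho": float(rho)},
        )

    mid = (y.max() + y.min()) / 2.0
    ic50_0 = c[np.argmin(np.abs(y - mid))]
    p0 = [ic50_0, 1.0, y.max(), y.min()]
    lower = [c.min() / 1e3, _HILL_BOUNDS[0], -np.inf, -np.inf]
    upper = [c.max() * 1e3, _HILL_BOUNDS[1], np.inf, np.inf]
    try:
        popt, pcov = optimize.curve_fit(
            four_pl, c, y, p0=p0, bounds=(lower, upper), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    ic50, hill, top, bottom = popt
    if not bottom < top:
        raise FitError("degenerate 4PL fit: bottom >= top",
                       best_params=dict(zip(["ic50", "hill", "top", "bottom"], popt)))
    # delta-method SE of log10(IC50) from the covariance of IC50
    var_ic50 = pcov[0, 0]
    se_log = float(np.sqrt(var_ic50) / (ic50 * np.log(10.0))) if np.isfinite(var_ic50) else np.nan
    return PotencyFit(ic50=float(ic50), hill=float(hill), top=float(top),
                      bottom=float(bottom), se_log_ic50=se_log,
                      df_resid=len(y) - 4, label=label or curve.replicate_id)


def compare_potencies(fits) -> pd.DataFrame:
    """All-pairs Tukey comparison of log10(IC50).

    Fits sharing a ``label`` are treated as replicates of one agent. With
    replicated groups the comparison uses the studentized-range test on the
    replicate log-IC50s (classic Tukey HSD); with one fit per group it falls
    back to the delta-method standard errors of each fit. For two groups the
    Tukey-adjusted p-value reduces exactly to the two-sided t-test.

    Returns a tidy frame (group_a, group_b, diff_log10_ic50, p_adj) ordered
    by group potency.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ConfigError("need at least two fits to compare")
    groups: dict[str, list[PotencyFit]] = {}
    for f in fits:
        groups.setdefault(f.label, []).append(f)
    names = sorted(groups, key=lambda g: np.mean([f.ic50 for f in groups[g]]))
    k = len(names)
    if k < 2:
        raise ConfigError("need at least two distinct group labels")

    replicated = all(len(groups[g]) >= 2 for g in names)
    rows = []
    if replicated:
        data = {g: np.log10([f.ic50 for f in groups[g]]) for g in names}
        df_err = sum(len(v) - 1 for v in data.values())
        mse = sum(((v - v.mean()) ** 2).sum() for v in data.values()) / df_err
        for i in range(k):
            for j in range(i + 1, k):
                a, b = names[i], names[j]
                diff = data[b].mean() - data[a].mean()
                se = np.sqrt(mse / 2.0 * (1.0 / len(data[a]) + 1.0 / len(data[b])))
                q = np.abs(diff) / se if se > 0 else np.inf
                p = float(stats.studentized_range.sf(q, k, df_err))
                rows.append((a, b, diff, min(p, 1.0)))
    else:
        for f in fits:
            if not np.isfinite(f.se_log_ic50):
                raise ConfigError(
                    f"fit {f.label!r} lacks a standard error; cannot compare")
        for i in range(k):
            for j in range(i + 1, k):
                fa, fb = groups[names[i]][0], groups[names[j]][0]
                diff = np.log10(fb.ic50) - np.log10(fa.ic50)
                se_d = np.sqrt(fa.se_log_ic50 ** 2 + fb.se_log_ic50 ** 2)
                df_err = fa.df_resid + fb.df_resid
                # studentized range statistic for two means with SE s each:
                # q = |diff| / s where s = SE of one mean = se_d / sqrt(2)
                q = np.abs(diff) * np.sqrt(2.0) / se_d if se_d > 0 else np.inf
                p = float(stats.studentized_range.sf(q, k, df_err))
                rows.append((names[i], names[j], diff, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "diff_log10_ic50", "p_adj"])
    out.attrs["potency_order"] = names
    return out


def read_inhibition_curves(path, sep=",") -> list[InhibitionCurve]:
    """Read curves from delimited text with columns replicate_id, conc_nM,
    response."""
    df = pd.read_csv(path, sep=sep)
    needed = ["replicate_id", "conc_nM", "response"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ConfigError(f"inhibition file {path} missing columns: {missing}")
    curves = []
    for rid, grp in df.groupby("replicate_id", sort=True):
        grp = grp.sort_values("conc_nM")
        curves.append(InhibitionCurve(
            inhibitor_concs=grp["conc_nM"].to_numpy(),
            responses=grp["response"].to_numpy(),
            replicate_id=str(rid),
        ))
    return curves
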