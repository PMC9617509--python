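"""Exposure-response for VEGF-induced retinal leakage.

Fluorescein-angiography leakage scores are dichotomized (score ≥ 2 =
moderate-to-severe leakage = 1, else 0) and linked to the model-assigned
percent free VEGF through a two-parameter logistic,

    p(x) = 1 / (1 + exp(−(x − x50) / slope)),

where x50 is the percent free VEGF at which the probability of
moderate-to-severe leakage is 0.5 and slope sets the steepness (% free VEGF
per logit). This parameterization makes back-calculated exposure tables
directly interpretable; the standard intercept/coefficient form is exposed
as a conversion.

Observations are treated as independent Bernoulli trials (multiple
challenges of the same animal are not cluster-corrected by default; a
cluster-robust variance option exists). The vehicle week-10 observations are
dropped by the default exclusion rule — their unusually low leakage scores
contradict the 100%-free-VEGF vehicle definition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .errors import ConfigError, FitError

__all__ = [
    "ExclusionRule",
    "LeakageLogisticModel",
    "dichotomize",
    "apply_exclusions",
    "fit_leakage_logistic",
    "backcalc_free_vegf",
    "classification_accuracy",
    "read_leakage_data",
    "write_leakage_data",
    "DEFAULT_EXCLUSIONS",
]

LEAKAGE_COLUMNS = ["animal_id", "agent", "challenge_day", "score", "percent_free"]


def challenge_week(day) -> np.ndarray:
    """Study week of a challenge day (day 5 → week 1, ..., day 68 → week 10)."""
    return np.ceil(np.asarray(day, dtype=float) / 7.0).astype(int)


def dichotomize(observations: pd.DataFrame, threshold: int = 2) -> pd.DataFrame:
    """Set the binary outcome: 1 for moderate-to-severe leakage
    (score ≥ threshold), 0 otherwise. Returns a copy."""
    out = observations.copy()
    if len(out) == 0:
        out["binary"] = pd.Series(dtype=int)
        return out
    scores = out["score"].to_numpy()
    if np.any(scores < 0) or not np.allclose(scores, np.round(scores)):
        raise ConfigError("scores must be nonnegative integers")
    out["binary"] = (scores >= threshold).astype(int)
    return out


@dataclass
class ExclusionRule:
    """Drops observations matching all given fields (None = wildcard)."""

    name: str
    agent: str | None = None
    week: int | None = None
    challenge_day: float | None = None

    def matches(self, df: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(df), dtype=bool)
        if self.agent is not None:
            mask &= (df["agent"] == self.agent).to_numpy()
        if self.week is not None:
            mask &= challenge_week(df["challenge_day"]) == self.week
        if self.challenge_day is not None:
            mask &= (df["challenge_day"] == self.challenge_day).to_numpy()
        return mask


#: The study's stated exclusion: vehicle observations at week 10 showed
#: unusually low leakage and are dropped before model fitting.
DEFAULT_EXCLUSIONS = [ExclusionRule(name="vehicle_week10", agent="vehicle", week=10)]


def apply_exclusions(observations: pd.DataFrame, rules=None):
    """Apply exclusion rules; returns (filtered_frame, exclusion_log).

    Every dropped record appears in the log together with the name of the
    rule that fired. An empty rule list is the identity.
    """
    rules = DEFAULT_EXCLUSIONS if rules is None else list(rules)
    drop = np.zeros(len(observations), dtype=bool)
    log_rows = []
    for rule in rules:
        hit = rule.matches(observations) & ~drop
        for idx in observations.index[hit]:
            log_rows.append({"index": idx, "rule": rule.name,
                             **observations.loc[idx, ["animal_id", "agent",
                                                      "challenge_day"]].to_dict()})
        drop |= rule.matches(observations)
    log = pd.DataFrame(log_rows, columns=["index", "rule", "animal_id", "agent",
                                          "challenge_day"])
    return observations.loc[~drop].copy(), log


@dataclass
class LeakageLogisticModel:
    """Two-parameter logistic: p(x) = 1/(1+exp(−(x−x50)/slope))."""

    x50: float
    slope: float
    fit_method: str = "constructed"
    n_obs: int = 0
    accuracy: float = float("nan")
    separation_flag: bool = False
    x50_se: float = float("nan")
    cluster_robust: bool = False

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-(x - self.x50) / self.slope))

    def backcalc(self, p: float) -> float:
        """Exact inverse: percent free VEGF at probability p ∈ (0, 1)."""
        if not 0.0 < p < 1.0:
            raise ConfigError("p must be strictly between 0 and 1")
        return self.x50 + self.slope * math.log(p / (1.0 - p))

    def elbow(self, p_low: float = 0.1) -> float:
        """Percent free VEGF at a low-probability elbow (default p = 0.1):
        an interpretive marker of where leakage risk starts to rise."""
        return self.backcalc(p_low)

    @property
    def intercept(self) -> float:
        """Standard GLM intercept: logit p = intercept + coef·x."""
        return -self.x50 / self.slope

    @property
    def coef(self) -> float:
        return 1.0 / self.slope

    @classmethod
    def from_points(cls, point_a: tuple[float, float], point_b: tuple[float, float]
                    ) -> "LeakageLogisticModel":
        """Exact two-point construction through (x_a, p_a) and (x_b, p_b)."""
        (xa, pa), (xb, pb) = point_a, point_b
        for p in (pa, pb):
            if not 0.0 < p < 1.0:
                raise ConfigError("probabilities must be strictly inside (0, 1)")
        la, lb = math.log(pa / (1 - pa)), math.log(pb / (1 - pb))
        if la == lb:
            raise ConfigError("the two points must have distinct probabilities")
        slope = (xb - xa) / (lb - la)
        x50 = xa - slope * la
        return cls(x50=x50, slope=slope, fit_method="two_point", n_obs=2)

    def to_dict(self) -> dict:
        return {"x50": self.x50, "slope": self.slope, "intercept": self.intercept,
                "coef": self.coef, "fit_method": self.fit_method,
                "n_obs": self.n_obs, "accuracy": self.accuracy,
                "separation_flag": self.separation_flag, "x50_se": self.x50_se}


def fit_leakage_logistic(observations: pd.DataFrame,
                         cluster_robust: bool = False) -> LeakageLogisticModel:
    """Bernoulli maximum-likelihood fit of the leakage logistic.

    Requires a ``binary`` column (see :func:`dichotomize`) with both classes
    present and a model-assigned ``percent_free`` column. Complete
    separation is flagged on the returned model (parameters from a weakly
    regularized fit, at the boundary of identifiability) rather than raised.
    ``cluster_robust`` reports an animal-clustered standard error for x50.
    """
    if "binary" not in observations.columns:
        raise ConfigError("observations need a 'binary' column; run dichotomize first")
    if "percent_free" not in observations.columns or observations["percent_free"].isna().any():
        raise ConfigError("observations need model-assigned percent_free values")
    y = observations["binary"].to_numpy(dtype=float)
    x = observations["percent_free"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError("both outcome classes must be present to fit the logistic")

    X = sm.add_constant(x)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0)
        if not res.mle_retvals.get("converged", True):
            raise PerfectSeparationError("did not converge")
        params = res.params
        cov = res.cov_params()
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        # boundary of identifiability: flag it and report a weakly
        # regularized fit instead of failing
        separation = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0)
        params = np.asarray(res.params)
        cov = None

    b0, b1 = float(params[0]), float(params[1])
    if b1 == 0:
        raise FitError("degenerate logistic fit: zero slope coefficient",
                       best_params={"intercept": b0, "coef": b1})
    x50 = -b0 / b1
    slope = 1.0 / b1

    x50_se = float("nan")
    if cov is not None:
        if cluster_robust and "animal_id" in observations.columns:
            res_cl = sm.Logit(y, X).fit(disp=0, cov_type="cluster",
                                        cov_kwds={"groups": observations["animal_id"]})
            cov = res_cl.cov_params()
        # delta method for x50 = -b0/b1
        grad = np.array([-1.0 / b1, b0 / b1 ** 2])
        x50_se = float(np.sqrt(grad @ np.asarray(cov) @ grad))

    model = LeakageLogisticModel(
        x50=x50, slope=slope, fit_method="bernoulli_mle", n_obs=len(y),
        separation_flag=separation, x50_se=x50_se, cluster_robust=cluster_robust,
    )
    model.accuracy = classification_accuracy(model, observations)
    return model


def backcalc_free_vegf(model: LeakageLogisticModel, p: float) -> float:
    """Percent free VEGF at which the model predicts probability ``p``."""
    return model.backcalc(p)


def classification_accuracy(model: LeakageLogisticModel,
                            observations: pd.DataFrame) -> float:
    """In-sample fraction of observations where (p(x) ≥ 0.5) matches the
    binary outcome."""
    if "binary" not in observations.columns:
        raise ConfigError("observations need a 'binary' column")
    pred = model.predict(observations["percent_free"].to_numpy(dtype=float)) >= 0.5
    return float(np.mean(pred == (observations["binary"].to_numpy() == 1)))


def read_leakage_data(path, sep=",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in LEAKAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"leakage file {path} missing columns: {missing}")
    return df


def write_leakage_data(df: pd.DataFrame, path, sep=",") -> None:
    cols = [c for c in LEAKAGE_COLUMNS + ["binary"] if c in df.columns]
    df.to_csv(path, sep=sep, index=False, columns=cols)
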