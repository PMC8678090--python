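"""Canopy-nitrogen regression models and the supporting statistics.

Two models link the red-edge index NDRE (x) to nitrogen status:

* Model I  — quadratic,    N%        = a*x**2 + b*x + c
* Model II — exponential,  N% * LAI  = alpha * exp(beta * x)

Model I is fitted after removing tillering-stage observations, whose canopy is
still sparse enough that the water background between seedlings contaminates
plot reflectance.  Model II keeps all six stages and folds canopy structure in
through the leaf area index (LAI = single-plant leaf area * plant density).

Goodness of fit is summarized by the pseudo-R² ``1 - SSres/SStot`` (identical
to the ordinary R² for the linear/quadratic fits), the adjusted R²
``1 - (1 - R²)(n - 1)/(n - k)`` with k the number of estimated coefficients,
the Pearson correlation of observed vs fitted values, and a two-sided F-test
p-value.  No multiple-testing correction is applied anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import STAGES, validate_stage

#: plant density (plants per square meter) of the standard field layout
DEFAULT_PLANT_DENSITY = 22.5

#: growth-duration cutoff (days, transplanting -> maturation) separating
#: early-maturation (EM) from late-maturation (LM) varieties
GD_CUTOFF_DAYS = 100.0


@dataclass
class FitSummary:
    n: int
    r_squared: float
    adj_r_squared: float
    pearson_r: float
    p_value: float


@dataclass
class NitrogenModelI:
    """Quadratic NDRE -> N% model, y = a*x^2 + b*x + c."""

    a: float
    b: float
    c: float
    summary: FitSummary

    @property
    def coefficients(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)


@dataclass
class NitrogenModelII:
    """Exponential NDRE -> N%*LAI model, y = alpha * exp(beta * x)."""

    alpha: float
    beta: float
    summary: FitSummary

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def coefficients(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


@dataclass
class VarietyInfo:
    variety: str
    gd_days: float
    maturity_group: Optional[str] = None  # "EM" | "LM"

    def __post_init__(self) -> None:
        if not (self.gd_days > 0):
            raise ValueError(f"growth duration must be positive for {self.variety}")


def _fit_summary(y: np.ndarray, fitted: np.ndarray, k: int) -> FitSummary:
    """Pseudo-R², adjusted R², observed-vs-fitted Pearson r, F-test p-value.

    ``k`` counts estimated coefficients including any intercept/scale term.
    """
    y = np.asarray(y, float)
    fitted = np.asarray(fitted, float)
    n = y.size
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if n > k:
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k)
    else:
        adj = float("nan")
    if np.std(fitted) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(y, fitted)[0, 1])
    else:
        r = float("nan")
    df1, df2 = k - 1, n - k
    if df1 > 0 and df2 > 0 and r2 < 1.0:
        f_stat = (r2 / df1) / ((1.0 - r2) / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    elif r2 >= 1.0:
        p = 0.0
    else:
        p = float("nan")
    return FitSummary(n=n, r_squared=r2, adj_r_squared=adj, pearson_r=r, p_value=p)


def exclude_tillering(
    records: Union[pd.DataFrame, Iterable], stage_col: str = "stage"
):
    """Drop all tillering-stage (TS) observations, preserving order otherwise.

    Accepts a DataFrame with a stage column, or any iterable of objects with a
    ``stage`` attribute.
    """
    if isinstance(records, pd.DataFrame):
        return records[records[stage_col] != "TS"].reset_index(drop=True)
    return [r for r in records if getattr(r, "stage") != "TS"]


def fit_model_i(x: Sequence[float], y: Sequence[float]) -> NitrogenModelI:
    """Least-squares quadratic of N% on NDRE.

    Requires n >= 4 points and at least three distinct x values (otherwise the
    quadratic design is rank-deficient).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 points for a quadratic fit")
    if np.unique(x).size < 3:
        raise ValueError("rank-deficient design: need >=3 distinct NDRE values")
    a, b, c = np.polyfit(x, y, 2)
    fitted = np.polyval([a, b, c], x)
    return NitrogenModelI(a=float(a), b=float(b), c=float(c),
                          summary=_fit_summary(y, fitted, k=3))


def predict_model_i(model: NitrogenModelI, x) -> np.ndarray:
    x = np.asarray(x, float)
    return model.a * x**2 + model.b * x + model.c


def fit_model_ii(
    x: Sequence[float],
    y: Sequence[float],
    initial: Optional[tuple[float, float]] = None,
    maxfev: int = 20000,
) -> NitrogenModelII:
    """Nonlinear least squares of y = alpha * exp(beta * x) on the original scale.

    Initialized by OLS of log(y) on x when all y > 0, otherwise from
    ``initial`` (default (1, 1)).  Requires n >= 3 and at least two distinct
    x values.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for the exponential fit")
    if np.unique(x).size < 2:
        raise ValueError("rank-deficient design: beta unidentifiable with constant NDRE")
    if np.all(y > 0):
        slope, intercept = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = initial if initial is not None else (1.0, 1.0)

    def _model(xv, alpha, beta):
        return alpha * np.exp(beta * xv)

    popt, _, infodict, mesg, ier = optimize.curve_fit(
        _model, x, y, p0=p0, maxfev=maxfev, full_output=True
    )
    if ier not in (1, 2, 3, 4):
        raise RuntimeError(
            f"exponential fit did not converge after {infodict['nfev']} evaluations: {mesg}"
        )
    alpha, beta = float(popt[0]), float(popt[1])
    fitted = _model(x, alpha, beta)
    return NitrogenModelII(alpha=alpha, beta=beta, summary=_fit_summary(y, fitted, k=2))


def predict_model_ii(model: NitrogenModelII, x) -> np.ndarray:
    x = np.asarray(x, float)
    return model.alpha * np.exp(model.beta * x)


def lai_from_leaf_area(la_s, d: float = DEFAULT_PLANT_DENSITY):
    """LAI = LA_S * d: single-plant leaf area (m^2) times plant density (1/m^2)."""
    la_s = np.asarray(la_s, float)
    if np.any(la_s < 0):
        raise ValueError("leaf area must be non-negative")
    if not d > 0:
        raise ValueError("plant density must be positive")
    out = la_s * d
    return float(out) if out.ndim == 0 else out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; raises on n < 3 or zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def linear_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, FitSummary]:
    """OLS line of y on x with R², adjusted R² and two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a linear fit")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: x has no variation")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    return float(slope), float(intercept), _fit_summary(y, fitted, k=2)


def split_by_gd(
    varieties: Union[pd.DataFrame, Iterable[VarietyInfo]],
    cutoff_days: float = GD_CUTOFF_DAYS,
) -> tuple[list[VarietyInfo], list[VarietyInfo]]:
    """Partition varieties into (EM, LM) by growth duration.

    GD >= cutoff -> late maturation (LM); the boundary day goes to LM.  The
    partition is exhaustive and disjoint; missing GD raises, listing the
    offending varieties.
    """
    if isinstance(varieties, pd.DataFrame):
        missing = varieties.loc[varieties["gd_days"].isna(), "variety"].tolist()
        if missing:
            raise ValueError(f"missing growth duration for: {missing}")
        varieties = [
            VarietyInfo(variety=str(r.variety), gd_days=float(r.gd_days))
            for r in varieties.itertuples()
        ]
    else:
        varieties = list(varieties)
        missing = [v.variety for v in varieties if v.gd_days is None or not np.isfinite(v.gd_days)]
        if missing:
            raise ValueError(f"missing growth duration for: {missing}")
    em, lm = [], []
    for v in varieties:
        group = "LM" if v.gd_days >= cutoff_days else "EM"
        v.maturity_group = group
        (lm if group == "LM" else em).append(v)
    return em, lm


def stage_correlation_table(
    records: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    stage_col: str = "stage",
    stages: Sequence[str] = STAGES,
) -> pd.DataFrame:
    """Stage-wise Pearson correlations between measurement pairs.

    One row per (stage, pair) with r, two-sided p and n.  Cells with fewer
    than 3 observations or zero variance are flagged (r/p = NaN, note set),
    never silently dropped.
    """
    rows = []
    for stage in stages:
        validate_stage(stage)
        sub = records[records[stage_col] == stage]
        for mx, my in pairs:
            pair_df = sub[[mx, my]].dropna()
            n = len(pair_df)
            note = ""
            r = p = float("nan")
            if n < 3:
                note = "insufficient n"
            elif pair_df[mx].std(ddof=0) == 0 or pair_df[my].std(ddof=0) == 0:
                note = "zero variance"
            else:
                r = pearson_r(pair_df[mx].to_numpy(), pair_df[my].to_numpy())
                # two-sided p via the exact t transform of r
                if abs(r) < 1.0:
                    t = r * math.sqrt((n - 2) / (1.0 - r**2))
                    p = float(2.0 * stats.t.sf(abs(t), n - 2))
                else:
                    p = 0.0
            rows.append(
                {"stage": stage, "measure_x": mx, "measure_y": my,
                 "r": r, "p": p, "n": n, "note": note}
            )
    return pd.DataFrame(rows, columns=["stage", "measure_x", "measure_y", "r", "p", "n", "note"])
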