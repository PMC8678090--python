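"""Dynamic nitrogen-curve phenotype screening and field yield/NUE traits.

The high-NUE signature is defined on a variety's six-stage nitrogen
trajectory: moderately high (but not maximal) canopy N through the vegetative
stages TS-BS, the highest N of the collection at full heading and milk
ripening, and a slower-than-typical post-booting decline.  The verbal
definition is operationalized by three configurable clauses
(:class:`PhenotypeRule`): a rank threshold at FHS/MRS, a percentile band for
the vegetative stages, and a quantile cap on the BS->MRS decline rate.

Field traits from the nitrogen dosage trial follow the standard yield
bookkeeping: seed setting rate SSR = 100 * full/total grains, grain number
per panicle GNP = full grains / effective panicles, thousand-grain weight
TGW = 5 * (200-grain weight), grain yield GY scaled from per-plant yield to
kg/ha, and NUE = GY per kg of nitrogen applied (undefined at the 0 kg/ha
treatment).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import REPRODUCTIVE_STAGES, STAGE_INDEX, STAGES, VEGETATIVE_STAGES

#: standard moisture fraction deducted from combine-harvest grain yield
STANDARD_MOISTURE = 0.135


@dataclass
class StageSeries:
    """Ordered six-stage trajectory of one nitrogen measure for one variety.

    ``values`` and ``ranks`` are aligned with the global stage order; missing
    stages are NaN.  Rank 1 is the highest value at that stage; ties share
    the minimum rank.
    """

    variety: str
    measure: str
    values: np.ndarray
    ranks: np.ndarray = field(default_factory=lambda: np.full(len(STAGES), np.nan))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.ranks = np.asarray(self.ranks, float)
        if self.values.shape != (len(STAGES),) or self.ranks.shape != (len(STAGES),):
            raise ValueError("StageSeries needs exactly one slot per stage")

    def value(self, stage: str) -> float:
        return float(self.values[STAGE_INDEX[stage]])

    def rank(self, stage: str) -> float:
        return float(self.ranks[STAGE_INDEX[stage]])

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))


@dataclass
class PhenotypeRule:
    """Quantitative thresholds for the qualitative high-NUE curve phenotype.

    ``reproductive_rank_max``: maximum allowed rank at FHS and MRS (1 = must
    be top of the collection).  ``vegetative_band``: percentile interval the
    TS-BS values must fall in, so an early-peaking variety that is maximal in
    the vegetative stages is rejected.  ``decline_quantile_max``: the variety's
    BS->MRS decline rate must not exceed this quantile of the collection's
    decline rates.
    """

    reproductive_rank_max: int = 1
    vegetative_band: tuple[float, float] = (40.0, 95.0)
    decline_quantile_max: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.vegetative_band
        if not (0 <= lo <= hi <= 100):
            raise ValueError("vegetative_band percentiles must satisfy 0 <= lo <= hi <= 100")
        if self.reproductive_rank_max < 1:
            raise ValueError("reproductive_rank_max must be >= 1")
        if not (0 <= self.decline_quantile_max <= 1):
            raise ValueError("decline_quantile_max must be in [0, 1]")


def build_stage_series(
    records: pd.DataFrame,
    measure: str,
    variety_col: str = "variety",
    stage_col: str = "stage",
) -> list[StageSeries]:
    """Assemble one StageSeries per variety with per-stage ranks.

    ``records`` is long-format with a variety column, a stage column and the
    measure column.  Duplicate (variety, stage) entries raise.  Rank 1 is the
    highest value at a stage; tied values share the minimum rank.
    """
    if records[variety_col].nunique() < 2:
        raise ValueError("need at least 2 varieties to build a ranked collection")
    dup = records.duplicated([variety_col, stage_col])
    if dup.any():
        bad = records.loc[dup, [variety_col, stage_col]].values.tolist()
        raise ValueError(f"duplicate (variety, stage) records: {bad}")
    varieties = list(dict.fromkeys(records[variety_col]))
    values = pd.DataFrame(np.nan, index=varieties, columns=list(STAGES))
    for row in records.itertuples():
        values.loc[getattr(row, variety_col), getattr(row, stage_col)] = getattr(row, measure)

    series = []
    mat = values.to_numpy()
    ranks = np.full_like(mat, np.nan)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ok = np.isfinite(col)
        for i in np.where(ok)[0]:
            # minimum rank under ties: 1 + number of strictly greater values
            ranks[i, j] = 1 + int(np.sum(col[ok] > col[i]))
    for i, v in enumerate(varieties):
        series.append(StageSeries(variety=str(v), measure=measure,
                                  values=mat[i], ranks=ranks[i]))
    return series


def decline_rate(series: StageSeries) -> float:
    """Mean per-stage nitrogen drop over booting -> milk ripening.

    ``(value(BS) - value(MRS)) / 2``; larger means faster decline.  A negative
    rate (nitrogen still rising late) is allowed and flagged downstream.
    """
    bs, mrs = series.value("BS"), series.value("MRS")
    if not (math.isfinite(bs) and math.isfinite(mrs)):
        raise ValueError(f"variety {series.variety}: BS and MRS values required")
    return (bs - mrs) / 2.0


def classify_high_nue(
    series_collection: Sequence[StageSeries],
    rule: PhenotypeRule = PhenotypeRule(),
) -> pd.DataFrame:
    """Flag varieties whose nitrogen curve matches the high-NUE phenotype.

    A variety is flagged iff (i) its rank at both FHS and MRS is within
    ``reproductive_rank_max``, (ii) each of TS, JS, PIS, BS lies inside the
    ``vegetative_band`` percentiles of that stage's distribution, and (iii)
    its BS->MRS decline rate does not exceed the collection's
    ``decline_quantile_max`` quantile.  Varieties with missing stages are
    excluded with a warning.  Returns a per-variety diagnostic table.
    """
    series_collection = list(series_collection)
    incomplete = [s.variety for s in series_collection if not s.complete]
    if incomplete:
        warnings.warn(
            f"excluding varieties with missing stages: {incomplete}", stacklevel=2
        )
    complete = [s for s in series_collection if s.complete]
    if len(complete) < 5:
        raise ValueError("need >=5 complete varieties for percentile-based screening")

    mat = np.vstack([s.values for s in complete])
    # ranks recomputed over the complete subset so clauses are self-consistent
    rank_mat = np.vstack([
        1 + np.sum(mat > mat[i], axis=0) for i in range(mat.shape[0])
    ])
    lo_p, hi_p = rule.vegetative_band
    veg_idx = [STAGE_INDEX[s] for s in VEGETATIVE_STAGES]
    rep_idx = [STAGE_INDEX[s] for s in REPRODUCTIVE_STAGES]
    bands = {
        j: (np.percentile(mat[:, j], lo_p), np.percentile(mat[:, j], hi_p))
        for j in veg_idx
    }
    rates = np.array([decline_rate(s) for s in complete])
    rate_cap = float(np.quantile(rates, rule.decline_quantile_max))

    rows = []
    for i, s in enumerate(complete):
        clause_rep = bool(all(rank_mat[i, j] <= rule.reproductive_rank_max for j in rep_idx))
        clause_veg = bool(
            all(bands[j][0] <= mat[i, j] <= bands[j][1] for j in veg_idx)
        )
        clause_dec = bool(rates[i] <= rate_cap)
        rows.append(
            {
                "variety": s.variety,
                "measure": s.measure,
                "flagged": clause_rep and clause_veg and clause_dec,
                "clause_reproductive": clause_rep,
                "clause_vegetative": clause_veg,
                "clause_decline": clause_dec,
                "rank_FHS": int(rank_mat[i, STAGE_INDEX["FHS"]]),
                "rank_MRS": int(rank_mat[i, STAGE_INDEX["MRS"]]),
                "decline_rate": float(rates[i]),
                "decline_negative": bool(rates[i] < 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FieldTraitRecord:
    """Per-plant (or per-plot) yield traits of the nitrogen dosage trial."""

    variety: Optional[str]
    treatment_kg_ha: float
    pl_cm: Optional[float]
    epn: float
    full_grains: float
    total_grains: float
    gnp: float
    weight_200_g: float
    tgw_g: float
    ssr_pct: float
    gyp_g: float
    gy_kg_ha: Optional[float]
    nue_kg_kg: Optional[float]

    def __post_init__(self) -> None:
        if not (0 <= self.ssr_pct <= 100):
            raise ValueError(f"SSR out of range: {self.ssr_pct}")


def field_traits(
    *,
    full_grains: float,
    total_grains: float,
    epn: float,
    weight_200_g: float,
    gyp_g: float,
    treatment_kg_ha: float,
    pl_cm: Optional[float] = None,
    plants_counted: Optional[float] = None,
    area_m2: Optional[float] = None,
    variety: Optional[str] = None,
    moisture_adjust: bool = False,
) -> FieldTraitRecord:
    """Derive the composite yield/NUE traits from raw counts and weights.

    GY is computed only when ``plants_counted`` and ``area_m2`` are given:
    GY[kg/ha] = GYP[g] * plants / area[m^2] * 10 (the g -> kg and m^2 -> ha
    conversions fold into the factor 10).  ``moisture_adjust`` deducts the
    13.5% standard moisture from GY (combine-harvest convention; off by
    default).  NUE = GY / N applied, undefined (None) at 0 kg/ha.
    """
    if min(full_grains, total_grains, epn) < 0:
        raise ValueError("grain and panicle counts must be non-negative")
    if total_grains == 0:
        raise ValueError("SSR undefined: total grain count is zero")
    if epn == 0:
        raise ValueError("GNP undefined: effective panicle number is zero")
    ssr = 100.0 * full_grains / total_grains
    gnp = full_grains / epn
    tgw = 5.0 * weight_200_g
    gy = None
    nue = None
    if plants_counted is not None and area_m2 is not None:
        if area_m2 <= 0:
            raise ValueError("field area must be positive")
        gy = gyp_g * plants_counted / area_m2 * 10.0
        if moisture_adjust:
            gy *= 1.0 - STANDARD_MOISTURE
        if treatment_kg_ha > 0:
            nue = gy / treatment_kg_ha
    return FieldTraitRecord(
        variety=variety,
        treatment_kg_ha=treatment_kg_ha,
        pl_cm=pl_cm,
        epn=epn,
        full_grains=full_grains,
        total_grains=total_grains,
        gnp=gnp,
        weight_200_g=weight_200_g,
        tgw_g=tgw,
        ssr_pct=ssr,
        gyp_g=gyp_g,
        gy_kg_ha=gy,
        nue_kg_kg=nue,
    )


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Student's two-sample t-test, two-sided; Welch variant by flag.

    Returns (t, df, p).  The degenerate zero-variance case with equal means is
    resolved to its defined limit (t = 0, p = 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            return (0.0, float(na + nb - 2), 1.0) if ma == mb else (math.inf, float(na + nb - 2), 0.0)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        t = (ma - mb) / math.sqrt(se2)
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            return (0.0, df, 1.0) if ma == mb else (math.inf, df, 0.0)
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    from scipy import stats

    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def compare_dosage_groups(
    trial: pd.DataFrame,
    trait_cols: Iterable[str] = ("gyp_g", "epn", "pl_cm", "weight_200_g"),
    variety_col: str = "variety",
    treatment_col: str = "treatment_kg_ha",
    welch: bool = False,
) -> pd.DataFrame:
    """Group means +- SD and pairwise t-tests per treatment for a 2-variety trial."""
    varieties = sorted(trial[variety_col].unique())
    if len(varieties) != 2:
        raise ValueError(f"expected exactly 2 varieties, got {varieties}")
    va, vb = varieties
    rows = []
    for treatment, sub in trial.groupby(treatment_col):
        ga = sub[sub[variety_col] == va]
        gb = sub[sub[variety_col] == vb]
        for trait in trait_cols:
            t, df, p = two_sample_t(ga[trait].to_numpy(), gb[trait].to_numpy(), welch=welch)
            rows.append(
                {
                    "treatment_kg_ha": treatment,
                    "trait": trait,
                    f"mean_{va}": ga[trait].mean(),
                    f"sd_{va}": ga[trait].std(ddof=1),
                    f"mean_{vb}": gb[trait].mean(),
                    f"sd_{vb}": gb[trait].std(ddof=1),
                    "t": t,
                    "df": df,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)
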