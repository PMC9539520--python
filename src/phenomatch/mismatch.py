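"""Population-level mismatch metrics and their fit to annual fledging rates.

Resource phenology is the daily proportion of seasonal invertebrate biomass.
Consumer phenology comes in two flavours: the peak-demand curve places each
chick at a single developmental point (the day it reaches the growth-curve
inflection), while the whole-demand curve sums the age-specific energetic
demand — predicted mass raised to an allometric exponent theta — of every
chick alive on every day.  Four annual metrics follow: proportional-overlap
of each demand curve with the resource curve, the resource-curve area
("curve height"), and the resource-minus-demand difference in quadratic peak
dates.  Each metric is related to annual fledging rates by a univariate
linear model and the four models are ranked by AICc weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthFit
from .resources import fit_quadratic_peak
from .survival import EncounterHistory, FLEDGE_AGE

DEFAULT_THETA = 0.75     # metabolic allometry exponent for whole demand


@dataclass
class PhenologyCurve:
    """Daily proportions over one season; non-negative, summing to 1."""
    year: int
    days: np.ndarray
    proportions: np.ndarray
    kind: str = "resource"      # resource | peak_demand | whole_demand

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0):
            raise ValueError("curve proportions must be non-negative")
        total = self.proportions.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"curve proportions must sum to 1 (got {total})")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=self.days)


def resource_curve(series: pd.DataFrame, year: int) -> PhenologyCurve:
    """Daily proportion of the year's total invertebrate biomass."""
    sub = series[series["year"] == year].dropna(subset=["biomass_mg"]).sort_values("day")
    total = sub["biomass_mg"].sum()
    if sub.empty or total <= 0:
        raise ValueError(f"no positive biomass in year {year}")
    return PhenologyCurve(year=int(year), days=sub["day"].to_numpy(),
                          proportions=sub["biomass_mg"].to_numpy() / total, kind="resource")


# ---------------------------------------------------------------------------
# Demand curves
# ---------------------------------------------------------------------------

def _alive_until(history: EncounterHistory) -> float:
    """Age up to which a chick contributes demand: fledge age if it survived,
    the midpoint of its death interval if it died (interval-censored)."""
    iv = history.intervals
    died = iv[iv["fate"] == "died_within"]
    if len(died):
        row = died.iloc[-1]
        return 0.5 * (float(row["start_age"]) + float(row["end_age"]))
    return float(iv["end_age"].max())


def peak_demand_curve(histories: list[EncounterHistory], fit: GrowthFit,
                      year: int) -> PhenologyCurve:
    """Daily frequency of chicks reaching the inflection age Ti.

    Each chick alive at age Ti contributes one unit on calendar day
    hatch + Ti; chicks dying earlier contribute nothing.
    """
    hs = [h for h in histories if h.year == year]
    if not hs:
        raise ValueError(f"no chicks in year {year}")
    Ti = fit.Ti_year.get(year, fit.Ti_mean)
    counts: dict[int, float] = {}
    for h in hs:
        if _alive_until(h) >= Ti:
            day = int(round(h.hatch_doy + Ti))
            counts[day] = counts.get(day, 0.0) + 1.0
    if not counts:
        raise ValueError(f"no chick survived to the inflection age in year {year}")
    days = np.array(sorted(counts))
    vals = np.array([counts[d] for d in days])
    return PhenologyCurve(year=int(year), days=days, proportions=vals / vals.sum(),
                          kind="peak_demand")


def whole_demand_curve(histories: list[EncounterHistory], fit: GrowthFit,
                       year: int, theta: float = DEFAULT_THETA) -> PhenologyCurve:
    """Age-structured demand: sum over alive chicks of predicted mass**theta.

    theta scales per-capita demand with body mass (0.75 by default, the
    metabolic allometry; 1 gives mass-proportional demand; 0 reduces to a
    daily head count).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    hs = [h for h in histories if h.year == year]
    if not hs:
        raise ValueError(f"no chicks in year {year}")
    demand: dict[int, float] = {}
    for h in hs:
        last_age = int(np.floor(_alive_until(h)))
        ages = np.arange(0, last_age + 1)
        mass = fit.predict_mass(ages, year)
        dem = np.asarray(mass, dtype=float) ** theta
        for a, d in zip(ages, dem):
            day = int(round(h.hatch_doy)) + int(a)
            demand[day] = demand.get(day, 0.0) + float(d)
    days = np.array(sorted(demand))
    vals = np.array([demand[d] for d in days])
    if vals.sum() <= 0:
        raise ValueError(f"zero total demand in year {year}")
    return PhenologyCurve(year=int(year), days=days, proportions=vals / vals.sum(),
                          kind="whole_demand")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def overlap_index(consumer: PhenologyCurve, resource: PhenologyCurve) -> float:
    """Proportional-area overlap: sum over days of min(consumer, resource).

    Days present in only one curve count as zero in the other; the index is
    symmetric, lies in [0, 1], and equals 1 only for identical curves.
    """
    if consumer.year != resource.year:
        raise ValueError("curves are from different years")
    a, b = consumer.as_series(), resource.as_series()
    days = a.index.union(b.index)
    return float(np.minimum(a.reindex(days, fill_value=0.0),
                            b.reindex(days, fill_value=0.0)).sum())


def demand_coverage(consumer: PhenologyCurve, resource: PhenologyCurve) -> float:
    """Alternative index: fraction of demand days covered by resource supply,
    sum over days of min(consumer_d, resource_d) / sum of consumer_d (== the
    symmetric overlap here since both curves sum to 1, but kept as a named
    variant for readers expecting a consumer-normalized quantity)."""
    return overlap_index(consumer, resource)


def curve_height(series: pd.DataFrame, year: int) -> float:
    """Cumulative resource availability: area under the unnormalized daily
    biomass curve at unit-day spacing (each sampled day a 1-day bin, so the
    area is the sum of daily biomass, in mg)."""
    sub = series[series["year"] == year].dropna(subset=["biomass_mg"])
    return float(sub["biomass_mg"].sum())


def curve_peak_day(curve, year: int) -> float:
    """Quadratic-vertex peak day of a daily series DataFrame or PhenologyCurve."""
    if isinstance(curve, PhenologyCurve):
        df = pd.DataFrame({"year": curve.year, "day": curve.days,
                           "biomass_mg": curve.proportions})
        return fit_quadratic_peak(df, curve.year).peak_day
    return fit_quadratic_peak(curve, year).peak_day


def peak_date_difference(resource, demand, year: int) -> float:
    """Resource peak day minus demand peak day, both from quadratic vertices
    (positive = resources peak later than consumer demand).  Either argument
    may be a daily series DataFrame or a PhenologyCurve."""
    return float(curve_peak_day(resource, year) - curve_peak_day(demand, year))


@dataclass
class MismatchMetrics:
    year: int
    overlap_whole: float
    overlap_peak: float
    peak_diff_days: float
    curve_height_mg: float


def annual_metrics(series: pd.DataFrame, histories: list[EncounterHistory],
                   fit: GrowthFit, years=None, theta: float = DEFAULT_THETA) -> pd.DataFrame:
    """All four mismatch metrics per year (NaN where a curve is degenerate)."""
    years = sorted({h.year for h in histories}) if years is None else sorted(years)
    rows = []
    for y in years:
        row = {"year": int(y), "overlap_whole": np.nan, "overlap_peak": np.nan,
               "peak_diff_days": np.nan, "curve_height_mg": np.nan}
        # metrics are independent: a degenerate curve voids only its own entry
        try:
            res = resource_curve(series, y)
        except ValueError:
            rows.append(row)
            continue
        row["curve_height_mg"] = curve_height(series, y)
        try:
            whole = whole_demand_curve(histories, fit, y, theta)
            row["overlap_whole"] = overlap_index(whole, res)
        except ValueError:
            pass
        try:
            peak = peak_demand_curve(histories, fit, y)
            row["overlap_peak"] = overlap_index(peak, res)
            row["peak_diff_days"] = peak_date_difference(series, peak, y)
        except ValueError:
            pass
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Annual models
# ---------------------------------------------------------------------------

METRIC_COLUMNS = ("overlap_whole", "overlap_peak", "peak_diff_days", "curve_height_mg")


def fit_annual_models(metrics: pd.DataFrame, fledging: pd.DataFrame,
                      metric_columns=METRIC_COLUMNS) -> pd.DataFrame:
    """Univariate OLS of annual fledging rate on each mismatch metric.

    Returns one row per metric with slope, SE, adjusted R², AICc and the
    Akaike weight over the model set.  Years missing either a metric or a
    fledging estimate are dropped per model; fewer than 4 common years
    raise.
    """
    import statsmodels.api as sm

    merged = metrics.merge(fledging[["year", "fledging"]], on="year", how="inner")
    rows = []
    for col in metric_columns:
        sub = merged.dropna(subset=[col, "fledging"])
        n = len(sub)
        if n < 4:
            raise ValueError(f"need >=4 years with data for metric {col!r} (have {n})")
        X = sm.add_constant(sub[col].to_numpy(float))
        res = sm.OLS(sub["fledging"].to_numpy(float), X).fit()
        k = 3.0  # intercept + slope + residual variance
        aicc = res.aic + (2 * k * (k + 1)) / max(n - k - 1, 0.5)
        rows.append({"metric": col, "slope": float(res.params[1]), "se": float(res.bse[1]),
                     "r2_adj": float(res.rsquared_adj), "aicc": float(aicc), "n_years": n})
    table = pd.DataFrame(rows)
    table["delta"] = table["aicc"] - table["aicc"].min()
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    return table.sort_values("aicc").reset_index(drop=True)
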