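"""Daily invertebrate resource series: availability, quality, peaks, trends.

Raw inputs are individual invertebrate capture records (one row per measured
animal: date, transect, trap type, taxonomic order, life stage, body length
in mm).  This module converts lengths to dry mass through taxon-specific
power-law allometry, restricts records to the size range a precocial
shorebird chick can actually swallow, aggregates to a per-day series of
biomass (mg per transect per day) and median per-capita body mass (mg), and
estimates annual peak dates and across-year linear trends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phenomatch")

# Prey definition: adult invertebrates within the gape-limited size range.
PREY_MIN_MM = 1.5
PREY_MAX_MM = 9.0
EXCLUDED_ORDERS = ("Collembola",)

# The six orders dominating the assemblage; order-level trend/peak analyses
# default to this list (configurable by the caller).
FOCAL_ORDERS = ("Araneae", "Hymenoptera", "Coleoptera", "Diptera", "Acari", "Hemiptera")

# Seasons shorter than this many sampled days are dropped from peak-date
# estimation (a handful of sample days cannot constrain a seasonal vertex).
MIN_SEASON_SPAN_DAYS = 30


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

@dataclass
class AllometryTable:
    """Per-order dry-mass power laws, mass_mg = a * length_mm ** b.

    A generic terrestrial-arthropod law is used for any order without its
    own row.  The shipped defaults are ordinary literature-style power-law
    coefficients and are meant to be overridden with study-specific values
    when available.
    """

    generic: tuple[float, float] = (0.0305, 2.62)
    per_order: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (a, b) in {"generic": self.generic, **self.per_order}.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"allometry coefficients must be positive ({name}: a={a}, b={b})")

    def coefficients(self, order: str) -> tuple[float, float]:
        return self.per_order.get(order, self.generic)

    @classmethod
    def from_csv(cls, path) -> "AllometryTable":
        df = pd.read_csv(path)
        required = {"order", "a", "b"}
        if not required.issubset(df.columns):
            raise ValueError(f"allometry CSV needs columns {sorted(required)}")
        per_order = {}
        generic = cls().generic
        for _, row in df.iterrows():
            if str(row["order"]).lower() in ("generic", "all", "all-taxa"):
                generic = (float(row["a"]), float(row["b"]))
            else:
                per_order[str(row["order"])] = (float(row["a"]), float(row["b"]))
        return cls(generic=generic, per_order=per_order)


#: Default table: generic arthropod law plus per-order overrides.  Values are
#: plausible field defaults, explicitly user-replaceable.
DEFAULT_ALLOMETRY = AllometryTable(
    generic=(0.0305, 2.62),
    per_order={
        "Araneae": (0.0500, 2.74),
        "Coleoptera": (0.0312, 2.62),
        "Diptera": (0.0375, 2.46),
        "Hymenoptera": (0.0346, 2.49),
        "Hemiptera": (0.0496, 2.26),
        "Acari": (0.0305, 2.62),
    },
)


def length_to_dry_mass(length_mm, order: str, table: AllometryTable = DEFAULT_ALLOMETRY):
    """Convert body length (mm) to inferred dry mass (mg) via a * L**b.

    Orders missing from the table fall back to the generic all-taxa row.
    Accepts scalars or arrays; rejects non-positive lengths.
    """
    length = np.asarray(length_mm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("length_mm must be positive")
    a, b = table.coefficients(order)
    out = a * length**b
    return float(out) if np.isscalar(length_mm) else out


# ---------------------------------------------------------------------------
# Filtering and aggregation
# ---------------------------------------------------------------------------

INVERT_COLUMNS = ["date", "transect", "trap_type", "order", "life_stage", "length_mm"]


def filter_potential_prey(records: pd.DataFrame) -> pd.DataFrame:
    """Keep adult records in the chick-accessible size window [1.5, 9] mm.

    Larvae (rarely eaten by chicks) and Collembola (primarily aquatic,
    unevenly recorded) are dropped.  Record order is preserved.
    """
    if records.empty:
        return records.copy()
    keep = (
        (records["life_stage"] == "adult")
        & (records["length_mm"] >= PREY_MIN_MM)
        & (records["length_mm"] <= PREY_MAX_MM)
        & ~records["order"].isin(EXCLUDED_ORDERS)
    )
    out = records.loc[keep].copy()
    logger.info("filter_potential_prey: kept %d of %d records", len(out), len(records))
    return out


def _with_year_day(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    dates = pd.to_datetime(df["date"])
    df["year"] = dates.dt.year
    df["day"] = dates.dt.dayofyear
    return df


def aggregate_daily(records: pd.DataFrame, table: AllometryTable = DEFAULT_ALLOMETRY,
                    n_transects: int | None = None) -> pd.DataFrame:
    """Collapse filtered records to the daily resource series.

    Per (year, day): ``biomass_mg`` is the mean over transects of each
    transect's summed dry mass (transects are treated as replicates);
    ``median_bodymass_mg`` is the median per-capita dry mass across all of
    that day's records.  Days where only a subset of transects reported are
    averaged over the reporting transects (trap failure is not
    distinguishable from non-sampling in the schema); ``n_transects``
    exposes that coverage alongside ``n_records``.

    Returns a DataFrame with columns
    [year, day, biomass_mg, median_bodymass_mg, n_records, n_transects].
    """
    if records.empty:
        return pd.DataFrame(
            columns=["year", "day", "biomass_mg", "median_bodymass_mg", "n_records", "n_transects"]
        )
    df = _with_year_day(records)
    mass = np.empty(len(df))
    for order, idx in df.groupby("order").groups.items():
        mass[df.index.get_indexer(idx)] = length_to_dry_mass(
            df.loc[idx, "length_mm"].to_numpy(), str(order), table
        )
    df["mass_mg"] = mass

    per_transect = df.groupby(["year", "day", "transect"])["mass_mg"].sum()
    daily = per_transect.groupby(["year", "day"]).agg(biomass_mg="mean", n_transects="size")
    med = df.groupby(["year", "day"])["mass_mg"].agg(median_bodymass_mg="median", n_records="size")
    out = daily.join(med).reset_index()
    return out[["year", "day", "biomass_mg", "median_bodymass_mg", "n_records", "n_transects"]]


def rolling_mean(series: pd.DataFrame, column: str, year: int, window: int, anchor_day: int):
    """Trailing mean of a daily column over `window` days ending at anchor_day.

    Missing days inside the window are simply skipped (no interpolation);
    a window with no data at all yields NaN.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sub = series[(series["year"] == year)
                 & (series["day"] > anchor_day - window)
                 & (series["day"] <= anchor_day)]
    if sub.empty:
        return float("nan")
    return float(sub[column].mean())


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakEstimate:
    year: int
    peak_day: float
    beta0: float
    beta1: float
    beta2: float


def fit_quadratic_peak(series: pd.DataFrame, year: int, column: str = "biomass_mg") -> PeakEstimate:
    """Annual peak date from the vertex of an OLS quadratic in day-of-year.

    Fits ``column ~ day + day^2`` within the year and returns the day where
    the first derivative vanishes, -b1/(2 b2).  A non-concave fit has no
    interior maximum and raises.
    """
    sub = series[series["year"] == year].dropna(subset=[column])
    days = sub["day"].to_numpy(float)
    if len(np.unique(days)) < 3:
        raise ValueError(f"need >=3 distinct days in year {year} to fit a quadratic")
    y = sub[column].to_numpy(float)
    # center day for conditioning, then shift the vertex back
    d0 = days.mean()
    X = np.column_stack([np.ones_like(days), days - d0, (days - d0) ** 2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0c, b1c, b2 = coef
    if b2 >= 0:
        raise ValueError(f"no interior maximum in year {year} (quadratic term {b2:.3g} >= 0)")
    peak = d0 - b1c / (2.0 * b2)
    # uncentered coefficients for reporting
    beta1 = b1c - 2.0 * b2 * d0
    beta0 = b0c - b1c * d0 + b2 * d0**2
    return PeakEstimate(year=int(year), peak_day=float(peak), beta0=float(beta0),
                        beta1=float(beta1), beta2=float(b2))


def annual_peaks(series: pd.DataFrame, column: str = "biomass_mg",
                 min_span: int = MIN_SEASON_SPAN_DAYS) -> pd.DataFrame:
    """Peak estimates for every year whose sampled span is long enough.

    Shortened seasons (span < `min_span` days) are excluded, as are years
    where the quadratic has no interior maximum.
    """
    rows = []
    for year, sub in series.groupby("year"):
        span = sub["day"].max() - sub["day"].min()
        if span < min_span:
            logger.warning("annual_peaks: year %s span %d days < %d, excluded", year, span, min_span)
            continue
        try:
            pk = fit_quadratic_peak(series, int(year), column=column)
        except ValueError as err:
            logger.warning("annual_peaks: year %s skipped (%s)", year, err)
            continue
        rows.append({"year": pk.year, "peak_day": pk.peak_day,
                     "beta0": pk.beta0, "beta1": pk.beta1, "beta2": pk.beta2})
    return pd.DataFrame(rows, columns=["year", "peak_day", "beta0", "beta1", "beta2"])


# ---------------------------------------------------------------------------
# Standardization and trends
# ---------------------------------------------------------------------------

def standardize_gelman(x) -> np.ndarray:
    """Center and scale by twice the sample SD: (x - mean) / (2 * sd).

    Puts continuous inputs on a half-SD scale so their coefficients are
    comparable with those of binary predictors.  Output has mean 0 and
    SD 0.5.  Degenerate (zero-variance) input raises.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance input cannot be standardized")
    return (arr - arr.mean()) / (2.0 * sd)


@dataclass
class TrendResult:
    slope: float            # response units per year
    se: float
    ci95_low: float
    ci95_high: float
    marginal_r2: float
    conditional_r2: float
    relevant: bool          # 95% CI excludes zero
    singular_fallback: bool = False


def fit_trend(data: pd.DataFrame, response: str,
              random_intercepts: tuple[str, ...] = ("trap_type",)) -> TrendResult:
    """Linear across-year trend of a response, with crossed random intercepts.

    Fits ``response ~ year`` by REML with random intercepts for the listed
    grouping factors (e.g. trap type, sample date), standardizing predictor
    and response internally (Gelman two-SD scaling) and back-transforming
    the slope to original units per year.  Marginal/conditional R² follow
    the Nakagawa variance-partition formulas.  A singular or failed mixed
    fit falls back to OLS with a logged warning.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM
    import statsmodels.api as sm

    df = data.dropna(subset=[response, "year"]).copy()
    years = df["year"].to_numpy(float)
    if len(np.unique(years)) < 2:
        raise ValueError("need >=2 distinct years for a trend")
    for factor in random_intercepts:
        if factor not in df.columns:
            raise ValueError(f"grouping factor {factor!r} missing from data")

    y_raw = df[response].to_numpy(float)
    sy, sx = 2.0 * y_raw.std(ddof=1), 2.0 * years.std(ddof=1)
    df["_y"] = (y_raw - y_raw.mean()) / sy
    df["_x"] = (years - years.mean()) / sx
    back = sy / sx  # slope scale factor back to original units per year

    singular = False
    var_random = 0.0
    try:
        if random_intercepts:
            vc = {f: f"0 + C({f})" for f in random_intercepts}
            df["_one"] = 1
            model = MixedLM.from_formula("_y ~ _x", groups="_one", vc_formula=vc, data=df)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True, method="lbfgs")
            if not np.isfinite(fit.bse["_x"]) or fit.bse["_x"] == 0:
                raise np.linalg.LinAlgError("degenerate SE")
            slope_std, se_std = fit.params["_x"], fit.bse["_x"]
            var_random = float(sum(np.asarray(fit.vcomp, float)))
            var_resid = float(fit.scale)
        else:
            raise np.linalg.LinAlgError("no random intercepts requested")
    except (np.linalg.LinAlgError, ValueError) as err:
        if random_intercepts:
            logger.warning("fit_trend: mixed fit failed (%s); falling back to OLS", err)
            singular = True
        X = sm.add_constant(df["_x"])
        ols = sm.OLS(df["_y"], X).fit()
        slope_std, se_std = ols.params["_x"], ols.bse["_x"]
        var_random, var_resid = 0.0, float(ols.mse_resid)

    var_fixed = float(np.var(slope_std * df["_x"].to_numpy()))
    total = var_fixed + var_random + var_resid
    marginal_r2 = var_fixed / total if total > 0 else 0.0
    conditional_r2 = (var_fixed + var_random) / total if total > 0 else 0.0

    slope = slope_std * back
    se = se_std * back
    lo, hi = slope - 1.96 * se, slope + 1.96 * se
    return TrendResult(
        slope=float(slope), se=float(se), ci95_low=float(lo), ci95_high=float(hi),
        marginal_r2=float(marginal_r2), conditional_r2=float(conditional_r2),
        relevant=bool(lo > 0 or hi < 0), singular_fallback=singular,
    )


def daily_series_with_dates(records: pd.DataFrame, table: AllometryTable = DEFAULT_ALLOMETRY) -> pd.DataFrame:
    """aggregate_daily plus the columns trend models need (trap_type, sample_date)."""
    series = aggregate_daily(filter_potential_prey(records), table)
    df = _with_year_day(records)
    trap = df.groupby(["year", "day"])["trap_type"].first().rename("trap_type")
    out = series.merge(trap.reset_index(), on=["year", "day"], how="left")
    out["sample_date"] = out["year"].astype(str) + "-" + out["day"].astype(str)
    return out
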