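"""Synthetic field seasons with known ground truth.

Emulates the three data streams of a precocial-shorebird mismatch study —
daily invertebrate transect samples, chick mass-at-capture records, and
radio-relocation histories — from a single configuration with known
parameters, so every downstream estimator can be tested as a
generator/estimator round trip.

What is emulated: a unimodal seasonal resource pulse with year-specific peak
date and height; order-specific lognormal body-length distributions;
per-individual logistic growth around a fixed adult asymptote; and daily
Bernoulli survival driven by a logit-linear model with an age x prey-size
interaction, observed only through ~3-day relocation intervals with
right-censoring at the radio lifespan (21 days).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import resources as res
from .resources import DEFAULT_ALLOMETRY, AllometryTable

# fixed RNG stream offsets so partial reruns of one stage are stable
_STREAM_RESOURCES = 1
_STREAM_CHICKS = 2

#: survival covariates, in design order (interaction last)
SURVIVAL_COVARIATES = ("biomass", "bodymass", "hatch", "age")


@dataclass
class SimConfig:
    """All ground-truth knobs of one simulated multi-year study.

    Survival coefficients ``beta`` act on Gelman-standardized (two-SD)
    covariates, mirroring the scale on which the survival model is fitted:
    keys are intercept, biomass, bodymass, hatch, age, age_x_bodymass.
    """

    years: tuple[int, ...] = (2009, 2010, 2011, 2014, 2015, 2016, 2019)
    season_start: int = 130
    season_end: int = 200
    n_transects: int = 2
    resource_peak_day: dict[int, float] = field(default_factory=dict)
    resource_peak_height: dict[int, float] = field(default_factory=dict)  # mg/transect/day at peak
    resource_width: float | dict[int, float] = 12.0  # days (Gaussian SD of the pulse; may vary by year)
    resource_skew: float = 0.0         # skew-normal shape; 0 = symmetric
    resource_baseline: float = 15.0    # mg/transect/day floor outside the pulse
    order_mix: dict[str, float] = field(default_factory=lambda: {
        "Araneae": 0.205, "Hymenoptera": 0.184, "Coleoptera": 0.175,
        "Diptera": 0.162, "Acari": 0.113, "Hemiptera": 0.077, "Collembola": 0.084,
    })
    length_meanlog: dict[str, float] = field(default_factory=lambda: {
        "Araneae": 1.10, "Hymenoptera": 1.00, "Coleoptera": 1.25,
        "Diptera": 1.05, "Acari": 0.10, "Hemiptera": 1.10, "Collembola": 0.30,
    })
    length_sdlog: dict[str, float] = field(default_factory=lambda: {
        o: 0.45 for o in ("Araneae", "Hymenoptera", "Coleoptera",
                          "Diptera", "Acari", "Hemiptera", "Collembola")
    })
    larval_fraction: float = 0.10
    #: seasonal covariation of prey size with the resource pulse: per-day shift
    #: of every order's length meanlog by coupling * (pulse - 1/2), so prey run
    #: larger near the biomass peak and smaller in the tails (0 = constant sizes)
    size_season_coupling: float = 0.0
    n_broods: dict[int, int] = field(default_factory=dict)
    chicks_per_brood: int = 2
    hatch_mean: dict[int, float] = field(default_factory=dict)
    hatch_sd: float = 4.0
    growth_A0: float = 249.0           # g, adult asymptote
    growth_K: float = 0.18             # 1/day
    growth_Ti: float = 12.0            # days, inflection age
    K_indiv_sd: float = 0.02           # 1/day, among-chick SD of K
    mass_noise_sd: float = 4.0         # g, capture measurement noise
    recapture_interval: int = 7        # days between mass captures
    beta: dict[str, float] = field(default_factory=lambda: {
        "intercept": 2.6, "biomass": 0.8, "bodymass": 0.4,
        "hatch": -0.3, "age": 0.1, "age_x_bodymass": 0.5,
    })
    relocation_interval: int = 3
    fledge_age: int = 21
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season_start >= self.season_end:
            raise ValueError("season_start must be < season_end")
        if self.fledge_age <= 0:
            raise ValueError("fledge_age must be positive")
        if self.hatch_sd < 0 or self.K_indiv_sd < 0 or self.mass_noise_sd < 0:
            raise ValueError("SDs must be non-negative")
        total = sum(self.order_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"order_mix must sum to 1 (got {total})")
        mid = 0.5 * (self.season_start + self.season_end)
        for y in self.years:
            self.resource_peak_day.setdefault(y, mid)
            self.resource_peak_height.setdefault(y, 300.0)
            self.n_broods.setdefault(y, 9)
            self.hatch_mean.setdefault(y, mid)


def default_config(seed: int = 0) -> SimConfig:
    """The default seven-season study: two anomalous early-resource years
    (sparse late-season food) in the middle of five roughly matched ones."""
    peak_day = {2009: 168, 2010: 165, 2011: 170, 2014: 150, 2015: 148, 2016: 166, 2019: 163}
    peak_height = {2009: 330, 2010: 300, 2011: 360, 2014: 210, 2015: 190, 2016: 310, 2019: 280}
    hatch_mean = {y: 162.0 for y in peak_day}
    return SimConfig(resource_peak_day=peak_day, resource_peak_height=peak_height,
                     hatch_mean=hatch_mean, seed=seed)


def late_prey_size_config(seed: int = 0) -> SimConfig:
    """Eight seasons where survival is driven by late-development prey size.

    The age x prey-size interaction dominates mortality, prey sizes track
    the seasonal pulse, and years range from matched/wide resource pulses to
    pulses that are aligned with mid-development but too narrow to cover the
    late, most demanding ages — the regime where a single-timepoint (peak
    demand) phenology misreads the cohort's exposure.
    """
    years = tuple(range(2009, 2017))
    peak = {2009: 174, 2010: 171, 2011: 176, 2012: 150,
            2013: 172, 2014: 148, 2015: 173, 2016: 170}
    width = {2009: 14, 2010: 5, 2011: 15, 2012: 6,
             2013: 5, 2014: 6, 2015: 15, 2016: 6}
    return SimConfig(
        years=years, resource_peak_day=peak, resource_width=width,
        resource_peak_height={y: 300.0 for y in years},
        n_broods={y: 13 for y in years}, hatch_mean={y: 160.0 for y in years},
        size_season_coupling=0.6,
        beta={"intercept": 3.0, "biomass": 0.2, "bodymass": 0.6,
              "hatch": 0.0, "age": 0.0, "age_x_bodymass": 1.5},
        seed=seed)


def small_config(seed: int = 0) -> SimConfig:
    """A three-season, <=30-chick configuration for fast fixtures."""
    years = (2009, 2014, 2016)
    return SimConfig(
        years=years,
        resource_peak_day={2009: 168, 2014: 150, 2016: 166},
        resource_peak_height={2009: 330, 2014: 210, 2016: 310},
        n_broods={y: 5 for y in years},
        hatch_mean={y: 162.0 for y in years},
        seed=seed,
    )


@dataclass
class SimTruth:
    """Realized ground truth for recovery tests."""
    beta: dict[str, float]
    covariate_stats: dict[str, tuple[float, float]]   # name -> (mean, sd) on raw scale
    growth_K: float
    growth_Ti: float
    K_indiv: dict[str, float]                         # chick_id -> K deviation
    hatch_age: dict[str, float]                       # chick_id -> hatch day-of-year
    death_age: dict[str, float | None]                # chick_id -> death age (None = fledged)
    latent_curve: dict[int, dict[int, float]]         # year -> day -> expected biomass
    fledged_fraction: dict[int, float]                # year -> realized fledge fraction

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["latent_curve"] = {str(y): {str(k): v for k, v in c.items()}
                             for y, c in self.latent_curve.items()}
        d["fledged_fraction"] = {str(y): v for y, v in self.fledged_fraction.items()}
        return json.dumps(d, indent=1)


def _doy_to_date(year: int, doy) -> pd.Series:
    base = pd.Timestamp(int(year), 1, 1)
    return pd.Series([base + pd.Timedelta(days=int(d) - 1) for d in np.atleast_1d(doy)])


def _width(config: SimConfig, year: int) -> float:
    w = config.resource_width
    return float(w[year]) if isinstance(w, dict) else float(w)


def _seasonal_shape(days: np.ndarray, peak: float, width: float, skew: float) -> np.ndarray:
    """Unimodal seasonal intensity, 1 at its mode; skew-normal when skew != 0."""
    from scipy import stats
    z = (days - peak) / width
    if skew == 0.0:
        return np.exp(-0.5 * z**2)
    dens = stats.skewnorm.pdf(z, skew)
    return dens / dens.max()


def _mean_percapita_mass(config: SimConfig, table: AllometryTable = DEFAULT_ALLOMETRY) -> float:
    """Expected dry mass of one sampled individual under the order mix."""
    total = 0.0
    for order, p in config.order_mix.items():
        a, b = table.coefficients(order)
        mu, sd = config.length_meanlog[order], config.length_sdlog[order]
        total += p * a * np.exp(b * mu + 0.5 * (b * sd) ** 2)
    return total


def simulate_resources(config: SimConfig) -> pd.DataFrame:
    """Draw individual invertebrate capture records for every season.

    Daily per-transect counts are Poisson with intensity proportional to the
    seasonal pulse, scaled so the expected per-transect dry-mass flux at the
    peak equals ``resource_peak_height``; body lengths are lognormal per
    order; a fixed fraction of records are larvae.  Trap type follows the
    study convention (pitfall through 2012, malaise from 2014).
    """
    rng = np.random.default_rng([_STREAM_RESOURCES, config.seed])
    days = np.arange(config.season_start, config.season_end + 1)
    if days.size == 0:
        raise ValueError("empty season")
    mean_mass = _mean_percapita_mass(config)
    orders = list(config.order_mix)
    probs = np.array([config.order_mix[o] for o in orders])

    rows = []
    for year in config.years:
        shape = _seasonal_shape(days, config.resource_peak_day[year],
                                _width(config, year), config.resource_skew)
        lam = (config.resource_baseline + config.resource_peak_height[year] * shape) / mean_mass
        trap = "pitfall" if year <= 2012 else "malaise"
        for t in range(1, config.n_transects + 1):
            counts = rng.poisson(lam)
            for day, n, pulse in zip(days, counts, shape):
                if n == 0:
                    continue
                size_shift = config.size_season_coupling * (pulse - 0.5)
                ords = rng.choice(len(orders), size=n, p=probs)
                for oi in ords:
                    order = orders[oi]
                    length = rng.lognormal(config.length_meanlog[order] + size_shift,
                                           config.length_sdlog[order])
                    length = max(0.5, round(length * 2) / 2)  # measured to nearest 0.5 mm
                    stage = "larva" if rng.random() < config.larval_fraction else "adult"
                    rows.append((year, day, f"T{t}", trap, order, stage, length))
    df = pd.DataFrame(rows, columns=["year", "day", "transect", "trap_type",
                                     "order", "life_stage", "length_mm"])
    if df.empty:
        return pd.DataFrame(columns=["date"] + res.INVERT_COLUMNS[1:])
    dates = [pd.Timestamp(int(y), 1, 1) + pd.Timedelta(days=int(d) - 1)
             for y, d in zip(df["year"], df["day"])]
    out = pd.DataFrame({
        "date": [d.date().isoformat() for d in dates],
        "transect": df["transect"], "trap_type": df["trap_type"], "order": df["order"],
        "life_stage": df["life_stage"], "length_mm": df["length_mm"],
    })
    return out


def latent_resource_curves(config: SimConfig) -> dict[int, dict[int, float]]:
    """Noise-free expected prey biomass (mg/transect/day) per year and day."""
    days = np.arange(config.season_start, config.season_end + 1)
    out: dict[int, dict[int, float]] = {}
    for year in config.years:
        shape = _seasonal_shape(days, config.resource_peak_day[year],
                                _width(config, year), config.resource_skew)
        out[year] = {int(d): float(config.resource_baseline + config.resource_peak_height[year] * s)
                     for d, s in zip(days, shape)}
    return out


def logistic_mass_curve(age, A0: float, K, Ti) -> np.ndarray:
    return A0 / (1.0 + np.exp(-np.asarray(K) * (np.asarray(age, float) - np.asarray(Ti))))


def _covariate_grid(config: SimConfig, series: pd.DataFrame,
                    hatch: dict[str, tuple[int, float]]) -> pd.DataFrame:
    """Raw survival covariates for every (chick, age 1..fledge_age) cell.

    biomass/bodymass are 3-day trailing means of the daily series at the
    chick's calendar day; missing resource days raise (the series must span
    hatch + fledge_age for every chick).
    """
    lut: dict[tuple[int, int], tuple[float, float]] = {}
    for year, sub in series.groupby("year"):
        s = sub.set_index("day")
        for day in range(config.season_start, config.season_end + 1):
            avail = [d for d in (day - 2, day - 1, day) if d in s.index]
            if not avail:
                continue  # whole trailing window unsampled -> covariate missing
            window = s.loc[avail]
            lut[(int(year), int(day))] = (float(window["biomass_mg"].mean()),
                                          float(window["median_bodymass_mg"].mean()))
    rows = []
    for cid, (year, h) in hatch.items():
        for age in range(1, config.fledge_age + 1):
            day = int(round(h)) + age
            if (year, day) not in lut:
                raise ValueError(f"resource covariates missing for year {year} day {day}"
                                 f" (chick {cid})")
            bm, pm = lut[(year, day)]
            rows.append((cid, year, age, bm, pm, h))
    return pd.DataFrame(rows, columns=["chick_id", "year", "age", "biomass", "bodymass", "hatch"])


def simulate_chicks(config: SimConfig, series: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate broods, growth trajectories, daily survival, and relocations.

    Returns (chicks, masses, relocations, truth).  Survival is drawn
    day-by-day from the logit-linear model on standardized covariates, so
    the interval likelihood downstream is exercised against an honest
    day-level process; deaths are observed only at the next scheduled
    relocation, and chicks alive at ``fledge_age`` are right-censored as
    fledged.
    """
    rng = np.random.default_rng([_STREAM_CHICKS, config.seed])
    A0, K0, Ti0 = config.growth_A0, config.growth_K, config.growth_Ti

    hatch: dict[str, tuple[int, float]] = {}
    chick_rows, k_indiv = [], {}
    latest_hatch = config.season_end - config.fledge_age
    for year in config.years:
        for b in range(1, config.n_broods[year] + 1):
            brood = f"B{year}-{b:03d}"
            plot = "North" if b % 2 else "South"
            h = float(np.clip(round(rng.normal(config.hatch_mean[year], config.hatch_sd)),
                              config.season_start + 3, latest_hatch))
            for c in range(1, config.chicks_per_brood + 1):
                cid = f"C{year}-{b:03d}-{c}"
                hatch[cid] = (year, h)
                k_indiv[cid] = float(rng.normal(0.0, config.K_indiv_sd))
                chick_rows.append((cid, brood, plot, year, h))
    chicks = pd.DataFrame(chick_rows, columns=["chick_id", "brood_id", "plot", "year", "hatch_doy"])
    if chicks.empty:
        empty = SimTruth(beta=dict(config.beta), covariate_stats={}, growth_K=K0,
                         growth_Ti=Ti0, K_indiv={}, hatch_age={}, death_age={},
                         latent_curve=latent_resource_curves(config),
                         fledged_fraction={y: float("nan") for y in config.years})
        return (pd.DataFrame(columns=["chick_id", "brood_id", "plot", "hatch_date"]),
                pd.DataFrame(columns=["chick_id", "date", "mass_g"]),
                pd.DataFrame(columns=["chick_id", "date", "status"]), empty)

    grid = _covariate_grid(config, series, hatch)
    stats = {}
    z = {}
    for name in SURVIVAL_COVARIATES:
        x = grid[name].to_numpy(float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            sd = 1.0
        stats[name] = (mu, sd)
        z[name] = (x - mu) / (2.0 * sd)
    beta = config.beta
    eta = (beta["intercept"] + beta["biomass"] * z["biomass"] + beta["bodymass"] * z["bodymass"]
           + beta["hatch"] * z["hatch"] + beta["age"] * z["age"]
           + beta["age_x_bodymass"] * z["age"] * z["bodymass"])
    grid = grid.assign(surv_prob=1.0 / (1.0 + np.exp(-eta)))

    death_age: dict[str, float | None] = {}
    mass_rows, reloc_rows = [], []
    fledged: dict[int, list[bool]] = {y: [] for y in config.years}
    for cid, sub in grid.groupby("chick_id", sort=False):
        year, h = hatch[cid]
        sub = sub.sort_values("age")
        u = rng.random(len(sub))
        died = np.nonzero(u > sub["surv_prob"].to_numpy())[0]
        d_age = int(sub["age"].iloc[died[0]]) if died.size else None
        death_age[cid] = float(d_age) if d_age is not None else None
        fledged[year].append(d_age is None)

        # relocations every relocation_interval days from hatch
        ages = list(range(0, config.fledge_age + 1, config.relocation_interval))
        if ages[-1] != config.fledge_age:
            ages.append(config.fledge_age)
        for a in ages:
            if d_age is not None and a >= d_age:
                reloc_rows.append((cid, year, h + a, "dead"))
                break
            reloc_rows.append((cid, year, h + a, "alive"))

        # mass captures at hatch and every recapture_interval days while alive
        K_i = K0 + k_indiv[cid]
        last = config.fledge_age if d_age is None else d_age - 1
        for a in range(0, config.fledge_age + 1, config.recapture_interval):
            if a > last:
                break
            m = logistic_mass_curve(a, A0, K_i, Ti0) + rng.normal(0.0, config.mass_noise_sd)
            mass_rows.append((cid, year, h + a, a, max(1.0, float(m))))

    masses = pd.DataFrame(mass_rows, columns=["chick_id", "year", "doy", "age", "mass_g"])
    relocs = pd.DataFrame(reloc_rows, columns=["chick_id", "year", "doy", "status"])

    def fmt_dates(df):
        return [(pd.Timestamp(int(y), 1, 1) + pd.Timedelta(days=int(round(d)) - 1)).date().isoformat()
                for y, d in zip(df["year"], df["doy"])]

    chicks_out = pd.DataFrame({
        "chick_id": chicks["chick_id"], "brood_id": chicks["brood_id"], "plot": chicks["plot"],
        "hatch_date": [(pd.Timestamp(int(y), 1, 1) + pd.Timedelta(days=int(h) - 1)).date().isoformat()
                       for y, h in zip(chicks["year"], chicks["hatch_doy"])],
    })
    masses_out = pd.DataFrame({"chick_id": masses["chick_id"], "date": fmt_dates(masses),
                               "mass_g": masses["mass_g"].round(1)})
    relocs_out = pd.DataFrame({"chick_id": relocs["chick_id"], "date": fmt_dates(relocs),
                               "status": relocs["status"]})

    truth = SimTruth(
        beta=dict(beta), covariate_stats=stats, growth_K=K0, growth_Ti=Ti0,
        K_indiv=k_indiv, hatch_age={c: h for c, (_, h) in hatch.items()},
        death_age=death_age, latent_curve=latent_resource_curves(config),
        fledged_fraction={y: (float(np.mean(v)) if v else float("nan"))
                          for y, v in fledged.items()},
    )
    return chicks_out, masses_out, relocs_out, truth


def simulate_study(config: SimConfig):
    """Full draw: invertebrate records, daily series, chick tables, truth."""
    inverts = simulate_resources(config)
    series = res.aggregate_daily(res.filter_potential_prey(inverts))
    chicks, masses, relocs, truth = simulate_chicks(config, series)
    return inverts, series, chicks, masses, relocs, truth


def write_fixture_set(config: SimConfig, outdir) -> dict[str, Path]:
    """Write the four CSVs plus the ground-truth JSON to `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inverts, _, chicks, masses, relocs, truth = simulate_study(config)
    paths = {
        "invertebrates": outdir / "invertebrates.csv",
        "chicks": outdir / "chicks.csv",
        "masses": outdir / "masses.csv",
        "relocations": outdir / "relocations.csv",
        "truth": outdir / "truth.json",
    }
    inverts.to_csv(paths["invertebrates"], index=False)
    chicks.to_csv(paths["chicks"], index=False)
    masses.to_csv(paths["masses"], index=False)
    relocs.to_csv(paths["relocations"], index=False)
    paths["truth"].write_text(truth.to_json())
    return paths
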