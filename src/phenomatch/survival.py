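"""Bayesian hierarchical known-fate survival of radio-tagged chicks.

Daily survival s is logit-linear in time-varying resource covariates
(3-day trailing means of invertebrate biomass and median body mass),
hatch date, age, and an age x prey-size interaction, with random
intercepts for brood, year, and study plot.  Fates are observed only at
relocation intervals, so an interval that ends in death contributes
1 - prod(s_d) over its days, while a survived (or right-censored) interval
contributes prod(s_d).  All covariates enter on the Gelman two-SD
standardized scale; coefficients are reported in logit form.

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme:
a joint adaptive proposal for the coefficient block, vectorised
single-site updates for the random intercepts, log-scale walks for the
intercept SDs, and Kuo-Mallick indicator flips for variable selection.
Convergence is judged by split-Rhat < 1.1 and effective sample sizes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .resources import rolling_mean

logger = logging.getLogger("phenomatch")

FLEDGE_AGE = 21
MISSING_DEATH_DAYS = 3          # consecutive not-found days treated as death
COVARIATE_WINDOW = 3            # trailing days for resource covariates
RHAT_LIMIT = 1.1

FIXED_EFFECT_NAMES = ("biomass", "bodymass", "hatch", "age",
                      "age_x_bodymass", "age_x_biomass")
RANDOM_FAMILIES = ("brood", "year", "plot")


# ---------------------------------------------------------------------------
# Encounter histories
# ---------------------------------------------------------------------------

@dataclass
class EncounterHistory:
    """One chick's ragged relocation record, cut into fate-coded intervals.

    ``intervals`` has one row per relocation interval with columns
    start_age, end_age, fate ("survived" | "died_within" | "censored"),
    and the interval covariates biomass, bodymass (3-day trailing means at
    the interval end), hatch (day-of-year) and age (interval midpoint).
    """
    chick_id: str
    brood_id: str
    year: int
    plot: str
    hatch_doy: float
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv):
            if (iv["start_age"] < 0).any() or (iv["end_age"] > FLEDGE_AGE).any():
                raise ValueError(f"{self.chick_id}: interval ages outside [0, {FLEDGE_AGE}]")
            died = np.nonzero((iv["fate"] == "died_within").to_numpy())[0]
            if died.size > 1 or (died.size == 1 and died[0] != len(iv) - 1):
                raise ValueError(f"{self.chick_id}: death must be the single final interval")


def _doy(date_str: str) -> tuple[int, int]:
    ts = pd.Timestamp(date_str)
    return ts.year, ts.dayofyear


def build_encounter_histories(chicks: pd.DataFrame, relocations: pd.DataFrame,
                              series: pd.DataFrame, fledge_age: int = FLEDGE_AGE,
                              missing_death_days: int = MISSING_DEATH_DAYS,
                              ) -> list[EncounterHistory]:
    """Cut relocation records into fate-coded intervals with covariates.

    Death is assigned either at a confirmed "dead" relocation or after
    `missing_death_days` consecutive not-found days; survival past
    `fledge_age` right-censors the chick as fledged.  Chicks flagged in an
    ``exclude`` column (human-caused mortality, day-0 radio loss) are
    dropped with a log entry.  Relocations before hatch or for unknown
    chicks raise.
    """
    known = set(chicks["chick_id"])
    unknown = set(relocations["chick_id"]) - known
    if unknown:
        raise ValueError(f"relocations reference unknown chicks: {sorted(unknown)[:5]}")

    histories: list[EncounterHistory] = []
    n_excluded = 0
    for _, chick in chicks.iterrows():
        cid = chick["chick_id"]
        if "exclude" in chick.index and isinstance(chick["exclude"], str) and chick["exclude"]:
            logger.info("build_encounter_histories: excluding %s (%s)", cid, chick["exclude"])
            n_excluded += 1
            continue
        year, hatch = _doy(chick["hatch_date"])
        rel = relocations[relocations["chick_id"] == cid].copy()
        if rel.empty:
            continue
        rel["age"] = [pd.Timestamp(d).dayofyear - hatch for d in rel["date"]]
        if (rel["age"] < 0).any():
            raise ValueError(f"{cid}: relocation before hatch date")
        rel = rel.sort_values("age")

        bounds: list[tuple[float, float, str]] = []
        last_alive = 0.0
        missing_run: list[float] = []
        done = False
        for _, r in rel.iterrows():
            a, status = float(r["age"]), str(r["status"])
            if a == 0.0 and status == "alive":
                continue
            if status == "alive":
                missing_run.clear()
                end = min(a, float(fledge_age))
                if end > last_alive:
                    bounds.append((last_alive, end, "survived"))
                    last_alive = end
                if last_alive >= fledge_age:
                    done = True
                    break
            elif status == "dead":
                bounds.append((last_alive, min(a, float(fledge_age)), "died_within"))
                done = True
                break
            elif status == "missing":
                if missing_run and a - missing_run[-1] > 1.0:
                    missing_run.clear()
                missing_run.append(a)
                if len(missing_run) >= missing_death_days:
                    bounds.append((last_alive, min(a, float(fledge_age)), "died_within"))
                    done = True
                    break
            else:
                raise ValueError(f"{cid}: unknown relocation status {status!r}")
        if not bounds:
            continue
        if bounds[-1][2] == "survived" and bounds[-1][1] >= fledge_age:
            s, e, _ = bounds[-1]
            bounds[-1] = (s, e, "censored")

        rows = []
        for s, e, fate in bounds:
            day_end = int(round(hatch + e))
            bm = rolling_mean(series[series["year"] == year], "biomass_mg",
                              year, COVARIATE_WINDOW, day_end)
            pm = rolling_mean(series[series["year"] == year], "median_bodymass_mg",
                              year, COVARIATE_WINDOW, day_end)
            if not (np.isfinite(bm) and np.isfinite(pm)):
                raise ValueError(f"{cid}: resource covariates missing around day {day_end}")
            rows.append({"start_age": s, "end_age": e, "fate": fate,
                         "biomass": bm, "bodymass": pm,
                         "hatch": float(hatch), "age": 0.5 * (s + e)})
        histories.append(EncounterHistory(
            chick_id=str(cid), brood_id=str(chick["brood_id"]), year=int(year),
            plot=str(chick.get("plot", "NA")), hatch_doy=float(hatch),
            intervals=pd.DataFrame(rows),
        ))
    logger.info("build_encounter_histories: %d histories (%d chicks excluded)",
                len(histories), n_excluded)
    return histories


def interval_log_likelihood(history: EncounterHistory, daily_survival_probs) -> float:
    """Known-fate log-likelihood of one history given per-day survival probs.

    `daily_survival_probs` is flat over the history's occupied days
    (interval by interval, one value per day).  Survived and censored
    intervals contribute sum(log s_d); an interval ending in death
    contributes log(1 - prod(s_d)).
    """
    probs = np.asarray(daily_survival_probs, dtype=float)
    if np.any(probs <= 0) or np.any(probs >= 1):
        raise ValueError("daily survival probabilities must lie strictly in (0, 1)")
    total, pos = 0.0, 0
    for _, iv in history.intervals.iterrows():
        n_days = int(round(iv["end_age"] - iv["start_age"]))
        chunk = np.log(probs[pos:pos + n_days])
        if len(chunk) != n_days:
            raise ValueError("daily_survival_probs shorter than occupied days")
        pos += n_days
        s = chunk.sum()
        total += float(np.log(-np.expm1(s))) if iv["fate"] == "died_within" else float(s)
    return total


# ---------------------------------------------------------------------------
# Model specification and flattened design
# ---------------------------------------------------------------------------

@dataclass
class SurvivalModelSpec:
    fixed_effects: tuple[str, ...] = ("biomass", "bodymass", "hatch", "age", "age_x_bodymass")
    random_intercepts: tuple[str, ...] = ("brood", "year", "plot")
    indicators: tuple[str, ...] = ()       # effects under Kuo-Mallick selection
    prior_sd_beta: float = 10.0            # N(0, tau) on standardized logit scale
    prior_sd_intercept: float = 10.0
    sigma_upper: float = 25.0              # Uniform(0, 25) on intercept SDs
    estimate_group_mean: bool = False      # family means fixed at 0 by default

    def __post_init__(self) -> None:
        for name in self.fixed_effects:
            if name not in FIXED_EFFECT_NAMES:
                raise ValueError(f"unknown fixed effect {name!r}")
        for name in self.random_intercepts:
            if name not in RANDOM_FAMILIES:
                raise ValueError(f"unknown random family {name!r}")
        for inter, main in (("age_x_bodymass", "bodymass"), ("age_x_biomass", "biomass")):
            if inter in self.fixed_effects:
                if main not in self.fixed_effects or "age" not in self.fixed_effects:
                    raise ValueError(f"{inter} requires both main effects in the model")
        if set(self.indicators) - set(self.fixed_effects):
            raise ValueError("indicators must be a subset of fixed_effects")


@dataclass
class MCMCSettings:
    chains: int = 3
    iterations: int = 5000      # total per chain, including adaptation + burn-in
    adapt: int = 600
    burn_in: int = 1000
    thin: int = 3               # keep every 3rd post-burn-in draw
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.iterations - self.adapt - self.burn_in) // self.thin <= 0:
            raise ValueError("no retained samples after adaptation/burn-in/thinning")


class _Design:
    """Day-level design flattened across all histories."""

    def __init__(self, histories: list[EncounterHistory], spec: SurvivalModelSpec,
                 stats: dict[str, tuple[float, float]] | None = None):
        iv_rows, day_counts = [], []
        for h in histories:
            for _, iv in h.intervals.iterrows():
                n_days = int(round(iv["end_age"] - iv["start_age"]))
                if n_days <= 0:
                    continue
                iv_rows.append({"chick": h.chick_id, "brood": h.brood_id,
                                "year": h.year, "plot": h.plot, "fate": iv["fate"],
                                "biomass": iv["biomass"], "bodymass": iv["bodymass"],
                                "hatch": iv["hatch"], "age": iv["age"]})
                day_counts.append(n_days)
        if not iv_rows:
            raise ValueError("no usable intervals")
        iv_df = pd.DataFrame(iv_rows)
        n_days_arr = np.asarray(day_counts)
        self.intervals = iv_df
        self.n_int = len(iv_df)
        self.seg = np.repeat(np.arange(self.n_int), n_days_arr)
        self.n_days = int(n_days_arr.sum())
        self.died = (iv_df["fate"] == "died_within").to_numpy()

        # Gelman two-SD standardization on the day-expanded scale
        if stats is None:
            stats = {}
            for name in ("biomass", "bodymass", "hatch", "age"):
                x = np.repeat(iv_df[name].to_numpy(float), n_days_arr)
                sd = x.std(ddof=1)
                stats[name] = (float(x.mean()), float(sd if sd > 0 else 1.0))
        self.stats = stats
        z = {name: (iv_df[name].to_numpy(float) - mu) / (2.0 * sd)
             for name, (mu, sd) in stats.items()}
        cols = {"intercept": np.ones(self.n_int)}
        for name in spec.fixed_effects:
            if name == "age_x_bodymass":
                cols[name] = z["age"] * z["bodymass"]
            elif name == "age_x_biomass":
                cols[name] = z["age"] * z["biomass"]
            else:
                cols[name] = z[name]
        self.names = list(cols)
        X_int = np.column_stack(list(cols.values()))
        self.X = X_int[self.seg]                    # day-level design
        self.p = self.X.shape[1]

        # random-effect bookkeeping: group index per interval and per day
        self.families = list(spec.random_intercepts)
        self.group_idx: dict[str, np.ndarray] = {}
        self.group_levels: dict[str, list] = {}
        for fam in self.families:
            codes, levels = pd.factorize(iv_df[fam])
            self.group_idx[fam] = codes
            self.group_levels[fam] = list(levels)
        years_int = iv_df["year"].to_numpy()
        self.year_levels = sorted(set(int(y) for y in years_int))
        ymap = {y: i for i, y in enumerate(self.year_levels)}
        self.year_of_day = np.array([ymap[int(y)] for y in years_int])[self.seg]
        self.days_per_year = np.bincount(self.year_of_day, minlength=len(self.year_levels))
        self.data_hash = hashlib.sha256(
            pd.util.hash_pandas_object(iv_df, index=False).values.tobytes()
        ).hexdigest()[:16]

    def interval_loglik(self, eta_day: np.ndarray) -> np.ndarray:
        """Per-interval log-likelihood from a day-level linear predictor."""
        log_s = -np.logaddexp(0.0, -eta_day)
        sums = np.bincount(self.seg, weights=log_s, minlength=self.n_int)
        out = np.where(self.died, np.log(-np.expm1(np.minimum(sums, -1e-12))), sums)
        return out


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    summary: pd.DataFrame                       # per parameter posterior summary
    draws: dict[str, np.ndarray]                # name -> (chains, kept)
    pointwise: np.ndarray                       # (total kept, n_int) log-likelihood
    waic: float
    waic_se: float
    p_waic: float
    inclusion: dict[str, float]                 # posterior inclusion probabilities
    annual_dsr_draws: pd.DataFrame              # (total kept, year) mean daily survival
    converged: bool
    data_hash: str
    settings: MCMCSettings
    spec: SurvivalModelSpec
    stats: dict[str, tuple[float, float]]
    design: "_Design" = field(repr=False, default=None)

    def coefficient(self, name: str) -> pd.Series:
        return self.summary.loc[name]


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin statistic on split chains; chains is (n_chains, n_draws)."""
    m, n = chains.shape
    if n < 4:
        return float("nan")
    half = n // 2
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    means = splits.mean(1)
    W = splits.var(1, ddof=1).mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((half - 1) / half + B / (W * half)))


def _ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    m, n = chains.shape
    x = chains - chains.mean(1, keepdims=True)
    var = x.var(1, ddof=0).mean()
    if var == 0 or n < 8:
        return float(m * n)
    max_lag = min(n - 2, 200)
    rho = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        rho[lag - 1] = np.mean([np.dot(xi[:-lag], xi[lag:]) / n for xi in x]) / var
    tau = 1.0
    for k in range(0, max_lag - 1, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
    return float(m * n / tau)


def fit_survival_mcmc(histories: list[EncounterHistory],
                      spec: SurvivalModelSpec | None = None,
                      settings: MCMCSettings | None = None,
                      stats: dict[str, tuple[float, float]] | None = None,
                      store_pointwise: bool = True) -> SurvivalFit:
    """Sample the posterior of the daily-survival model.

    `stats` optionally supplies externally computed standardization
    constants (mean, SD per raw covariate); by default they are computed
    from the day-expanded data.  Non-convergence (any split-Rhat >= 1.1)
    flags the result but still returns it.
    """
    spec = spec or SurvivalModelSpec()
    settings = settings or MCMCSettings()
    design = _Design(histories, spec, stats)
    X, p = design.X, design.p
    names = design.names
    sel = np.array([nm in spec.indicators for nm in names])
    prior_sd = np.full(p, spec.prior_sd_beta)
    prior_sd[0] = spec.prior_sd_intercept

    kept_per_chain = (settings.iterations - settings.adapt - settings.burn_in) // settings.thin
    warm = settings.adapt + settings.burn_in
    n_fam = len(design.families)

    beta_draws = np.empty((settings.chains, kept_per_chain, p))
    gamma_draws = np.empty((settings.chains, kept_per_chain, p))
    sigma_draws = np.empty((settings.chains, kept_per_chain, n_fam))
    pw = (np.empty((settings.chains, kept_per_chain, design.n_int))
          if store_pointwise else None)
    syear = np.empty((settings.chains, kept_per_chain, len(design.year_levels)))

    # crude empirical daily survival for initialising the intercept
    surv_days = design.n_days - design.died.sum()
    s0 = np.clip(surv_days / design.n_days, 0.05, 0.995)
    logit_s0 = float(np.log(s0 / (1 - s0)))

    for chain in range(settings.chains):
        rng = np.random.default_rng([settings.seed, chain])
        beta = np.zeros(p)
        beta[0] = logit_s0 + 0.3 * rng.normal()
        gamma = np.ones(p)
        u = {f: 0.01 * rng.normal(size=len(design.group_levels[f]))
             for f in design.families}
        sigma = {f: 1.0 for f in design.families}
        g_day = {f: design.group_idx[f][design.seg] for f in design.families}

        def eta_from_state(b=None):
            b = beta if b is None else b
            e = X @ (b * gamma)
            for f in design.families:
                e = e + u[f][g_day[f]]
            return e

        eta = eta_from_state()
        ll_int = design.interval_loglik(eta)
        ll = ll_int.sum()

        # adaptive block proposal for beta
        cov_scale = 2.38**2 / p
        prop_chol = np.eye(p) * 0.1
        hist_mean = beta.copy()
        hist_cov = np.eye(p) * 0.01
        step_u = {f: 0.5 for f in design.families}
        step_s = {f: 0.5 for f in design.families}

        kept = 0
        for it in range(settings.iterations):
            # --- coefficient block ---
            prop = beta + prop_chol @ rng.normal(size=p)
            eta_p = eta_from_state(prop)
            ll_int_p = design.interval_loglik(eta_p)
            ll_p = ll_int_p.sum()
            dprior = -0.5 * np.sum((prop / prior_sd) ** 2) + 0.5 * np.sum((beta / prior_sd) ** 2)
            if np.log(rng.random()) < ll_p - ll + dprior:
                beta, eta, ll_int, ll = prop, eta_p, ll_int_p, ll_p

            # --- indicator flips (Kuo-Mallick) + prior refresh of excluded betas ---
            if sel.any():
                for k in np.nonzero(sel)[0]:
                    g_new = 1.0 - gamma[k]
                    delta = (g_new - gamma[k]) * beta[k] * X[:, k]
                    eta_p = eta + delta
                    ll_int_p = design.interval_loglik(eta_p)
                    ll_p = ll_int_p.sum()
                    if np.log(rng.random()) < ll_p - ll:
                        gamma[k], eta, ll_int, ll = g_new, eta_p, ll_int_p, ll_p
                    if gamma[k] == 0.0:
                        beta[k] = prior_sd[k] * rng.normal()   # exact Gibbs from prior
                # forced heredity: interaction on -> mains on
                for inter, mains in (("age_x_bodymass", ("age", "bodymass")),
                                     ("age_x_biomass", ("age", "biomass"))):
                    if inter in names and gamma[names.index(inter)] == 1.0:
                        changed = False
                        for mnm in mains:
                            kk = names.index(mnm)
                            if gamma[kk] == 0.0:
                                gamma[kk] = 1.0
                                changed = True
                        if changed:
                            eta = eta_from_state()
                            ll_int = design.interval_loglik(eta)
                            ll = ll_int.sum()

            # --- random intercepts: vectorised single-site updates per family ---
            for f in design.families:
                ng = len(u[f])
                prop_u = u[f] + step_u[f] * rng.normal(size=ng)
                delta = (prop_u - u[f])[g_day[f]]
                ll_int_p = design.interval_loglik(eta + delta)
                by_g = design.group_idx[f]
                d_ll = (np.bincount(by_g, weights=ll_int_p, minlength=ng)
                        - np.bincount(by_g, weights=ll_int, minlength=ng))
                d_pr = (u[f] ** 2 - prop_u**2) / (2 * sigma[f] ** 2)
                acc = np.log(rng.random(ng)) < d_ll + d_pr
                if acc.any():
                    new_u = np.where(acc, prop_u, u[f])
                    eta = eta + (new_u - u[f])[g_day[f]]
                    u[f] = new_u
                    ll_int = design.interval_loglik(eta)
                    ll = float(ll_int.sum())
                if it < warm:
                    step_u[f] *= np.exp(0.05 * (acc.mean() - 0.44))

                # sum-to-zero sweep: move the family mean into the intercept
                # so the global level stays identified (2-level families
                # otherwise trade freely against the intercept)
                m_f = u[f].mean()
                if m_f != 0.0:
                    u[f] = u[f] - m_f
                    beta[0] += m_f

                # --- intercept SD: log-scale walk under Uniform(0, upper) ---
                ls = np.log(sigma[f]) + step_s[f] * rng.normal()
                s_new = np.exp(ls)
                if s_new < spec.sigma_upper:
                    d = (-0.5 * np.sum(u[f] ** 2) * (1 / s_new**2 - 1 / sigma[f] ** 2)
                         - ng * (np.log(s_new) - np.log(sigma[f]))
                         + (np.log(s_new) - np.log(sigma[f])))   # Jacobian of log walk
                    if np.log(rng.random()) < d:
                        sigma[f] = s_new
                        if it < warm:
                            step_s[f] *= np.exp(0.05 * (1 - 0.44))
                    elif it < warm:
                        step_s[f] *= np.exp(0.05 * (0 - 0.44))

            # --- proposal adaptation (frozen after warm-up) ---
            if it < warm:
                w = 1.0 / (it + 2)
                diff = beta - hist_mean
                hist_mean = hist_mean + w * diff
                hist_cov = (1 - w) * hist_cov + w * np.outer(diff, diff)
                if it >= 50 and it % 25 == 0:
                    try:
                        prop_chol = np.linalg.cholesky(
                            cov_scale * (hist_cov + 1e-8 * np.eye(p)))
                    except np.linalg.LinAlgError:
                        pass
            elif (it - warm) % settings.thin == settings.thin - 1 and kept < kept_per_chain:
                beta_draws[chain, kept] = beta
                gamma_draws[chain, kept] = gamma
                sigma_draws[chain, kept] = [sigma[f] for f in design.families]
                s_day = 1.0 / (1.0 + np.exp(-eta))
                syear[chain, kept] = (np.bincount(design.year_of_day, weights=s_day,
                                                  minlength=len(design.year_levels))
                                      / design.days_per_year)
                if pw is not None:
                    pw[chain, kept] = ll_int
                kept += 1

    # --- summaries ---
    rows = []
    inclusion: dict[str, float] = {}
    all_draws: dict[str, np.ndarray] = {}
    for j, nm in enumerate(names):
        ch = beta_draws[:, :, j]
        flat = ch.ravel()
        p_pos = float(np.mean(flat > 0))
        rows.append({
            "parameter": nm, "mean": flat.mean(), "sd": flat.std(ddof=1),
            "ci95_low": np.quantile(flat, 0.025), "ci95_high": np.quantile(flat, 0.975),
            "rhat": _split_rhat(ch), "ess": _ess(ch),
            "bayes_p": 1.0 - 2.0 * min(p_pos, 1.0 - p_pos),
        })
        all_draws[nm] = ch
        if sel[j]:
            inclusion[nm] = float(gamma_draws[:, :, j].mean())
    for i, f in enumerate(design.families):
        ch = sigma_draws[:, :, i]
        flat = ch.ravel()
        rows.append({"parameter": f"sigma_{f}", "mean": flat.mean(), "sd": flat.std(ddof=1),
                     "ci95_low": np.quantile(flat, 0.025), "ci95_high": np.quantile(flat, 0.975),
                     "rhat": _split_rhat(ch), "ess": _ess(ch), "bayes_p": float("nan")})
        all_draws[f"sigma_{f}"] = ch
    summary = pd.DataFrame(rows).set_index("parameter")
    converged = bool(np.all(summary["rhat"].dropna() < RHAT_LIMIT))
    if not converged:
        logger.warning("fit_survival_mcmc: split-Rhat >= %.2f for %s",
                       RHAT_LIMIT, list(summary.index[summary["rhat"] >= RHAT_LIMIT]))

    if pw is not None:
        pw_flat = pw.reshape(-1, design.n_int)
        waic, waic_se, p_waic = waic_from_pointwise(pw_flat)
    else:
        pw_flat, waic, waic_se, p_waic = np.empty((0, design.n_int)), np.nan, np.nan, np.nan

    annual_dsr = pd.DataFrame(syear.reshape(-1, len(design.year_levels)),
                              columns=design.year_levels)
    return SurvivalFit(summary=summary, draws=all_draws, pointwise=pw_flat,
                       waic=waic, waic_se=waic_se, p_waic=p_waic,
                       inclusion=inclusion, annual_dsr_draws=annual_dsr,
                       converged=converged,
                       data_hash=design.data_hash, settings=settings, spec=spec,
                       stats=design.stats, design=design)


# ---------------------------------------------------------------------------
# WAIC and model selection
# ---------------------------------------------------------------------------

def waic_from_pointwise(pointwise: np.ndarray) -> tuple[float, float, float]:
    """WAIC = -2 (lppd - p_waic) from a (draws, observations) log-lik matrix."""
    if pointwise.size == 0:
        return float("nan"), float("nan"), float("nan")
    m = pointwise.max(0)
    lppd_i = m + np.log(np.mean(np.exp(pointwise - m), axis=0))
    p_i = pointwise.var(0, ddof=1)
    elpd_i = lppd_i - p_i
    waic = float(-2.0 * elpd_i.sum())
    se = float(2.0 * np.sqrt(len(elpd_i) * elpd_i.var(ddof=1)))
    return waic, se, float(p_i.sum())


def compare_waic(fit_a: SurvivalFit, fit_b: SurvivalFit) -> pd.DataFrame:
    """WAIC table for two fits of the same data; the lower WAIC wins."""
    if fit_a.data_hash != fit_b.data_hash:
        raise ValueError("fits were not computed on the same data")
    rows = [{"model": "A", "waic": fit_a.waic, "se": fit_a.waic_se, "p_waic": fit_a.p_waic},
            {"model": "B", "waic": fit_b.waic, "se": fit_b.waic_se, "p_waic": fit_b.p_waic}]
    table = pd.DataFrame(rows)
    table["delta"] = table["waic"] - table["waic"].min()
    table.attrs["winner"] = "A" if fit_a.waic <= fit_b.waic else "B"
    return table


def indicator_selection(histories: list[EncounterHistory],
                        spec: SurvivalModelSpec | None = None,
                        settings: MCMCSettings | None = None,
                        threshold: float = 0.5,
                        stats: dict[str, tuple[float, float]] | None = None,
                        ) -> tuple[dict[str, float], SurvivalModelSpec, SurvivalFit]:
    """Kuo-Mallick selection over the full model's fixed effects.

    Every non-intercept effect gets a Bernoulli(0.5) inclusion indicator;
    the posterior mean of each indicator is its inclusion probability.
    Effects above `threshold` form the selected model, with main effects
    forced in whenever their interaction is selected.
    """
    spec = spec or SurvivalModelSpec()
    if not spec.indicators:
        spec = replace(spec, indicators=tuple(spec.fixed_effects))
    fit = fit_survival_mcmc(histories, spec, settings, stats=stats)
    keep = {nm for nm, pr in fit.inclusion.items() if pr > threshold}
    for inter, mains in (("age_x_bodymass", ("age", "bodymass")),
                         ("age_x_biomass", ("age", "biomass"))):
        if inter in keep:
            keep.update(mains)
    selected = replace(spec, fixed_effects=tuple(nm for nm in spec.fixed_effects if nm in keep),
                       indicators=())
    return fit.inclusion, selected, fit


# ---------------------------------------------------------------------------
# Extrapolation to fledging
# ---------------------------------------------------------------------------

def dsr_to_fledging(daily_survival: float, se: float,
                    fledge_age: int = FLEDGE_AGE) -> tuple[float, float]:
    """First-order delta method for F = s**21 and its standard error."""
    if not 0 < daily_survival <= 1:
        raise ValueError("daily survival must lie in (0, 1]")
    if se < 0:
        raise ValueError("se must be non-negative")
    f = daily_survival**fledge_age
    f_se = fledge_age * daily_survival ** (fledge_age - 1) * se
    return float(f), float(f_se)


def annual_fledging(fit: SurvivalFit, fledge_age: int = FLEDGE_AGE) -> pd.DataFrame:
    """Per-year fledging probability from posterior mean daily survival.

    Uses each year's posterior distribution of mean daily survival (averaged
    over that year's observed chick-days at the sampled coefficient and
    random-intercept values, so group effects are marginalized) and
    extrapolates to fledging with the delta method.  Returns columns
    [year, dsr, dsr_se, fledging, fledging_se].
    """
    rows = []
    for year in fit.annual_dsr_draws.columns:
        s_year = fit.annual_dsr_draws[year].to_numpy()
        dsr, dsr_se = float(s_year.mean()), float(s_year.std(ddof=1))
        f, f_se = dsr_to_fledging(dsr, dsr_se, fledge_age)
        rows.append({"year": int(year), "dsr": dsr, "dsr_se": dsr_se,
                     "fledging": f, "fledging_se": f_se})
    return pd.DataFrame(rows)
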