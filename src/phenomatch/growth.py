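"""Chick growth: fixed-asymptote logistic curves, model selection, and body condition.

Mass at age a follows A0 / (1 + exp(-K (a - Ti))) with the asymptote A0
fixed at the mean adult mass (249 g by default); the growth coefficient K
carries an individual random intercept (absorbing unmeasured sex and other
among-chick variation), and both K and the inflection age Ti may be constant
or year-specific — four candidate structures, ranked by conditional AIC.

The body condition index (BCI) of a recapture interval is observed mass gain
divided by the gain the top growth curve predicts over the same ages; BCI is
then modelled against resource abundance/quality and hatch date with a
penalized-spline age term.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .resources import rolling_mean

logger = logging.getLogger("phenomatch")

DEFAULT_A0 = 249.0      # g, mean adult mass (both sexes pooled)
CAIC_CANDIDATE_DELTA = 4.0
COLLINEARITY_R = 0.7

STRUCTURES = (("constant", "constant"), ("constant", "annual"),
              ("annual", "constant"), ("annual", "annual"))


def logistic_mass(age, A0: float = DEFAULT_A0, K: float = 0.18, Ti: float = 12.0):
    """Logistic growth curve: mass (g) at `age` days; inflection at Ti with mass A0/2."""
    age = np.asarray(age, dtype=float)
    if np.any(age < 0):
        raise ValueError("age must be >= 0")
    out = A0 / (1.0 + np.exp(-K * (age - Ti)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Nonlinear mixed-effects fitting (Laplace marginal likelihood)
# ---------------------------------------------------------------------------

@dataclass
class GrowthFit:
    """One fitted candidate structure."""
    K_structure: str                 # "constant" | "annual"
    Ti_structure: str
    A0: float
    K_year: dict[int, float]         # year -> K (identical values when constant)
    Ti_year: dict[int, float]
    K_indiv: dict[str, float]        # chick -> BLUP deviation on K
    sigma: float                     # residual SD, g
    sigma_b: float                   # among-chick SD of K, 1/day
    loglik: float                    # Laplace marginal log-likelihood
    cond_loglik: float
    edf: float                       # fixed params + shrinkage df of random K
    caic: float
    converged: bool
    delta_caic: float = float("nan")
    is_candidate: bool = False

    @property
    def K_mean(self) -> float:
        return float(np.mean(list(self.K_year.values())))

    @property
    def Ti_mean(self) -> float:
        return float(np.mean(list(self.Ti_year.values())))

    def predict_mass(self, age, year: int | None = None, chick_id: str | None = None):
        years = sorted(self.K_year)
        y = year if year in self.K_year else years[0]
        K = self.K_year[y] + (self.K_indiv.get(chick_id, 0.0) if chick_id else 0.0)
        return logistic_mass(age, self.A0, K, self.Ti_year[y])


class _Packed:
    """Ragged capture data padded to a rectangle for vectorised inner Newton."""

    def __init__(self, captures: pd.DataFrame):
        self.chicks = captures["chick_id"].unique().tolist()
        self.years = sorted(captures["year"].unique())
        n = len(self.chicks)
        m = int(captures.groupby("chick_id").size().max())
        self.age = np.zeros((n, m))
        self.mass = np.zeros((n, m))
        self.mask = np.zeros((n, m), dtype=bool)
        self.year_idx = np.zeros(n, dtype=int)
        ymap = {y: i for i, y in enumerate(self.years)}
        for i, (cid, sub) in enumerate(captures.groupby("chick_id", sort=False)):
            k = len(sub)
            self.age[i, :k] = sub["age"].to_numpy(float)
            self.mass[i, :k] = sub["mass_g"].to_numpy(float)
            self.mask[i, :k] = True
            self.year_idx[i] = ymap[int(sub["year"].iloc[0])]
        self.n_obs = int(self.mask.sum())


def _laplace_loglik(packed: _Packed, A0, Kv, Tiv, sigma, sigma_b, newton_iters=25):
    """Laplace-approximate marginal log-likelihood plus per-chick K BLUPs.

    Inner step: 1-D Gauss-Newton for each chick's K deviation b_i, run
    vectorised across chicks.  Returns (marginal ll, conditional ll, b_hat,
    per-chick GN information J_i used for the shrinkage df).
    """
    K = Kv[packed.year_idx][:, None]
    Ti = Tiv[packed.year_idx][:, None]
    a, mvals, mask = packed.age, packed.mass, packed.mask
    s2, sb2 = sigma**2, max(sigma_b, 1e-8) ** 2
    b = np.zeros(len(packed.chicks))
    for _ in range(newton_iters):
        u = (K + b[:, None]) * (a - Ti)
        p = 1.0 / (1.0 + np.exp(-u))
        f = A0 * p
        fb = A0 * p * (1 - p) * (a - Ti)          # df/db
        r = np.where(mask, mvals - f, 0.0)
        fb = np.where(mask, fb, 0.0)
        grad = -(r * fb).sum(1) / s2 + b / sb2
        hess = (fb * fb).sum(1) / s2 + 1.0 / sb2
        step = grad / hess
        step = np.clip(step, -0.05, 0.05)          # K is O(0.1): keep Newton tame
        b = b - step
        if np.max(np.abs(step)) < 1e-12:
            break
    u = (K + b[:, None]) * (a - Ti)
    p = 1.0 / (1.0 + np.exp(-u))
    f = A0 * p
    fb = np.where(mask, A0 * p * (1 - p) * (a - Ti), 0.0)
    r = np.where(mask, mvals - f, 0.0)
    rss_i = (r * r).sum(1)
    J = (fb * fb).sum(1) / s2                      # GN information about b_i
    g = rss_i / (2 * s2) + b**2 / (2 * sb2)
    gpp = J + 1.0 / sb2
    cond_ll = -0.5 * packed.n_obs * np.log(2 * np.pi * s2) - rss_i.sum() / (2 * s2)
    # marginal = data term at the mode, plus the Gaussian prior on b and the
    # Laplace curvature correction -0.5 log(sigma_b^2 g'')
    marg_ll = (cond_ll - (b**2).sum() / (2 * sb2)
               - 0.5 * np.sum(np.log(sb2 * gpp)))
    return marg_ll, cond_ll, b, J


def _fit_one_structure(packed: _Packed, K_structure: str, Ti_structure: str, A0: float,
                       start_K: float, start_Ti: float, n_restarts: int,
                       rng: np.random.Generator) -> GrowthFit | None:
    ny = len(packed.years)
    nK = ny if K_structure == "annual" else 1
    nT = ny if Ti_structure == "annual" else 1

    def unpack(theta):
        Kv = theta[:nK] if nK > 1 else np.full(ny, theta[0])
        Tiv = theta[nK:nK + nT] if nT > 1 else np.full(ny, theta[nK])
        sigma, sigma_b = np.exp(theta[nK + nT]), np.exp(theta[nK + nT + 1])
        return np.asarray(Kv, float), np.asarray(Tiv, float), sigma, sigma_b

    def nll(theta):
        Kv, Tiv, sigma, sigma_b = unpack(theta)
        if np.any(Kv <= 0) or np.any(Tiv <= 0) or sigma > 1e3 or sigma_b > 10:
            return 1e10
        ll, *_ = _laplace_loglik(packed, A0, Kv, Tiv, sigma, sigma_b)
        return -ll if np.isfinite(ll) else 1e10

    base = np.concatenate([np.full(nK, start_K), np.full(nT, start_Ti),
                           [np.log(5.0), np.log(0.02)]])
    best = None
    for it in range(max(1, n_restarts)):
        x0 = base.copy()
        if it > 0:  # jittered restart
            x0[:nK] *= rng.uniform(0.7, 1.3, nK)
            x0[nK:nK + nT] *= rng.uniform(0.8, 1.2, nT)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sol = optimize.minimize(nll, x0, method="Nelder-Mead",
                                        options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9})
        except Exception:   # noqa: BLE001 - any numerical failure counts as non-convergence
            continue
        if best is None or sol.fun < best.fun:
            best = sol
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        return None

    Kv, Tiv, sigma, sigma_b = unpack(best.x)
    ll, cll, b_hat, J = _laplace_loglik(packed, A0, Kv, Tiv, sigma, sigma_b)
    shrink_df = float(np.sum(J / (J + 1.0 / max(sigma_b, 1e-8) ** 2)))
    p_fixed = nK + nT
    edf = p_fixed + shrink_df
    caic = -2.0 * cll + 2.0 * (edf + 1.0)   # +1 for the residual SD
    return GrowthFit(
        K_structure=K_structure, Ti_structure=Ti_structure, A0=A0,
        K_year={y: float(Kv[i]) for i, y in enumerate(packed.years)},
        Ti_year={y: float(Tiv[i]) for i, y in enumerate(packed.years)},
        K_indiv={c: float(b_hat[i]) for i, c in enumerate(packed.chicks)},
        sigma=float(sigma), sigma_b=float(sigma_b),
        loglik=float(ll), cond_loglik=float(cll), edf=float(edf), caic=float(caic),
        converged=bool(best.success or best.fun < 1e9),
    )


def fit_growth_models(captures: pd.DataFrame, A0: float = DEFAULT_A0,
                      start_K: float = 0.18, start_Ti: float = 12.0,
                      n_restarts: int = 4, max_restarts: int = 100,
                      structures=STRUCTURES, seed: int = 0) -> list[GrowthFit]:
    """Fit the four candidate logistic structures and rank them by cAIC.

    `captures` needs columns chick_id, year, age, mass_g.  Each structure is
    fitted by Laplace-approximate maximum likelihood with multi-start
    Nelder-Mead (up to `max_restarts` jittered restarts; `n_restarts` by
    default).  Candidates within ΔcAIC < 4 of the best are flagged.
    Non-converging structures are dropped with a warning; if all fail an
    error is raised.
    """
    if captures.empty or captures.groupby("chick_id").size().max() < 2:
        raise ValueError("need chicks with >=2 captures to fit growth")
    rng = np.random.default_rng(seed)
    packed = _Packed(captures)
    fits = []
    for Ks, Tis in structures:
        fit = _fit_one_structure(packed, Ks, Tis, A0, start_K, start_Ti,
                                 min(n_restarts, max_restarts), rng)
        if fit is None:
            logger.warning("growth structure (K=%s, Ti=%s) failed to converge; dropped", Ks, Tis)
            continue
        fits.append(fit)
    if not fits:
        raise RuntimeError("no growth structure converged")
    fits.sort(key=lambda f: f.caic)
    best = fits[0].caic
    for f in fits:
        f.delta_caic = f.caic - best
        f.is_candidate = f.delta_caic < CAIC_CANDIDATE_DELTA
    return fits


def estimate_age_from_mass(mass_g: float, fit: GrowthFit, year: int | None = None) -> float:
    """Invert the year-appropriate growth curve, rounding to the nearest half-day."""
    A0 = fit.A0
    if not 0 < mass_g < A0:
        raise ValueError(f"mass must be in (0, {A0}) g")
    years = sorted(fit.K_year)
    y = year if year in fit.K_year else years[0]
    K, Ti = fit.K_year[y], fit.Ti_year[y]
    age = Ti - np.log(A0 / mass_g - 1.0) / K
    return float(round(age * 2.0) / 2.0)


# ---------------------------------------------------------------------------
# Body condition index
# ---------------------------------------------------------------------------

@dataclass
class BCIRecord:
    chick_id: str
    year: int
    age1: float
    age2: float
    doy2: float              # calendar day of the second capture
    observed_gain_g: float
    predicted_gain_g: float
    bci: float


def compute_bci(captures: pd.DataFrame, fit: GrowthFit) -> list[BCIRecord]:
    """BCI per recapture: observed gain / gain predicted by the top curve.

    Uses the population (year-level) curve, so BCI measures deviation from
    expected growth rather than from the chick's own shrunken trajectory.
    Intervals with non-positive predicted gain are skipped with a warning.
    """
    out: list[BCIRecord] = []
    for cid, sub in captures.groupby("chick_id", sort=False):
        sub = sub.sort_values("age")
        year = int(sub["year"].iloc[0])
        ages = sub["age"].to_numpy(float)
        masses = sub["mass_g"].to_numpy(float)
        doys = sub["doy"].to_numpy(float) if "doy" in sub else np.full(len(sub), np.nan)
        for j in range(1, len(sub)):
            pred = (fit.predict_mass(ages[j], year) - fit.predict_mass(ages[j - 1], year))
            if pred <= 0:
                logger.warning("compute_bci: non-positive predicted gain for %s, interval skipped", cid)
                continue
            obs = masses[j] - masses[j - 1]
            out.append(BCIRecord(chick_id=str(cid), year=year, age1=float(ages[j - 1]),
                                 age2=float(ages[j]), doy2=float(doys[j]),
                                 observed_gain_g=float(obs), predicted_gain_g=float(pred),
                                 bci=float(obs / pred)))
    return out


# ---------------------------------------------------------------------------
# BCI vs resources (penalized-spline additive model)
# ---------------------------------------------------------------------------

@dataclass
class BCIModelResult:
    timescale: int                       # selected trailing window, days
    timescale_table: pd.DataFrame        # window vs AICc
    model_table: pd.DataFrame            # subset models: caic, weight
    coefficients: pd.DataFrame           # averaged (or top-model) coefs with SEs
    top_weight: float
    averaged: bool
    dropped_collinear: list[str] = field(default_factory=list)
    n: int = 0


def _fit_additive(y, X: pd.DataFrame, age: np.ndarray, spline_df: int, alpha=None):
    from statsmodels.gam.api import BSplines, GLMGam
    bs = BSplines(age[:, None], df=[spline_df], degree=[3])
    gam = GLMGam(np.asarray(y, float), exog=X, smoother=bs,
                 alpha=[1.0] if alpha is None else alpha)
    if alpha is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                alpha = gam.select_penweight()[0]     # GCV-chosen smoothing
            except Exception:  # noqa: BLE001
                alpha = [1.0]
        gam = GLMGam(np.asarray(y, float), exog=X, smoother=bs, alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = gam.fit()
    edf = float(np.sum(res.edf))
    n = len(y)
    k = edf + 1.0
    aicc = res.aic + (2.0 * k * (k + 1.0)) / max(n - k - 1.0, 1.0)
    return res, aicc, alpha


def fit_bci_model(bci_records: list[BCIRecord], series: pd.DataFrame,
                  hatch_doy: dict[str, float], spline_df: int = 8,
                  windows: tuple[int, ...] = (1, 3, 7)) -> BCIModelResult:
    """Model BCI against resource abundance/quality, hatch date and an age spline.

    Stage 1 selects the trailing-average timescale of the resource covariates
    (the day-of-recapture value coincides with the 1-day window) by AICc of
    fixed-effects-only additive fits.  Stage 2 fits every subset of the three
    fixed effects (always with the penalized age spline), ranks them, and
    conditionally averages coefficients over the ΔcAIC < 4 set when no model
    holds weight > 0.90.  Covariate pairs with |Pearson r| >= 0.7 are pruned
    (later-listed covariate dropped).
    """
    rows = []
    for rec in bci_records:
        if rec.chick_id not in hatch_doy or not np.isfinite(rec.doy2):
            continue
        rows.append({"bci": rec.bci, "year": rec.year, "doy": rec.doy2,
                     "age": rec.age2, "hatch": hatch_doy[rec.chick_id]})
    df = pd.DataFrame(rows)
    if len(df) < 10:
        raise ValueError("too few BCI records with covariates to model")

    # exclude years lacking recaptures entirely happens upstream (no records);
    # attach windowed resource covariates
    for w in windows:
        df[f"biomass_{w}"] = [rolling_mean(series, "biomass_mg", int(y), w, int(d))
                              for y, d in zip(df["year"], df["doy"])]
        df[f"bodymass_{w}"] = [rolling_mean(series, "median_bodymass_mg", int(y), w, int(d))
                               for y, d in zip(df["year"], df["doy"])]
    df = df.dropna()
    y = df["bci"].to_numpy(float)
    age = df["age"].to_numpy(float)
    sdf = int(min(spline_df, max(4, len(df) // 6)))

    ts_rows = []
    for w in windows:
        X = pd.DataFrame({"const": np.ones(len(df)), "biomass": df[f"biomass_{w}"],
                          "bodymass": df[f"bodymass_{w}"], "hatch": df["hatch"]})
        _, aicc, _ = _fit_additive(y, X, age, sdf)
        ts_rows.append({"window": w, "aicc": aicc})
    ts_table = pd.DataFrame(ts_rows)
    w_best = int(ts_table.loc[ts_table["aicc"].idxmin(), "window"])

    covs = {"biomass": df[f"biomass_{w_best}"].to_numpy(float),
            "bodymass": df[f"bodymass_{w_best}"].to_numpy(float),
            "hatch": df["hatch"].to_numpy(float)}
    # collinearity pruning: drop the later-listed member of any |r| >= 0.7 pair
    dropped = []
    names = list(covs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if a in covs and b in covs and len(set(covs[a])) > 1 and len(set(covs[b])) > 1:
                r = np.corrcoef(covs[a], covs[b])[0, 1]
                if abs(r) >= COLLINEARITY_R:
                    logger.warning("fit_bci_model: |r(%s,%s)|=%.2f >= %.1f, dropping %s",
                                   a, b, abs(r), COLLINEARITY_R, b)
                    covs.pop(b)
                    dropped.append(b)
    names = list(covs)

    model_rows, fits = [], []
    for k in range(len(names) + 1):
        for subset in itertools.combinations(names, k):
            X = pd.DataFrame({"const": np.ones(len(df))})
            for nm in subset:
                X[nm] = covs[nm]
            res, aicc, _ = _fit_additive(y, X, age, sdf)
            model_rows.append({"model": "+".join(subset) or "(intercept)",
                               "subset": subset, "caic": aicc})
            fits.append((subset, res))
    table = pd.DataFrame(model_rows)
    table["delta"] = table["caic"] - table["caic"].min()
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    table = table.sort_values("caic").reset_index(drop=True)
    top_weight = float(table["weight"].iloc[0])

    in_set = table[table["delta"] < CAIC_CANDIDATE_DELTA] if top_weight <= 0.90 else table.iloc[:1]
    wsum: dict[str, float] = {}
    csum: dict[str, float] = {}
    ssum: dict[str, float] = {}
    for _, row in in_set.iterrows():
        subset = row["subset"]
        res = next(r for s, r in fits if s == subset)
        for nm in subset:
            wsum[nm] = wsum.get(nm, 0.0) + row["weight"]
            csum[nm] = csum.get(nm, 0.0) + row["weight"] * float(res.params[nm])
            ssum[nm] = ssum.get(nm, 0.0) + row["weight"] * float(res.bse[nm])
    coef = pd.DataFrame([{"term": nm, "coef": csum[nm] / wsum[nm],
                          "se": ssum[nm] / wsum[nm], "weight_in": wsum[nm]}
                         for nm in wsum])
    return BCIModelResult(timescale=w_best, timescale_table=ts_table,
                          model_table=table.drop(columns=["subset"]),
                          coefficients=coef, top_weight=top_weight,
                          averaged=bool(top_weight <= 0.90 and len(in_set) > 1),
                          dropped_collinear=dropped, n=len(df))
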