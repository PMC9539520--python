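"""Encounter histories, interval likelihood, the MCMC sampler, WAIC, delta method."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import phenomatch as pm
from phenomatch.survival import MCMCSettings, SurvivalModelSpec, waic_from_pointwise

from conftest import make_history


def chick_row(cid="c1", brood="b1", hatch="2009-06-09"):
    return {"chick_id": cid, "brood_id": brood, "plot": "North", "hatch_date": hatch}


def reloc(cid, doy, status, year=2009):
    date = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=doy - 1)
    return {"chick_id": cid, "date": date.date().isoformat(), "status": status}


@pytest.fixture()
def flat_series():
    rows = [{"year": 2009, "day": d, "biomass_mg": 100.0, "median_bodymass_mg": 1.5,
             "n_records": 5, "n_transects": 2} for d in range(140, 200)]
    return pd.DataFrame(rows)


HATCH_DOY = 160  # 2009-06-09


class TestBuildEncounterHistories:
    def test_death_after_survived_relocations(self, flat_series):
        chicks = pd.DataFrame([chick_row()])
        relocs = pd.DataFrame([reloc("c1", HATCH_DOY + a, "alive") for a in (0, 3, 6)]
                              + [reloc("c1", HATCH_DOY + 8, "dead")])
        (h,) = pm.build_encounter_histories(chicks, relocs, flat_series)
        iv = h.intervals
        assert [(r["start_age"], r["end_age"], r["fate"]) for _, r in iv.iterrows()] == [
            (0.0, 3.0, "survived"), (3.0, 6.0, "survived"), (6.0, 8.0, "died_within")]

    def test_survival_to_radio_lifespan_is_censored(self, flat_series):
        chicks = pd.DataFrame([chick_row()])
        relocs = pd.DataFrame([reloc("c1", HATCH_DOY + a, "alive")
                               for a in range(0, 22, 3)])
        (h,) = pm.build_encounter_histories(chicks, relocs, flat_series)
        assert h.intervals["fate"].iloc[-1] == "censored"
        assert h.intervals["end_age"].iloc[-1] == 21.0

    def test_three_consecutive_missing_days_mean_death(self, flat_series):
        chicks = pd.DataFrame([chick_row()])
        relocs = pd.DataFrame(
            [reloc("c1", HATCH_DOY + a, "alive") for a in (0, 3, 6, 9)]
            + [reloc("c1", HATCH_DOY + a, "missing") for a in (10, 11, 12)])
        (h,) = pm.build_encounter_histories(chicks, relocs, flat_series)
        last = h.intervals.iloc[-1]
        assert last["fate"] == "died_within"
        assert last["end_age"] == 12.0

    def test_isolated_missing_day_is_not_death(self, flat_series):
        chicks = pd.DataFrame([chick_row()])
        relocs = pd.DataFrame(
            [reloc("c1", HATCH_DOY, "alive"), reloc("c1", HATCH_DOY + 4, "missing"),
             reloc("c1", HATCH_DOY + 6, "alive"), reloc("c1", HATCH_DOY + 9, "alive")])
        (h,) = pm.build_encounter_histories(chicks, relocs, flat_series)
        assert "died_within" not in set(h.intervals["fate"])

    def test_flagged_chicks_excluded(self, flat_series):
        chicks = pd.DataFrame([dict(chick_row(), exclude="human-caused mortality"),
                               dict(chick_row(cid="c2", brood="b2"))])
        relocs = pd.DataFrame([reloc(c, HATCH_DOY + a, "alive")
                               for c in ("c1", "c2") for a in (0, 3)])
        histories = pm.build_encounter_histories(chicks, relocs, flat_series)
        assert [h.chick_id for h in histories] == ["c2"]

    def test_unknown_chick_and_pre_hatch_relocation_raise(self, flat_series):
        chicks = pd.DataFrame([chick_row()])
        with pytest.raises(ValueError, match="unknown"):
            pm.build_encounter_histories(
                chicks, pd.DataFrame([reloc("ghost", HATCH_DOY, "alive")]), flat_series)
        with pytest.raises(ValueError, match="before hatch"):
            pm.build_encounter_histories(
                chicks, pd.DataFrame([reloc("c1", HATCH_DOY - 2, "alive"),
                                      reloc("c1", HATCH_DOY + 3, "alive")]), flat_series)


class TestIntervalLikelihood:
    def test_three_day_survival_product(self):
        h = make_history(intervals=[(0, 3, "survived")])
        assert pm.interval_log_likelihood(h, [0.9] * 3) == pytest.approx(np.log(0.729))

    def test_three_day_death_complement(self):
        h = make_history(intervals=[(0, 3, "died_within")])
        assert pm.interval_log_likelihood(h, [0.9] * 3) == pytest.approx(np.log(0.271))

    def test_censored_contributes_like_survived(self):
        hs = make_history(intervals=[(0, 3, "survived")])
        hc = make_history(intervals=[(0, 3, "censored")])
        probs = [0.8, 0.93, 0.99]
        assert pm.interval_log_likelihood(hs, probs) == pm.interval_log_likelihood(hc, probs)

    def test_survived_and_died_partition_unity(self):
        probs = [0.8, 0.95, 0.7, 0.99]
        ls = pm.interval_log_likelihood(make_history(intervals=[(0, 4, "survived")]), probs)
        ld = pm.interval_log_likelihood(make_history(intervals=[(0, 4, "died_within")]), probs)
        assert np.exp(ls) + np.exp(ld) == pytest.approx(1.0)

    def test_matches_enumeration_on_two_interval_history(self):
        """Brute force: enumerate all per-day alive/dead placements of a
        2-interval history ending in death and sum their probabilities."""
        probs = np.array([0.9, 0.85, 0.8, 0.7, 0.95])
        h = make_history(intervals=[(0, 2, "survived"), (2, 5, "died_within")])
        ll = pm.interval_log_likelihood(h, probs)
        # survive days 1-2, then die on day 3, 4, or 5
        total = 0.0
        for death_day in (2, 3, 4):
            p = probs[0] * probs[1]
            for d in range(2, death_day):
                p *= probs[d]
            p *= 1 - probs[death_day]
            total += p
        assert ll == pytest.approx(np.log(total))

    def test_rejects_degenerate_probabilities(self):
        h = make_history(intervals=[(0, 3, "survived")])
        with pytest.raises(ValueError):
            pm.interval_log_likelihood(h, [0.9, 1.0, 0.9])


class TestSpecValidation:
    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError, match="main effects"):
            SurvivalModelSpec(fixed_effects=("age", "age_x_bodymass"))

    def test_settings_must_retain_samples(self):
        with pytest.raises(ValueError):
            MCMCSettings(iterations=100, adapt=60, burn_in=50)


def constant_survival_histories(n=300, s=0.9, seed=0):
    rng = np.random.default_rng(seed)
    histories = []
    for i in range(n):
        bounds, last = [], 0
        dead = False
        for end in range(3, 24, 3):
            end = min(end, 21)
            alive = rng.random(end - last) < s
            if alive.all():
                bounds.append((last, end, "survived"))
                last = end
            else:
                bounds.append((last, end, "died_within"))
                dead = True
                break
        if not dead:
            s0, e0, _ = bounds[-1]
            bounds[-1] = (s0, e0, "censored")
        histories.append(make_history(chick_id=f"c{i}", brood=f"b{i // 2}",
                                      intervals=bounds))
    return histories


class TestMCMC:
    def test_intercept_only_matches_closed_form_mle(self):
        """On constant-survival data the posterior mean daily survival should
        sit within 0.02 of the generating rate (binomial MLE oracle)."""
        histories = constant_survival_histories(n=300, s=0.9, seed=3)
        spec = SurvivalModelSpec(fixed_effects=(), random_intercepts=())
        fit = pm.fit_survival_mcmc(histories, spec,
                                   MCMCSettings(chains=2, iterations=3000, seed=1))
        post_s = 1.0 / (1.0 + np.exp(-fit.summary.loc["intercept", "mean"]))
        assert post_s == pytest.approx(0.9, abs=0.02)
        assert fit.converged

    def test_posterior_invariant_to_chick_order(self):
        histories = constant_survival_histories(n=60, s=0.92, seed=5)
        spec = SurvivalModelSpec(fixed_effects=(), random_intercepts=())
        settings = MCMCSettings(chains=2, iterations=2000, seed=7)
        fit1 = pm.fit_survival_mcmc(histories, spec, settings)
        fit2 = pm.fit_survival_mcmc(histories[::-1], spec, settings)
        assert fit1.summary.loc["intercept", "mean"] == pytest.approx(
            fit2.summary.loc["intercept", "mean"], abs=1e-12)

    def test_hierarchical_fit_runs_with_random_intercepts(self, small_study):
        histories = pm.build_encounter_histories(
            small_study["chicks"], small_study["relocs"], small_study["series"])
        fit = pm.fit_survival_mcmc(histories, SurvivalModelSpec(),
                                   MCMCSettings(chains=2, iterations=2500, seed=2))
        assert {"sigma_brood", "sigma_year", "sigma_plot"} <= set(fit.summary.index)
        assert np.isfinite(fit.waic)
        annual = pm.annual_fledging(fit)
        assert set(annual["year"]) == {2009, 2014, 2016}
        assert ((annual["fledging"] >= 0) & (annual["fledging"] <= 1)).all()


class TestWAIC:
    def test_identical_fits_tie(self):
        histories = constant_survival_histories(n=40, seed=1)
        spec = SurvivalModelSpec(fixed_effects=(), random_intercepts=())
        settings = MCMCSettings(chains=2, iterations=2000, seed=3)
        fit1 = pm.fit_survival_mcmc(histories, spec, settings)
        fit2 = pm.fit_survival_mcmc(histories, spec, settings)
        table = pm.compare_waic(fit1, fit2)
        assert table["delta"].abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_data_rejected(self):
        spec = SurvivalModelSpec(fixed_effects=(), random_intercepts=())
        settings = MCMCSettings(chains=2, iterations=2000, seed=3)
        fit1 = pm.fit_survival_mcmc(constant_survival_histories(n=20, seed=1), spec, settings)
        fit2 = pm.fit_survival_mcmc(constant_survival_histories(n=21, seed=2), spec, settings)
        with pytest.raises(ValueError):
            pm.compare_waic(fit1, fit2)

    def test_matches_quadrature_on_bernoulli_beta_toy(self):
        """Conjugate toy: y ~ Bernoulli(p), p ~ Beta(2, 2).  WAIC from exact
        posterior draws must match quadrature-based lppd and p_waic."""
        rng = np.random.default_rng(0)
        y = np.array([1, 1, 0, 1, 0, 1, 1, 1, 0, 1])
        a, b = 2 + y.sum(), 2 + (1 - y).sum()
        draws = rng.beta(a, b, size=40000)
        pointwise = np.where(y[None, :] == 1, np.log(draws)[:, None],
                             np.log1p(-draws)[:, None])
        waic, _, p_waic = waic_from_pointwise(pointwise)

        post = stats.beta(a, b)
        lppd, p_quad = 0.0, 0.0
        for yi in y:
            like = (lambda p: p) if yi == 1 else (lambda p: 1 - p)
            mean_like = integrate.quad(lambda p: like(p) * post.pdf(p), 0, 1)[0]
            mean_ll = integrate.quad(lambda p: np.log(like(p)) * post.pdf(p), 0, 1,
                                     points=[0, 1])[0]
            mean_ll2 = integrate.quad(lambda p: np.log(like(p)) ** 2 * post.pdf(p), 0, 1,
                                      points=[0, 1])[0]
            lppd += np.log(mean_like)
            p_quad += mean_ll2 - mean_ll**2
        waic_quad = -2 * (lppd - p_quad)
        assert waic == pytest.approx(waic_quad, abs=0.1)


class TestIndicatorSelection:
    def test_strong_effect_selected_noise_near_prior(self):
        """A planted |beta| = 2 effect should earn inclusion > 0.9 while a
        pure-noise covariate stays near its Bernoulli(0.5) prior."""
        rng = np.random.default_rng(4)
        histories = []
        # n sized so the null coefficient's posterior scale stays comparable
        # to the unit slab: inclusion odds ~ posterior SD / slab SD
        for i in range(120):
            x = rng.normal(0, 0.5)       # standardized-scale covariate
            noise_cov = rng.normal(0, 0.5)
            s = 1 / (1 + np.exp(-(2.6 + 2.0 * x)))
            bounds, last, dead = [], 0, False
            for end in range(3, 24, 3):
                end = min(end, 21)
                if (rng.random(end - last) < s).all():
                    bounds.append((last, end, "survived"))
                    last = end
                else:
                    bounds.append((last, end, "died_within"))
                    dead = True
                    break
            if not dead:
                s0, e0, _ = bounds[-1]
                bounds[-1] = (s0, e0, "censored")
            h = make_history(chick_id=f"c{i}", brood=f"b{i}", intervals=bounds)
            h.intervals["biomass"] = x          # planted signal
            h.intervals["bodymass"] = noise_cov  # pure noise
            histories.append(h)
        # weakly-informative slab: a very diffuse slab would swamp the
        # indicator odds (Bartlett effect) and pin null inclusion near 0
        spec = SurvivalModelSpec(fixed_effects=("biomass", "bodymass"),
                                 random_intercepts=(),
                                 indicators=("biomass", "bodymass"),
                                 prior_sd_beta=1.0)
        # (mean, sd) chosen so z = (x - 0)/(2 * 0.5) = x: planted scale preserved
        stats_in = {"biomass": (0.0, 0.5), "bodymass": (0.0, 0.5),
                    "hatch": (160.0, 1.0), "age": (10.0, 5.0)}
        inclusion, selected, _ = pm.indicator_selection(
            histories, spec, MCMCSettings(chains=2, iterations=4000, seed=6),
            stats=stats_in)
        assert inclusion["biomass"] > 0.9
        assert 0.2 <= inclusion["bodymass"] <= 0.8
        assert "biomass" in selected.fixed_effects


class TestDeltaMethod:
    def test_certain_survival(self):
        assert pm.dsr_to_fledging(1.0, 0.0) == (1.0, 0.0)

    def test_hand_value_and_monte_carlo(self):
        f, se = pm.dsr_to_fledging(0.9, 0.01)
        assert f == pytest.approx(0.9**21, rel=1e-9)
        assert f == pytest.approx(0.1094, abs=5e-4)
        assert se == pytest.approx(0.0255, abs=5e-4)
        rng = np.random.default_rng(0)
        mc = rng.normal(0.9, 0.01, 100000) ** 21
        assert se == pytest.approx(mc.std(), rel=0.10)

    @pytest.mark.parametrize("s,se_s", list(itertools.product(
        [0.85, 0.9, 0.95, 0.99], [0.005, 0.01, 0.015])))
    def test_delta_se_tracks_monte_carlo(self, s, se_s):
        _, se = pm.dsr_to_fledging(s, se_s)
        rng = np.random.default_rng(42)
        mc = rng.normal(s, se_s, 200000) ** 21
        assert se == pytest.approx(mc.std(), rel=0.10)

    @pytest.mark.parametrize("s", [0.85, 0.9, 0.95, 0.99])
    def test_delta_se_second_order_deviation_bounded(self, s):
        """At SE(s) = 0.02 the curvature of s**21 makes the first-order SE
        genuinely low by ~10-15% (the s**21 second derivative term is
        O(sigma^4) but large); the deviation stays below 20%."""
        _, se = pm.dsr_to_fledging(s, 0.02)
        rng = np.random.default_rng(42)
        mc = rng.normal(s, 0.02, 200000) ** 21
        assert se == pytest.approx(mc.std(), rel=0.20)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pm.dsr_to_fledging(1.2, 0.01)
        with pytest.raises(ValueError):
            pm.dsr_to_fledging(0.0, 0.01)
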