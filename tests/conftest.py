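import numpy as np
import pandas as pd
import pytest

import phenomatch as pm


@pytest.fixture(scope="session")
def small_study():
    """One small simulated three-season study shared across tests."""
    cfg = pm.small_config(seed=11)
    inverts, series, chicks, masses, relocs, truth = pm.simulate_study(cfg)
    return {"config": cfg, "inverts": inverts, "series": series, "chicks": chicks,
            "masses": masses, "relocs": relocs, "truth": truth}


@pytest.fixture()
def toy_series():
    """Constant two-year daily series for curve/overlap arithmetic."""
    rows = []
    for year, bio in ((2009, 100.0), (2010, 50.0)):
        for day in range(150, 160):
            rows.append({"year": year, "day": day, "biomass_mg": bio,
                         "median_bodymass_mg": 1.5, "n_records": 10, "n_transects": 2})
    return pd.DataFrame(rows)


def make_history(chick_id="c1", year=2009, hatch=160.0, intervals=None,
                 brood="b1", plot="North"):
    """Hand-build an encounter history from (start, end, fate) triples."""
    iv = pd.DataFrame([{"start_age": s, "end_age": e, "fate": f,
                        "biomass": 100.0, "bodymass": 1.5, "hatch": hatch,
                        "age": 0.5 * (s + e)}
                       for s, e, f in (intervals or [(0, 21, "censored")])])
    return pm.EncounterHistory(chick_id=chick_id, brood_id=brood, year=year,
                               plot=plot, hatch_doy=hatch, intervals=iv)


@pytest.fixture()
def uniform_curve():
    def _make(year=2009, start=150, length=10, kind="resource"):
        days = np.arange(start, start + length)
        return pm.PhenologyCurve(year=year, days=days,
                                 proportions=np.full(length, 1.0 / length), kind=kind)
    return _make
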