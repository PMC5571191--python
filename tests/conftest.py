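import numpy as np
import pytest

import peakeffort as pe


@pytest.fixture(scope="session")
def calendar():
    return pe.study_calendar()


@pytest.fixture(scope="session")
def small_population(calendar):
    """One simulated study population reused across read-only tests."""
    cfg = pe.SimulationConfig(n_females=400, seed=7)
    hists = pe.simulate_population(cfg)
    summaries = pe.summarize_females(hists, calendar)
    return {
        "config": cfg,
        "histories": hists,
        "summaries": summaries,
        "sets": pe.build_analysis_sets(summaries),
        "annual": pe.annual_table(hists, calendar),
    }


@pytest.fixture
def toy_histories(calendar):
    """Three hand-built females: a 4-year breeder, a one-event female and a
    non-breeder."""
    def rec(fid, cohort, age, pups, recruits):
        return pe.AnnualRecord(fid, cohort, cohort + age, pups, recruits)

    a = pe.FemaleLifeHistory("A", 1990, 4, tuple(
        rec("A", 1990, age, pups, rc)
        for age, pups, rc in [(1, 2, 0), (2, 4, 1), (3, 4, 2), (4, 1, 0)]))
    b = pe.FemaleLifeHistory("B", 1992, 1, (rec("B", 1992, 1, 5, 1),))
    c = pe.FemaleLifeHistory("C", 1995, 3, tuple(
        rec("C", 1995, age, 0, 0) for age in (1, 2, 3)))
    return [a, b, c]


def glmm_population(seed, n=800, q=20, beta0=0.5, beta1=0.3, sd=0.4,
                    family="poisson", theta=8.0, sigma=0.7):
    """Single-batch random-intercept data drawn from the model the fitter
    assumes; returns a DataFrame with columns y, x, cohort."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    g = rng.integers(0, q, n)
    x = rng.normal(size=n)
    bc = rng.normal(0.0, sd, q)
    eta = beta0 + beta1 * x + bc[g]
    if family == "poisson":
        y = rng.poisson(np.exp(eta))
    elif family == "negative_binomial":
        y = rng.poisson(rng.gamma(theta, np.exp(eta) / theta))
    elif family == "binomial":
        y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    else:
        y = eta + rng.normal(0.0, sigma, n)
    return pd.DataFrame({"y": y, "x": x, "cohort": g})
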