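import numpy as np
import pandas as pd
import pytest

import treatpath as tp
from treatpath import prep
from treatpath.rp import exponential_fit

# the constant-hazard triple used throughout the closed-form oracle tests
RATES = {"h1": 0.004, "h2": 0.002, "h3": 0.003}


def closed_form_constant(t, l1=RATES["h1"], l2=RATES["h2"], l3=RATES["h3"]):
    """Analytic illness-death occupancy for constant hazards."""
    t = np.asarray(t, dtype=float)
    c = l1 + l2
    p11 = np.exp(-c * t)
    p12 = l1 / (c - l3) * (np.exp(-l3 * t) - np.exp(-c * t))
    return p11, p12, 1.0 - p11 - p12


def closed_form_los(T, l1=RATES["h1"], l2=RATES["h2"], l3=RATES["h3"]):
    c = l1 + l2
    L1 = (1.0 - np.exp(-c * T)) / c
    L2 = l1 / (c - l3) * ((1.0 - np.exp(-l3 * T)) / l3 - (1.0 - np.exp(-c * T)) / c)
    return L1, L2


@pytest.fixture
def constant_fits():
    """Constant transition hazards exactly encoded on the estimation path."""
    return {t: exponential_fit(r) for t, r in RATES.items()}


@pytest.fixture(scope="session")
def stage4_cohort():
    """One moderately sized generator cohort shared across read-only tests."""
    params = tp.colon_stage4_like(n_patients=20_000, seed=11)
    cohort = prep.jitter_same_day(tp.simulate_cohort(params), seed=2)
    return params, cohort


@pytest.fixture(scope="session")
def stage4_datasets(stage4_cohort):
    _, cohort = stage4_cohort
    return prep.build_transition_datasets(cohort)


def constant_params(l1, l2, l3, n=10_000, seed=0, **kw):
    """Generator params with constant hazards and no covariate effects."""
    return tp.SimulationParams(
        n_patients=n,
        seed=seed,
        baseline={
            "h1": {"family": "constant", "rate": l1},
            "h2": {"family": "constant", "rate": l2},
            "h3": {"family": "constant", "rate": l3},
        },
        same_day_fraction=0.0,
        **kw,
    )
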