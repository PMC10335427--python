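import dataclasses

import numpy as np
import pytest

import riskvalid as rv


@pytest.fixture(scope="session")
def model():
    return rv.default_model()


@pytest.fixture(scope="session")
def small_cohort():
    """Default-spec synthetic cohort at n=800 (fast, still >100 events at
    larger seeds is not guaranteed; used for structural checks only)."""
    return rv.generate_cohort(rv.default_cohort_spec(n=800, seed=11))


@pytest.fixture(scope="session")
def complete_table(model):
    """A complete (no-missingness) predictor table with outcomes drawn from
    the shipped model with its intercept solved for 11% prevalence."""
    spec = dataclasses.replace(
        rv.default_cohort_spec(n=5000, seed=23), missing_rates={}
    )
    cohort = rv.generate_cohort(spec)
    return cohort


def brute_force_auc(p, y):
    """Independent oracle: exhaustive case-control pair counting, ties 0.5."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    cases = p[y == 1]
    controls = p[y == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))
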