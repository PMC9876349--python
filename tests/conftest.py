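"""Shared fixtures: synthetic datasets, calibration products, oracles.

Everything is generated programmatically at test time from fixed seeds; the
expensive calibration products (MLE, MCMC chains) are session-scoped so the
suite pays for them once.
"""

import numpy as np
import pytest

from spheroidox.inference import (
    GREENSPAN_PARAM_NAMES,
    filter_outliers,
    fit_mle,
    make_greenspan_model,
)
from spheroidox.synthetic import generate_dataset, ground_truth_bundle

GREENSPAN_BOUNDS = np.array([(50.0, 400.0), (0.05, 2.0), (80.0, 500.0),
                             (0.05, 3.0), (0.2, 1.0)])


def bisect(f, lo, hi, tol=1e-9, maxiter=200):
    """Plain bisection, used as the independent root oracle throughout."""
    flo = f(lo)
    for _ in range(maxiter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0.0 or hi - lo < tol:
            return mid
        if (flo > 0) == (fm > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def normoxia_truth():
    return ground_truth_bundle("normoxia_like")[0]


@pytest.fixture(scope="session")
def normoxia_dataset():
    params, design = ground_truth_bundle("normoxia_like")
    return filter_outliers(generate_dataset(params, design, seed=11))


@pytest.fixture(scope="session")
def greenspan_model():
    return make_greenspan_model()


@pytest.fixture(scope="session")
def normoxia_mle(normoxia_dataset, greenspan_model):
    return fit_mle(normoxia_dataset, greenspan_model, GREENSPAN_BOUNDS,
                   n_starts=8, seed=1, param_names=GREENSPAN_PARAM_NAMES)
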