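import numpy as np
import pytest

from eve2sim import (
    DataFeatures,
    RateSet,
    make_tf_profiles,
    run_full_estimation,
)


@pytest.fixture(scope="session")
def profiles():
    return make_tf_profiles()


@pytest.fixture(scope="session")
def calibration(profiles):
    return run_full_estimation(DataFeatures(), profiles)


@pytest.fixture(scope="session")
def rates(calibration):
    return calibration.rates


@pytest.fixture(scope="session")
def center_conc(profiles):
    """Stripe-center TF input: zero repressors, activators at the anchors."""
    return profiles.conc_at(42, time_varying=False)


def generator_matrix(conc, rate_set: RateSet) -> np.ndarray:
    """Brute-force 16x16 CTMC generator of the binding network (test oracle).

    Built directly from the elementary binding/unbinding reactions,
    independently of the product-form shortcut it is used to check.
    """
    c = conc.at(0.0)
    Q = np.zeros((16, 16))
    for s in range(16):
        for site in range(4):
            bit = 8 >> site
            if s & bit:  # bound -> unbind
                rate = rate_set.k_unbind[site]
                dest = s & ~bit
            else:  # unbound -> bind
                rate = rate_set.k_bind[site] * c[site]
                dest = s | bit
            Q[s, dest] += rate
            Q[s, s] -= rate
    return Q


def stationary_from_generator(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a CTMC by linear solve (test oracle)."""
    n = Q.shape[0]
    scale = np.abs(Q).max()
    if scale > 0:  # rescaling time units leaves the stationary law unchanged
        Q = Q / scale
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi
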