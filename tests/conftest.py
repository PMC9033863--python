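import numpy as np
import pytest

from fedcox import SiteData


@pytest.fixture
def two_subject_site():
    """A=(t=1, event, x=1), B=(t=2, censored, x=0)."""
    return SiteData("two", times=[1.0, 2.0], events=[1, 0], X=[[1.0], [0.0]])


@pytest.fixture
def d0():
    """Three-subject single-covariate site used throughout the unit tests."""
    return SiteData("D0", times=[1.0, 2.0, 3.0], events=[1, 0, 1],
                    X=[[0.5], [-0.3], [0.8]])


@pytest.fixture
def all_censored_site():
    return SiteData("cens", times=[1.0, 2.0, 3.0], events=[0, 0, 0],
                    X=[[0.1], [0.2], [0.3]])


def random_site(rng, n=None, p=2, site_id="rnd", with_ties=False):
    """Small random site with ~50% events; optional duplicated times."""
    n = n or int(rng.integers(3, 7))
    times = rng.exponential(1.0, size=n) + 0.05
    if with_ties and n >= 4:
        times[1] = times[0]
        times[3] = times[2]
    events = rng.integers(0, 2, size=n)
    if events.sum() == 0:
        events[int(rng.integers(0, n))] = 1
    X = rng.normal(size=(n, p))
    return SiteData(site_id, times=times, events=events, X=X)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
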