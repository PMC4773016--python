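import numpy as np
import pytest

from cmega import build_griffith, build_switch

#: Seed for the statistical validation runs (fixed; chosen up front).
VALIDATION_SEED = 20251001


@pytest.fixture(scope="session")
def switch():
    return build_switch()


@pytest.fixture(scope="session")
def griffith():
    return build_griffith()


@pytest.fixture(scope="session")
def griffith_small():
    return build_griffith(d=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def subsample_summary(summary, step):
    """View of an EnsembleSummary on every ``step``-th grid point."""
    import copy

    out = copy.copy(summary)
    out.grid = summary.grid[::step]
    out.mean = summary.mean[::step]
    out.std = summary.std[::step]
    out.m4 = summary.m4[::step]
    return out
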