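"""Shared fixtures: the default synthetic study and its fitted decompositions.

The expensive global fits are session-scoped so that the end-to-end
recovery checks and the comparative/property checks share one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import laminarpa as lp
from laminarpa.synthetic import SyntheticConfig, make_ground_truth, make_recordings

SEED = 1


@pytest.fixture(scope="session")
def truth():
    """Default noise-free, low-synchrony ground truth."""
    return make_ground_truth(SyntheticConfig(), seed=SEED)


@pytest.fixture(scope="session")
def recordings(truth):
    return make_recordings(truth, seed=SEED)


@pytest.fixture(scope="session")
def geometry(truth):
    return truth.geometry


@pytest.fixture(scope="session")
def mua_fit(truth, recordings):
    """Full-budget trapezoid/rate fit on the default fixture."""
    cfg = lp.AnalysisConfig(n_populations=5, rng_seed=SEED)
    return lp.fit_mua(recordings.mua, truth.geometry, cfg)


@pytest.fixture(scope="session")
def csd_fit(truth, recordings):
    """Full-budget kernel fit on the default fixture (true rates)."""
    cfg = lp.AnalysisConfig(rng_seed=SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lp.fit_csd(recordings.csd, truth.rates_all, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
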