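import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

import hoconn as hc


@pytest.fixture
def rng():
    return np.random.default_rng(20170802)


@pytest.fixture
def small_ts(rng):
    """A 60-timepoint, 8-region random scan."""
    return hc.ROITimeSeries(rng.standard_normal((60, 8)), tr_seconds=2.0)


@pytest.fixture(scope="session")
def atlas58():
    """The packaged 58-ROI region table."""
    return hc.bundled_atlas()


@pytest.fixture
def random_lofc(rng):
    """A valid random 6-region correlation matrix (PD by construction)."""
    x = rng.standard_normal((80, 6))
    return hc.compute_lofc(hc.ROITimeSeries(x))


def make_tset(rng, n_subjects=3, n_sessions=2, T=40, n=5):
    """Small complete design of random scans (helper, not a fixture)."""
    subjects = tuple(f"s{i}" for i in range(n_subjects))
    sessions = tuple(f"e{j}" for j in range(n_sessions))
    entries = {
        (s, e): hc.ROITimeSeries(rng.standard_normal((T, n)))
        for s in subjects
        for e in sessions
    }
    return hc.ROITimeSeriesSet(entries, subjects, sessions)
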