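import numpy as np
import pytest

from specfx.io import fixture_common_peak_matrix, load_fixture


@pytest.fixture(scope="session")
def table3_areas():
    """Relative areas, batches x peaks (reference dataset)."""
    return load_fixture("table3").drop(columns="rsd_printed").T


@pytest.fixture(scope="session")
def table2_rts():
    return load_fixture("table2").drop(columns="rsd_printed").T


@pytest.fixture(scope="session")
def activity():
    """Per-batch efficacy indices: DPPH % and T-AOC umol/mL."""
    return load_fixture("table5")[["dpph_pct", "t_aoc"]]


@pytest.fixture(scope="session")
def fixture_matrix():
    return fixture_common_peak_matrix()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
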