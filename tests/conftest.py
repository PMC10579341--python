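"""Shared test fixtures and small helpers."""

import numpy as np
import pytest

from edensat.eden_core import LatticeState, SimParams, run


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(sites, L=21, t=0.0):
    return LatticeState(L, sites, t=t)


def cube_sites(origin, size):
    ox, oy, oz = origin
    return [
        (ox + i, oy + j, oz + k)
        for i in range(size)
        for j in range(size)
        for k in range(size)
    ]


@pytest.fixture(scope="session")
def small_jump_run():
    """One modest satellite-regime run reused by several read-only tests."""
    return run(SimParams(k_s=0.1, sigma=5.0, L=121, max_events=20_000, seed=11))
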