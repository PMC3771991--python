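"""Shared fixtures: small synthetic systems used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from pcgc import TimeSeriesSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ar1_pair(t: int, rng: np.random.Generator, a: float = 0.5, b: float = 0.5):
    """x drives y one step ahead; returns a T x 2 array (x, y)."""
    x = np.zeros(t)
    y = np.zeros(t)
    e = rng.standard_normal((t, 2))
    for i in range(1, t):
        x[i] = a * x[i - 1] + e[i, 0]
        y[i] = a * y[i - 1] + b * x[i - 1] + e[i, 1]
    return np.column_stack([x, y])


def chain_xwy(t: int, rng: np.random.Generator, extra_noise: int = 0):
    """Causal chain x -> w -> y (no direct x -> y), plus optional noise columns."""
    x = np.zeros(t)
    w = np.zeros(t)
    y = np.zeros(t)
    e = rng.standard_normal((t, 3))
    for i in range(1, t):
        x[i] = 0.5 * x[i - 1] + e[i, 0]
        w[i] = 0.3 * w[i - 1] + 0.8 * x[i - 1] + e[i, 1]
        y[i] = 0.3 * y[i - 1] + 0.8 * w[i - 1] + e[i, 2]
    cols = [x, w, y]
    if extra_noise:
        cols.append(rng.standard_normal((t, extra_noise)))
        return np.column_stack(cols[:3] + [cols[3]])
    return np.column_stack(cols)


@pytest.fixture
def coupled_pair_ts(rng) -> TimeSeriesSet:
    return TimeSeriesSet(ar1_pair(2000, rng), dt=2.0)


@pytest.fixture
def chain_ts(rng) -> TimeSeriesSet:
    return TimeSeriesSet(chain_xwy(5000, rng))
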