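"""Shared oracles and fixtures.

The oracles here are deliberately independent of the package's solver: a
damped fixed-point iteration and a plain bisection restricted to the
descending branch of the concave residual, both driven by direct evaluation
of the residual formula.
"""

from __future__ import annotations

import numpy as np
import pytest


def residual_direct(x, pad, pes, et, pep, c_k=0.53, p_k=0.51):
    """Direct evaluation of the coupling residual, no package code."""
    return (pad / pes) * (1.0 + c_k * x**p_k * et / pep) - 1.0 - x


def fixed_point_root(pad, pes, et, pep, c_k=0.53, p_k=0.51, x0=1.0, tol=1e-14):
    """Larger root of the residual via the natural iteration x <- A-1 + B*x^p.

    The iteration map has derivative < 1 at the larger root (attracting),
    so plain iteration converges there from x0 = 1.
    """
    a = pad / pes
    b = a * c_k * et / pep
    x = x0
    for _ in range(10_000):
        x_new = a - 1.0 + b * x**p_k
        if abs(x_new - x) < tol:
            return x_new
        x = x_new
    raise RuntimeError("fixed-point oracle failed to converge")


def bisect_descending(pad, pes, et, pep, c_k=0.53, p_k=0.51, hi=50.0, tol=1e-12):
    """Largest root by bisection on the descending branch of the residual.

    Locates the branch by scanning a log-spaced grid for the maximum of g,
    then bisects between the grid argmax and the first negative point beyond
    it.  Returns None when g < 0 everywhere on the grid.
    """

    def g(x):
        return residual_direct(x, pad, pes, et, pep, c_k, p_k)

    grid = np.logspace(-4, np.log10(hi), 4000)
    vals = np.array([g(x) for x in grid])
    i_max = int(np.argmax(vals))
    if vals[i_max] < 0:
        return None
    lo = grid[i_max]
    above = np.where((np.arange(grid.size) > i_max) & (vals < 0))[0]
    b = grid[above[0]] if above.size else hi
    while b - lo > tol:
        mid = 0.5 * (lo + b)
        if g(mid) >= 0:
            lo = mid
        else:
            b = mid
    return 0.5 * (lo + b)


@pytest.fixture
def table1_beat():
    """Cohort-mean inputs of the healthy-adult study population."""
    from vacef import BeatRecord

    return BeatRecord(pep=97.0, et=303.0, sbp=119.0, dbp=72.0, id="table1")


@pytest.fixture
def rng():
    return np.random.default_rng(20230612)
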