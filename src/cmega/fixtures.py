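"""Deterministic synthetic fixtures for property tests.

Randomized-but-valid parameter sets and hybrid states, seeded so that the
same seed always yields the same fixture.  Parameter sets jitter each
default rate log-uniformly within a factor of three; states draw a random
promoter occupancy, a small mRNA count, and Poisson means spanning the
regimes the hybrid visits (including the sub-unit values that force the
exact inverse-moment fallback).
"""

from __future__ import annotations

from typing import List

import numpy as np

from .hybrid import HybridState
from .networks import GRIFFITH_PARAMS, SWITCH_PARAMS


def generate_fixture(kind: str, seed, model: str = "switch", n: int = 100):
    """Generate ``n`` fixture items of ``kind`` ('params' or 'states')."""
    rng = np.random.default_rng(seed)
    if kind == "params":
        return _params(rng, model, n)
    if kind == "states":
        return _states(rng, model, n)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _params(rng, model: str, n: int) -> List[dict]:
    base = SWITCH_PARAMS if model == "switch" else GRIFFITH_PARAMS
    out = []
    for _ in range(n):
        factors = np.exp(rng.uniform(np.log(1 / 3), np.log(3), size=len(base)))
        out.append(
            {k: float(v * f) for (k, v), f in zip(base.items(), factors)}
        )
    return out


def _states(rng, model: str, n: int, d: int = 10) -> List[HybridState]:
    n_prom = 3 if model == "switch" else 5
    dim = 1 if model == "switch" else d
    out = []
    for _ in range(n):
        s = int(rng.integers(n_prom))
        m = int(rng.integers(0, 7))
        # mix small and moderate Poisson means
        if rng.random() < 0.25:
            lam = rng.uniform(0.0, 2.0, size=dim)
        else:
            lam = rng.uniform(0.0, 150.0, size=dim)
        out.append(HybridState(model, s, m, lam))
    return out
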