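"""Shared fixtures and independent oracles.

The oracles deliberately avoid the code paths they check: the brute-force
state enumeration scans all 2^n occupancy vectors with its own run test, and
the continuous-time stationary oracle assembles the generator Q directly
from event predicates and rates and solves Q pi = 0 by a dense null-space,
never touching the averaged-transition-matrix machinery.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.linalg

from ribolattice import LatticeConfig
from ribolattice.lattice import allowed_events, apply_event, build_events


@pytest.fixture
def toy_config() -> LatticeConfig:
    """The worked 2-codon example: alpha=0.6, beta=0.4, gamma_1=1."""
    return LatticeConfig(2, 1, alpha=0.6, beta=0.4, gamma=1.0)


TOY_PI = {(1, 1): 0.36, (1, 0): 0.24, (0, 1): 0.24, (0, 0): 0.16}
TOY_ME = np.array([
    [0.8, 0.0, 0.3, 0.0],
    [0.2, 0.5, 0.0, 0.3],
    [0.0, 0.5, 0.5, 0.0],
    [0.0, 0.0, 0.2, 0.7],
])


def brute_force_states(n: int, r: int) -> set[tuple[int, ...]]:
    """All occupancy vectors that decompose into disjoint length-r runs."""

    def valid(x) -> bool:
        i = 0
        while i < n:
            if x[i]:
                if i + r > n or any(v == 0 for v in x[i:i + r]):
                    return False
                i += r
            else:
                i += 1
        return True

    return {x for x in itertools.product((0, 1), repeat=n) if valid(x)}


def ctmc_stationary(config: LatticeConfig, states, stop=None) -> np.ndarray:
    """Stationary law of the continuous-time chain with generator built
    from raw rates on allowed transitions (dense null-space solve)."""
    index = {s: k for k, s in enumerate(states)}
    m = len(states)
    Q = np.zeros((m, m))
    events = build_events(config, stop)
    for s in states:
        j = index[s]
        for e in allowed_events(s, config, events=events):
            t = apply_event(s, e, config)
            i = index[t]
            Q[i, j] += e.rate
            Q[j, j] -= e.rate
    ns = scipy.linalg.null_space(Q)
    assert ns.shape[1] == 1, "CTMC oracle expects a unique stationary law"
    pi = ns[:, 0]
    pi = pi / pi.sum()
    assert np.all(pi > -1e-12)
    return np.clip(pi, 0.0, None)
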