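"""Stochastic simulation of the codon-based model.

Five statistically equivalent update schemes are implemented.  Four use the
random-sequential update rule (one event at most per step):

* ``conventional``     — pick an index uniformly from the full event set,
  fire with probability gamma_i if the state allows it; fixed step
  dt = 1/(n-r+2) (rates rescaled by their maximum when any exceeds 1);
* ``alternative``      — pick index i directly with probability
  gamma_i/(n-r+2) (skip otherwise); same fixed step;
* ``efficient-fixed``  — pick i with probability gamma_i/sum(gamma) over the
  full event set, fire if allowed; dt = 1/sum(gamma).  This is the
  uniformized chain solved exactly by :mod:`ribolattice.pbn`;
* ``efficient-varying`` — pick i among the *allowed* events with probability
  gamma_i/sum_allowed(gamma); dt = 1/sum_allowed(gamma); every step fires.

The fifth is the ``parallel`` update rule: all allowed events fire
independently with probability gamma_i/max_allowed(gamma) within one step
dt = 1/max_allowed(gamma), swept left to right with applicability frozen at
the start of the step (equivalent to the particle-ordered-sequential rule
for unidirectional hops).

Densities are time-weighted (each pre-step state weighted by the step's dt)
so that estimates are comparable across schemes with different clocks; the
translation-rate estimate is exit events per unit simulated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lattice import Event, LatticeConfig, build_events, heads_to_state

__all__ = ["SimulationConfig", "SimulationSummary", "Kernel", "run", "ALGORITHMS"]

ALGORITHMS = {
    "conventional": "conventional",
    "a4": "conventional",
    "alternative": "alternative",
    "a5": "alternative",
    "efficient-fixed": "efficient-fixed",
    "a6": "efficient-fixed",
    "efficient-varying": "efficient-varying",
    "a1": "efficient-varying",
    "random-sequential": "efficient-varying",
    "parallel": "parallel",
    "a2": "parallel",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Algorithm choice, run length and reproducibility settings."""

    algorithm: str = "efficient-varying"
    steps: int = 100_000
    burn_in: int | None = None  # defaults to steps // 10
    seed: int = 0
    record_states: bool = False

    def resolved_burn_in(self) -> int:
        b = self.steps // 10 if self.burn_in is None else self.burn_in
        if not 0 <= b < self.steps:
            raise ValueError(f"need steps > burn_in >= 0, got steps={self.steps}, burn_in={b}")
        return b

    def canonical_algorithm(self) -> str:
        try:
            return ALGORITHMS[self.algorithm.lower()]
        except KeyError:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {sorted(set(ALGORITHMS.values()))}") from None


@dataclass
class SimulationSummary:
    """Time-weighted estimates from one stochastic run."""

    rho: np.ndarray                    # per-codon occupancy estimates
    c: float                           # exits per unit simulated time
    mean_occupancy: float              # time-averaged ribosome count
    total_time: float                  # simulated time after burn-in
    n_events: dict[str, int]           # post-burn-in event counts per key
    state_freq: dict[str, float] | None = None
    degenerate: bool = False           # absorbing state reached
    algorithm: str = ""
    seed: int = 0
    steps: int = 0
    burn_in: int = 0


class Kernel:
    """Event bookkeeping over the head-position representation of a state.

    A state is a sorted tuple of ribosome head positions (1-based); the head
    at ``h`` covers codons ``h-r+1..h``.  The kernel exposes the allowed
    event set and event application in O(#ribosomes) per step.
    """

    def __init__(self, config: LatticeConfig, stop=None):
        self.config = config
        self.stop = stop
        self.events: list[Event] = build_events(config, stop)
        self.rates = np.array([e.rate for e in self.events])
        self.n, self.r = config.n, config.r
        self.entry_idx = 0
        self.exit_idx = len(self.events) - 1
        self.hop_idx: dict[int, int] = {}
        self.dis_idx: dict[int, int] = {}
        for k, e in enumerate(self.events):
            if e.kind == "hop":
                self.hop_idx[e.pos] = k
            elif e.kind == "dissociation":
                self.dis_idx[e.pos] = k

    def allowed(self, heads: list[int]) -> list[int]:
        """Indices (into ``self.events``) of the allowed events, in order."""
        n, r = self.n, self.r
        out = []
        if not heads or heads[0] >= 2 * r:
            out.append(self.entry_idx)
        for m, h in enumerate(heads):
            if h == n:
                out.append(self.exit_idx)
                continue
            nxt = heads[m + 1] if m + 1 < len(heads) else None
            if nxt is None or nxt >= h + r + 1:
                out.append(self.hop_idx[h])
                if h in self.dis_idx:
                    out.append(self.dis_idx[h])
        return sorted(out)

    def apply(self, heads: list[int], event_idx: int) -> None:
        """Apply an allowed event in place."""
        e = self.events[event_idx]
        if e.kind == "entry":
            heads.insert(0, self.r)
        elif e.kind == "exit":
            heads.pop()
        elif e.kind == "hop":
            heads[heads.index(e.pos)] += 1
        else:
            heads.remove(e.pos)

    def occupancy(self, heads: Sequence[int]) -> tuple[int, ...]:
        return heads_to_state(heads, self.n, self.r)


def _accumulate(occ: np.ndarray, heads: list[int], dt: float, r: int) -> None:
    for h in heads:
        occ[h - r:h] += dt


def run(config: LatticeConfig, sim: SimulationConfig, stop=None,
        kernel: Kernel | None = None) -> SimulationSummary:
    """Simulate from the empty lattice and return time-weighted estimates."""
    algorithm = sim.canonical_algorithm()
    burn_in = sim.resolved_burn_in()
    kern = kernel if kernel is not None else Kernel(config, stop)
    rng = np.random.default_rng(sim.seed)
    n, r = kern.n, kern.r
    events = kern.events
    rates = kern.rates
    n_ev = len(events)

    # fixed-step schemes: rescale rates above 1 per the max-rate normalization
    scale = max(1.0, float(rates.max())) if n_ev else 1.0
    total_rate = float(rates.sum())
    cum_fixed = np.cumsum(rates / total_rate) if total_rate > 0 else None

    heads: list[int] = []
    occ = np.zeros(n)
    time_acc = 0.0
    ribo_time = 0.0
    exits = 0
    counts: dict[str, int] = {}
    state_time: dict[tuple[int, ...], float] = {} if sim.record_states else None
    degenerate = False

    for step in range(sim.steps):
        allowed = kern.allowed(heads)
        fired: list[int] = []

        if algorithm == "efficient-varying":
            pos = [idx for idx in allowed if rates[idx] > 0]
            tot = float(rates[pos].sum()) if pos else 0.0
            if tot <= 0:
                degenerate = True
                break
            dt = 1.0 / tot
            u = rng.random() * tot
            acc = 0.0
            for idx in pos:
                acc += rates[idx]
                if u < acc:
                    fired.append(idx)
                    break
            else:
                fired.append(pos[-1])
        elif algorithm == "conventional":
            dt = 1.0 / (n_ev * scale)
            idx = int(rng.integers(n_ev))
            u = rng.random()
            if idx in allowed and u < rates[idx] / scale:
                fired.append(idx)
            if not allowed or float(rates[allowed].sum()) <= 0:
                degenerate = True
                break
        elif algorithm == "alternative":
            dt = 1.0 / (n_ev * scale)
            u = rng.random() * n_ev * scale
            acc = 0.0
            pick = None
            for idx in range(n_ev):
                acc += rates[idx]
                if u < acc:
                    pick = idx
                    break
            if pick is not None and pick in allowed:
                fired.append(pick)
            if not allowed or float(rates[allowed].sum()) <= 0:
                degenerate = True
                break
        elif algorithm == "efficient-fixed":
            if cum_fixed is None:
                degenerate = True
                break
            dt = 1.0 / total_rate
            u = rng.random()
            pick = int(np.searchsorted(cum_fixed, u, side="right"))
            pick = min(pick, n_ev - 1)
            if pick in allowed:
                fired.append(pick)
            if not allowed or float(rates[allowed].sum()) <= 0:
                degenerate = True
                break
        else:  # parallel
            w = rates[allowed]
            gmax = float(w.max()) if len(w) else 0.0
            if gmax <= 0:
                degenerate = True
                break
            dt = 1.0 / gmax
            # sweep left to right; a hop and a dissociation acting on the
            # same ribosome form one actor: attempt then branch on mu
            k = 0
            while k < len(allowed):
                idx = allowed[k]
                e = events[idx]
                if (e.kind == "hop" and k + 1 < len(allowed)
                        and events[allowed[k + 1]].kind == "dissociation"
                        and events[allowed[k + 1]].pos == e.pos):
                    dis = allowed[k + 1]
                    tot_act = e.rate + events[dis].rate
                    if rng.random() < min(1.0, tot_act / gmax):
                        mu = e.rate / tot_act if tot_act > 0 else 0.0
                        fired.append(idx if rng.random() < mu else dis)
                    k += 2
                else:
                    if rng.random() < e.rate / gmax:
                        fired.append(idx)
                    k += 1

        record = step >= burn_in
        if record:
            _accumulate(occ, heads, dt, r)
            ribo_time += len(heads) * dt
            time_acc += dt
            if state_time is not None:
                s = kern.occupancy(heads)
                state_time[s] = state_time.get(s, 0.0) + dt
        for idx in fired:
            kern.apply(heads, idx)
            if record:
                key = events[idx].key
                counts[key] = counts.get(key, 0) + 1
                if events[idx].kind == "exit":
                    exits += 1

    if time_acc <= 0:
        return SimulationSummary(rho=np.zeros(n), c=0.0, mean_occupancy=0.0,
                                 total_time=0.0, n_events={}, state_freq=None,
                                 degenerate=True, algorithm=algorithm,
                                 seed=sim.seed, steps=sim.steps, burn_in=burn_in)

    freq = None
    if state_time is not None:
        freq = {"".join(map(str, s)): t / time_acc for s, t in sorted(state_time.items())}
    return SimulationSummary(
        rho=occ / time_acc,
        c=exits / time_acc,
        mean_occupancy=ribo_time / time_acc,
        total_time=time_acc,
        n_events=counts,
        state_freq=freq,
        degenerate=degenerate,
        algorithm=algorithm,
        seed=sim.seed,
        steps=sim.steps,
        burn_in=burn_in,
    )
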