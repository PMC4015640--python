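"""Deterministic timed Petri-net comparator.

Each ribosome-movement transition carries the deterministic waiting time
``w_i = 1/gamma_i`` (the mean of the stochastic waiting time).  Initiation
with footprint ``r`` waits

    w_init = max(1/alpha, 1/sum_{j=r}^{2r-1} gamma_j)   (default, "rate-sum")
    w_init = max(1/alpha, sum_{j=r}^{2r-1} 1/gamma_j)   (init_rule="wait-sum")

i.e. the slower of the initiation rate and the combined early-elongation
step; both readings of that combination are available.  The steady
translation rate is set by the single slowest waiting time,

    c = 1 / max(w_init, max_i 1/gamma_i, 1/beta),

so a premature stop codon enters only as a slowed rate ``mu * gamma_j`` and
consecutive equally-slow codons give exactly the same rate as a single one.

``pn_simulate`` runs the matching discrete-event dynamics as a max-plus
head pipeline: tokens (ribosome heads) advance one codon per firing, a
transition fires at ``max(arrival + waiting time, instant the codon ahead
frees)``, and heads cannot overtake.  Its asymptotic exit rate equals the
closed form; codon densities are read off as covered-time fractions over the
post-transient window (a convention — the deterministic model itself defines
no density).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import ConfigurationError, LatticeConfig

__all__ = ["waiting_times", "pn_translation_rate", "pn_simulate", "PetriSchedule"]


def waiting_times(config: LatticeConfig, init_rule: str = "rate-sum",
                  stop=None) -> tuple[float, np.ndarray, float]:
    """(w_init, hop waiting times w_r..w_{n-1}, w_exit).

    With a premature stop at j the hop waiting time there is 1/(mu*gamma_j)
    (the dissociation branch is ignored in this deterministic model).
    """
    n, r = config.n, config.r
    gam = np.array(config.gamma, dtype=float)
    if stop is not None:
        if stop.mu < 0 or stop.mu > 1:
            raise ConfigurationError(f"readthrough mu must lie in [0, 1], got {stop.mu}")
        gam[stop.position - r] = stop.mu * config.gamma_at(stop.position)
    if config.alpha <= 0 or config.beta <= 0 or np.any(gam <= 0):
        raise ConfigurationError("Petri-net comparator needs strictly positive rates")
    early = gam[: min(r, len(gam))]
    if len(early) < r:  # entry window reaches the exit step
        early = np.concatenate([early, [config.beta] * (r - len(early))])
    if init_rule == "rate-sum":
        w_early = 1.0 / early.sum()
    elif init_rule == "wait-sum":
        w_early = float((1.0 / early).sum())
    else:
        raise ConfigurationError(f"unknown init_rule {init_rule!r}")
    w_init = max(1.0 / config.alpha, w_early)
    return w_init, 1.0 / gam, 1.0 / config.beta


def pn_translation_rate(config: LatticeConfig, init_rule: str = "rate-sum",
                        stop=None) -> float:
    """Closed-form steady translation rate 1 / (slowest waiting time)."""
    w_init, w_hop, w_exit = waiting_times(config, init_rule, stop)
    slowest = max(w_init, w_exit, float(w_hop.max()) if len(w_hop) else 0.0)
    return 1.0 / slowest


@dataclass
class PetriSchedule:
    """Deterministic firing schedule and derived steady-state readouts."""

    entry_times: np.ndarray     # one per ribosome
    exit_times: np.ndarray
    rho: np.ndarray             # covered-time fraction per codon (window)
    c: float                    # asymptotic exit rate over the window
    window: tuple[float, float]
    partial: bool = False       # t_end shorter than transient + one period


def pn_simulate(config: LatticeConfig, t_end: float,
                init_rule: str = "rate-sum", stop=None) -> PetriSchedule:
    """Deterministic event-driven simulation up to ``t_end``.

    Max-plus recursion per ribosome k over head positions i = r..n:
        entry_k   = max(entry_{k-1} + w_init, depart_{k-1}(r))
        depart_k(i) = max(arrive_k(i) + w_i, depart_{k-1}(i + 1))
        exit_k    = max(arrive_k(n) + w_exit, exit_{k-1})
    where arrive_k(i+1) = depart_k(i) and heads cannot overtake.
    """
    n, r = config.n, config.r
    w_init, w_hop, w_exit = waiting_times(config, init_rule, stop)

    entries: list[float] = []
    exits: list[float] = []
    departs: list[np.ndarray] = []  # depart time per head position r..n-1
    arrivals: list[np.ndarray] = []  # arrival time per head position r..n
    prev_dep: np.ndarray | None = None
    prev_exit = -np.inf
    prev_entry = -np.inf
    t_guard = 0.0
    while t_guard <= t_end:
        e = prev_entry + w_init if entries else 0.0
        if prev_dep is not None:
            # codon r frees when the predecessor departs it (or exits, r = n)
            e = max(e, prev_dep[0] if len(prev_dep) else prev_exit)
        if e > t_end:
            break
        arr = np.empty(n - r + 1)
        dep = np.empty(n - r)
        arr[0] = e
        for k in range(n - r):      # head position i = r + k
            d = arr[k] + w_hop[k]
            if prev_dep is not None:
                nxt = prev_dep[k + 1] if k + 1 < n - r else prev_exit
                d = max(d, nxt)
            dep[k] = d
            arr[k + 1] = d
        x = max(arr[-1] + w_exit, prev_exit)
        entries.append(e)
        exits.append(x)
        arrivals.append(arr)
        departs.append(dep)
        prev_entry, prev_dep, prev_exit = e, dep, x
        t_guard = e

    entries_a = np.array(entries)
    exits_a = np.array(exits)
    window = (0.5 * t_end, t_end)
    partial = len(exits_a) < 4 or exits_a[min(3, len(exits_a) - 1)] > window[0]

    occ = np.zeros(n)
    lo, hi = window
    for arr, x in zip(arrivals, exits_a):
        # head at position i during [arrive(i), depart(i)); covers i-r+1..i
        times = np.append(arr, x)  # depart(n) := exit
        for k in range(n - r + 1):
            i = r + k
            a, d = times[k], times[k + 1]
            ov = max(0.0, min(d, hi) - max(a, lo))
            if ov > 0:
                occ[i - r:i] += ov
        # codons freed at exit: head leaves codon n at exit time; the span
        # above already credits coverage until the exit firing.
    occ = np.clip(occ / (hi - lo), 0.0, 1.0)

    in_win = exits_a[(exits_a >= lo) & (exits_a < hi)]
    c = len(in_win) / (hi - lo) if hi > lo else 0.0
    return PetriSchedule(entry_times=entries_a, exit_times=exits_a, rho=occ,
                         c=float(c), window=window, partial=bool(partial))
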