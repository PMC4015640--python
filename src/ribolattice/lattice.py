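"""Codon lattice, reachable state space and event semantics.

The mRNA is a 1-D lattice of ``n`` codons; each ribosome covers ``r``
consecutive codons.  The occupancy state is a 0/1 vector ``x`` of length
``n``.  Three kinds of events move ribosomes:

* entry  (rate alpha): needs codons 1..r empty, then occupies them;
* hop at codon i (rate gamma_i, i = r..n-1): the ribosome whose head is at
  codon i advances one codon, freeing codon i-r+1 and filling codon i+1;
* exit (rate beta): the ribosome whose head is at codon n leaves, freeing
  codons n-r+1..n.

With an optional premature stop codon at position j the hop at j splits into
readthrough (rate mu*gamma_j) and premature dissociation (rate
(1-mu)*gamma_j, clearing codons j-r+1..j).

Codon positions are 1-based at every public interface.  States are plain
tuples of ints so they hash and compare naturally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

__all__ = [
    "LatticeConfig",
    "Event",
    "build_events",
    "enumerate_states",
    "count_states",
    "is_reachable",
    "event_allowed",
    "event_allowed_full",
    "allowed_events",
    "apply_event",
    "occurrence_probability",
    "state_to_heads",
    "heads_to_state",
]


class ConfigurationError(ValueError):
    """Invalid lattice or rate configuration."""


class StateError(ValueError):
    """Occupancy vector not reachable under the given configuration."""


@dataclass(frozen=True)
class LatticeConfig:
    """Complete parameterization of the codon-based model.

    Parameters
    ----------
    n : int
        Number of codons (lattice length), ``n >= 1``.
    r : int
        Ribosome footprint in codons, ``1 <= r <= n``.
    alpha : float
        Initiation (entry) rate; ``>= 0``.
    beta : float
        Termination (exit) rate; ``> 0`` whenever the translation rate
        ``c = beta * rho_n`` is requested.
    gamma : float or sequence of float
        Elongation rates ``gamma_i`` for hop events ``i = r..n-1``.  A scalar
        is broadcast to all ``n - r`` hops.
    """

    n: int
    r: int
    alpha: float
    beta: float
    gamma: tuple[float, ...] = field(default=())

    def __init__(self, n: int, r: int, alpha: float, beta: float,
                 gamma: float | Sequence[float] = 1.0):
        if not (isinstance(n, int) and n >= 1):
            raise ConfigurationError(f"n must be an integer >= 1, got {n!r}")
        if not (isinstance(r, int) and 1 <= r <= n):
            raise ConfigurationError(f"r must satisfy 1 <= r <= n={n}, got {r!r}")
        if isinstance(gamma, (int, float)):
            gam = (float(gamma),) * (n - r)
        else:
            gam = tuple(float(g) for g in gamma)
            if len(gam) != n - r:
                raise ConfigurationError(
                    f"gamma must have length n - r = {n - r}, got {len(gam)}")
        for name, val in (("alpha", alpha), ("beta", beta)):
            if not math.isfinite(val) or val < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {val}")
        for g in gam:
            if not math.isfinite(g) or g < 0:
                raise ConfigurationError(f"gamma rates must be finite and >= 0, got {g}")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "alpha", float(alpha))
        object.__setattr__(self, "beta", float(beta))
        object.__setattr__(self, "gamma", gam)

    def gamma_at(self, i: int) -> float:
        """Elongation rate of the hop event at head position ``i`` (1-based)."""
        if not self.r <= i <= self.n - 1:
            raise ConfigurationError(
                f"hop position must lie in {self.r}..{self.n - 1}, got {i}")
        return self.gamma[i - self.r]

    def with_gamma_at(self, i: int, rate: float) -> "LatticeConfig":
        """Copy of this config with ``gamma_i`` replaced."""
        self.gamma_at(i)  # validates i
        gam = list(self.gamma)
        gam[i - self.r] = float(rate)
        return LatticeConfig(self.n, self.r, self.alpha, self.beta, gam)

    @property
    def event_index_set(self) -> tuple[int, ...]:
        """The index set Ie = {0, r, r+1, ..., n} (n - r + 2 members)."""
        return (0, *range(self.r, self.n), self.n)


@dataclass(frozen=True)
class Event:
    """One update event: entry, hop, exit, or premature dissociation.

    ``pos`` is the head position of the acting ribosome (0 for entry by
    convention, ``n`` for exit).  ``rate`` is the event rate carried into
    every solver.  The ``key`` is a stable label used in reports:
    ``"entry"``, ``"hop@i"``, ``"exit"``, ``"dis@j"``.
    """

    kind: str  # "entry" | "hop" | "exit" | "dissociation"
    pos: int
    rate: float

    @property
    def key(self) -> str:
        if self.kind == "entry":
            return "entry"
        if self.kind == "exit":
            return "exit"
        if self.kind == "hop":
            return f"hop@{self.pos}"
        return f"dis@{self.pos}"

    @property
    def index(self) -> int:
        """Paper-style event index: 0 entry, n exit, i for hop at i."""
        return self.pos


def build_events(config: LatticeConfig, stop=None) -> list[Event]:
    """Full event list in canonical order (entry, hops ascending with the
    dissociation event right after its hop, exit).

    ``stop`` is an optional premature-stop specification with attributes
    ``position`` (head position j, r <= j < n) and ``mu`` (readthrough
    probability).  At the stop codon the hop carries rate ``mu*gamma_j`` and
    an extra dissociation event carries rate ``(1-mu)*gamma_j``.
    """
    n, r = config.n, config.r
    events = [Event("entry", 0, config.alpha)]
    for i in range(r, n):
        g = config.gamma_at(i)
        if stop is not None and stop.position == i:
            if not 0.0 <= stop.mu <= 1.0:
                raise ConfigurationError(f"readthrough mu must lie in [0, 1], got {stop.mu}")
            if not r <= stop.position <= n - 1:
                raise ConfigurationError(
                    f"premature stop position must lie in {r}..{n - 1}, got {stop.position}")
            events.append(Event("hop", i, stop.mu * g))
            events.append(Event("dissociation", i, (1.0 - stop.mu) * g))
        else:
            events.append(Event("hop", i, g))
    if stop is not None and not config.r <= stop.position <= n - 1:
        raise ConfigurationError(
            f"premature stop position must lie in {config.r}..{n - 1}, got {stop.position}")
    events.append(Event("exit", n, config.beta))
    return events


# ---------------------------------------------------------------------------
# state space


def state_to_heads(x: Sequence[int], r: int) -> tuple[int, ...]:
    """Decompose occupancy vector ``x`` into ribosome head positions.

    Raises :class:`StateError` if the occupied codons are not a disjoint
    union of runs of exactly ``r`` consecutive 1s.
    """
    heads = []
    n = len(x)
    i = 0
    while i < n:
        if x[i]:
            run = 0
            while i < n and x[i]:
                run += 1
                i += 1
                if run == r:
                    break
            if run != r:
                raise StateError(f"state {tuple(x)} is not a union of length-{r} runs")
            heads.append(i)  # i is now 1-based head position
        else:
            i += 1
    return tuple(heads)


def heads_to_state(heads: Iterable[int], n: int, r: int) -> tuple[int, ...]:
    """Occupancy vector with ribosome heads at the given 1-based positions."""
    x = [0] * n
    for h in heads:
        if not r <= h <= n:
            raise StateError(f"head position {h} outside {r}..{n}")
        for k in range(h - r, h):
            if x[k]:
                raise StateError(f"overlapping ribosomes at head {h}")
            x[k] = 1
    return tuple(x)


def is_reachable(x: Sequence[int], config: LatticeConfig) -> bool:
    """True iff ``x`` is a valid occupancy state (disjoint length-r runs)."""
    if len(x) != config.n or any(v not in (0, 1) for v in x):
        return False
    try:
        state_to_heads(x, config.r)
    except StateError:
        return False
    return True


def count_states(n: int, r: int) -> int:
    """Closed-form reachable-state count: sum_k C(n - k*r + k, k)."""
    total = 0
    k = 0
    while k * r <= n:
        total += math.comb(n - k * r + k, k)
        k += 1
    return total


def enumerate_states(config: LatticeConfig) -> list[tuple[int, ...]]:
    """All reachable occupancy states, exactly once, in canonical order.

    Canonical order: ribosome count descending, then lexicographically by the
    tuple of head positions.  For the 2-codon, r=1 lattice this yields
    ``[1 1], [1 0], [0 1], [0 0]``.
    """
    n, r = config.n, config.r
    kmax = n // r
    states: list[tuple[int, ...]] = []
    for k in range(kmax, -1, -1):
        # heads h_1 < ... < h_k with h_1 >= r, h_{m+1} >= h_m + r, h_k <= n:
        # substitute u_m = h_m - (m-1)*(r-1) to get a plain combination.
        for combo in combinations(range(r, n - (k - 1) * (r - 1) + 1), k):
            heads = tuple(h + m * (r - 1) for m, h in enumerate(combo))
            states.append(heads_to_state(heads, n, r))
    return states


# ---------------------------------------------------------------------------
# event applicability and application


def event_allowed(x: Sequence[int], event: Event, config: LatticeConfig) -> bool:
    """Reduced occurrence predicate, valid on reachable states.

    On the reachable state space the full-window conditions reduce to:
    entry iff codon r empty; hop/dissociation at i iff codon i occupied and
    codon i+1 empty; exit iff codon n occupied.
    """
    n, r = config.n, config.r
    if event.kind == "entry":
        return x[r - 1] == 0
    if event.kind == "exit":
        return x[n - 1] == 1
    i = event.pos
    return x[i - 1] == 1 and x[i] == 0


def event_allowed_full(x: Sequence[int], event: Event, config: LatticeConfig) -> bool:
    """Full-window occurrence predicate (cross-check oracle).

    Entry requires codons 1..r all empty; exit requires codons n-r+1..n all
    occupied; a hop (or dissociation) at i requires codons i-r+1..i occupied
    and codon i+1 empty.
    """
    n, r = config.n, config.r
    if event.kind == "entry":
        return all(x[k] == 0 for k in range(r))
    if event.kind == "exit":
        return all(x[k] == 1 for k in range(n - r, n))
    i = event.pos
    return all(x[k] == 1 for k in range(i - r, i)) and x[i] == 0


def allowed_events(x: Sequence[int], config: LatticeConfig, stop=None,
                   events: Sequence[Event] | None = None) -> list[Event]:
    """The allowed event set Ie(x), in canonical event order.

    Raises :class:`StateError` for unreachable ``x``.
    """
    if not is_reachable(x, config):
        raise StateError(f"state {tuple(x)} unreachable for n={config.n}, r={config.r}")
    if events is None:
        events = build_events(config, stop)
    return [e for e in events if event_allowed(x, e, config)]


def apply_event(x: Sequence[int], event: Event, config: LatticeConfig) -> tuple[int, ...]:
    """Apply ``event`` to ``x``; identity when the event is not allowed.

    Total on reachable states and closed over the reachable state space.
    """
    if not event_allowed(x, event, config):
        return tuple(x)
    n, r = config.n, config.r
    y = list(x)
    if event.kind == "entry":
        for k in range(r):
            y[k] = 1
    elif event.kind == "exit":
        for k in range(n - r, n):
            y[k] = 0
    elif event.kind == "hop":
        i = event.pos
        y[i - r] = 0
        y[i] = 1
    else:  # premature dissociation: clear the whole footprint
        j = event.pos
        for k in range(j - r, j):
            y[k] = 0
    return tuple(y)


def occurrence_probability(x: Sequence[int], event: Event, config: LatticeConfig) -> int:
    """psi_i(x) on a single state: 1 if the event is allowed, else 0.

    The actual event rate is ``psi_i(x) * gamma_i``.
    """
    return 1 if event_allowed(x, event, config) else 0
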