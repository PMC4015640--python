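"""Exact stationary solver via the probabilistic-Boolean-network formulation.

The random-sequential dynamics with event-selection probabilities
``p_i = gamma_i / sum(gamma)`` (the efficient fixed-time-step scheme) is a
discrete-time Markov chain over the reachable occupancy states.  Each event
``e_i`` acts as a deterministic Boolean function on the state (the identity
where the event is disallowed), so it has a 0/1 column-stochastic transition
matrix ``M_i``; the chain's transition matrix is the probability-weighted
average ``M_E = sum_i p_i M_i``.  This chain is the uniformization
``I + Q / sum(gamma)`` of the continuous-time model, hence its stationary
law ``pi`` equals the continuous-time stationary law, and

    rho = sum_i pi_i * chi_i          (codon densities)
    c   = beta * rho_n                (translation rate)

are exact, with no Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .lattice import (
    ConfigurationError,
    Event,
    LatticeConfig,
    build_events,
    enumerate_states,
)

__all__ = [
    "boolean_event_rule",
    "build_event_matrix",
    "build_transition_matrix",
    "stationary_distribution",
    "power_iteration",
    "steady_state_profiles",
    "solve",
    "rank_states",
    "rate_sensitivity",
    "average_occurrence_probability",
    "StationarySolution",
    "AveragedTransitionMatrix",
]


class ReducibleChainError(RuntimeError):
    """The averaged chain has no unique recurrent class."""


@dataclass(frozen=True)
class AveragedTransitionMatrix:
    """Column-stochastic M_E over the canonical reachable-state order."""

    matrix: sp.csc_matrix
    states: tuple[tuple[int, ...], ...]
    events: tuple[Event, ...]
    probabilities: tuple[float, ...]
    config: LatticeConfig


@dataclass(frozen=True)
class StationarySolution:
    """Exact stationary state density and derived steady-state profiles."""

    states: tuple[tuple[int, ...], ...]
    pi: np.ndarray      # stationary probability per state
    rho: np.ndarray     # codon densities rho_1..rho_n
    c: float            # translation rate beta * rho_n
    config: LatticeConfig


def boolean_event_rule(event: Event, config: LatticeConfig) -> Callable[[Sequence[int]], tuple[int, ...]]:
    """The per-codon Boolean update function of one event.

    These are the conjunction/disjunction/negation forms (independent of the
    predicate-plus-shift semantics in :mod:`ribolattice.lattice`, against
    which they are tested exhaustively):

    * entry:  y_k = (NOT x_r) OR x_k for k = 1..r, identity elsewhere;
    * exit:   y_k = (NOT x_n) AND x_k for k = n-r+1..n, identity elsewhere;
    * hop j:  y_{j-r+1} = ((NOT x_j) OR x_{j+1}) AND x_{j-r+1},
              y_{j+1}   = (x_j AND NOT x_{j+1}) OR x_{j+1}, identity elsewhere;
    * dissociation j: y_k = ((NOT x_j) OR x_{j+1}) AND x_k for
              k = j-r+1..j, identity elsewhere.
    """
    n, r = config.n, config.r

    if event.kind == "entry":
        def rule(x):
            fire = 1 - x[r - 1]
            return tuple((fire | x[k]) if k < r else x[k] for k in range(n))
    elif event.kind == "exit":
        def rule(x):
            keep = 1 - x[n - 1]
            return tuple((keep & x[k]) if k >= n - r else x[k] for k in range(n))
    elif event.kind == "hop":
        j = event.pos

        def rule(x):
            keep = (1 - x[j - 1]) | x[j]
            y = list(x)
            y[j - r] = keep & x[j - r]
            y[j] = (x[j - 1] & (1 - x[j])) | x[j]
            return tuple(y)
    elif event.kind == "dissociation":
        j = event.pos

        def rule(x):
            keep = (1 - x[j - 1]) | x[j]
            return tuple((keep & x[k]) if j - r <= k < j else x[k] for k in range(n))
    else:  # pragma: no cover
        raise ValueError(f"unknown event kind {event.kind!r}")
    return rule


def build_event_matrix(event: Event, states: Sequence[tuple[int, ...]],
                       config: LatticeConfig) -> sp.csc_matrix:
    """0/1 column-stochastic matrix of one event's Boolean rule.

    Column j holds the indicator of the image of state chi_j (identity
    column where the event is disallowed).
    """
    index = {s: k for k, s in enumerate(states)}
    rule = boolean_event_rule(event, config)
    m = len(states)
    rows = np.empty(m, dtype=np.int64)
    for j, s in enumerate(states):
        rows[j] = index[rule(s)]
    data = np.ones(m)
    indptr = np.arange(m + 1)
    return sp.csc_matrix((data, rows, indptr), shape=(m, m))


def build_transition_matrix(config: LatticeConfig, stop=None) -> AveragedTransitionMatrix:
    """Assemble M_E = sum_i (gamma_i / sum gamma) M_i over reachable states."""
    events = build_events(config, stop)
    total = sum(e.rate for e in events)
    if total <= 0:
        raise ConfigurationError("total event rate must be positive")
    states = tuple(enumerate_states(config))
    probs = tuple(e.rate / total for e in events)
    m_e = sp.csc_matrix((len(states), len(states)))
    for e, p in zip(events, probs):
        if p > 0:
            m_e = m_e + p * build_event_matrix(e, states, config)
    return AveragedTransitionMatrix(sp.csc_matrix(m_e), states, tuple(events),
                                    probs, config)


def _terminal_class(M: sp.csc_matrix) -> np.ndarray:
    """Indices of the unique recurrent class of the chain, else raise."""
    m = M.shape[0]
    ncomp, labels = connected_components(M.T, directed=True, connection="strong")
    if ncomp == 1:
        return np.arange(m)
    # terminal components: no outgoing edge M[i, j] > 0 with label[i] != label[j]
    coo = M.tocoo()
    outgoing = set()
    for i, j in zip(coo.row, coo.col):
        if labels[i] != labels[j]:
            outgoing.add(labels[j])
    terminal = [c for c in range(ncomp) if c not in outgoing]
    if len(terminal) != 1:
        raise ReducibleChainError(
            f"chain has {len(terminal)} terminal classes; stationary law not unique")
    return np.flatnonzero(labels == terminal[0])


def stationary_distribution(M: AveragedTransitionMatrix | sp.spmatrix,
                            method: str = "linear",
                            tol: float = 1e-12, maxiter: int = 200000) -> np.ndarray:
    """Solve M_E pi = pi with sum(pi) = 1, pi >= 0.

    ``method='linear'`` (default) solves the rank-deficient linear system
    with the normalization replacing one equation; ``method='power'``
    iterates ``pi <- M_E pi`` to relative tolerance ``tol`` (the limit form
    of the stationary law).  On a reducible chain with a unique terminal
    class the solve is restricted to that class and transient states get
    probability 0.
    """
    A = M.matrix if isinstance(M, AveragedTransitionMatrix) else sp.csc_matrix(M)
    m = A.shape[0]
    keep = _terminal_class(A)
    sub = A[np.ix_(keep, keep)] if len(keep) < m else A
    k = sub.shape[0]
    if method == "linear":
        rhs = np.zeros(k)
        rhs[-1] = 1.0
        if k <= 400:
            system = sub.toarray() - np.eye(k)
            system[-1, :] = 1.0
            pi_sub = np.linalg.solve(system, rhs)
        else:
            system = (sub - sp.identity(k, format="csc")).tolil()
            system[-1, :] = 1.0
            pi_sub = sp.linalg.spsolve(system.tocsc(), rhs)
    elif method == "power":
        pi_sub = np.full(k, 1.0 / k)
        dense = sub.tocsr()
        for _ in range(maxiter):
            nxt = dense @ pi_sub
            nxt /= nxt.sum()
            if np.max(np.abs(nxt - pi_sub)) <= tol * max(1.0, np.max(np.abs(nxt))):
                pi_sub = nxt
                break
            pi_sub = nxt
        else:
            raise RuntimeError("power iteration did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")
    pi_sub = np.clip(pi_sub, 0.0, None)
    pi_sub /= pi_sub.sum()
    pi = np.zeros(m)
    pi[keep] = pi_sub
    return pi


power_iteration = lambda M, **kw: stationary_distribution(M, method="power", **kw)  # noqa: E731


def steady_state_profiles(pi: np.ndarray, states: Sequence[tuple[int, ...]],
                          config: LatticeConfig) -> StationarySolution:
    """Codon densities rho = sum_i pi_i chi_i and translation rate c = beta rho_n."""
    chi = np.asarray(states, dtype=float)
    rho = pi @ chi
    c = config.beta * rho[-1]
    return StationarySolution(tuple(states), np.asarray(pi, dtype=float), rho, float(c), config)


def solve(config: LatticeConfig, stop=None, method: str = "linear") -> StationarySolution:
    """Build M_E, solve for pi and return the full stationary solution."""
    M = build_transition_matrix(config, stop)
    pi = stationary_distribution(M, method=method)
    return steady_state_profiles(pi, M.states, config)


class CachedSolver:
    """Repeated exact solves that vary only the initiation rate.

    The reachable states and per-event matrices depend on (n, r) and the
    event set but not on the rates, so they are built once; each call
    reassembles M_E with the new probability weights and re-solves.
    """

    def __init__(self, config: LatticeConfig, stop=None):
        self.config = config
        self.stop = stop
        self.states = tuple(enumerate_states(config))
        self.events = build_events(config, stop)
        self.matrices = [build_event_matrix(e, self.states, config)
                         for e in self.events]

    def solve_alpha(self, alpha: float) -> StationarySolution:
        cfg = LatticeConfig(self.config.n, self.config.r, alpha,
                            self.config.beta, self.config.gamma)
        rates = np.array([alpha if e.kind == "entry" else e.rate
                          for e in self.events])
        total = rates.sum()
        if total <= 0:
            raise ConfigurationError("total event rate must be positive")
        m_e = sum((p * M for p, M in zip(rates / total, self.matrices) if p > 0),
                  start=sp.csc_matrix((len(self.states), len(self.states))))
        pi = stationary_distribution(sp.csc_matrix(m_e))
        return steady_state_profiles(pi, self.states, cfg)


def average_occurrence_probability(sol: StationarySolution, event: Event) -> float:
    """Stationary mean occurrence probability psi_bar_i = <psi_i(x)>_pi."""
    from .lattice import occurrence_probability
    return float(sum(p * occurrence_probability(s, event, sol.config)
                     for p, s in zip(sol.pi, sol.states)))


def rank_states(sol: StationarySolution, k: int = 1):
    """The k most and k least probable states (ties broken by canonical order).

    Returns ``(top, bottom)`` where each is a list of ``(state, density)``.
    """
    m = len(sol.states)
    k = min(k, m)
    order = sorted(range(m), key=lambda i: (-sol.pi[i], i))
    top = [(sol.states[i], float(sol.pi[i])) for i in order[:k]]
    order_low = sorted(range(m), key=lambda i: (sol.pi[i], i))
    bottom = [(sol.states[i], float(sol.pi[i])) for i in order_low[:k]]
    return top, bottom


def rate_sensitivity(config: LatticeConfig, target: str, event: Event,
                     delta: float, stop=None) -> float:
    """Central finite-difference sensitivity of a steady-state target.

    ``target`` is ``'c'``, ``'rho_i'`` (codon i, 1-based) or ``'pi_j'``
    (canonical state index j, 1-based).  ``event`` names the perturbed rate
    (entry -> alpha, exit -> beta, hop at i -> gamma_i).  Two exact solves,
    no Monte-Carlo noise.
    """

    def perturbed(eps: float) -> LatticeConfig:
        if event.kind == "entry":
            val = config.alpha + eps
            if val <= 0 and eps < 0:
                raise ConfigurationError(f"delta={delta} makes alpha non-positive")
            return LatticeConfig(config.n, config.r, val, config.beta, config.gamma)
        if event.kind == "exit":
            val = config.beta + eps
            if val <= 0:
                raise ConfigurationError(f"delta={delta} makes beta non-positive")
            return LatticeConfig(config.n, config.r, config.alpha, val, config.gamma)
        val = config.gamma_at(event.pos) + eps
        if val <= 0:
            raise ConfigurationError(f"delta={delta} makes gamma_{event.pos} non-positive")
        return config.with_gamma_at(event.pos, val)

    def read(sol: StationarySolution) -> float:
        if target == "c":
            return sol.c
        kind, _, idx = target.partition("_")
        i = int(idx)
        if kind == "rho":
            return float(sol.rho[i - 1])
        if kind == "pi":
            return float(sol.pi[i - 1])
        raise ValueError(f"unknown target {target!r}")

    hi = solve(perturbed(+delta), stop)
    lo = solve(perturbed(-delta), stop)
    return (read(hi) - read(lo)) / (2.0 * delta)
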