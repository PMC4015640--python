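"""Regulatory extensions: slow codons, premature stop codons, initiation feedback.

Slow codons are plain rate edits of the elongation profile.  A premature
stop codon at position ``j`` splits the hop attempt there into readthrough
(rate ``mu * gamma_j``, a normal hop) and premature dissociation (rate
``(1 - mu) * gamma_j``, clearing the ribosome's footprint); the extra event
integrates into the event set consumed by every simulator and by the exact
solver.

Negative autoregulation of initiation couples the protein concentration
``rho_I`` back into the initiation rate,

    alpha = alpha_I / (1 + k_I * rho_I),
    d rho_I / dt = c * rho_m - d_I * rho_I,

and is solved two ways: a damped self-consistent fixed point over any
steady-state backend (the exact solver by default), and a fully stochastic
coupling where ``rho_I`` is advanced inside the random-sequential
(varying-step) simulation loop.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from . import pbn
from .lattice import ConfigurationError, LatticeConfig
from .simulate import Kernel, SimulationConfig, SimulationSummary, _accumulate

__all__ = [
    "PrematureStopSpec",
    "FeedbackSpec",
    "FeedbackSimResult",
    "make_slow_profile",
    "feedback_fixed_point",
    "feedback_stochastic_sim",
]


@dataclass(frozen=True)
class PrematureStopSpec:
    """Premature stop codon at head position ``position`` with readthrough ``mu``."""

    position: int
    mu: float

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigurationError(f"readthrough mu must lie in [0, 1], got {self.mu}")


@dataclass
class FeedbackSimResult:
    """Summary plus the protein-concentration path of a coupled run."""

    summary: SimulationSummary
    trace_t: np.ndarray       # cumulative simulated time after each recorded step
    trace_rho: np.ndarray     # rho_I sampled at each recorded step end
    rho_I_mean: float         # exact time average of rho_I over the window


@dataclass(frozen=True)
class FeedbackSpec:
    """Initiation autoregulation parameters.

    ``alpha_I`` is the maximal initiation rate (protein-free limit), ``k_I``
    the autoregulation strength, ``d_I`` the protein degradation rate and
    ``rho_m`` the (constant) mRNA concentration.
    """

    alpha_I: float
    k_I: float
    d_I: float
    rho_m: float = 1.0

    def __post_init__(self):
        if self.alpha_I < 0 or self.k_I < 0:
            raise ConfigurationError("alpha_I and k_I must be >= 0")
        if self.d_I <= 0 or self.rho_m <= 0:
            raise ConfigurationError("d_I and rho_m must be > 0")

    def alpha(self, rho_I: float) -> float:
        return self.alpha_I / (1.0 + self.k_I * rho_I)


def make_slow_profile(config: LatticeConfig, positions: Iterable[int],
                      slow_rate: float) -> LatticeConfig:
    """Replace ``gamma`` at the given 1-based head positions by ``slow_rate``."""
    out = config
    for pos in positions:
        out = out.with_gamma_at(pos, slow_rate)
    return out


def premature_dissociation_rule(spec: PrematureStopSpec, config: LatticeConfig):
    """State-to-state function and rate of the dissociation branch.

    Clears codons j-r+1..j when codon j is occupied and codon j+1 empty,
    identity otherwise; fires at rate (1 - mu) * gamma_j.
    """
    from .lattice import Event
    event = Event("dissociation", spec.position,
                  (1.0 - spec.mu) * config.gamma_at(spec.position))
    rule = pbn.boolean_event_rule(event, config)
    return rule, event.rate


def feedback_fixed_point(spec: FeedbackSpec, config: LatticeConfig,
                         solver: Callable[[float], float] | None = None,
                         damping: float = 0.5, tol: float = 1e-10,
                         max_iter: int = 500) -> tuple[float, float, float]:
    """Self-consistent steady state (alpha*, c*, rho_I*) of the feedback loop.

    ``solver`` maps an initiation rate to a steady translation rate; the
    exact solver is the default.  Iterates
    rho_I <- (1 - damping) * rho_I + damping * c(alpha) * rho_m / d_I with
    alpha recomputed each round, until successive rho_I differ by <= tol.
    """
    if solver is None:
        cached = pbn.CachedSolver(config)

        def solver(alpha: float) -> float:
            return cached.solve_alpha(alpha).c

    rho_i = 0.0
    trace = []
    for _ in range(max_iter):
        alpha = spec.alpha(rho_i)
        c = solver(alpha)
        target = c * spec.rho_m / spec.d_I
        new = (1.0 - damping) * rho_i + damping * target
        trace.append((alpha, c, new))
        if abs(new - rho_i) <= tol * max(1.0, abs(new)):
            return spec.alpha(new), solver(spec.alpha(new)), new
        rho_i = new
    raise RuntimeError(
        f"feedback fixed point did not converge in {max_iter} iterations; "
        f"last iterates: {trace[-3:]}")


def feedback_stochastic_sim(spec: FeedbackSpec, config: LatticeConfig,
                            sim: SimulationConfig, scheme: str = "event",
                            rho_I0: float = 0.0):
    """Random-sequential simulation with the protein concentration coupled in.

    At every varying-dt step the protein degrades by the exact interval
    factor ``rho_I <- rho_I * exp(-d_I * dt)`` and, under the default
    ``scheme='event'``, gains ``rho_m`` per completed exit event; under
    ``scheme='euler'`` production uses the running translation-rate estimate
    instead (``rho_I += c_hat * rho_m * dt``).  The initiation rate is
    recomputed from rho_I before each event draw.

    Returns a :class:`FeedbackSimResult`; its ``rho_I_mean`` is the exact
    time average of the piecewise-exponential rho_I path over the recorded
    window (the per-step trace samples the path only at step ends).
    """
    if sim.canonical_algorithm() != "efficient-varying":
        raise ValueError("stochastic feedback coupling requires the "
                         "varying-step random-sequential algorithm")
    if scheme not in ("event", "euler"):
        raise ValueError(f"unknown scheme {scheme!r}")
    burn_in = sim.resolved_burn_in()
    kern = Kernel(config)
    rng = np.random.default_rng(sim.seed)
    n, r = kern.n, kern.r
    rates = kern.rates.copy()

    heads: list[int] = []
    rho_I = float(rho_I0)
    occ = np.zeros(n)
    time_acc = 0.0
    ribo_time = 0.0
    exits = 0
    all_exits = 0
    all_time = 0.0
    counts: dict[str, int] = {}
    trace_t: list[float] = []
    trace_rho: list[float] = []
    rho_int = 0.0             # exact integral of rho_I over recorded time
    degenerate = False

    for step in range(sim.steps):
        rates[kern.entry_idx] = spec.alpha(rho_I)
        allowed = kern.allowed(heads)
        pos = [idx for idx in allowed if rates[idx] > 0]
        tot = float(rates[pos].sum()) if pos else 0.0
        if tot <= 0:
            degenerate = True
            break
        dt = 1.0 / tot
        u = rng.random() * tot
        acc = 0.0
        fired = pos[-1]
        for idx in pos:
            acc += rates[idx]
            if u < acc:
                fired = idx
                break

        record = step >= burn_in
        if record:
            _accumulate(occ, heads, dt, r)
            ribo_time += len(heads) * dt
            time_acc += dt

        is_exit = kern.events[fired].kind == "exit"
        kern.apply(heads, fired)
        all_time += dt
        if is_exit:
            all_exits += 1
        if record:
            key = kern.events[fired].key
            counts[key] = counts.get(key, 0) + 1
            if is_exit:
                exits += 1

        # protein bookkeeping over this step's dt; degradation is integrated
        # exactly over the interval (the first-order Euler factor 1 - d_I*dt
        # over-decays at the coarse varying steps of small lattices)
        decay = np.exp(-spec.d_I * dt)
        if record:
            rho_int += rho_I * (1.0 - decay) / spec.d_I
        rho_I *= decay
        if scheme == "event":
            if is_exit:
                rho_I += spec.rho_m
        else:
            c_hat = all_exits / all_time if all_time > 0 else 0.0
            rho_I += c_hat * spec.rho_m * dt
        if record:
            trace_t.append(all_time)
            trace_rho.append(rho_I)

    if time_acc <= 0:
        summary = SimulationSummary(rho=np.zeros(n), c=0.0, mean_occupancy=0.0,
                                    total_time=0.0, n_events={}, degenerate=True,
                                    algorithm="efficient-varying", seed=sim.seed,
                                    steps=sim.steps, burn_in=burn_in)
        return FeedbackSimResult(summary, np.array(trace_t), np.array(trace_rho), 0.0)
    summary = SimulationSummary(
        rho=occ / time_acc,
        c=exits / time_acc,
        mean_occupancy=ribo_time / time_acc,
        total_time=time_acc,
        n_events=counts,
        degenerate=degenerate,
        algorithm="efficient-varying",
        seed=sim.seed,
        steps=sim.steps,
        burn_in=burn_in,
    )
    return FeedbackSimResult(summary, np.array(trace_t), np.array(trace_rho),
                             rho_int / time_acc)
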