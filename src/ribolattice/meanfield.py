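"""Heinrich–Rapoport mean-field model of ribosome traffic.

The state variables are head-occupancy probabilities ``h_i`` (probability
that codon ``i`` carries the head of a ribosome, ``i = r..n``).  Fluxes are
closed with conditional vacancy probabilities

    W_0 = 1 - sum_{s=r}^{min(2r-1, n)} h_s                 (entry window)
    W_i = (1 - sum_{s=1}^{r} h_{i+s}) / (1 - sum_{s=1}^{r-1} h_{i+s}),
                                            r <= i <= n-r
    W_i = 1,  i > n-r        (with h_i = 0 for i > n)

so that  c_0 = gamma_0 rho_m rho_r W_0,  c_i = gamma_i rho_m h_i W_i and
c_n = gamma_n rho_m h_n.  The transient dynamics is
rho_m dh_i/dt = c_{i-1} - c_i (with c_{r-1} meaning the entry flux c_0);
at steady state all fluxes balance:  gamma_0 W_0 = gamma_i h_i W_i
= gamma_n h_n = c (per unit mRNA, rho_r = 1).

The steady state closes in the single scalar unknown ``c``: given a trial
``c``, the profile follows from h_i = c/gamma_i for the last r codons and a
backward recursion, and the entry relation returns the initiation rate that
would sustain that ``c``; the solver root-finds implied-alpha(c) = alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .lattice import ConfigurationError, LatticeConfig

__all__ = ["MeanFieldParams", "MeanFieldState", "mf_fluxes", "mf_integrate",
           "mf_steady_state", "implied_alpha", "head_to_codon_density"]


@dataclass(frozen=True)
class MeanFieldParams:
    """Lattice rates plus mRNA / free-ribosome concentrations."""

    config: LatticeConfig
    rho_m: float = 1.0
    rho_r: float = 1.0

    def __post_init__(self):
        if self.rho_m <= 0 or self.rho_r <= 0:
            raise ConfigurationError("rho_m and rho_r must be positive")


@dataclass(frozen=True)
class MeanFieldState:
    """Head occupancies, vacancy probabilities, fluxes and translation rate."""

    h: np.ndarray        # h_i for i = r..n  (length n - r + 1)
    W: np.ndarray        # W_0, W_r..W_{n-1}, W_n  (length n - r + 2)
    c_flux: np.ndarray   # c_0, c_r..c_{n-1}, c_n  (length n - r + 2)
    c: float             # steady translation rate per mRNA


class InvalidProfileError(ValueError):
    """Head-occupancy profile leaves the physical domain."""


def _rates(config: LatticeConfig) -> np.ndarray:
    """gamma_0=alpha, gamma_r..gamma_{n-1}, gamma_n=beta."""
    return np.array([config.alpha, *config.gamma, config.beta])


def _vacancies(h: np.ndarray, config: LatticeConfig) -> np.ndarray:
    """W_0 and W_i for i = r..n per the closure above."""
    n, r = config.n, config.r
    hp = np.zeros(n + r + 2)          # hp[i] = h_i, 1-based, 0 beyond n
    hp[r:n + 1] = h
    W = np.ones(n - r + 2)
    W[0] = 1.0 - hp[r:min(2 * r - 1, n) + 1].sum()
    for i in range(r, n - r + 1):     # slot 1.. covers i = r..n-r
        num = 1.0 - hp[i + 1:i + r + 1].sum()
        den = 1.0 - hp[i + 1:i + r].sum()
        if den <= 0:
            raise InvalidProfileError(f"vacancy denominator <= 0 at codon {i}")
        W[i - r + 1] = num / den
    return W


def mf_fluxes(h: np.ndarray, params: MeanFieldParams) -> np.ndarray:
    """Fluxes c_0, c_r..c_{n-1}, c_n for a head-occupancy profile."""
    cfg = params.config
    g = _rates(cfg)
    W = _vacancies(np.asarray(h, dtype=float), cfg)
    c = np.empty_like(g)
    c[0] = g[0] * params.rho_m * params.rho_r * W[0]
    c[1:-1] = g[1:-1] * params.rho_m * h[:-1] * W[1:-1]
    c[-1] = g[-1] * params.rho_m * h[-1]
    return c


def mf_integrate(params: MeanFieldParams, t_end: float,
                 h0: np.ndarray | None = None, rtol: float = 1e-10,
                 atol: float = 1e-12):
    """Integrate rho_m dh_i/dt = c_{i-1} - c_i to ``t_end``.

    Returns the scipy ``OdeResult``; ``result.y[:, -1]`` is the terminal
    profile (near a fixed point for large ``t_end``).
    """
    cfg = params.config
    m = cfg.n - cfg.r + 1
    y0 = np.zeros(m) if h0 is None else np.asarray(h0, dtype=float)

    def rhs(_t, h):
        c = mf_fluxes(h, params)
        return (c[:-1] - c[1:]) / params.rho_m

    result = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol)
    if not result.success:
        raise RuntimeError(f"mean-field integration failed: {result.message}")
    return result


def _profile_for_c(c: float, config: LatticeConfig) -> np.ndarray:
    """Backward recursion: the head profile sustaining translation rate c.

    h_i = c/gamma_i for i = n-r+1..n, then
    h_i = c (1 - sum_{s=1}^{r-1} h_{i+s}) / (gamma_i (1 - sum_{s=1}^{r} h_{i+s}))
    for i = n-r down to r.  Raises InvalidProfileError when the profile
    leaves [0, 1] or a denominator closes.
    """
    n, r = config.n, config.r
    g = _rates(config)
    hp = np.zeros(n + 2)
    for i in range(n, n - r, -1):     # i = n-r+1..n
        gi = g[-1] if i == n else config.gamma_at(i)
        hp[i] = c / gi
        if not 0.0 <= hp[i] <= 1.0:
            raise InvalidProfileError(f"h_{i} = {hp[i]:.4g} outside [0, 1]")
    for i in range(n - r, r - 1, -1):
        den_sum = hp[i + 1:i + r + 1].sum()
        num_sum = hp[i + 1:i + r].sum()
        den = config.gamma_at(i) * (1.0 - den_sum)
        if den <= 0:
            raise InvalidProfileError(f"denominator closed at codon {i}")
        hp[i] = c * (1.0 - num_sum) / den
        if not 0.0 <= hp[i] <= 1.0:
            raise InvalidProfileError(f"h_{i} = {hp[i]:.4g} outside [0, 1]")
    return hp[r:n + 1]


def implied_alpha(c: float, config: LatticeConfig) -> float:
    """Initiation rate that would sustain translation rate ``c``.

    gamma_0 = c / W_0 evaluated on the backward-recursion profile; returns
    ``inf`` when the profile is unphysical (c beyond the attainable branch).
    """
    if c == 0.0:
        return 0.0
    try:
        h = _profile_for_c(c, config)
    except InvalidProfileError:
        return np.inf
    n, r = config.n, config.r
    w0 = 1.0 - h[:min(2 * r - 1, n) - r + 1].sum()
    if w0 <= 0:
        return np.inf
    return c / w0


def mf_steady_state(params: MeanFieldParams) -> MeanFieldState:
    """Solve the steady-state relations by a bracketed root-find on ``c``.

    ``implied_alpha`` is monotone increasing on the physical (low-density)
    branch and spans (0, inf), so a bisection bracket always exists below
    ``min_i gamma_i``.  The smallest physical root is returned.
    """
    cfg = params.config
    alpha = cfg.alpha
    if alpha == 0.0:
        m = cfg.n - cfg.r + 1
        h = np.zeros(m)
        W = _vacancies(h, cfg)
        flux = mf_fluxes(h, params)
        return MeanFieldState(h=h, W=W, c_flux=flux, c=0.0)
    g = _rates(cfg)
    c_cap = float(g.min()) * (1.0 - 1e-12)

    def f(c):
        ia = implied_alpha(c, cfg)
        return ia - alpha if np.isfinite(ia) else np.inf

    # expand an upper bracket: smallest c with implied_alpha(c) >= alpha
    lo = 0.0
    hi = c_cap
    if f(hi) < 0:  # even the fastest physical profile needs less initiation
        c_star = hi
    else:
        # bisect on the sign change of f (monotone on the physical branch);
        # inf values act as positive
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-15 * max(1.0, c_cap):
                break
        if np.isfinite(f(hi)):
            c_star = brentq(f, lo if lo > 0 else 1e-300, hi, xtol=1e-15, rtol=1e-15)
        else:
            c_star = lo
    if c_star <= 0:
        raise RuntimeError(
            f"no steady-state root in (0, {c_cap:.4g}) for alpha={alpha}")
    h = _profile_for_c(c_star, cfg)
    W = _vacancies(h, cfg)
    flux = mf_fluxes(h, params)
    return MeanFieldState(h=h, W=W, c_flux=flux, c=float(c_star))


def head_to_codon_density(h: np.ndarray, config: LatticeConfig) -> np.ndarray:
    """Codon densities rho_m = sum_{s=0}^{r-1} h_{m+s} from head occupancies."""
    n, r = config.n, config.r
    hp = np.zeros(n + r + 1)
    hp[r:n + 1] = h
    return np.array([hp[m:m + r].sum() for m in range(1, n + 1)])
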