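# Methods

## The codon-based model

An mRNA of `n` codons is a 1-D lattice; a ribosome covers `r` consecutive
codons and is identified by its head position (the rightmost covered codon).
The occupancy state is a 0/1 vector `x` of length `n`. Three event families
move ribosomes, indexed by the head position at which they act
(`Ie = {0, r, r+1, …, n}`, `n − r + 2` events):

| event | rate | occurrence condition | effect |
|---|---|---|---|
| entry (`i = 0`) | `α` | codons `1..r` empty | occupy `1..r` |
| hop at `i` (`r ≤ i ≤ n−1`) | `γ_i` | codon `i` occupied, `i+1` empty | free `i−r+1`, fill `i+1` |
| exit (`i = n`) | `β` | codon `n` occupied | free `n−r+1..n` |

The rate law is `p_i(x) = ψ_i(x)·γ_i`, with `ψ_i(x)` the 0/1 indicator of
the occurrence condition. On reachable states (disjoint unions of length-`r`
runs) the full-window conditions reduce to single-codon tests; both forms
are implemented and their equivalence is asserted exhaustively in the test
suite. The reachable-state count is `Σ_k C(n − k·r + k, k)` (1113 states at
`n = 50`, `r = 12`).

Canonical state order (a convention of this package — the source model fixes
it only for the 2-codon example): ribosome count descending, then
lexicographically by head-position tuples. For `n = 2, r = 1` this yields
`[1 1], [1 0], [0 1], [0 0]`, making printed matrices directly comparable.

## Exact stationary solver

Each event acts as a deterministic Boolean function on the state (identity
where disallowed): entry `y_k = ¬x_r ∨ x_k` (`k ≤ r`); exit
`y_k = ¬x_n ∧ x_k` (`k > n−r`); hop at `j` clears `j−r+1` and fills `j+1`
under the guard `x_j ∧ ¬x_{j+1}`; premature dissociation at `j` clears the
whole footprint under the same guard. Each rule yields a 0/1
column-stochastic matrix `M_i` over the canonical state order, and the
random-sequential chain with selection probabilities `p_i = γ_i / Σγ` has
transition matrix `M_E = Σ p_i M_i`. This chain is precisely the
uniformization `I + Q/Σγ` of the continuous-time model, so its stationary
law `π` (solved from `(M_E − I)π = 0`, `Σπ = 1`; dense below 400 states,
sparse LU above; power iteration available as a cross-check) is the
continuous-time stationary law. Codon densities are `ρ = Σ_i π_i χ_i` and
the translation rate `c = β·ρ_n`; at stationarity `ψ̄_i·γ_i = c` for every
event (flux balance), which the tests assert to 1e−10.

The full `2^n` Boolean-state embedding is never formed: matrices are built
directly over reachable states (identical to reducing the full-space
operator, at a fraction of the memory). A reducible chain (e.g. readthrough
probability `μ = 0`, or `α = 0`) is handled by restricting the solve to the
unique terminal class and assigning transient states probability 0; several
terminal classes raise a diagnostic error.

## Stochastic simulators

Four random-sequential schemes and one parallel scheme, all agreeing with
the rate law:

* **conventional** — uniform index draw over the full event set, fire with
  probability `γ_i` if allowed; `Δt = 1/(n−r+2)`;
* **alternative** — index drawn with probability `γ_i/(n−r+2)`; same `Δt`;
* **efficient-fixed** — index drawn with `γ_i/Σγ`; `Δt = 1/Σγ` (the
  uniformized chain solved exactly above);
* **efficient-varying** — index drawn among *allowed* events with
  `γ_i/Σ_allowed γ`; `dt = 1/Σ_allowed γ`; never skips;
* **parallel** — every allowed event fires independently with probability
  `γ_i / max_allowed γ` within `dt = 1/max_allowed γ`, applicability frozen
  at the start of the step (equivalent to a left-to-right particle-ordered
  sweep for unidirectional hops; simultaneously allowed events always have
  disjoint supports, so the application order is immaterial).

Rates above 1 are rescaled by their maximum in the two fixed-step schemes
(their firing draws are probabilities) and reported times are un-scaled.
Densities are **time-weighted** — each pre-step state is weighted by the
step's time increment — because the varying-step scheme makes plain per-step
averages biased; the translation-rate estimate is exit events over simulated
time. Burn-in defaults to 10 % of the steps. One seeded NumPy generator per
run; draws are consumed in a fixed documented order (selection, then firing;
parallel sweeps draw in ascending event order), so identical seed and
configuration give bit-identical results. An empty allowed set (or zero
total allowed rate, e.g. `α = 0` from the empty lattice) ends the run and
flags the summary degenerate.

With a premature stop codon the hop and dissociation branch at `j` belong to
one ribosome; in the parallel sweep they form a single actor that attempts
with the combined probability and then branches readthrough/dissociation
with probability `μ : 1−μ`, matching the "readthrough with fixed probability
when the ribosome tries to move" semantics.

## Mean-field (Heinrich–Rapoport) model

State variables are head-occupancy probabilities `h_i` (`i = r..n`). Fluxes
close through conditional vacancy probabilities

    W_0 = 1 − Σ_{s=r}^{min(2r−1,n)} h_s,
    W_i = (1 − Σ_{s=1}^{r} h_{i+s}) / (1 − Σ_{s=1}^{r−1} h_{i+s})  (r ≤ i ≤ n−r),
    W_i = 1 otherwise,

with `c_0 = α ρ_m ρ_r W_0`, `c_i = γ_i ρ_m h_i W_i`, `c_n = β ρ_m h_n`, and
transient dynamics `ρ_m dh_i/dt = c_{i−1} − c_i` (LSODA, rtol 1e−10). At
steady state the relations close in the single unknown `c`: the last `r`
heads are `h_i = c/γ_i`, a backward recursion fills the rest, and the entry
relation returns the initiation rate that would sustain `c`. The solver
root-finds `implied-α(c) = α` on `(0, min γ·(1−ε))`; `implied-α` is monotone
increasing on the physical branch (checked numerically in the tests), so a
bisection bracket plus Brent refinement is reliable; profiles leaving
`[0, 1]` mark the trial infeasible. The smallest physical root is returned —
the low-density branch reached from an empty lattice. `ρ_r` is held constant
(no ribosome-pool depletion); the reported `c` is per unit mRNA.

## Petri-net comparator

Transitions carry deterministic waiting times `w_i = 1/γ_i`. With footprint
`r` the effective initiation wait is
`w_init = max(1/α, 1/Σ_{j=r}^{2r−1} γ_j)` by default — the slower of
initiation and the combined early-elongation step read as a rate sum; the
alternative waiting-time-sum reading `max(1/α, Σ 1/γ_j)` sits behind
`init_rule="wait-sum"` since the source phrasing admits both. The default is
the one consistent with the comparator's other published behaviours
(saturation at the slowest single waiting time; Petri rates above the
stochastic rates at matched parameters). The steady translation rate is
`c = 1/max(w_init, max_i 1/γ_i, 1/β)`, so one slow codon and two
consecutive equally-slow codons give identical `c` — the deterministic
model's characteristic blind spot. A premature stop enters only as the
slowed rate `μγ_j` (the dissociation branch has no waiting-time semantics
here).

`pn_simulate` runs the matching discrete-event dynamics as a max-plus head
pipeline: a token fires at `max(arrival + w, instant the codon ahead
frees)` and heads cannot overtake; its asymptotic exit rate equals the
closed form by construction. Codon densities are read off as covered-time
fractions over the second half of the horizon — a convention, since the
deterministic model itself defines no density.

## Regulation

* **Slow codons** are rate edits `γ_pos ← slow_rate`.
* **Premature stop** at `j` with readthrough `μ`: hop rate `μγ_j` plus a
  dissociation event at `(1−μ)γ_j` clearing codons `j−r+1..j` — the only
  split that keeps the total attempt rate `γ_j` while realizing readthrough
  with probability `μ` per attempt. It enters every simulator and the exact
  solver as one extra event.
* **Initiation feedback** `α = α_I/(1 + k_I ρ_I)`,
  `dρ_I/dt = c ρ_m − d_I ρ_I`. The fixed point iterates
  `ρ_I ← (1−λ)ρ_I + λ·c(α)ρ_m/d_I` with damping `λ = 0.5` (guards
  oscillation of the undamped map) over a cached exact solver that rebuilds
  only the event weights per iteration. The stochastic coupling advances
  `ρ_I` inside the varying-step loop: degradation uses the exact interval
  factor `exp(−d_I·dt)` (a first-order Euler factor over-decays at the
  coarse steps of small lattices and visibly biases the stationary protein
  level), production is event-driven (`+ρ_m` per exit); an all-Euler
  production variant using the running rate estimate sits behind
  `scheme="euler"`. The reported `rho_I_mean` integrates the
  piecewise-exponential path exactly, so the ergodic identity
  `⟨ρ_I⟩ = ĉ ρ_m/d_I` holds up to Monte-Carlo error.

## Scenario presets and problem sizes

Presets mirror the study conditions: the worked toy example
(`n=2, r=1, α=0.6, β=0.4, γ=1`); model and update-rule comparisons at
`n=50, r=12` with `β=γ=0.5` and `β=0.5, γ=1` under initiation sweeps; slow
codons at position 25 (and 25–26) with `α=β=1`; a premature stop at codon 25
with `α=1, β=0.1` under a readthrough sweep; and initiation feedback with
`β=γ=1, ρ_m=1` under `k_I` and `d_I` sweeps. The feedback scenarios need a
maximal initiation rate that the source never prints; the presets set
`α_I = 1` (the scale of the other unit rates) and expose it as a parameter.
Simulation presets default to reduced step counts (20 000; `--full` restores
400 000) — stochastic estimates then carry Monte-Carlo errors of order 1 %,
which is what the preset-level assertions tolerate.

Test-suite problem sizes: exhaustive state-space and Boolean-rule checks run
at `n ≤ 12`; simulator-versus-exact comparisons at `n ≤ 20, r ≤ 4` with
60 000–120 000 steps (standard errors a few 1e−3 on `c`); the exact solver is
additionally exercised at the full 1113-state `n=50, r=12` geometry.
Simulation tolerances are set at roughly four standard errors of the
corresponding estimator.

## What the generator does and does not emulate

All inputs are model configurations; there is no external data. The model
captures exclusion, footprint geometry, initiation/elongation/termination
kinetics and the listed regulatory motifs. It does not model ribosome-pool
depletion, codon-level biochemistry (tRNA cycles, proofreading),
frameshifting, mRNA decay, or traffic between mRNAs — agreement of the
solvers here therefore says nothing about those mechanisms, only about the
consistency of the formalisms on the shared abstraction.

## Known limitations

* The exact solver scales with the reachable-state count (exponential in
  `n/r`); it is intended for moderate geometries (≈ 1e4 states), with the
  simulators taking over beyond that.
* The parallel update rule has no exact-solver counterpart here; parallel
  claims are Monte-Carlo only.
* The Petri comparator's density readout and its `r > 1` initiation wait are
  conventions (flagged above), not uniquely determined by the source model.
* The mean-field solver returns the low-density branch; high-density or
  maximal-current phases reached from non-empty initial conditions are out
  of scope.
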