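# Methods

## Problem and model

A constraint-based metabolic model consists of a stoichiometric matrix
`S` (metabolites × reactions), per-reaction flux bounds
`v_min ≤ v ≤ v_max`, and optionally a linear objective (e.g. biomass).
Steady states satisfy `S v = 0`. The second law of thermodynamics adds a
further requirement: matter must flow downhill in Gibbs energy, so a
viable flux configuration cannot contain a closed cycle of reactions that
transfers matter back to its starting point with no net free-energy
expenditure.

For a given configuration `v`, define the signed matrix
`Ω_mr = −sign(v_r)·S_mr` over the *thermodynamically constrained*
reactions: exchanges (boundary uptakes/sinks), the objective reaction,
reactions with non-integer ("effective") stoichiometry and reactions with
null flux carry no such constraint and are excluded. The configuration is
feasible iff a chemical-potential vector `μ` exists with `μ·Ω > 0`
(every active reaction dissipates free energy in its operating
direction). By Gordan's theorem of the alternatives, exactly one of these
holds:

* `μ·Ω > 0` is solvable (a feasibility certificate exists), or
* `Ω k = 0` has a nonzero solution with `k ≥ 0` — an infeasible cycle.

Physiological ranges for the individual `μ_m` and the estimation of real
chemical potentials are out of scope: the certificate is existential.

## Feasibility checking by relaxation

`check_feasibility` iterates the classic relaxation dynamics: at each
step select the least unsatisfied constraint (l.u.c.)
`r_t = argmin_r μ·Ω_r` and shift `μ ← μ + α Ω_{:,r_t}`. Two step rules
are provided: Motzkin (`α = λ(margin − μ·Ω_r)/‖Ω_r‖²` with
over-relaxation `λ = 1.5`; the default, and the faster of the two) and
MinOver (small fixed `α = 0.01·margin`). The strict inequality is
replaced by `μ·Ω_r ≥ margin` with `margin = 1`: any solution of the
strict system rescales to clear any positive margin, so this only fixes
the scale of the certificate while making convergence decidable.

Numerical choices:

* Initialization: uniform random `μ ∈ [0,1)^M`, seeded. Convergence does
  not depend on the prior; only the returned certificate does.
* Step cap `T = 1000 ×` (number of retained reactions) by default.
* Convergence is declared at least slack `≥ margin·(1 − 10⁻⁹)`. The
  relative tolerance matters: once the worst violation falls below
  machine precision the Motzkin step underflows (`μ + αΩ == μ`) and an
  exact-margin test can stall one ulp short of convergence forever.
* Ties in the argmin break toward the lowest reaction index, making the
  trace deterministic given `μ0`.

On infeasible instances the dynamics cycles through the reactions
implicated in the cycles; the distinct l.u.c. indices (full history, no
windowing) form the candidate set passed to the loop search. The
`verify_certificate` helper recomputes the slacks `μ·Ω` so callers can
confirm a certificate independently of the trace flag.

## Loop search

Cycles are nonzero non-negative integer solutions of `Ω k = 0` — an
NP-hard integer feasibility problem in general. `find_loop_annealing`
minimizes the infeasibility energy `E(k) = ‖Ω k‖²` (zero exactly on
cycles) by Metropolis simulated annealing over
`k_r ∈ {0, …, k_max}` restricted to the candidate reactions:

* Moves: pick a uniform random candidate reaction, propose `k_r ± 1`,
  rejecting proposals outside `[0, k_max]`. Rejection (rather than
  reflection) at the boundaries preserves detailed balance, so at fixed
  `β` the chain samples `P(k) ∝ e^{−βE(k)}` exactly — a property the test
  suite checks against Boltzmann ratios on a two-reaction system.
* Energy updates are incremental (`ΔE = 2δ·(res·Ω_r) + ‖Ω_r‖²`) in exact
  integer arithmetic, so a reported zero is exact, and every accepted
  cycle is additionally re-verified as `Ω k = 0` over the integers.
* Schedule: `β` geometric from 0.05 to 20 over 40 stages, 200 sweeps per
  stage, up to 20 random restarts, `k_max = 2`. Canonical cycles
  overwhelmingly carry unit multiplicities; `k_max` is configurable. The
  defaults suit genome-scale candidate lists; the test fixtures (≤ 10
  candidate reactions) use a proportionally smaller schedule (25 stages,
  50 sweeps, 5–6 restarts), which is ample at that problem size.
* The all-zero state minimizes `E` trivially; it is excluded as a result,
  not biased against in the moves.
* Loops are canonicalized by dividing `k` by its gcd; identity is the
  canonical `k` over the full reaction index space.

`find_loop_annealing` returning nothing does not certify absence of
cycles; the dichotomy is decided by the relaxation. Two independent
oracles back the stochastic search in tests: exhaustive enumeration
(`brute_force_loops`, guarded at 14 candidate reactions) and an LP
feasibility certificate (`loop_exists_lp`; real solvability of
`Ωk = 0, k ≥ 0, Σk = 1` is equivalent to integer solvability after
scaling, because `Ω` is integer).

`reduce_to_independent` keeps a maximal linearly independent subset of
the signed cycle vectors `n` (`n_r = sign(v_r)·k_r`, a null vector of the
internal stoichiometric matrix) by exact rational elimination (sympy),
scanning in discovery order so earlier representatives win.

## Correction

Cycles make flux patterns degenerate: `v′ = v + Σ_a L^a n^a` preserves
`S v = 0` for any coefficients `L`. Correction chooses coefficients that
break the cycles without violating the non-stoichiometric constraints
`A v ≥ b` (bounds, fixed exchanges, fixed objective value).

**Local rule.** For a single cycle, `L = −min_{r: k_r>0} |v_r|/k_r`
zeroes the smallest-magnitude cycle flux and shrinks the others without
any sign change, so plain irreversibility constraints (`v_r ≥ 0`) can
never be violated. Ties break toward the lowest reaction index; the
minimizing reaction is set to exactly zero (avoiding a `k_r > 1`
floating-point residue). If the shifted vector violates a constraint —
typically a lower bound strictly above zero, as for an ATP maintenance
flux — the input is returned unchanged and the cycle is reported
uncorrectable. `correct_all` removes one cycle per iteration in discovery
order; the outcome can depend on that order, which is inherent to the
rule, and iteration is capped at `10 × N` since each successful step
zeroes at least one flux.

`admissible_L_interval` reports the full set of admissible coefficients
for one cycle: the cycle-breaking set C2 is piecewise constant in `L`
between the points where a cycle flux crosses zero, so each open segment
(probed at its midpoint) and each breakpoint is classified by exhaustive
enumeration on the cycle support, and the result is intersected with the
constraint set C1 (each row of `A v′ ≥ b` is linear in `L`).

**Global rule.** `correct_global` minimizes the taxicab norm
`Q1(v) = Σ_r |v_r|` subject to `S v = 0`, the bounds, and equality pins
on every exchange flux and on the objective inner product. The LP uses
the standard positive/negative split `v = x⁺ − x⁻` (HiGHS); bounds map
onto the split parts, including lower bounds strictly above zero
(`x⁺_r ≥ lb_r` when `lb_r > 0`). Any Q1 minimizer is cycle-free wherever
the bounds allow: if a cycle ran with all support fluxes active, a small
shift along `−n` would strictly reduce the norm while staying feasible,
contradicting optimality. Cycles can survive only through reactions
pinned strictly away from zero; the result is therefore re-checked and
surviving cycles are reported with the binding bounds named.

L1 problems often have degenerate optimal faces (on the worked example
below, an entire segment of configurations attains the minimum). To make
the output unique the solver performs a second stage: minimize `‖v‖²`
over the optimal face (equalities reduced to an independent row set via
pivoted QR, then SLSQP on the split variables). This selects the limit of
the `Q_p` minimizers as `p → 1⁺` and is the point quoted in the worked
example. Norms with `p > 1` are intentionally unsupported: only `p = 1`
is LP-representable, and the cycle-freeness argument covers the selected
point regardless.

**Overlap.** Similarity between two configurations is
`q = (1/N) Σ_r s_r` with `s_r = 2 v^a_r v^b_r / ((v^a_r)² + (v^b_r)²)`,
and `s_r = 1` when the reaction is null (|v| < v₀ = 10⁻⁶) in both — the
maximal per-reaction score, so identical vectors give exactly `q = 1`,
opposed ones `q = −1`, and `q ∈ [−1, 1]` always. The same threshold `v₀`
is used for null-flux detection everywhere (subnetwork construction,
local rule, overlap accounting).

**ΔG sign readout.** For a feasible corrected configuration the
relaxation certificate supplies chemical potentials; the sign of
`Σ_m μ_m S_mr` for a named reaction (e.g. ATP hydrolysis) is reported as
a physiological plausibility check. The certificate fixes only signs, not
magnitudes, and depends on the certificate found — this readout is an
interpretation layered on the computed potentials, not a calibrated
free-energy estimate.

## Worked example

The bundled four-reaction network (two metabolites; internal conversions
R1: A→B and R2: B→A; intake and sink fixed at 2) with internal fluxes
`(3, 1)` contains the cycle `k = (1,1)`. Without the bound on the second
internal flux the cycle-removing coefficients form the interval
`L ∈ [−3, −1]`; the irreversibility bound `v₂ ≥ 0` contributes
`C1 = {L ≥ −1}`, pinning `L = −1` and giving the local correction
`(2, 0)`. With `v₂ ≥ ε`: for `ε < −1` the Q1 minimizer (least-norm
point) is `(1, −1)`; for `−1 ≤ ε ≤ 0` the bound clamps `v₂ = ε` and mass
balance (`v₁ − v₂ = 2`) forces the feasible minimizer `(2 + ε, ε)`; for
`ε > 0` the minimizer retains the cycle and is flagged infeasible.

## Census over direction assignments

The census characterizes the cycles of a network independently of any
particular flux solution. Each sampled configuration assigns every
irreversible reaction its mandated direction and every reversible one a
uniform random direction, with unit flux magnitudes — direction patterns
alone pose the feasibility problem, and all-reactions-active is a worst
case relative to an optimum that runs only part of the network. Each
assignment is checked and corrected (local rule, no bound checks: bounds
are irrelevant to a pure sign problem) until consistent; the cycles
encountered are pooled and reduced to an independent basis.

The saturation curve records the cumulative basis size after each
configuration; sampling stops being informative once no new independent
cycle appears. Delete-block jackknife over equal partitions of the
configuration stream (default 10 blocks) gives the standard error
`sqrt((B−1)/B · Σ_b (θ_b − θ̄)²)` at every curve point. A master seed
fans out to per-stage seeds through `SeedSequence` spawning, so
assignments, relaxation starts and annealing restarts are independently
reproducible and the whole run is bit-reproducible under a fixed seed.

## Synthetic fixtures

`generate_random_loopy_network` plants a known number of cycles: each is
a closed chain of 3–5 reversible unit-stoichiometry conversions over
distinct metabolites, so `k = 1` on its reactions solves `Ωk = 0`
exactly when the cycle runs forward. Remaining reaction slots become
conversions joining previously disconnected components (a forest, which
cannot close new cycles) and then exchanges, so the network's
independent-cycle count equals the planted count exactly — this is what
lets saturation tests assert an exact basis size. Bounds are ±10 on
cycle reactions, `[0, 10]` or `[−10, 10]` on fillers; no generated bound
forces a flux strictly away from zero, matching the hypotheses of the
Q1 cycle-freeness argument.

What the fixtures do not emulate: genome-scale dimensions, shared
reactions between cycles, non-unit stoichiometry inside cycles,
compartment structure, and the solver degeneracy of realistic FBA
problems. Passing tests therefore demonstrate correctness of the
machinery on exactly-known ground truth, not performance claims on
genome-scale reconstructions; the CLI defaults (full annealing schedule,
`T = 1000 × kept`) are the knobs meant for the latter.

## Known limitations

* `admissible_L_interval` handles one cycle at a time; the joint
  coefficient space of several interacting cycles is not searched.
* The local strategy stops at the first uncorrectable cycle: removing
  others first might occasionally unblock it, but the search over removal
  orders is combinatorial and not attempted.
* The annealing provides no certificate of absence; a `None` result on a
  non-converged relaxation is an error state the orchestration surfaces
  (after widening the candidate set to all retained reactions) rather
  than silently accepting.
* SBML numbers pass through double precision; exact rationals survive
  only in the TSV dialect (`p/q` entries).
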