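"""Infeasible-cycle search: simulated annealing, brute force, independence.

A cycle is a nonzero non-negative integer vector ``k`` with ``Omega k = 0``.
Finding one is an NP-hard integer feasibility problem in general, so the
search minimizes the quadratic infeasibility energy

    E(k) = sum_m ( sum_r Omega[m, r] k_r )^2

over ``k_r in {0, 1, ..., k_max}`` by Metropolis simulated annealing
restricted to a candidate reaction set (typically the least-unsatisfied
constraints reported by the relaxation).  ``E(k) = 0`` with ``k != 0``
certifies a cycle; every accepted cycle is re-verified in exact integer
arithmetic.  The signed null-space vector ``n_r = sign(v_r) k_r`` of a
cycle satisfies ``S n = 0`` on the internal network and is the direction
along which fluxes can be shifted without breaking mass balance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import sympy

from .network import ThermoSubnetwork

__all__ = [
    "Loop",
    "AnnealingSchedule",
    "energy",
    "find_loop_annealing",
    "brute_force_loops",
    "reduce_to_independent",
    "loop_exists_lp",
    "loops_to_tsv",
]

#: hard cap on candidate-set size for exhaustive enumeration
BRUTE_FORCE_GUARD = 14


@dataclass
class Loop:
    """A cycle in canonical form over the full reaction index space.

    ``k`` holds non-negative integer multiplicities (zero off the cycle),
    divided by their gcd; ``n = sign(v) * k`` is the matching signed
    null-space vector of the internal stoichiometric matrix.
    """

    k: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if (self.k < 0).any():
            raise ValueError("loop multiplicities must be non-negative")
        if not self.k.any():
            raise ValueError("loop must be nonzero")
        if not np.array_equal(np.abs(self.n), self.k):
            raise ValueError("n must equal sign(v) * k componentwise")
        g = int(np.gcd.reduce(self.k[self.k > 0]))
        if g > 1:
            self.k = self.k // g
            self.n = self.n // g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Loop):
            return NotImplemented
        return (np.array_equal(self.k, other.k)
                and np.array_equal(self.n, other.n))

    def __hash__(self) -> int:
        return hash(self.key())

    @property
    def support(self) -> np.ndarray:
        """Global indices of the reactions in the cycle."""
        return np.nonzero(self.k)[0]

    @property
    def length(self) -> int:
        return int(np.count_nonzero(self.k))

    def key(self) -> tuple:
        """Hashable identity: the canonical k over the full index space."""
        return tuple(self.k.tolist())

    def verify(self, sub: ThermoSubnetwork) -> bool:
        """Exact integer check of ``Omega k = 0`` on the kept reactions."""
        k_kept = self.k[sub.kept_reactions]
        if k_kept.sum() != self.k.sum():  # support outside the kept set
            return False
        return not (sub.omega_int() @ k_kept).any()


@dataclass
class AnnealingSchedule:
    """Geometric inverse-temperature ramp for the Metropolis search."""

    beta_start: float = 0.05
    beta_end: float = 20.0
    n_stages: int = 40
    sweeps_per_stage: int = 200
    k_max: int = 2
    n_restarts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.beta_start < self.beta_end):
            raise ValueError("need 0 < beta_start < beta_end")
        if self.k_max < 1:
            raise ValueError("k_max must be at least 1")

    def betas(self) -> np.ndarray:
        return np.geomspace(self.beta_start, self.beta_end, self.n_stages)


def energy(sub: ThermoSubnetwork, k: np.ndarray) -> float:
    """Quadratic infeasibility energy of a multiplicity vector on the kept
    reactions; zero iff ``k`` solves ``Omega k = 0``."""
    k = np.asarray(k)
    if (k < 0).any():
        raise ValueError("multiplicities must be non-negative")
    res = sub.omega @ k
    return float(res @ res)


def _make_loop(sub: ThermoSubnetwork, candidates: np.ndarray,
               k_local: np.ndarray) -> Loop:
    k_full = np.zeros(sub.n_reactions_total, dtype=np.int64)
    k_full[candidates] = k_local
    n_full = np.zeros_like(k_full)
    for g in candidates[k_local > 0]:
        n_full[g] = sub.direction_signs[sub.kept_position(g)] * k_full[g]
    return Loop(k=k_full, n=n_full)


def find_loop_annealing(
    sub: ThermoSubnetwork,
    candidates,
    schedule: AnnealingSchedule | None = None,
) -> Loop | None:
    """Search for a cycle supported on ``candidates`` (global indices).

    Runs up to ``schedule.n_restarts`` independent annealings; each sweeps
    the geometric beta ramp, proposing single-reaction moves ``k_r -> k_r
    +- 1`` (rejected outside ``[0, k_max]``) accepted by the Metropolis
    rule on the energy difference.  Returns the first zero-energy nonzero
    state, canonicalized and integer-verified, or ``None`` when the
    schedule is exhausted (absence of a cycle is *not* certified).
    """
    if schedule is None:
        schedule = AnnealingSchedule()
    candidates = np.asarray(list(candidates), dtype=np.intp)
    if candidates.size == 0:
        raise ValueError("candidate set must be nonempty")
    positions = np.array([sub.kept_position(g) for g in candidates])
    om = sub.omega_int()[:, positions]           # (M, C) exact integers
    norms2 = np.einsum("mc,mc->c", om, om)
    rng = np.random.default_rng(schedule.seed)
    c = candidates.size
    betas = schedule.betas()
    kmax = schedule.k_max

    for _ in range(schedule.n_restarts):
        k = rng.integers(0, kmax + 1, size=c)
        res = om @ k
        e = int(res @ res)
        if e == 0 and k.any():
            return _make_loop(sub, candidates, k)
        for beta in betas:
            n_moves = schedule.sweeps_per_stage * c
            picks = rng.integers(0, c, size=n_moves)
            deltas = rng.choice((-1, 1), size=n_moves)
            accepts = rng.random(size=n_moves)
            for r, d, u in zip(picks, deltas, accepts):
                new = k[r] + d
                if new < 0 or new > kmax:
                    continue
                de = 2 * d * (res @ om[:, r]) + norms2[r]
                if de <= 0 or u < math.exp(-beta * de):
                    k[r] = new
                    res += d * om[:, r]
                    e += de
                    if e == 0 and k.any():
                        loop = _make_loop(sub, candidates, k)
                        if loop.verify(sub):
                            return loop
    return None


def sample_multiplicities(
    sub: ThermoSubnetwork,
    candidates,
    beta: float,
    n_sweeps: int,
    k_max: int = 1,
    seed: int = 0,
    burn_in: int = 100,
) -> dict[tuple, int]:
    """Fixed-temperature Metropolis visit counts over multiplicity states.

    Diagnostic for the sampler: at inverse temperature ``beta`` the chain's
    stationary distribution is ``P(k) proportional to exp(-beta E(k))``, so
    long-run state frequencies must match Boltzmann ratios.  Returns a map
    from state tuples to visit counts (one count per attempted move after
    burn-in).
    """
    candidates = np.asarray(list(candidates), dtype=np.intp)
    positions = np.array([sub.kept_position(g) for g in candidates])
    om = sub.omega_int()[:, positions]
    norms2 = np.einsum("mc,mc->c", om, om)
    rng = np.random.default_rng(seed)
    c = candidates.size
    k = rng.integers(0, k_max + 1, size=c)
    res = om @ k
    counts: dict[tuple, int] = {}
    total = burn_in + n_sweeps * c
    for step in range(total):
        r = int(rng.integers(c))
        d = int(rng.choice((-1, 1)))
        new = k[r] + d
        if 0 <= new <= k_max:
            de = 2 * d * (res @ om[:, r]) + norms2[r]
            if de <= 0 or rng.random() < math.exp(-beta * de):
                k[r] = new
                res += d * om[:, r]
        if step >= burn_in:
            key = tuple(int(x) for x in k)
            counts[key] = counts.get(key, 0) + 1
    return counts


def brute_force_loops(
    sub: ThermoSubnetwork,
    k_max: int = 3,
    candidates=None,
) -> list[Loop]:
    """Exhaustively enumerate cycles with multiplicities ``<= k_max``.

    Oracle for the stochastic search on small instances; guarded at
    ``BRUTE_FORCE_GUARD`` candidate reactions.  Results are canonical and
    deduplicated (a multiple of a loop collapses onto it).
    """
    if candidates is None:
        candidates = sub.kept_reactions
    candidates = np.asarray(list(candidates), dtype=np.intp)
    c = candidates.size
    if c > BRUTE_FORCE_GUARD:
        raise ValueError(
            f"{c} candidate reactions exceed the enumeration guard "
            f"({BRUTE_FORCE_GUARD})"
        )
    if c == 0:
        return []
    positions = np.array([sub.kept_position(g) for g in candidates])
    om = sub.omega_int()[:, positions]
    base = k_max + 1
    total = base ** c
    found: dict[tuple, Loop] = {}
    chunk = 1 << 18
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        digits = np.empty((idx.size, c), dtype=np.int64)
        rem = idx
        for j in range(c):
            digits[:, j] = rem % base
            rem = rem // base
        residuals = digits @ om.T
        zero = ~residuals.any(axis=1) & digits.any(axis=1)
        for k_local in digits[zero]:
            loop = _make_loop(sub, candidates, k_local)
            found.setdefault(loop.key(), loop)
    return list(found.values())


def reduce_to_independent(loops: list[Loop]) -> list[Loop]:
    """Maximal linearly independent sublist of the signed vectors ``n``.

    Exact rational Gaussian elimination (sympy); loops are scanned in
    discovery order and kept only if they enlarge the span, so composite
    cycles decomposable into earlier ones are dropped.
    """
    kept: list[Loop] = []
    basis = None
    for loop in loops:
        row = sympy.Matrix([[int(x) for x in loop.n]])
        if basis is None:
            kept.append(loop)
            basis = row
            continue
        stacked = basis.col_join(row)
        if stacked.rank() > basis.rank():
            kept.append(loop)
            basis = stacked
    return kept


def loop_exists_lp(sub: ThermoSubnetwork, candidates=None) -> bool:
    """LP certificate for the existence of a cycle on the candidate set.

    ``Omega k = 0, k >= 0, sum k = 1`` is feasible over the reals iff a
    rational — hence, after scaling, integer — cycle exists.  Independent
    cross-check for the enumeration and the relaxation dichotomy.
    """
    from scipy.optimize import linprog

    if candidates is None:
        candidates = sub.kept_reactions
    candidates = np.asarray(list(candidates), dtype=np.intp)
    if candidates.size == 0:
        return False
    positions = np.array([sub.kept_position(g) for g in candidates])
    om = sub.omega[:, positions]
    A_eq = np.vstack([om, np.ones((1, om.shape[1]))])
    b_eq = np.zeros(A_eq.shape[0])
    b_eq[-1] = 1.0
    res = linprog(
        c=np.zeros(om.shape[1]), A_eq=A_eq, b_eq=b_eq,
        bounds=[(0, None)] * om.shape[1], method="highs",
    )
    return res.status == 0


def loops_to_tsv(loops: list[Loop], reaction_ids: list[str]) -> str:
    """One block per loop: reaction id, multiplicity, direction sign."""
    lines = ["loop\treaction\tmultiplicity\tdirection"]
    for i, loop in enumerate(loops):
        for r in loop.support:
            sign = int(np.sign(loop.n[r]))
            lines.append(f"{i}\t{reaction_ids[r]}\t{int(loop.k[r])}\t{sign:+d}")
    return "\n".join(lines) + "\n"


def loops_to_json(loops: list[Loop], reaction_ids: list[str]) -> str:
    return json.dumps([
        {
            "reactions": {
                reaction_ids[r]: {"k": int(loop.k[r]), "sign": int(np.sign(loop.n[r]))}
                for r in loop.support
            },
            "length": loop.length,
        }
        for loop in loops
    ])
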