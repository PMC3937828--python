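"""Loop census over random direction assignments, and an internal FBA solver.

The census characterizes the cycles of a *network* (rather than one flux
configuration) by sampling direction assignments: every irreversible
reaction runs in its mandated direction, every reversible one forward or
backward with probability 1/2, and all reactions are active with unit
flux — a worst case relative to an optimal state that typically runs only
a fraction of the network.  Each assignment is checked and corrected until
thermodynamically consistent; the cycles found along the way are pooled
and reduced to an independent basis by exact Gaussian elimination.  The
cumulative basis size as a function of configurations tested saturates
once no new independent cycle appears; delete-block jackknife resampling
over the configuration stream puts an error band on that curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .correction import correct_local
from .feasibility import check_feasibility
from .loops import AnnealingSchedule, Loop, reduce_to_independent
from .network import FluxVector, MetabolicNetwork, build_thermo_subnetwork

__all__ = ["DirectionAssignment", "CensusResult", "run_fba", "census"]


@dataclass
class DirectionAssignment:
    """Per-reaction operating direction in {+1, -1}.

    Irreversible reactions carry their mandated sign; reversible ones are
    sampled uniformly.  Exchange and other thermodynamically unconstrained
    reactions receive a sign too, but it never enters the analysis.
    """

    signs: np.ndarray
    seed: int

    @classmethod
    def sample(cls, net: MetabolicNetwork, seed: int) -> "DirectionAssignment":
        rng = np.random.default_rng(seed)
        signs = rng.choice((-1, 1), size=net.n_reactions)
        signs[net.lower_bounds >= 0] = 1
        signs[net.upper_bounds <= 0] = -1
        return cls(signs=signs.astype(int), seed=seed)

    def unit_fluxes(self) -> FluxVector:
        return FluxVector(self.signs.astype(float))


@dataclass
class CensusResult:
    """Outcome of a loop census run."""

    n_configs: int
    loop_basis: list[Loop]
    saturation_curve: list[tuple[int, int]]
    jackknife_blocks: int
    error_band: list[float]
    reaction_ids: list[str] = field(default_factory=list)

    @property
    def n_independent(self) -> int:
        return len(self.loop_basis)

    def curve_tsv(self) -> str:
        lines = ["n_configs\tn_independent_loops\tjackknife_error"]
        for (n, count), err in zip(self.saturation_curve, self.error_band):
            lines.append(f"{n}\t{count}\t{err:.6g}")
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "n_configs": self.n_configs,
            "n_independent_loops": self.n_independent,
            "loop_lengths": [l.length for l in self.loop_basis],
            "saturation_curve": self.saturation_curve,
            "jackknife_blocks": self.jackknife_blocks,
            "jackknife_error": self.error_band,
        })


def run_fba(net: MetabolicNetwork) -> FluxVector:
    """Maximize the network objective over ``S v = 0`` within the bounds.

    Plain LP (HiGHS); deterministic for a fixed model. Raises when no
    objective is set or the LP is infeasible/unbounded.
    """
    from scipy.optimize import linprog

    if net.objective is None:
        raise ValueError("network carries no objective vector")
    bounds = [
        (lb if np.isfinite(lb) else None, ub if np.isfinite(ub) else None)
        for lb, ub in zip(net.lower_bounds, net.upper_bounds)
    ]
    res = linprog(
        c=-net.objective,
        A_eq=net.stoichiometry,
        b_eq=np.zeros(net.n_metabolites),
        bounds=bounds,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"FBA LP failed (status {res.status}): {res.message}")
    return FluxVector(res.x)


def _derive_seed(seed: int, counter: int) -> int:
    return int(np.random.SeedSequence(entropy=seed,
                                      spawn_key=(counter,)).generate_state(1)[0]
               % (2**31))


def _consistent_loops(net: MetabolicNetwork, assignment: DirectionAssignment,
                      schedule: AnnealingSchedule | None, seed: int,
                      step_cap: int | None, max_rounds: int) -> list[Loop]:
    """Detect-and-deactivate until the assignment is feasible; return the
    cycles encountered (in discovery order)."""
    from .correction import LinearConstraints, _find_one_loop

    v = assignment.unit_fluxes()
    # direction assignments pose a pure sign problem: bounds play no role
    no_constraints = LinearConstraints.unconstrained(net.n_reactions)
    found: list[Loop] = []
    for it in range(max_rounds):
        sub = build_thermo_subnetwork(net, v)
        if sub.is_trivially_feasible:
            return found
        trace = check_feasibility(sub, step_cap=step_cap,
                                  seed=_derive_seed(seed, 2 * it))
        if trace.converged:
            return found
        loop = _find_one_loop(sub, trace, schedule, seed, 2 * it + 1)
        if loop is None:
            raise RuntimeError(
                "census: loop search failed on a non-converged assignment "
                f"(candidates: {trace.candidate_ids})"
            )
        found.append(loop)
        # local rule without bound checks: zero the smallest loop flux
        result = correct_local(net, v, loop, constraints=no_constraints)
        if not result.corrected:
            raise RuntimeError("census: unconstrained correction failed")
        v = result.v_after
    raise RuntimeError(f"census: assignment not feasible after {max_rounds} "
                       "corrections")


def census(
    net: MetabolicNetwork,
    n_configs: int,
    jackknife_blocks: int = 10,
    seed: int = 0,
    schedule: AnnealingSchedule | None = None,
    step_cap: int | None = None,
) -> CensusResult:
    """Sample ``n_configs`` direction assignments and pool their cycles.

    Returns the independent cycle basis, the saturation curve (cumulative
    basis size after each configuration) and the delete-block jackknife
    standard error of each curve point over ``jackknife_blocks`` equal
    partitions of the configuration stream.
    """
    if n_configs < jackknife_blocks or jackknife_blocks < 2:
        raise ValueError("need n_configs >= jackknife_blocks >= 2")
    per_config: list[list[Loop]] = []
    max_rounds = 10 * net.n_reactions
    for i in range(n_configs):
        assignment = DirectionAssignment.sample(net, _derive_seed(seed, i))
        per_config.append(_consistent_loops(
            net, assignment, schedule, _derive_seed(seed, n_configs + i),
            step_cap, max_rounds,
        ))

    stream: list[Loop] = [l for loops in per_config for l in loops]
    basis = reduce_to_independent(stream)

    def count_at(upto: int, skip_block: int | None) -> int:
        pool: list[Loop] = []
        for i in range(upto):
            if skip_block is not None and _block_of(i) == skip_block:
                continue
            pool.extend(per_config[i])
        return len(reduce_to_independent(pool))

    def _block_of(i: int) -> int:
        return min(i * jackknife_blocks // n_configs, jackknife_blocks - 1)

    curve = [(i + 1, count_at(i + 1, None)) for i in range(n_configs)]
    band: list[float] = []
    B = jackknife_blocks
    for i in range(n_configs):
        theta = np.array([count_at(i + 1, b) for b in range(B)], dtype=float)
        band.append(float(np.sqrt((B - 1) / B * ((theta - theta.mean()) ** 2).sum())))
    return CensusResult(
        n_configs=n_configs,
        loop_basis=basis,
        saturation_curve=curve,
        jackknife_blocks=jackknife_blocks,
        error_band=band,
        reaction_ids=list(net.reaction_ids),
    )
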