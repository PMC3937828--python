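"""Removal of infeasible cycles from flux configurations.

Two strategies, both preserving mass balance (shifts happen along
null-space vectors ``n`` of the internal stoichiometric matrix), the flux
bounds ``A v >= b`` and the objective value:

* *local*: given one cycle, shift ``v' = v + L n`` with ``L`` chosen to
  zero the smallest-magnitude cycle flux without changing any sign
  (``L = -min_{r: k_r > 0} |v_r| / k_r``).  This lifts the flux degeneracy
  the cycle creates while staying as close as possible to the input.  A
  cycle through a reaction bounded strictly away from zero may be
  uncorrectable, in which case the input is returned unchanged.
* *global*: minimize the taxicab norm ``Q1(v) = sum_r |v_r|`` subject to
  all constraints, with exchange fluxes and the objective value pinned to
  the input.  Any Q1 minimizer is cycle-free wherever the bounds allow:
  along a cycle direction with all fluxes active, the norm strictly
  decreases, contradicting optimality.  Degenerate optimal faces are
  resolved to the minimum-Euclidean-norm point (the limit of the Q_p
  minimizers as p -> 1+).

Similarity between configurations is measured by the overlap
``q = (1/N) sum_r 2 v^a_r v^b_r / ((v^a_r)^2 + (v^b_r)^2)``, with a
reaction null in both configurations scoring its maximal value 1;
``q = 1`` for identical vectors and ``q = -1`` for opposed ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .feasibility import check_feasibility, verify_certificate
from .loops import (
    AnnealingSchedule,
    Loop,
    brute_force_loops,
    find_loop_annealing,
)
from .network import (
    FluxVector,
    MetabolicNetwork,
    ThermoSubnetwork,
    build_thermo_subnetwork,
)

__all__ = [
    "LinearConstraints",
    "Interval",
    "LocalCorrectionResult",
    "CorrectionReport",
    "correct_local",
    "admissible_L_interval",
    "correct_global",
    "overlap",
    "correct_all",
    "delta_g_sign",
]

OBJECTIVE_RTOL = 1e-8
LP_TOL = 1e-9


@dataclass
class LinearConstraints:
    """All non-stoichiometric constraints, encoded as ``A v >= b``."""

    A: np.ndarray
    b: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.asarray(self.b, dtype=float)
        if self.A.shape[0] != self.b.size:
            raise ValueError("A and b row counts differ")
        if not self.labels:
            self.labels = [f"row{i}" for i in range(self.b.size)]

    @classmethod
    def from_network(
        cls,
        net: MetabolicNetwork,
        fix_exchanges_to: FluxVector | None = None,
        fix_objective_to: float | None = None,
    ) -> "LinearConstraints":
        """Bounds of ``net`` as inequality rows, optionally pinning every
        exchange flux and the objective inner product to given values."""
        rows, rhs, labels = [], [], []
        n = net.n_reactions
        for r in range(n):
            rid = net.reaction_ids[r]
            if np.isfinite(net.lower_bounds[r]):
                e = np.zeros(n)
                e[r] = 1.0
                rows.append(e)
                rhs.append(net.lower_bounds[r])
                labels.append(f"{rid} >= {net.lower_bounds[r]:g}")
            if np.isfinite(net.upper_bounds[r]):
                e = np.zeros(n)
                e[r] = -1.0
                rows.append(e)
                rhs.append(-net.upper_bounds[r])
                labels.append(f"{rid} <= {net.upper_bounds[r]:g}")
        if fix_exchanges_to is not None:
            for r in np.nonzero(net.exchange_flags)[0]:
                val = float(fix_exchanges_to.values[r])
                for sgn in (1.0, -1.0):
                    e = np.zeros(n)
                    e[r] = sgn
                    rows.append(e)
                    rhs.append(sgn * val)
                labels.append(f"{net.reaction_ids[r]} fixed >= {val:g}")
                labels.append(f"{net.reaction_ids[r]} fixed <= {val:g}")
        if fix_objective_to is not None and net.objective is not None:
            for sgn in (1.0, -1.0):
                rows.append(sgn * net.objective)
                rhs.append(sgn * fix_objective_to)
            labels.append(f"objective fixed >= {fix_objective_to:g}")
            labels.append(f"objective fixed <= {fix_objective_to:g}")
        return cls(np.array(rows), np.array(rhs), labels)

    @classmethod
    def unconstrained(cls, n_reactions: int) -> "LinearConstraints":
        """Empty constraint set (every shift is admissible)."""
        return cls(np.zeros((0, n_reactions)), np.zeros(0))

    def violations(self, v: np.ndarray, tol: float = LP_TOL) -> list[str]:
        slack = self.A @ v - self.b
        return [self.labels[i] for i in np.nonzero(slack < -tol)[0]]


@dataclass
class Interval:
    """A connected interval of admissible degeneracy coefficients ``L``."""

    lo: float
    hi: float
    lo_open: bool = False
    hi_open: bool = False

    def __post_init__(self) -> None:
        self.lo = float(self.lo)
        self.hi = float(self.hi)

    def contains(self, x: float, tol: float = 0.0) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo - tol
        below = x < self.hi if self.hi_open else x <= self.hi + tol
        return above and below


@dataclass
class LocalCorrectionResult:
    v_after: FluxVector
    corrected: bool
    coefficient: float
    violated: list[str] = field(default_factory=list)


def _check_loop(net: MetabolicNetwork, v: FluxVector, loop: Loop) -> None:
    """Validate that ``loop`` is a genuine cycle of the configuration."""
    support = loop.support
    if not v.active[support].all():
        raise ValueError("loop reaction carries a null flux in v")
    signs = np.sign(v.values[support])
    if not np.array_equal(loop.n[support], signs * loop.k[support]):
        raise ValueError("loop direction pattern does not match sign(v)")
    residual = net.stoichiometry @ loop.n
    if np.abs(residual).max() > 1e-9:
        raise ValueError("loop is not in the null space of S (Omega k != 0)")


def correct_local(
    net: MetabolicNetwork,
    v: FluxVector,
    loop: Loop,
    constraints: LinearConstraints | None = None,
) -> LocalCorrectionResult:
    """Apply the degeneracy-lifting rule to remove one cycle.

    ``L = -min_{r in support} |v_r| / k_r`` (ties broken toward the lowest
    reaction index); the shifted configuration zeroes that reaction, keeps
    every other sign, and is returned only if it satisfies ``constraints``
    (default: the network bounds).  Otherwise the input is returned
    unchanged with the violated constraints named.
    """
    _check_loop(net, v, loop)
    if constraints is None:
        constraints = LinearConstraints.from_network(net)
    support = loop.support
    ratios = np.abs(v.values[support]) / loop.k[support]
    j = int(np.argmin(ratios))  # argmin returns the first (lowest-index) tie
    L = -float(ratios[j])
    new_values = v.values + L * loop.n
    new_values[support[j]] = 0.0  # exact zero for the minimizing reaction
    violated = constraints.violations(new_values)
    if violated:
        return LocalCorrectionResult(v_after=v, corrected=False,
                                     coefficient=L, violated=violated)
    return LocalCorrectionResult(v_after=v.copy_with(new_values),
                                 corrected=True, coefficient=L)


def _loop_free_at(net: MetabolicNetwork, v: FluxVector, loop: Loop,
                  L: float, k_max: int = 3) -> bool:
    """Is ``v + L n`` free of cycles supported on the loop's reactions?"""
    vals = v.values + L * loop.n
    support = loop.support
    active = support[np.abs(vals[support]) >= v.zero_threshold]
    if active.size == 0:
        return True
    signs = np.sign(vals[active]).astype(int)
    omega = -net.stoichiometry[:, active] * signs[np.newaxis, :]
    sub = ThermoSubnetwork(
        kept_reactions=active,
        omega=omega,
        direction_signs=signs,
        reaction_ids=[net.reaction_ids[i] for i in active],
        n_reactions_total=net.n_reactions,
    )
    return not brute_force_loops(sub, k_max=k_max)


def admissible_L_interval(
    net: MetabolicNetwork,
    v: FluxVector,
    loop: Loop,
    constraints: LinearConstraints | None = None,
) -> list[Interval]:
    """Set of coefficients ``L`` for which ``v + L n`` both satisfies the
    non-stoichiometric constraints (C1) and breaks the cycle (C2).

    C2 is piecewise constant in ``L`` between the points where a cycle
    flux crosses zero; each piece is classified by exhaustive search on
    the cycle support.  Pass ``constraints=None`` to obtain C2 alone.
    Only the single-loop case (one scalar coefficient) is supported.
    """
    _check_loop(net, v, loop)
    support = loop.support
    breaks = sorted({-v.values[r] / loop.n[r] for r in support})
    # probe points: each breakpoint, the midpoints between them, and one
    # point beyond each end
    span = max(breaks[-1] - breaks[0], 1.0)
    pieces: list[tuple[Interval, float]] = []
    pieces.append((Interval(-np.inf, breaks[0], hi_open=True),
                   breaks[0] - span))
    for i, b in enumerate(breaks):
        pieces.append((Interval(b, b), b))
        if i + 1 < len(breaks):
            pieces.append((Interval(b, breaks[i + 1], lo_open=True,
                                    hi_open=True),
                           0.5 * (b + breaks[i + 1])))
    pieces.append((Interval(breaks[-1], np.inf, lo_open=True),
                   breaks[-1] + span))

    free = [(piece, _loop_free_at(net, v, loop, probe))
            for piece, probe in pieces]
    # merge contiguous loop-free pieces into maximal intervals
    merged: list[Interval] = []
    current: Interval | None = None
    for piece, ok in free:
        if ok:
            if current is None:
                current = Interval(piece.lo, piece.hi,
                                   piece.lo_open, piece.hi_open)
            else:
                current.hi, current.hi_open = piece.hi, piece.hi_open
        else:
            if current is not None:
                merged.append(current)
                current = None
    if current is not None:
        merged.append(current)

    if constraints is None:
        return merged
    # C1: each row a.(v + L n) >= b is linear in L
    lo, hi = -np.inf, np.inf
    a_n = constraints.A @ loop.n.astype(float)
    slack0 = constraints.A @ v.values - constraints.b
    for i in range(constraints.b.size):
        if a_n[i] > 1e-12:
            lo = max(lo, -slack0[i] / a_n[i])
        elif a_n[i] < -1e-12:
            hi = min(hi, -slack0[i] / a_n[i])
        elif slack0[i] < -LP_TOL:
            return []
    out = []
    for piece in merged:
        new_lo = max(piece.lo, lo)
        new_hi = min(piece.hi, hi)
        if new_lo > new_hi:
            continue
        if new_lo == new_hi and (piece.lo_open and new_lo == piece.lo):
            continue
        if new_lo == new_hi and (piece.hi_open and new_hi == piece.hi):
            continue
        out.append(Interval(
            new_lo, new_hi,
            lo_open=piece.lo_open and new_lo == piece.lo,
            hi_open=piece.hi_open and new_hi == piece.hi,
        ))
    return out


def correct_global(
    net: MetabolicNetwork,
    v: FluxVector,
    constraints: LinearConstraints | None = None,
    p: int = 1,
    fix_exchanges: bool = True,
    fix_objective: bool = True,
    tie_break: bool = True,
) -> FluxVector:
    """Minimize the taxicab norm ``Q1`` of the fluxes under all constraints.

    The LP splits each flux into positive and negative parts; exchange
    fluxes (and the objective inner product, when an objective is set) are
    pinned by equality to the values of ``v``.  With ``tie_break`` the
    minimum-Euclidean-norm point of the optimal face is returned, which
    makes the result unique and coincides with the ``p -> 1+`` limit of
    the Q_p minimizers.  Only ``p = 1`` is LP-representable and supported.
    """
    from scipy.optimize import LinearConstraint, linprog, minimize

    if p != 1:
        raise NotImplementedError("only the Q1 (taxicab) norm is supported")
    n = net.n_reactions
    S = net.stoichiometry
    # equalities: mass balance, fixed exchanges, fixed objective value
    eq_rows = [S]
    eq_rhs = [np.zeros(net.n_metabolites)]
    if fix_exchanges:
        ex = np.nonzero(net.exchange_flags)[0]
        E = np.zeros((ex.size, n))
        E[np.arange(ex.size), ex] = 1.0
        eq_rows.append(E)
        eq_rhs.append(v.values[ex])
    if fix_objective and net.objective is not None:
        eq_rows.append(net.objective[np.newaxis, :])
        eq_rhs.append(np.array([float(net.objective @ v.values)]))
    A_eq_v = np.vstack(eq_rows)
    b_eq = np.concatenate(eq_rhs)
    # drop linearly dependent equality rows (consistent by construction);
    # degenerate row sets break the least-squares subproblems of the QP stage
    from scipy.linalg import qr

    _, _, piv = qr(A_eq_v.T, pivoting=True)
    rank = np.linalg.matrix_rank(A_eq_v)
    keep_rows = np.sort(piv[:rank])
    A_eq_v = A_eq_v[keep_rows]
    b_eq = b_eq[keep_rows]

    # split v = x+ - x-; the directional parts inherit the bounds, including
    # lower bounds strictly above zero (x+ >= lb when lb > 0)
    A_eq = np.hstack([A_eq_v, -A_eq_v])
    lb_pos = np.maximum(net.lower_bounds, 0.0)
    ub_pos = np.maximum(net.upper_bounds, 0.0)
    lb_neg = np.maximum(-net.upper_bounds, 0.0)
    ub_neg = np.maximum(-net.lower_bounds, 0.0)
    bounds = [(lo, u if np.isfinite(u) else None)
              for lo, u in zip(lb_pos, ub_pos)]
    bounds += [(lo, u if np.isfinite(u) else None)
               for lo, u in zip(lb_neg, ub_neg)]
    A_ub = b_ub = None
    if constraints is not None:
        A_ub = np.hstack([-constraints.A, constraints.A])
        b_ub = -constraints.b
    cost = np.ones(2 * n)
    res = linprog(c=cost, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    if res.status != 0:
        active = []
        if res.status == 2:
            active = ["mass balance / fixed exchanges / fixed objective",
                      "flux bounds"]
        raise RuntimeError(
            f"Q1 minimization LP failed (status {res.status}: {res.message}); "
            f"inconsistent constraints: {active}"
        )
    x = res.x
    q1_star = float(cost @ x)

    if tie_break:
        face = [LinearConstraint(A_eq, b_eq, b_eq),
                LinearConstraint(cost, -np.inf, q1_star + 1e-9)]
        if A_ub is not None:
            face.append(LinearConstraint(A_ub, -np.inf, b_ub))
        D = np.hstack([np.eye(n), -np.eye(n)])

        def sqnorm(z):
            w = D @ z
            return float(w @ w)

        def grad(z):
            return 2.0 * D.T @ (D @ z)

        qp = minimize(sqnorm, x, jac=grad, bounds=bounds, constraints=face,
                      method="SLSQP",
                      options={"maxiter": 200, "ftol": 1e-12})
        if qp.success and cost @ qp.x <= q1_star + 1e-6:
            x = qp.x
    return v.copy_with(x[:n] - x[n:])


def overlap(v_a: FluxVector, v_b: FluxVector) -> float:
    """Normalized similarity of two flux configurations, in ``[-1, 1]``.

    Per-reaction score ``2 v^a v^b / ((v^a)^2 + (v^b)^2)``; a reaction null
    in both configurations contributes the maximal score 1.  Symmetric, 1
    iff the vectors agree reaction-wise, -1 iff they are opposed.
    """
    if len(v_a) != len(v_b):
        raise ValueError("flux vectors live on different reaction spaces")
    if v_a.zero_threshold != v_b.zero_threshold:
        raise ValueError("flux vectors use different null thresholds")
    a, b = v_a.values, v_b.values
    both_null = ~v_a.active & ~v_b.active
    denom = a * a + b * b
    scores = np.ones(len(v_a))
    live = ~both_null
    scores[live] = 2.0 * a[live] * b[live] / denom[live]
    return float(scores.mean())


@dataclass
class CorrectionReport:
    """Before/after record of a full detect-and-correct run."""

    v_before: FluxVector
    v_after: FluxVector
    removed_loops: list[Loop]
    uncorrectable_loops: list[tuple[Loop, list[str]]]
    strategy: str
    overlap_before_after: float
    active_counts_before: tuple[int, int]
    active_counts_after: tuple[int, int]
    feasible: bool
    was_feasible_on_input: bool

    @property
    def status(self) -> str:
        if self.was_feasible_on_input:
            return "feasible"
        if self.feasible and not self.uncorrectable_loops:
            return "corrected"
        return "uncorrectable loops remain"

    def to_json(self, reaction_ids: list[str] | None = None) -> str:
        def loop_dict(loop: Loop):
            sup = loop.support
            names = ([reaction_ids[r] for r in sup] if reaction_ids
                     else [int(r) for r in sup])
            return {"reactions": names,
                    "k": [int(loop.k[r]) for r in sup],
                    "signs": [int(np.sign(loop.n[r])) for r in sup]}

        return json.dumps({
            "status": self.status,
            "strategy": self.strategy,
            "n_removed": len(self.removed_loops),
            "removed_loops": [loop_dict(l) for l in self.removed_loops],
            "uncorrectable_loops": [
                {"loop": loop_dict(l), "violated": viol}
                for l, viol in self.uncorrectable_loops
            ],
            "overlap_before_after": self.overlap_before_after,
            "active_reactions": {"before": self.active_counts_before[0],
                                 "after": self.active_counts_after[0]},
            "active_metabolites": {"before": self.active_counts_before[1],
                                   "after": self.active_counts_after[1]},
        }, indent=2)


def _active_counts(net: MetabolicNetwork, v: FluxVector) -> tuple[int, int]:
    """(active reactions, metabolites touched by an active reaction)."""
    act = v.active
    n_active = int(act.sum())
    touched = (net.stoichiometry[:, act] != 0).any(axis=1)
    return n_active, int(touched.sum())


def _derive_seed(seed: int, counter: int) -> int:
    return int(np.random.SeedSequence(entropy=seed,
                                      spawn_key=(counter,)).generate_state(1)[0]
               % (2**31))


def _find_one_loop(sub, trace, schedule, seed, counter):
    sched = schedule if schedule is not None else AnnealingSchedule()
    sched = AnnealingSchedule(
        beta_start=sched.beta_start, beta_end=sched.beta_end,
        n_stages=sched.n_stages, sweeps_per_stage=sched.sweeps_per_stage,
        k_max=sched.k_max, n_restarts=sched.n_restarts,
        seed=_derive_seed(seed, counter),
    )
    loop = find_loop_annealing(sub, trace.candidate_set, sched)
    if loop is None and len(trace.candidate_set) < sub.n_kept:
        # widen the search to every retained reaction before giving up
        loop = find_loop_annealing(sub, sub.kept_reactions, sched)
    return loop


def correct_all(
    net: MetabolicNetwork,
    v: FluxVector,
    constraints: LinearConstraints | None = None,
    strategy: str = "local",
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    step_cap: int | None = None,
    max_iterations: int | None = None,
    objective_tolerance: float = OBJECTIVE_RTOL,
) -> CorrectionReport:
    """Iterate check -> find -> correct until the configuration is feasible
    or only uncorrectable cycles remain.

    With ``strategy="local"`` one cycle is removed per iteration, in
    discovery order (the outcome may depend on that order); with
    ``strategy="global"`` a single Q1 minimization replaces the whole
    loop-removal sequence and the result is re-checked.
    """
    if strategy not in ("local", "global"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if constraints is None:
        constraints = LinearConstraints.from_network(
            net, fix_exchanges_to=v,
            fix_objective_to=(float(net.objective @ v.values)
                              if net.objective is not None else None),
        )
    obj_before = (float(net.objective @ v.values)
                  if net.objective is not None else None)
    cap = max_iterations if max_iterations is not None else 10 * net.n_reactions
    removed: list[Loop] = []
    uncorrectable: list[tuple[Loop, list[str]]] = []
    v_cur = v
    feasible = False
    was_feasible = False

    def is_feasible(vv: FluxVector, counter: int) -> bool:
        sub = build_thermo_subnetwork(net, vv)
        if sub.is_trivially_feasible:
            return True
        trace = check_feasibility(sub, step_cap=step_cap,
                                  seed=_derive_seed(seed, counter))
        is_feasible.last = (sub, trace)  # type: ignore[attr-defined]
        return trace.converged

    if strategy == "local":
        for it in range(cap):
            if is_feasible(v_cur, it):
                feasible = True
                was_feasible = it == 0
                break
            sub, trace = is_feasible.last  # type: ignore[attr-defined]
            loop = _find_one_loop(sub, trace, schedule, seed, it)
            if loop is None:
                raise RuntimeError(
                    "loop search exhausted without a cycle although the "
                    f"relaxation did not converge (candidates: "
                    f"{trace.candidate_ids})"
                )
            result = correct_local(net, v_cur, loop, constraints)
            if result.corrected:
                removed.append(loop)
                v_cur = result.v_after
            else:
                uncorrectable.append((loop, result.violated))
                break
        else:
            raise RuntimeError(
                f"iteration cap {cap} exceeded; removed {len(removed)} loops "
                "so far without reaching feasibility"
            )
    else:
        if is_feasible(v_cur, 0):
            feasible = True
            was_feasible = True
        else:
            sub, trace = is_feasible.last  # type: ignore[attr-defined]
            v_cur = correct_global(net, v_cur, constraints=None,
                                   fix_exchanges=True, fix_objective=True)
            if is_feasible(v_cur, 1):
                feasible = True
            else:
                sub2, trace2 = is_feasible.last  # type: ignore[attr-defined]
                loop = _find_one_loop(sub2, trace2, schedule, seed, 1)
                if loop is not None:
                    pinned = [
                        f"{net.reaction_ids[r]} >= {net.lower_bounds[r]:g}"
                        for r in loop.support
                        if net.lower_bounds[r] > 0
                    ] or ["unidentified binding constraint"]
                    uncorrectable.append((loop, pinned))

    if net.objective is not None and obj_before is not None:
        obj_after = float(net.objective @ v_cur.values)
        scale = max(abs(obj_before), 1.0)
        if abs(obj_after - obj_before) > objective_tolerance * scale:
            raise RuntimeError(
                f"objective drifted from {obj_before} to {obj_after}"
            )

    return CorrectionReport(
        v_before=v,
        v_after=v_cur,
        removed_loops=removed,
        uncorrectable_loops=uncorrectable,
        strategy=strategy,
        overlap_before_after=overlap(v, v_cur),
        active_counts_before=_active_counts(net, v),
        active_counts_after=_active_counts(net, v_cur),
        feasible=feasible,
        was_feasible_on_input=was_feasible,
    )


def delta_g_sign(net: MetabolicNetwork, v: FluxVector, reaction_id: str,
                 seed: int = 0) -> int:
    """Sign of the Gibbs energy change of a named reaction, read off the
    chemical-potential certificate of a feasible configuration.

    ``Delta G_r = sum_m mu_m S_mr`` up to a positive scale; requires the
    reaction to be retained in the thermodynamic subnetwork and the
    relaxation to converge.
    """
    sub = build_thermo_subnetwork(net, v)
    r = net.reaction_index(reaction_id)
    if r not in sub.kept_reactions:
        raise ValueError(f"{reaction_id!r} carries no thermodynamic "
                         "constraint in this configuration")
    trace = check_feasibility(sub, seed=seed)
    if not trace.converged:
        raise RuntimeError("configuration is not feasible: no certificate")
    slack = verify_certificate(sub, trace.mu_final)
    j = sub.kept_position(r)
    # slack_j = -sign(v_r) * mu.S_col, so Delta G sign = -sign(v_r)*slack sign
    return int(np.sign(-sub.direction_signs[j] * slack[j]))
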