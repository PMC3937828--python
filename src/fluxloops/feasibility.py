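"""Thermodynamic feasibility checking by relaxation on chemical potentials.

A flux configuration is thermodynamically feasible iff a chemical-potential
vector ``mu`` exists with ``mu . Omega > 0`` (every retained reaction runs
downhill in Gibbs energy).  By Gordan's theorem of the alternatives, exactly
one of the following holds: such a ``mu`` exists, or the dual system
``Omega k = 0`` has a nonzero solution ``k >= 0`` — an infeasible cycle.

The relaxation dynamics repeatedly selects the *least unsatisfied
constraint* (l.u.c.), the reaction ``r_t`` minimizing ``mu . Omega[:, r]``,
and shifts ``mu`` along that column.  On feasible instances the iteration
converges in polynomial time; on infeasible ones it cycles through the
reactions implicated in the cycles, so the distinct l.u.c. indices form a
small candidate set on which the loop search can be restricted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import ThermoSubnetwork

__all__ = ["RelaxationTrace", "check_feasibility", "verify_certificate"]

#: default strictness margin replacing the scale-free strict inequality
DEFAULT_MARGIN = 1.0

#: over-relaxation factor of the Motzkin update
MOTZKIN_LAMBDA = 1.5

#: fixed step size of the MinOver update, in units of the margin
MINOVER_ALPHA = 0.01

#: relative slack tolerance of the convergence test: a least slack of
#: margin * (1 - CONVERGENCE_RTOL) counts as converged.  Without it the
#: update step underflows once the worst violation falls below machine
#: precision and the iteration stalls just under the margin forever.
CONVERGENCE_RTOL = 1e-9


@dataclass
class RelaxationTrace:
    """Outcome of a relaxation run.

    ``luc_history`` and ``candidate_set`` hold *global* reaction indices of
    the parent network; ``candidate_set`` lists the distinct least
    unsatisfied constraints in order of first appearance.
    """

    converged: bool
    mu_final: np.ndarray
    luc_history: list[int]
    candidate_set: list[int]
    steps_used: int
    step_cap: int
    margin: float = DEFAULT_MARGIN
    candidate_ids: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "converged": self.converged,
            "steps_used": self.steps_used,
            "step_cap": self.step_cap,
            "margin": self.margin,
            "candidate_reactions": self.candidate_ids,
            "mu_final": list(map(float, self.mu_final)),
        })


def check_feasibility(
    sub: ThermoSubnetwork,
    mu0: np.ndarray | None = None,
    step_cap: int | None = None,
    margin: float = DEFAULT_MARGIN,
    scheme: str = "motzkin",
    seed: int = 0,
) -> RelaxationTrace:
    """Relax chemical potentials towards ``mu . Omega >= margin``.

    Parameters
    ----------
    sub
        Signed thermodynamic subnetwork (must retain at least one reaction).
    mu0
        Initial chemical potentials; default is a uniform random vector in
        [0, 1) drawn with ``seed``.
    step_cap
        Maximum number of relaxation steps ``T``; default
        ``1000 * n_kept``.
    margin
        Strictness margin: any solution of the strict system ``mu.Omega > 0``
        can be rescaled to clear an arbitrary positive margin, so this only
        fixes the scale of the certificate.
    scheme
        ``"motzkin"`` (step proportional to the violation, over-relaxed) or
        ``"minover"`` (small fixed step).

    Returns a :class:`RelaxationTrace`; ``converged=False`` means the step
    cap was exhausted and ``candidate_set`` holds the reactions cycled
    through by the l.u.c. dynamics.
    """
    if sub.is_trivially_feasible:
        raise ValueError("empty thermodynamic subnetwork: nothing to check")
    if margin <= 0:
        raise ValueError("margin must be positive")
    if scheme not in ("motzkin", "minover"):
        raise ValueError(f"unknown scheme {scheme!r}")
    omega = sub.omega
    norms2 = np.einsum("mr,mr->r", omega, omega)
    if (norms2 == 0).any():
        j = int(np.nonzero(norms2 == 0)[0][0])
        raise ValueError(
            f"zero Omega column for reaction {sub.reaction_ids[j]!r}: "
            "the constraint would be vacuous"
        )
    if step_cap is None:
        step_cap = 1000 * sub.n_kept
    if step_cap <= 0:
        raise ValueError("step_cap must be positive")
    if mu0 is None:
        mu = np.random.default_rng(seed).uniform(size=omega.shape[0])
    else:
        mu = np.asarray(mu0, dtype=float).copy()
        if mu.shape != (omega.shape[0],) or not np.isfinite(mu).all():
            raise ValueError("mu0 must be a finite vector over the metabolites")

    history: list[int] = []
    converged = False
    steps = 0
    for t in range(step_cap):
        scores = mu @ omega
        worst = int(np.argmin(scores))  # ties: lowest index
        if scores[worst] >= margin * (1.0 - CONVERGENCE_RTOL):
            converged = True
            break
        history.append(int(sub.kept_reactions[worst]))
        if scheme == "motzkin":
            alpha = MOTZKIN_LAMBDA * (margin - scores[worst]) / norms2[worst]
        else:
            alpha = MINOVER_ALPHA * margin
        mu += alpha * omega[:, worst]
        steps = t + 1

    candidates = list(dict.fromkeys(history))
    id_of = dict(zip(sub.kept_reactions.tolist(), sub.reaction_ids))
    return RelaxationTrace(
        converged=converged,
        mu_final=mu,
        luc_history=history,
        candidate_set=candidates,
        steps_used=steps,
        step_cap=step_cap,
        margin=margin,
        candidate_ids=[id_of[r] for r in candidates],
    )


def verify_certificate(sub: ThermoSubnetwork, mu: np.ndarray) -> np.ndarray:
    """Per-reaction slacks ``mu . Omega[:, r]``; all positive certifies
    feasibility of the underlying flux configuration."""
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (sub.omega.shape[0],):
        raise ValueError("mu length does not match metabolite count")
    return mu @ sub.omega
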