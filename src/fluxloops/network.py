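"""Stoichiometric network data model, readers/writers and fixture generators.

A metabolic network at steady state satisfies the mass balance ``S v = 0``,
where ``S`` is the metabolites x reactions stoichiometric matrix and ``v``
the flux vector, with per-reaction bounds ``v_min <= v <= v_max``.
Thermodynamic analysis works on a *signed* restriction of the network: for a
given flux vector the matrix ``Omega`` with entries
``Omega[m, r] = -sign(v_r) * S[m, r]`` collects, over the thermodynamically
constrained reactions, the inequalities ``mu . Omega > 0`` that a vector of
chemical potentials must satisfy for the configuration to be free of
infeasible cycles.  Exchange (boundary) reactions, the objective reaction,
reactions with non-integer stoichiometry and reactions carrying a null flux
carry no such constraint and are excluded from ``Omega``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "MetabolicNetwork",
    "FluxVector",
    "ThermoSubnetwork",
    "NetworkFormatError",
    "NetworkValidationError",
    "read_network",
    "write_network",
    "toy_network",
    "build_thermo_subnetwork",
    "generate_random_loopy_network",
    "read_flux_tsv",
    "write_flux_tsv",
]

#: default magnitude below which a flux is treated as null
DEFAULT_ZERO_THRESHOLD = 1e-6

#: tolerance used to decide whether a stoichiometric coefficient is integer
INTEGER_STOICH_TOL = 1e-9


class NetworkValidationError(ValueError):
    """Raised when a network or flux vector violates a structural invariant."""


class NetworkFormatError(ValueError):
    """Raised when an input file cannot be parsed in the requested dialect."""


@dataclass
class MetabolicNetwork:
    """A stoichiometric network with flux bounds.

    Parameters
    ----------
    stoichiometry
        Dense ``(M, N)`` matrix; entry ``[m, r]`` is the signed
        stoichiometric coefficient of metabolite ``m`` in reaction ``r``
        (products positive, substrates negative).
    reaction_ids, metabolite_ids
        Unique identifier lists of lengths ``N`` and ``M``.
    lower_bounds, upper_bounds
        Per-reaction flux bounds (arbitrary flux units).
    exchange_flags
        Boolean mask marking boundary (uptake/sink) reactions.  If omitted,
        a reaction whose column has exactly one nonzero entry is flagged.
    objective
        Optional per-reaction objective coefficients (e.g. biomass).
    """

    stoichiometry: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    exchange_flags: np.ndarray | None = None
    objective: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.reaction_ids = list(self.reaction_ids)
        self.metabolite_ids = list(self.metabolite_ids)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        if self.n_reactions == 0:
            raise NetworkValidationError("network has no reactions")
        if self.stoichiometry.shape != (self.n_metabolites, self.n_reactions):
            raise NetworkValidationError(
                f"stoichiometry shape {self.stoichiometry.shape} does not match "
                f"{self.n_metabolites} metabolites x {self.n_reactions} reactions"
            )
        for name, ids in (("reaction", self.reaction_ids),
                          ("metabolite", self.metabolite_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})
                raise NetworkValidationError(f"duplicate {name} ids: {dup}")
        if self.lower_bounds.shape != (self.n_reactions,) or \
                self.upper_bounds.shape != (self.n_reactions,):
            raise NetworkValidationError("bounds length does not match reactions")
        bad = np.nonzero(self.lower_bounds > self.upper_bounds)[0]
        if bad.size:
            raise NetworkValidationError(
                f"lower bound exceeds upper bound for {self.reaction_ids[bad[0]]}"
            )
        if self.exchange_flags is None:
            self.exchange_flags = self.detect_exchanges()
        else:
            self.exchange_flags = np.asarray(self.exchange_flags, dtype=bool)
            if self.exchange_flags.shape != (self.n_reactions,):
                raise NetworkValidationError("exchange_flags length mismatch")
        if self.objective is not None:
            self.objective = np.asarray(self.objective, dtype=float)
            if self.objective.shape != (self.n_reactions,):
                raise NetworkValidationError("objective length mismatch")
            if not self.objective.any():
                self.objective = None

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def reversible(self) -> np.ndarray:
        """Mask of reactions allowed to run in both directions."""
        return (self.lower_bounds < 0) & (self.upper_bounds > 0)

    def detect_exchanges(self) -> np.ndarray:
        """Boundary reactions: columns with exactly one nonzero coefficient."""
        return np.count_nonzero(self.stoichiometry, axis=0) == 1

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def integer_stoichiometry_mask(self) -> np.ndarray:
        """Mask of reactions whose coefficients are all (near-)integer."""
        dist = np.abs(self.stoichiometry - np.rint(self.stoichiometry))
        return (dist <= INTEGER_STOICH_TOL).all(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        obj_a = self.objective if self.objective is not None else 0
        obj_b = other.objective if other.objective is not None else 0
        return (
            self.reaction_ids == other.reaction_ids
            and self.metabolite_ids == other.metabolite_ids
            and np.array_equal(self.stoichiometry, other.stoichiometry)
            and np.array_equal(self.lower_bounds, other.lower_bounds)
            and np.array_equal(self.upper_bounds, other.upper_bounds)
            and np.array_equal(self.exchange_flags, other.exchange_flags)
            and np.array_equal(np.atleast_1d(obj_a), np.atleast_1d(obj_b))
        )


@dataclass
class FluxVector:
    """A flux configuration aligned to a network's reaction list."""

    values: np.ndarray
    zero_threshold: float = DEFAULT_ZERO_THRESHOLD

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise NetworkValidationError("flux vector must be one-dimensional")
        if self.zero_threshold <= 0:
            raise NetworkValidationError("zero_threshold must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def active(self) -> np.ndarray:
        """Mask of reactions carrying a non-null flux (|v| >= threshold)."""
        return np.abs(self.values) >= self.zero_threshold

    def copy_with(self, values: np.ndarray) -> "FluxVector":
        return FluxVector(np.asarray(values, dtype=float),
                          zero_threshold=self.zero_threshold)


@dataclass
class ThermoSubnetwork:
    """The signed restriction of a network used for thermodynamic checks.

    ``omega[:, j] = -direction_signs[j] * S[:, kept_reactions[j]]``.
    """

    kept_reactions: np.ndarray          # global reaction indices, shape (K,)
    omega: np.ndarray                   # (M, K)
    direction_signs: np.ndarray         # (K,) entries in {+1, -1}
    reaction_ids: list[str] = field(default_factory=list)
    n_reactions_total: int = 0          # N of the parent network
    _pos: dict[int, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.kept_reactions = np.asarray(self.kept_reactions, dtype=np.intp)
        self.omega = np.asarray(self.omega, dtype=float)
        self.direction_signs = np.asarray(self.direction_signs, dtype=int)
        self._pos = {int(g): j for j, g in enumerate(self.kept_reactions)}

    @property
    def n_kept(self) -> int:
        return self.kept_reactions.size

    @property
    def is_trivially_feasible(self) -> bool:
        """No reaction carries a thermodynamic constraint."""
        return self.n_kept == 0

    def kept_position(self, global_index: int) -> int:
        return self._pos[int(global_index)]

    def omega_int(self) -> np.ndarray:
        """Omega as an exact integer matrix (kept reactions have integer S)."""
        return np.rint(self.omega).astype(np.int64)


def build_thermo_subnetwork(net: MetabolicNetwork, v: FluxVector) -> ThermoSubnetwork:
    """Restrict ``net`` to thermodynamically constrained reactions under ``v``.

    Excluded are exchange reactions, the objective reaction(s), reactions
    with non-integer stoichiometry, reactions touching no metabolite and
    reactions whose flux is null.  The sign of each retained flux fixes the
    operating direction; ``sign(0)`` is never consulted because null fluxes
    are excluded first.
    """
    if len(v) != net.n_reactions:
        raise NetworkValidationError("flux vector length does not match network")
    keep = ~net.exchange_flags
    keep &= net.integer_stoichiometry_mask()
    keep &= np.count_nonzero(net.stoichiometry, axis=0) > 0
    if net.objective is not None:
        keep &= net.objective == 0
    keep &= v.active
    kept = np.nonzero(keep)[0]
    signs = np.sign(v.values[kept]).astype(int)
    omega = -net.stoichiometry[:, kept] * signs[np.newaxis, :]
    return ThermoSubnetwork(
        kept_reactions=kept,
        omega=omega,
        direction_signs=signs,
        reaction_ids=[net.reaction_ids[i] for i in kept],
        n_reactions_total=net.n_reactions,
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def toy_network(epsilon: float = 0.0,
                free_bound: float = 1000.0) -> tuple[MetabolicNetwork, FluxVector]:
    """The four-reaction example network with one infeasible two-cycle.

    Two metabolites A and B; R1 converts A -> B, R2 converts B -> A, an
    intake feeds A at a fixed rate 2 and a sink drains B at the same rate.
    The internal flux vector (3, 1) runs R1 and R2 in the same net
    direction, closing a cycle that could transfer matter without free
    energy expenditure.  ``epsilon`` is the lower bound imposed on the
    second internal flux (``epsilon = 0`` makes R2 irreversible).
    """
    S = np.array([
        [-1.0, 1.0, 1.0, 0.0],
        [1.0, -1.0, 0.0, -1.0],
    ])
    net = MetabolicNetwork(
        stoichiometry=S,
        reaction_ids=["R1", "R2", "EX_in", "EX_out"],
        metabolite_ids=["A", "B"],
        lower_bounds=np.array([-free_bound, float(epsilon), 2.0, 2.0]),
        upper_bounds=np.array([free_bound, free_bound, 2.0, 2.0]),
    )
    v = FluxVector(np.array([3.0, 1.0, 2.0, 2.0]))
    return net, v


def generate_random_loopy_network(
    n_metabolites: int,
    n_reactions: int,
    n_planted_cycles: int,
    seed: int,
    cycle_length: tuple[int, int] = (3, 5),
):
    """Random mass-balanced network with ``n_planted_cycles`` planted cycles.

    Each planted cycle is a closed chain of reversible unit-stoichiometry
    conversions over distinct metabolites, so ``k = (1, ..., 1)`` on its
    reactions solves ``Omega k = 0`` when every cycle reaction runs forward.
    Remaining reaction slots are filled first with conversions that connect
    previously disconnected components (a forest, which cannot close new
    cycles) and then with exchange reactions; the independent-cycle count of
    the result therefore equals ``n_planted_cycles`` exactly.

    Returns ``(network, loops)`` where each loop is a
    :class:`fluxloops.loops.Loop` over the full reaction space.
    """
    from .loops import Loop  # deferred: loops imports network types

    if n_metabolites <= 0 or n_reactions <= 0 or n_planted_cycles < 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = cycle_length
    if lo < 3:
        raise ValueError("planted cycles need at least 3 reactions")

    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_planted_cycles)]
    if sum(lengths) > n_metabolites or sum(lengths) > n_reactions:
        raise ValueError(
            "infeasible size combination: planted cycles need "
            f"{sum(lengths)} metabolites and reactions"
        )

    columns: list[np.ndarray] = []
    rxn_ids: list[str] = []
    lbs: list[float] = []
    ubs: list[float] = []
    # union-find over metabolites to keep filler conversions acyclic
    parent = list(range(n_metabolites))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    met_pool = list(rng.permutation(n_metabolites))
    loop_supports: list[list[int]] = []
    for length in lengths:
        mets = [met_pool.pop() for _ in range(length)]
        support = []
        for i in range(length):
            col = np.zeros(n_metabolites)
            col[mets[i]] = -1.0
            col[mets[(i + 1) % length]] = 1.0
            support.append(len(columns))
            columns.append(col)
            rxn_ids.append(f"C{len(loop_supports)}_{i}")
            lbs.append(-10.0)
            ubs.append(10.0)
        for m in mets[1:]:
            parent[find(m)] = find(mets[0])
        loop_supports.append(support)

    # filler conversions: only between distinct components (forest edges)
    while len(columns) < n_reactions:
        roots = {find(m) for m in range(n_metabolites)}
        if len(roots) > 1:
            ra, rb = rng.choice(sorted(roots), size=2, replace=False)
            a = int(rng.choice([m for m in range(n_metabolites) if find(m) == ra]))
            b = int(rng.choice([m for m in range(n_metabolites) if find(m) == rb]))
            col = np.zeros(n_metabolites)
            col[a], col[b] = -1.0, 1.0
            columns.append(col)
            rxn_ids.append(f"T{len(columns)}")
            if rng.random() < 0.5:
                lbs.append(-10.0)
            else:
                lbs.append(0.0)
            ubs.append(10.0)
            parent[find(a)] = find(b)
        else:
            m = int(rng.integers(n_metabolites))
            col = np.zeros(n_metabolites)
            col[m] = 1.0
            columns.append(col)
            rxn_ids.append(f"EX{len(columns)}")
            lbs.append(-10.0)
            ubs.append(10.0)

    net = MetabolicNetwork(
        stoichiometry=np.column_stack(columns),
        reaction_ids=rxn_ids,
        metabolite_ids=[f"m{i}" for i in range(n_metabolites)],
        lower_bounds=np.array(lbs),
        upper_bounds=np.array(ubs),
    )
    loops = []
    for support in loop_supports:
        k = np.zeros(net.n_reactions, dtype=np.int64)
        k[support] = 1
        loops.append(Loop(k=k, n=k.copy()))
    return net, loops


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# Matrix file: header row of reaction ids, first column metabolite ids,
# entries decimal or rational "p/q".  Sidecar "<path>.meta.tsv": one row per
# reaction with lower/upper bound, exchange flag and objective coefficient.

def _format_coeff(x: float) -> str:
    if x == int(x):
        return str(int(x))
    frac = Fraction(x).limit_denominator(10**6)
    if abs(float(frac) - x) < 1e-12:
        return f"{frac.numerator}/{frac.denominator}"
    return repr(x)


def _parse_coeff(tok: str) -> float:
    tok = tok.strip()
    if "/" in tok:
        return float(Fraction(tok))
    return float(tok)


def _meta_path(path: str) -> str:
    return str(path) + ".meta.tsv"


def _write_tsv(net: MetabolicNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metabolite\t" + "\t".join(net.reaction_ids) + "\n")
        for m, mid in enumerate(net.metabolite_ids):
            row = "\t".join(_format_coeff(x) for x in net.stoichiometry[m])
            fh.write(f"{mid}\t{row}\n")
    obj = net.objective if net.objective is not None else np.zeros(net.n_reactions)
    with open(_meta_path(path), "w") as fh:
        fh.write("reaction\tlower_bound\tupper_bound\texchange\tobjective\n")
        for r, rid in enumerate(net.reaction_ids):
            fh.write(
                f"{rid}\t{float(net.lower_bounds[r])!r}\t"
                f"{float(net.upper_bounds[r])!r}\t"
                f"{int(net.exchange_flags[r])}\t{float(obj[r])!r}\n"
            )


def _read_tsv(path: str) -> MetabolicNetwork:
    try:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 2:
                raise NetworkFormatError(f"{path}: header row has no reactions")
            rxn_ids = header[1:]
            met_ids, rows = [], []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                toks = line.rstrip("\n").split("\t")
                if len(toks) != len(rxn_ids) + 1:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: expected {len(rxn_ids) + 1} columns, "
                        f"got {len(toks)}"
                    )
                met_ids.append(toks[0])
                try:
                    rows.append([_parse_coeff(t) for t in toks[1:]])
                except (ValueError, ZeroDivisionError) as exc:
                    raise NetworkFormatError(
                        f"{path}:{lineno}: bad coefficient ({exc})"
                    ) from exc
    except OSError as exc:
        raise NetworkFormatError(f"cannot read {path}: {exc}") from exc

    meta = _meta_path(path)
    lb = np.full(len(rxn_ids), -np.inf)
    ub = np.full(len(rxn_ids), np.inf)
    exch = None
    obj = np.zeros(len(rxn_ids))
    if os.path.exists(meta):
        exch = np.zeros(len(rxn_ids), dtype=bool)
        index = {rid: i for i, rid in enumerate(rxn_ids)}
        with open(meta) as fh:
            fh.readline()
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                toks = line.rstrip("\n").split("\t")
                if len(toks) != 5:
                    raise NetworkFormatError(f"{meta}:{lineno}: expected 5 columns")
                if toks[0] not in index:
                    raise NetworkFormatError(
                        f"{meta}:{lineno}: unknown reaction {toks[0]!r}"
                    )
                r = index[toks[0]]
                lb[r], ub[r] = float(toks[1]), float(toks[2])
                exch[r] = bool(int(toks[3]))
                obj[r] = float(toks[4])
    return MetabolicNetwork(
        stoichiometry=np.array(rows),
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        lower_bounds=lb,
        upper_bounds=ub,
        exchange_flags=exch,
        objective=obj if obj.any() else None,
    )


# ---------------------------------------------------------------------------
# SBML (via cobrapy, FBC bounds/objective)
# ---------------------------------------------------------------------------

def _to_cobra(net: MetabolicNetwork):
    import cobra

    model = cobra.Model("fluxloops_model")
    mets = []
    for mid in net.metabolite_ids:
        m = cobra.Metabolite(mid, compartment="c")
        mets.append(m)
    model.add_metabolites(mets)
    rxns = []
    for r, rid in enumerate(net.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(net.lower_bounds[r])
        rxn.upper_bound = float(net.upper_bounds[r])
        rxns.append(rxn)
    model.add_reactions(rxns)
    for r, rxn in enumerate(rxns):
        coeffs = {
            mets[m]: float(net.stoichiometry[m, r])
            for m in range(net.n_metabolites)
            if net.stoichiometry[m, r] != 0
        }
        rxn.add_metabolites(coeffs)
    if net.objective is not None:
        model.objective = {
            rxns[r]: float(net.objective[r])
            for r in np.nonzero(net.objective)[0]
        }
    return model


def _from_cobra(model) -> MetabolicNetwork:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(model, array_type="dense")
    rxn_ids = [r.id for r in model.reactions]
    met_ids = [m.id for m in model.metabolites]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    obj = np.array([r.objective_coefficient for r in model.reactions], dtype=float)
    return MetabolicNetwork(
        stoichiometry=S,
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        lower_bounds=lb,
        upper_bounds=ub,
        objective=obj if obj.any() else None,
    )


def read_network(path: str, format: str = "auto") -> MetabolicNetwork:
    """Read a network from SBML (Level 2/3, FBC bounds) or the TSV dialect."""
    if format == "auto":
        format = "sbml" if str(path).endswith((".xml", ".sbml")) else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        import logging

        import cobra

        # objective-less models are fine here; mute cobra's error line
        sbml_logger = logging.getLogger("cobra.io.sbml")
        level = sbml_logger.level
        sbml_logger.setLevel(logging.CRITICAL)
        try:
            model = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # cobra raises a zoo of parse errors
            raise NetworkFormatError(f"cannot parse SBML {path}: {exc}") from exc
        finally:
            sbml_logger.setLevel(level)
        return _from_cobra(model)
    raise ValueError(f"unknown format {format!r}")


def write_network(net: MetabolicNetwork, path: str, format: str = "auto") -> None:
    """Write a network as SBML Level 3 (FBC) or the TSV dialect."""
    if format == "auto":
        format = "sbml" if str(path).endswith((".xml", ".sbml")) else "tsv"
    if format == "tsv":
        _write_tsv(net, path)
    elif format == "sbml":
        import cobra

        cobra.io.write_sbml_model(_to_cobra(net), str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def write_flux_tsv(net: MetabolicNetwork, v: FluxVector, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction\tflux\n")
        for rid, x in zip(net.reaction_ids, v.values):
            fh.write(f"{rid}\t{float(x)!r}\n")


def read_flux_tsv(net: MetabolicNetwork, path: str,
                  zero_threshold: float = DEFAULT_ZERO_THRESHOLD) -> FluxVector:
    values = np.zeros(net.n_reactions)
    seen = np.zeros(net.n_reactions, dtype=bool)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("reaction"):
            raise NetworkFormatError(f"{path}: missing 'reaction\\tflux' header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            if len(toks) != 2:
                raise NetworkFormatError(f"{path}:{lineno}: expected 2 columns")
            r = net.reaction_index(toks[0])
            values[r] = float(toks[1])
            seen[r] = True
    if not seen.all():
        missing = net.reaction_ids[int(np.nonzero(~seen)[0][0])]
        raise NetworkFormatError(f"{path}: no flux given for {missing}")
    return FluxVector(values, zero_threshold=zero_threshold)
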