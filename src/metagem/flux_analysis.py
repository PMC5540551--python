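"""Stage 4 — flux balance analysis with biogeochemical objective functions.

FBA maximizes Z = c'v subject to steady-state mass balance S v = 0 and flux
bounds v_LB <= v <= v_UB.  For a community meta-organism the biologically
meaningful objectives are not biomass but the reactions regulating the
nitrogen, sulfur and carbon cycles; the shipped objective library carries
those reaction sets, plus the TCA-related and fatty-acid-elongation blocks
(including the cytoplasm<->mitochondrion exchange reactions) used to probe
the effect of compartmentalization on flux predictions.

Bound policy: irreversible reactions (0, 100), reversible reactions
(-1000, 100) mmol gDW^-1 h^-1, overridable per problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_core import (
    DEFAULT_UPPER_BOUND,
    REVERSIBLE_LOWER_BOUND,
    COEFF_TOL,
    CompartmentalizedNetwork,
    StoichiometricMatrix,
    build_stoichiometric_matrix,
    parse_equation,
)

__all__ = [
    "ObjectiveFunction",
    "BoundPolicy",
    "FluxProblem",
    "FluxResult",
    "build_problem",
    "solve",
    "active_flux_fraction",
    "exclude_reactions",
    "objective_library",
    "instantiate_objective",
    "ACTIVE_FLUX_TOLERANCE",
]

#: |v| above which a flux counts as active (LP solver noise floor).
ACTIVE_FLUX_TOLERANCE = 1e-6


@dataclass
class ObjectiveFunction:
    """Named weight vector c over reaction ids (unit weights by default)."""

    name: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not any(self.weights.values()):
            raise ValueError(f"objective {self.name!r} has no nonzero weight")

    @staticmethod
    def for_reactions(name: str, reaction_ids: Iterable[str]) -> "ObjectiveFunction":
        return ObjectiveFunction(name, {r: 1.0 for r in reaction_ids})


@dataclass(frozen=True)
class BoundPolicy:
    upper: float = DEFAULT_UPPER_BOUND
    reversible_lower: float = REVERSIBLE_LOWER_BOUND

    def bounds_for(self, reversible: bool) -> tuple[float, float]:
        return (self.reversible_lower if reversible else 0.0, self.upper)


@dataclass
class FluxProblem:
    matrix: StoichiometricMatrix
    objective: ObjectiveFunction
    lower: np.ndarray
    upper: np.ndarray

    @property
    def c(self) -> np.ndarray:
        c = np.zeros(len(self.matrix.col_index))
        for rid, w in self.objective.weights.items():
            c[self.matrix.col(rid)] = w
        return c


@dataclass
class FluxResult:
    Z: float | None
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded | solver_error
    active_fractions: dict[str, float | None] = field(default_factory=dict)

    @property
    def v(self) -> np.ndarray:
        return np.array(list(self.fluxes.values()))


def build_problem(
    network: CompartmentalizedNetwork,
    objective: ObjectiveFunction,
    bound_policy: BoundPolicy | None = None,
) -> FluxProblem:
    """Assemble S, c and the bound vectors.

    With ``bound_policy=None`` the bounds stored on each reaction are used;
    passing a policy re-derives every bound from the reaction's
    reversibility (e.g. to re-run with an upper bound of 1000).
    """
    matrix = build_stoichiometric_matrix(network)
    missing = [r for r in objective.weights if r not in network.reactions]
    if missing:
        raise KeyError(f"objective {objective.name!r} references absent reactions: {missing}")
    lbs, ubs = [], []
    for rid in matrix.col_index:
        rxn = network.reactions[rid]
        if bound_policy is None:
            lbs.append(rxn.lower_bound)
            ubs.append(rxn.upper_bound)
        else:
            lo, hi = bound_policy.bounds_for(rxn.reversible)
            lbs.append(lo)
            ubs.append(hi)
    return FluxProblem(matrix, objective, np.array(lbs), np.array(ubs))


_STATUS = {0: "optimal", 1: "solver_error", 2: "infeasible", 3: "unbounded", 4: "solver_error"}


def solve(problem: FluxProblem, *, stabilize: bool = False) -> FluxResult:
    """Maximize c'v subject to S v = 0 and the bounds (HiGHS).

    ``stabilize=True`` runs a secondary step that fixes the optimum Z and
    minimizes the total absolute flux, making active-flux counts
    well-defined under degenerate alternative optima.
    """
    S = problem.matrix.S
    n = len(problem.matrix.col_index)
    c = problem.c
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([problem.lower, problem.upper]),
        method="highs",
    )
    status = _STATUS.get(res.status, "solver_error")
    if status != "optimal":
        return FluxResult(Z=None, fluxes={}, status=status)
    v = res.x
    Z = float(c @ v)
    if stabilize:
        v = _minimize_total_flux(problem, Z, v)
    fluxes = {rid: float(v[j]) for j, rid in enumerate(problem.matrix.col_index)}
    return FluxResult(Z=Z, fluxes=fluxes, status="optimal")


def _minimize_total_flux(problem: FluxProblem, Z: float, fallback: np.ndarray) -> np.ndarray:
    S = problem.matrix.S
    ns, n = S.shape
    c = problem.c
    big = max(np.max(np.abs(problem.lower)), np.max(np.abs(problem.upper)), 1.0)
    # variables [v | s], minimize sum s with s >= |v|
    obj = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sp.hstack([S, sp.csr_matrix((ns, n))]).tocsr()
    eye = sp.identity(n)
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])]).tocsr()
    b_ub = np.zeros(2 * n)
    # keep the optimum (to LP tolerance)
    A_ub = sp.vstack([A_ub, sp.csr_matrix(np.concatenate([-c, np.zeros(n)]))]).tocsr()
    b_ub = np.concatenate([b_ub, [-Z + 1e-9 * max(abs(Z), 1.0)]])
    bounds = np.column_stack(
        [
            np.concatenate([problem.lower, np.zeros(n)]),
            np.concatenate([problem.upper, np.full(n, big)]),
        ]
    )
    res = linprog(
        obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(ns), bounds=bounds, method="highs"
    )
    if res.status != 0:
        return fallback
    return res.x[:n]


def active_flux_fraction(
    result: FluxResult,
    scopes: Mapping[str, Iterable[str]],
    tolerance: float = ACTIVE_FLUX_TOLERANCE,
) -> dict[str, float | None]:
    """Percentage of reactions in each scope carrying |v| > tolerance.

    Scopes are named reaction subsets (whole network, one compartment, a
    pathway tag).  Empty scopes report ``None`` (NA).
    """
    if result.status != "optimal":
        raise ValueError("active-flux fractions require an optimal solution")
    out: dict[str, float | None] = {}
    for name, ids in scopes.items():
        ids = list(ids)
        if not ids:
            out[name] = None
            continue
        active = sum(1 for r in ids if abs(result.fluxes.get(r, 0.0)) > tolerance)
        out[name] = 100.0 * active / len(ids)
    result.active_fractions.update(out)
    return out


def exclude_reactions(problem: FluxProblem, reaction_ids: Iterable[str]) -> FluxProblem:
    """Force the listed reactions' bounds to (0, 0); everything else untouched."""
    lower = problem.lower.copy()
    upper = problem.upper.copy()
    for rid in reaction_ids:
        j = problem.matrix.col_index.index(rid) if rid in problem.matrix.col_index else -1
        if j < 0:
            raise KeyError(f"unknown reaction {rid!r}")
        lower[j] = 0.0
        upper[j] = 0.0
    return FluxProblem(problem.matrix, problem.objective, lower, upper)


# ---------------------------------------------------------------------------
# objective library (carbon / sulfur / nitrogen cycles, TCA, fatty acids)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectiveTemplate:
    """One template reaction of an objective block, in the package's
    equation dialect (species placed in the cytoplasm unless tagged)."""

    id: str
    equation: str


@dataclass
class ObjectiveBlock:
    name: str
    templates: list[ObjectiveTemplate]

    def template_ids(self) -> list[str]:
        return [t.id for t in self.templates]


def objective_library(*, electron_acceptor: str = "fdxox") -> dict[str, ObjectiveBlock]:
    """The shipped biogeochemical objective blocks.

    The generic electron acceptor written simply as "A" in the source
    tables is mapped to oxidized ferredoxin by default (it balances the
    reduced-ferredoxin terms of the same blocks); override
    ``electron_acceptor`` to remap it.
    """
    A = electron_acceptor
    nitrogen = [
        ObjectiveTemplate(
            "NFIX",
            f"8 h + 8 fdxrd + 16 h2o + 16 atp + 1 n2 <=> 2 nh4 + 1 h2 + 8 {A} + 16 adp + 16 pi",
        ),
        ObjectiveTemplate("HAO", "1 q + 1 h2o + 1 nh2oh <=> 1 nh4 + 1 o2 + 1 qh2"),
        ObjectiveTemplate("NIR", "5 h + 1 no2 + 2 focytc = 2 ficytc + 1 h2o + 1 nh2oh"),
        ObjectiveTemplate("NOR", "2 h + 2 focytc + 1 n2o <=> 2 ficytc + 1 h2o + 1 n2"),
    ]
    sulfur = [
        ObjectiveTemplate("SQR", "3 h2o + 3 nadp + 1 h2s <=> 1 h + 1 so3 + 3 nadph"),
        ObjectiveTemplate("SOR", f"3 h2o + 3 {A} + 1 h2s = 8 h + 1 so3 + 3 fdxrd"),
        ObjectiveTemplate("APR", "2 h + 2 focytc + 1 so4 <=> 1 so3 + 2 ficytc + 1 h2o"),
        ObjectiveTemplate("SOX", "1 h2o2 + 1 so4 <=> 1 so3 + 1 h2o + 1 o2"),
    ]
    tca = [
        ObjectiveTemplate("ACKr", "1 acp + 1 adp <=> 1 ac + 1 atp"),
        ObjectiveTemplate("T_oaa_cm", "oaa@c <=> oaa@m"),
        ObjectiveTemplate("T_accoa_cm", "accoa@c <=> accoa@m"),
        ObjectiveTemplate("T_akg_cm", "akg@c <=> akg@m"),
        ObjectiveTemplate("CITL", "cit + coa <=> accoa + h2o + oaa"),
        ObjectiveTemplate("PEPCK", "atp + oaa <=> adp + pep + co2"),
        ObjectiveTemplate("PDHL", "accoa + dhlam <=> coa + adhlam"),
    ]
    fatty = [
        ObjectiveTemplate("FACOAL160", "atp + hdca + coa <=> amp + pmtcoa + ppi"),
        ObjectiveTemplate("ELONG", "pmtcoa + accoa <=> coa + oxoacoa"),
        ObjectiveTemplate("T_accoa_cm", "accoa@c <=> accoa@m"),
    ]
    return {
        "nitrogen_cycle": ObjectiveBlock("nitrogen_cycle", nitrogen),
        "sulfur_cycle": ObjectiveBlock("sulfur_cycle", sulfur),
        "tca_cycle": ObjectiveBlock("tca_cycle", tca),
        "fatty_acid_elongation": ObjectiveBlock("fatty_acid_elongation", fatty),
    }


def _stoich_key(stoich: Mapping[str, float]) -> tuple:
    return tuple(sorted((s, round(c, 9)) for s, c in stoich.items()))


def instantiate_objective(
    network: CompartmentalizedNetwork,
    block: ObjectiveBlock,
) -> tuple[ObjectiveFunction | None, list[str]]:
    """Resolve a template block against a network.

    A template matches a network reaction by id, else by exact (possibly
    orientation-flipped) stoichiometry.  Copies of a matching reaction in
    several compartments all join the objective (duplicated pathways
    contribute per copy).  Returns the unit-weight objective over matched
    reactions and the list of unresolved template ids (None if nothing
    matched).
    """
    by_stoich: dict[tuple, list[str]] = {}
    for rid in sorted(network.reactions):
        r = network.reactions[rid]
        by_stoich.setdefault(_stoich_key(r.stoichiometry), []).append(rid)
        by_stoich.setdefault(
            _stoich_key({s: -c for s, c in r.stoichiometry.items()}), []
        ).append(rid)
    matched: list[str] = []
    unresolved: list[str] = []
    for t in block.templates:
        hits = []
        # id match: the exact id or its per-compartment copies
        for rid in sorted(network.reactions):
            if rid == t.id or rid.startswith(f"{t.id}@"):
                hits.append(rid)
        if not hits:
            stoich, _ = parse_equation(t.equation)
            hits = sorted(set(by_stoich.get(_stoich_key(stoich), [])))
        if hits:
            matched.extend(hits)
        else:
            unresolved.append(t.id)
    matched = sorted(set(matched))
    if not matched:
        return None, unresolved
    return ObjectiveFunction.for_reactions(block.name, matched), unresolved


def steady_state_residual(problem: FluxProblem, result: FluxResult) -> float:
    """max |S v| over species for an optimal solution (should be < 1e-6)."""
    v = np.array([result.fluxes[r] for r in problem.matrix.col_index])
    return float(np.max(np.abs(problem.matrix.S @ v))) if len(v) else 0.0


def write_objective_templates(path, *, electron_acceptor: str = "fdxox") -> None:
    """Dump the objective library as a plain-text equation file (one block
    header per cycle, one template per line, standard dialect)."""
    lines = []
    for name, block in objective_library(electron_acceptor=electron_acceptor).items():
        lines.append(f"# {name}")
        for t in block.templates:
            lines.append(f"{t.id}\t{t.equation}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
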