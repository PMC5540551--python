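"""Stage 3 — gap detection (GapFind) and gap filling (GapFill) as MILPs.

A species is a *no-production* dead end when no admissible flux pattern can
make any reaction produce it, and a *no-consumption* dead end in the
symmetric sense.  Production is certified GapFind-style: a binary indicator
per candidate producing (species, reaction, direction) pair is linked to
the flux through a big-M constraint requiring an individual contribution of
at least ``eps``, while steady-state mass balance is relaxed to allow
accumulation (``S v >= 0``); consumption uses the network with every
reaction reversed.  Gap filling selects a minimum-cardinality set of
database reactions (plus exchange templates) whose addition makes target
species producible *and* consumable.

Compartmentalized curation follows a fixed three-step order: cytoplasmic
gaps are filled first; then cytoplasm<->inner-compartment exchange
reactions are added (a large share of inner-compartment gaps are shared
with the cytoplasm and can be resolved by exchange alone); finally the
remaining compartments are completed separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .model_core import (
    CompartmentalizedNetwork,
    NetworkError,
    Reaction,
    Species,
    build_stoichiometric_matrix,
    infer_rtype,
)

__all__ = [
    "GapConfig",
    "GapReport",
    "GapFillSolution",
    "CurationStats",
    "gapfind",
    "gapfill",
    "gapfill_batch",
    "curate_compartmentalized",
    "reconnection_percentage",
    "instantiate_candidates",
]


@dataclass(frozen=True)
class GapConfig:
    """MILP constants: eps is the minimum flux that counts as production,
    M the big-M scale (per-pair values are tightened from the actual
    bounds so large stoichiometric coefficients cannot defeat the
    linearization)."""

    eps: float = 1e-3
    M: float = 1000.0


@dataclass
class GapReport:
    """Dead-end species of a network, with per-compartment bookkeeping."""

    non_produced: set[str] = field(default_factory=set)
    non_consumed: set[str] = field(default_factory=set)
    per_compartment_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    common_gaps: dict[tuple[str, str], int] = field(default_factory=dict)

    def problem_species(self) -> set[str]:
        return self.non_produced | self.non_consumed

    def connected(self, universe: set[str]) -> set[str]:
        return universe - self.problem_species()


@dataclass
class GapFillSolution:
    target_species: str
    added_reaction_ids: list[str] = field(default_factory=list)
    added_exchange_ids: list[str] = field(default_factory=list)
    feasible: bool = False

    @property
    def n_added(self) -> int:
        return len(self.added_reaction_ids) + len(self.added_exchange_ids)


@dataclass
class CurationStats:
    """Reconnection bookkeeping over the pre-curation species universe."""

    per_compartment_before: dict[str, float | None] = field(default_factory=dict)
    per_compartment_after: dict[str, float | None] = field(default_factory=dict)
    added_by_step: dict[str, list[str]] = field(default_factory=dict)
    common_gaps: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total_added(self) -> int:
        return sum(len(v) for v in self.added_by_step.values())


# ---------------------------------------------------------------------------
# GapFind
# ---------------------------------------------------------------------------


def _milp(c, constraints, integrality, bounds, options=None):
    """milp with an infeasibility double-check.

    HiGHS presolve can falsely prove big-M certificate systems infeasible
    (observed on networks where the all-zero vector satisfies every
    constraint); any infeasible verdict is therefore re-checked with
    presolve disabled before being believed.  Conversely, solutions found
    without presolve can exploit the integrality tolerance (w ~ 1 - 1e-6
    relaxes a big-M certificate by more than eps), so callers must verify
    certificates numerically and never trust a claimed-feasible solution
    as such.
    """
    options = dict(options or {})
    res = milp(
        c, constraints=constraints, integrality=integrality, bounds=bounds,
        options=options,
    )
    if res.status == 2:
        options["presolve"] = False
        res = milp(
            c, constraints=constraints, integrality=integrality, bounds=bounds,
            options=options,
        )
    return res


def _certified_rows(S, v, pairs, eps) -> set[int]:
    """Species rows whose production certificate the flux vector *actually*
    delivers: S v >= 0 (to tolerance) and an individual pair contribution
    of at least ~eps.  Immune to solver tolerance fakery."""
    if v is None:
        return set()
    if len(v) and float((S @ v).min()) < -1e-6:
        return set()
    good: set[int] = set()
    for i, j, s in pairs:
        if s * v[j] >= eps * 0.9:
            good.add(i)
    return good


def _pair_lp_producible(S, lb, ub, j, s, eps) -> bool:
    """LP feasibility of {bounds, S v >= 0, s v_j >= eps}, with the
    returned point verified numerically before being believed."""
    from scipy.optimize import linprog

    ns, n = S.shape
    extra = sp.csr_matrix(([-s], ([0], [j])), shape=(1, n))
    A_ub = sp.vstack([-S, extra]).tocsr()
    b_ub = np.concatenate([np.zeros(ns), [-eps]])
    bounds = np.column_stack([lb, ub])
    for options in ({}, {"presolve": False}):
        res = linprog(
            np.zeros(n), A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs",
            options=options,
        )
        if res.status == 0 and res.x is not None:
            v = res.x
            if float((S @ v).min()) >= -1e-6 and s * v[j] >= eps * 0.9:
                return True
            return False
        if res.status != 2:
            return False
    return False


def _producing_pairs(S: sp.csc_matrix, lb: np.ndarray, ub: np.ndarray):
    """(row, col, signed coeff) triples that can contribute production:
    positive coefficients of forward-capable reactions and negative
    coefficients of backward-capable ones."""
    pairs = []
    Sc = S.tocoo()
    for i, j, s in zip(Sc.row, Sc.col, Sc.data):
        if (s > 0 and ub[j] > 0) or (s < 0 and lb[j] < 0):
            pairs.append((int(i), int(j), float(s)))
    return pairs


def _pair_bigM(s: float, lb_j: float, ub_j: float, eps: float) -> float:
    return eps + abs(s) * max(abs(lb_j), abs(ub_j))


def _producible_rows(
    S: sp.csc_matrix, lb: np.ndarray, ub: np.ndarray, config: GapConfig
) -> set[int]:
    """Row indices of species producible under the GapFind semantics.

    One global MILP maximizes the number of certified species; its flux
    vector is then verified numerically (solver integrality tolerances can
    fake a big-M certificate), and every species left uncertified — through
    certificate conflicts, alternative optima or tolerance artifacts — is
    decided by verified per-pair LP feasibility (certification sweep).
    """
    ns, n = S.shape
    pairs = _producing_pairs(S, lb, ub)
    if not pairs:
        return set()
    rows_with_pairs = sorted({i for i, _, _ in pairs})
    x_pos = {i: k for k, i in enumerate(rows_with_pairs)}
    nw, nx = len(pairs), len(rows_with_pairs)
    nvar = n + nw + nx

    # constraint blocks (rows of one big sparse matrix)
    data, ri, ci, clo, cup = [], [], [], [], []
    row = 0
    # S v >= 0
    Sc = S.tocoo()
    for i, j, s in zip(Sc.row, Sc.col, Sc.data):
        data.append(s)
        ri.append(int(i))
        ci.append(int(j))
    row = ns
    clo.extend([0.0] * ns)
    cup.extend([np.inf] * ns)
    # pair certificates: s v_j - Mp w_p >= eps - Mp
    for p, (i, j, s) in enumerate(pairs):
        Mp = _pair_bigM(s, lb[j], ub[j], config.eps)
        data.extend([s, -Mp])
        ri.extend([row, row])
        ci.extend([j, n + p])
        clo.append(config.eps - Mp)
        cup.append(np.inf)
        row += 1
    # x_i - sum w_p(i) <= 0
    for k, i in enumerate(rows_with_pairs):
        data.append(1.0)
        ri.append(row + k)
        ci.append(n + nw + k)
    for p, (i, j, s) in enumerate(pairs):
        data.append(-1.0)
        ri.append(row + x_pos[i])
        ci.append(n + p)
    clo.extend([-np.inf] * nx)
    cup.extend([0.0] * nx)
    row += nx

    A = sp.csr_matrix((data, (ri, ci)), shape=(row, nvar))
    constraint = LinearConstraint(A, np.array(clo), np.array(cup))
    var_lb = np.concatenate([lb, np.zeros(nw + nx)])
    var_ub = np.concatenate([ub, np.ones(nw + nx)])
    integrality = np.concatenate([np.zeros(n), np.ones(nw + nx)])

    c = np.zeros(nvar)
    c[n + nw :] = -1.0  # maximize number of certified species
    res = _milp(
        c,
        constraints=[constraint],
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"gapfind MILP failed: {res.message}")
    produced = _certified_rows(S, res.x[:n], pairs, config.eps)
    # certification sweep: species the joint optimum's flux vector does not
    # certify (conflicting certificates, alternative optima, or solver
    # tolerance artifacts) are decided by verified per-pair LPs
    for i, j, s in pairs:
        if i in produced:
            continue
        if _pair_lp_producible(S, lb, ub, j, s, config.eps):
            produced.add(i)
    return produced


def gapfind(
    network: CompartmentalizedNetwork, config: GapConfig | None = None
) -> GapReport:
    """Identify non-produced and non-consumed species.

    Non-consumed species are found by running the production MILP on the
    sign-reversed network: S is negated while the flux bounds stay put, so
    a certified "production" of the transformed problem is a drain
    (individual contribution <= -eps under S v <= 0) of the original.
    """
    config = config or GapConfig()
    matrix = build_stoichiometric_matrix(network)
    if not matrix.col_index:
        report = GapReport(
            non_produced=set(matrix.row_index), non_consumed=set(matrix.row_index)
        )
        _fill_compartment_counts(report, network)
        return report
    lb = np.array([network.reactions[r].lower_bound for r in matrix.col_index])
    ub = np.array([network.reactions[r].upper_bound for r in matrix.col_index])
    produced = _producible_rows(matrix.S, lb, ub, config)
    consumed = _producible_rows(-matrix.S, lb, ub, config)
    all_rows = set(range(len(matrix.row_index)))
    report = GapReport(
        non_produced={matrix.row_index[i] for i in all_rows - produced},
        non_consumed={matrix.row_index[i] for i in all_rows - consumed},
    )
    _fill_compartment_counts(report, network)
    return report


def _fill_compartment_counts(report: GapReport, network: CompartmentalizedNetwork) -> None:
    comps = sorted(network.compartments())
    problem_mets: dict[str, set[str]] = {c: set() for c in comps}
    for c in comps:
        in_c = [s for s in network.species.values() if s.compartment == c]
        ids = {s.id for s in in_c}
        np_c = ids & report.non_produced
        nc_c = ids & report.non_consumed
        report.per_compartment_counts[c] = {
            "species": len(ids),
            "non_produced": len(np_c),
            "non_consumed": len(nc_c),
            "problem": len(np_c | nc_c),
        }
        problem_mets[c] = {Species.from_id(s).metabolite_id for s in np_c | nc_c}
    for a, b in combinations(comps, 2):
        report.common_gaps[(a, b)] = len(problem_mets[a] & problem_mets[b])


# ---------------------------------------------------------------------------
# GapFill
# ---------------------------------------------------------------------------


def instantiate_candidates(
    candidate_db: list[Reaction],
    compartment: str,
    network: CompartmentalizedNetwork,
) -> list[Reaction]:
    """Re-locate database reactions into a compartment.

    Every species of a (single-compartment) template is moved to
    ``compartment``; templates already present in the network (by id) are
    skipped; cross-compartment templates are kept verbatim.  Candidate
    metabolites must be declared in the network's metabolite table.
    """
    out = []
    for rxn in sorted(candidate_db, key=lambda r: r.id):
        if rxn.rtype in ("transport", "exchange"):
            new = rxn
        else:
            stoich = {
                f"{Species.from_id(s).metabolite_id}@{compartment}": c
                for s, c in rxn.stoichiometry.items()
            }
            new_id = rxn.id if compartment == "c" else f"{rxn.id}@{compartment}"
            new = replace(rxn, id=new_id, stoichiometry=stoich)
        if new.id in network.reactions:
            continue
        if any(
            Species.from_id(s).metabolite_id not in network.metabolites
            for s in new.stoichiometry
        ):
            raise NetworkError(
                f"candidate {new.id} references metabolites absent from the network"
            )
        out.append(new)
    return out


def _gapfill_system(network, candidates):
    """Shared index arrays for the gap-filling MILPs."""
    species = sorted(
        set(network.species)
        | {s for r in candidates for s in r.stoichiometry}
    )
    row = {s: i for i, s in enumerate(species)}
    net_cols = sorted(network.reactions)
    cols = net_cols + [r.id for r in candidates]
    rxns = {**{r: network.reactions[r] for r in net_cols}, **{r.id: r for r in candidates}}
    data, ri, ci = [], [], []
    for j, rid in enumerate(cols):
        for sid, coeff in rxns[rid].stoichiometry.items():
            data.append(coeff)
            ri.append(row[sid])
            ci.append(j)
    S = sp.csc_matrix((data, (ri, ci)), shape=(len(species), len(cols)))
    lb = np.array([rxns[r].lower_bound for r in cols])
    ub = np.array([rxns[r].upper_bound for r in cols])
    return species, cols, S, lb, ub, len(net_cols)


def _build_fill_milp(S, lb, ub, n_net, target_rows, config):
    """Constraint system with two flux blocks (production certificates on v,
    consumption certificates on u) and shared inclusion binaries y.

    Variable layout: [v (n) | u (n) | y (d) | w_prod... | w_cons...].
    Returns (A, clo, cup, integrality, var_lb, var_ub, w_index) where
    w_index maps each target row to its (prod, cons) binary column lists.
    """
    ns, n = S.shape
    d = n - n_net
    prod_pairs = {
        t: [(j, s) for (i, j, s) in _producing_pairs(S, lb, ub) if i == t]
        for t in target_rows
    }
    cons_pairs = {
        t: [(j, s) for (i, j, s) in _producing_pairs(-S, lb, ub) if i == t]
        for t in target_rows
    }
    nwp = sum(len(v) for v in prod_pairs.values())
    nwc = sum(len(v) for v in cons_pairs.values())
    off_u, off_y, off_wp, off_wc = n, 2 * n, 2 * n + d, 2 * n + d + nwp
    nvar = 2 * n + d + nwp + nwc

    data, ri, ci, clo, cup = [], [], [], [], []
    Sc = S.tocoo()
    # S v >= 0 ; S u <= 0
    for i, j, s in zip(Sc.row, Sc.col, Sc.data):
        data.extend([s, s])
        ri.extend([int(i), ns + int(i)])
        ci.extend([int(j), off_u + int(j)])
    clo.extend([0.0] * ns + [-np.inf] * ns)
    cup.extend([np.inf] * ns + [0.0] * ns)
    row = 2 * ns
    # candidate gating: lb_r y <= v_r <= ub_r y (same for u)
    for k in range(d):
        j = n_net + k
        for off in (0, off_u):
            data.extend([1.0, -ub[j]])
            ri.extend([row, row])
            ci.extend([off + j, off_y + k])
            clo.append(-np.inf)
            cup.append(0.0)
            row += 1
            data.extend([1.0, -lb[j]])
            ri.extend([row, row])
            ci.extend([off + j, off_y + k])
            clo.append(0.0)
            cup.append(np.inf)
            row += 1
    # certificates
    w_index: dict[int, tuple[list[int], list[int]]] = {}
    wp = off_wp
    wc = off_wc
    for t in target_rows:
        plist, clist = [], []
        for j, s in prod_pairs[t]:
            Mp = _pair_bigM(s, lb[j], ub[j], config.eps)
            data.extend([s, -Mp])
            ri.extend([row, row])
            ci.extend([j, wp])
            clo.append(config.eps - Mp)
            cup.append(np.inf)
            plist.append(wp)
            wp += 1
            row += 1
        for j, s in cons_pairs[t]:
            # s = (-S)_tj: a production certificate of the sign-reversed
            # system, i.e. an individual drain of the original species
            Mp = _pair_bigM(s, lb[j], ub[j], config.eps)
            data.extend([s, -Mp])
            ri.extend([row, row])
            ci.extend([off_u + j, wc])
            clo.append(config.eps - Mp)
            cup.append(np.inf)
            clist.append(wc)
            wc += 1
            row += 1
        w_index[t] = (plist, clist)

    var_lb = np.concatenate([lb, lb, np.zeros(d + nwp + nwc)])
    var_ub = np.concatenate([ub, ub, np.ones(d + nwp + nwc)])
    integrality = np.concatenate([np.zeros(2 * n), np.ones(d + nwp + nwc)])
    return (data, ri, ci, clo, cup, row), integrality, var_lb, var_ub, w_index, off_y


def _lex_penalty(candidates: list[Reaction]) -> np.ndarray:
    """Rank-based penalty below 1/(2 d): prefers lexicographically earlier
    reaction ids among equal-cardinality solutions without ever trading
    cardinality for preference."""
    d = len(candidates)
    if d == 0:
        return np.zeros(0)
    order = np.argsort([r.id for r in candidates])
    pen = np.zeros(d)
    scale = 1.0 / (4.0 * d * d)
    for rank, idx in enumerate(order):
        pen[idx] = rank * scale
    return pen


def _solve_fill(system, integrality, var_lb, var_ub, c):
    data, ri, ci, clo, cup, nrow = system
    A = sp.csr_matrix((data, (ri, ci)), shape=(nrow, len(c)))
    return _milp(
        c,
        constraints=[LinearConstraint(A, np.array(clo), np.array(cup))],
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"mip_rel_gap": 0.0},
    )


def gapfill(
    network: CompartmentalizedNetwork,
    targets: list[str],
    candidate_db: list[Reaction],
    config: GapConfig | None = None,
) -> list[GapFillSolution]:
    """Per-target minimum-cardinality fills.

    For each target species, minimize the number of candidate additions
    subject to the target being both producible and consumable in the
    augmented network.  Infeasible targets are returned with
    ``feasible=False`` (never dropped).  Minimality is guaranteed by MILP
    optimality; ties are broken lexicographically by reaction id.
    """
    config = config or GapConfig()
    candidates = sorted(candidate_db, key=lambda r: r.id)
    solutions = []
    if not candidates and not targets:
        return solutions
    species, cols, S, lb, ub, n_net = _gapfill_system(network, candidates)
    row = {s: i for i, s in enumerate(species)}
    pen = _lex_penalty(candidates)
    for target in sorted(targets):
        if target not in row:
            solutions.append(GapFillSolution(target_species=target, feasible=False))
            continue
        t = row[target]
        system, integ, vlb, vub, w_index, off_y = _build_fill_milp(
            S, lb, ub, n_net, [t], config
        )
        plist, clist = w_index[t]
        if not plist or not clist:
            solutions.append(GapFillSolution(target_species=target, feasible=False))
            continue
        nvar = len(vlb)
        # at least one production and one consumption certificate
        data, ri, ci, clo, cup, nrow = system
        for group in (plist, clist):
            for w in group:
                data.append(1.0)
                ri.append(nrow)
                ci.append(w)
            clo.append(1.0)
            cup.append(np.inf)
            nrow += 1
        c = np.zeros(nvar)
        d = len(candidates)
        c[off_y : off_y + d] = 1.0 + pen
        res = _solve_fill((data, ri, ci, clo, cup, nrow), integ, vlb, vub, c)
        if res.status != 0 or res.x is None:
            solutions.append(GapFillSolution(target_species=target, feasible=False))
            continue
        chosen = [candidates[k] for k in range(d) if res.x[off_y + k] > 0.5]
        if not _target_resolved_lp(network, chosen, target, config):
            solutions.append(GapFillSolution(target_species=target, feasible=False))
            continue
        solutions.append(
            GapFillSolution(
                target_species=target,
                added_reaction_ids=sorted(
                    r.id for r in chosen if r.rtype != "exchange"
                ),
                added_exchange_ids=sorted(
                    r.id for r in chosen if r.rtype == "exchange"
                ),
                feasible=True,
            )
        )
    return solutions


def _target_resolved_lp(
    network: CompartmentalizedNetwork,
    additions: list[Reaction],
    target: str,
    config: GapConfig,
) -> bool:
    """Verified check that a target is producible and consumable in the
    network augmented with the given reactions (guards the MILP against
    solver tolerance fakery)."""
    species, cols, S, lb, ub, _ = _gapfill_system(network, additions)
    row = {s: i for i, s in enumerate(species)}
    if target not in row:
        return False
    t = row[target]
    for Sdir in (S, -S):
        ok = False
        for i, j, s in _producing_pairs(Sdir, lb, ub):
            if i == t and _pair_lp_producible(Sdir, lb, ub, j, s, config.eps):
                ok = True
                break
        if not ok:
            return False
    return True


def gapfill_batch(
    network: CompartmentalizedNetwork,
    targets: list[str],
    candidate_db: list[Reaction],
    config: GapConfig | None = None,
) -> tuple[list[str], dict[str, bool]]:
    """Shared MILP over a target batch: maximize the number of resolved
    targets, then (through weighting) minimize the additions.

    The resolved-count weight exceeds the largest possible addition cost,
    so no target is ever sacrificed to save database reactions.
    """
    config = config or GapConfig()
    candidates = sorted(candidate_db, key=lambda r: r.id)
    targets = sorted(set(targets))
    if not targets:
        return [], {}
    species, cols, S, lb, ub, n_net = _gapfill_system(network, candidates)
    row = {s: i for i, s in enumerate(species)}
    target_rows = [row[t] for t in targets if t in row]
    system, integ, vlb, vub, w_index, off_y = _build_fill_milp(
        S, lb, ub, n_net, target_rows, config
    )
    d = len(candidates)
    data, ri, ci, clo, cup, nrow = system
    # z_t binaries appended at the end
    nvar = len(vlb)
    z_of = {}
    for t in target_rows:
        z = nvar
        nvar += 1
        z_of[t] = z
        plist, clist = w_index[t]
        for group in (plist, clist):
            # z_t - sum w <= 0 (an empty group forces z_t = 0)
            data.append(1.0)
            ri.append(nrow)
            ci.append(z)
            for w in group:
                data.append(-1.0)
                ri.append(nrow)
                ci.append(w)
            clo.append(-np.inf)
            cup.append(0.0)
            nrow += 1
    vlb = np.concatenate([vlb, np.zeros(len(target_rows))])
    vub = np.concatenate([vub, np.ones(len(target_rows))])
    integ = np.concatenate([integ, np.ones(len(target_rows))])
    c = np.zeros(nvar)
    c[off_y : off_y + d] = 1.0 + _lex_penalty(candidates)
    W = 2.0 * d + 2.0
    for t in target_rows:
        c[z_of[t]] = -W
    res = _solve_fill((data, ri, ci, clo, cup, nrow), integ, vlb, vub, c)
    if res.status != 0 or res.x is None:
        return [], {t: False for t in targets}
    chosen_rxns = [candidates[k] for k in range(d) if res.x[off_y + k] > 0.5]
    chosen = sorted(r.id for r in chosen_rxns)
    resolved = {}
    for t in targets:
        if t not in row or res.x[z_of[row[t]]] <= 0.5:
            resolved[t] = False
        else:
            resolved[t] = _target_resolved_lp(network, chosen_rxns, t, config)
    return chosen, resolved


# ---------------------------------------------------------------------------
# compartmentalized three-step curation
# ---------------------------------------------------------------------------


def _exchange_candidates_for(
    network: CompartmentalizedNetwork, inner_problem: set[str]
) -> list[Reaction]:
    """Cytoplasm<->inner exchange templates for problem species whose
    cytoplasmic counterpart exists."""
    out = []
    for sid in sorted(inner_problem):
        spec = Species.from_id(sid)
        c_side = f"{spec.metabolite_id}@c"
        if c_side not in network.species:
            continue
        rid = f"XCH_{spec.metabolite_id}_c_{spec.compartment}"
        if rid in network.reactions:
            continue
        out.append(
            Reaction(
                id=rid,
                stoichiometry={c_side: -1.0, sid: 1.0},
                reversible=True,
                rtype="transport",
            )
        )
    return out


def _boundary_candidates_for(
    network: CompartmentalizedNetwork, e_problem: set[str]
) -> list[Reaction]:
    out = []
    for sid in sorted(e_problem):
        spec = Species.from_id(sid)
        rid = f"EXF_{spec.metabolite_id}_e"
        if rid in network.reactions:
            continue
        out.append(
            Reaction(id=rid, stoichiometry={sid: -1.0}, reversible=True, rtype="exchange")
        )
    return out


def _add_reactions(network, reactions_by_id, ids):
    for rid in ids:
        if rid not in network.reactions:
            network.add_reaction(reactions_by_id[rid])


def curate_compartmentalized(
    network: CompartmentalizedNetwork,
    candidate_db: list[Reaction],
    transport_db: list[Reaction] | None = None,
    config: GapConfig | None = None,
) -> tuple[CompartmentalizedNetwork, CurationStats]:
    """Three-step curation of a compartmentalized network.

    1. fill cytoplasmic gaps from the candidate database;
    2. add cytoplasm<->inner exchange reactions (both species must already
       exist) resolving inner gaps shared with the cytoplasm;
    3. fill the remaining compartments separately (candidate database
       instantiated per compartment; boundary exchanges for the
       extracellular space).

    Statistics (reconnection percentages, common-gap counts) are reported
    over the pre-curation species universe.
    """
    config = config or GapConfig()
    net = network.copy()
    before = gapfind(net, config)
    added_by_step: dict[str, list[str]] = {
        "cytoplasm": [],
        "exchanges": [],
        "inner": [],
    }

    def comp_of(sid: str) -> str:
        return Species.from_id(sid).compartment

    # step 1 — cytoplasm
    targets_c = sorted(s for s in before.problem_species() if comp_of(s) == "c")
    if targets_c:
        cands = instantiate_candidates(candidate_db, "c", net)
        by_id = {r.id: r for r in cands}
        chosen, _ = gapfill_batch(net, targets_c, cands, config)
        _add_reactions(net, by_id, chosen)
        added_by_step["cytoplasm"] = chosen

    # step 2 — cytoplasm<->inner exchanges
    report = gapfind(net, config)
    inner_comps = sorted(net.compartments() - {"c", "e"})
    inner_problem = {
        s for s in report.problem_species() if comp_of(s) in inner_comps
    }
    if inner_problem:
        cands = _exchange_candidates_for(net, inner_problem)
        if transport_db:
            existing = {r.id for r in cands}
            for t in sorted(transport_db, key=lambda r: r.id):
                if (
                    t.rtype == "transport"
                    and "e" not in t.compartments()
                    and t.id not in existing
                    and t.id not in net.reactions
                    and all(s in net.species for s in t.stoichiometry)
                ):
                    cands.append(t)
        by_id = {r.id: r for r in cands}
        chosen, _ = gapfill_batch(net, sorted(inner_problem), cands, config)
        _add_reactions(net, by_id, chosen)
        added_by_step["exchanges"] = chosen

    # step 3 — remaining compartments, separately
    report = gapfind(net, config)
    for comp in inner_comps + ["e"]:
        targets = sorted(
            s for s in report.problem_species() if comp_of(s) == comp
        )
        if not targets:
            continue
        if comp == "e":
            cands = _boundary_candidates_for(net, set(targets))
        else:
            cands = instantiate_candidates(candidate_db, comp, net)
        by_id = {r.id: r for r in cands}
        chosen, _ = gapfill_batch(net, targets, cands, config)
        _add_reactions(net, by_id, chosen)
        added_by_step["inner"].extend(chosen)
        if chosen:
            report = gapfind(net, config)

    after = gapfind(net, config)
    stats = reconnection_percentage(before, after, network)
    stats.added_by_step = added_by_step
    stats.common_gaps = dict(before.common_gaps)
    net.log(
        "curate_compartmentalized: added "
        + ", ".join(f"{k}={len(v)}" for k, v in added_by_step.items())
    )
    return net, stats


def reconnection_percentage(
    before: GapReport,
    after: GapReport,
    network: CompartmentalizedNetwork,
) -> CurationStats:
    """Percentage of connected species per compartment, before vs after.

    A species is connected when it is neither non-produced nor
    non-consumed.  Percentages are over the species of ``network`` (the
    pre-curation universe); empty compartments report ``None`` (NA).
    """
    stats = CurationStats()
    by_comp = network.species_by_compartment()
    for comp in sorted(network.compartments()):
        ids = set(by_comp.get(comp, []))
        if not ids:
            stats.per_compartment_before[comp] = None
            stats.per_compartment_after[comp] = None
            continue
        stats.per_compartment_before[comp] = (
            100.0 * len(before.connected(ids) & ids) / len(ids)
        )
        stats.per_compartment_after[comp] = (
            100.0 * len(after.connected(ids) & ids) / len(ids)
        )
    return stats
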