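"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check:

* dead-end detection: per-(species, reaction) LP feasibility enumeration
  (plain linprog, no binaries) versus the package's global MILP;
* gap filling: exhaustive subset search over the candidate database;
* FBA: brute-force vertex enumeration of the flux polytope.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from metagem.model_core import (
    CompartmentalizedNetwork,
    Metabolite,
    Reaction,
    infer_rtype,
)

EPS = 1e-3


# ---------------------------------------------------------------------------
# dense arrays straight from the reaction dicts (independent of the package's
# matrix builder)
# ---------------------------------------------------------------------------


def dense_arrays(network: CompartmentalizedNetwork):
    species = sorted({s for r in network.reactions.values() for s in r.stoichiometry})
    cols = sorted(network.reactions)
    S = np.zeros((len(species), len(cols)))
    row = {s: i for i, s in enumerate(species)}
    for j, rid in enumerate(cols):
        for sid, coeff in network.reactions[rid].stoichiometry.items():
            S[row[sid], j] = coeff
    lb = np.array([network.reactions[r].lower_bound for r in cols])
    ub = np.array([network.reactions[r].upper_bound for r in cols])
    return species, cols, S, lb, ub


def _producible_rows_lp(S: np.ndarray, lb, ub, eps: float) -> set[int]:
    """Species rows for which some (reaction, direction) pair can deliver an
    individual production contribution >= eps while S v >= 0 holds."""
    ns, n = S.shape
    produced: set[int] = set()
    for i in range(ns):
        for j in range(n):
            s = S[i, j]
            if s == 0:
                continue
            if not ((s > 0 and ub[j] > 0) or (s < 0 and lb[j] < 0)):
                continue
            # feasibility: S v >= 0 and s*v_j >= eps
            extra = np.zeros(n)
            extra[j] = -s
            A_ub = np.vstack([-S, extra])
            b_ub = np.concatenate([np.zeros(ns), [-eps]])
            res = linprog(
                np.zeros(n),
                A_ub=A_ub,
                b_ub=b_ub,
                bounds=np.column_stack([lb, ub]),
                method="highs",
            )
            if res.status == 0:
                produced.add(i)
                break
    return produced


def gap_oracle(network: CompartmentalizedNetwork, eps: float = EPS):
    """(non_produced, non_consumed) species-id sets by LP enumeration."""
    species, cols, S, lb, ub = dense_arrays(network)
    produced = _producible_rows_lp(S, lb, ub, eps)
    # consumption = production of the sign-reversed network (same bounds)
    consumed = _producible_rows_lp(-S, lb, ub, eps)
    every = set(range(len(species)))
    return (
        {species[i] for i in every - produced},
        {species[i] for i in every - consumed},
    )


def species_resolved(network: CompartmentalizedNetwork, target: str, eps: float = EPS) -> bool:
    """Target is both producible and consumable (LP-oracle semantics)."""
    non_p, non_c = gap_oracle(network, eps)
    return target not in non_p and target not in non_c


def exhaustive_min_fill(
    network: CompartmentalizedNetwork,
    target: str,
    candidates: list[Reaction],
    eps: float = EPS,
) -> int | None:
    """Smallest candidate subset making the target producible and
    consumable; None when no subset works.  Candidates must number <= 8."""
    assert len(candidates) <= 8
    for size in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            aug = network.copy()
            for rxn in subset:
                if rxn.id not in aug.reactions:
                    aug.add_reaction(rxn)
            if target in aug.species and species_resolved(aug, target, eps):
                return size
    return None


# ---------------------------------------------------------------------------
# brute-force FBA by vertex enumeration
# ---------------------------------------------------------------------------


def lp_max_by_vertex_enumeration(S: np.ndarray, lb, ub, c, tol: float = 1e-7):
    """Maximum of c'v over {S v = 0, lb <= v <= ub} by enumerating vertices.

    A vertex has n linearly independent active constraints: rank(S) from the
    equalities plus n - rank(S) variables pinned at a bound.  Only usable
    for n <= 8.  Returns None when the polytope is empty.
    """
    ns, n = S.shape
    assert n <= 8
    rank = np.linalg.matrix_rank(S) if ns else 0
    n_fixed = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free] if free else np.zeros((ns, 0))
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue
        for pattern in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            for j, val in zip(fixed, pattern):
                v[j] = val
            rhs = -S[:, fixed] @ np.array(pattern) if fixed else np.zeros(ns)
            if free:
                sol, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                v[free] = sol
            if np.max(np.abs(S @ v)) > tol if ns else False:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            z = float(c @ v)
            if best is None or z > best:
                best = z
    return best


# ---------------------------------------------------------------------------
# random fixture networks
# ---------------------------------------------------------------------------


def random_network(seed: int, max_reactions: int = 30) -> CompartmentalizedNetwork:
    """Small random network with exchanges, for the oracle batteries."""
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(6, 14))
    net = CompartmentalizedNetwork()
    for i in range(n_mets):
        net.add_metabolite(Metabolite(f"m{i:02d}", f"met {i}", {"C": 1}, 0, None))
    n_boundary = int(rng.integers(1, 4))
    boundary = rng.choice(n_mets, size=n_boundary, replace=False)
    for b in sorted(boundary.tolist()):
        mid = f"m{b:02d}"
        net.add_reaction(
            Reaction(
                f"EX_{mid}", {f"{mid}@e": -1.0}, True, -1000.0, 100.0, rtype="exchange"
            )
        )
        net.add_reaction(
            Reaction(
                f"T_{mid}",
                {f"{mid}@e": -1.0, f"{mid}@c": 1.0},
                True,
                -1000.0,
                100.0,
                rtype="transport",
            )
        )
    hi = max(4, max_reactions - 2 * n_boundary + 1)
    n_rxn = int(rng.integers(3, hi))
    made = 0
    k = 0
    while made < n_rxn and k < 10 * n_rxn:
        k += 1
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        picks = rng.choice(n_mets, size=n_sub + n_prod, replace=False)
        stoich: dict[str, float] = {}
        for idx in picks[:n_sub]:
            stoich[f"m{idx:02d}@c"] = -float(rng.integers(1, 3))
        for idx in picks[n_sub:]:
            stoich[f"m{idx:02d}@c"] = float(rng.integers(1, 3))
        rev = bool(rng.random() < 0.4)
        net.add_reaction(
            Reaction(
                f"r{made:03d}",
                stoich,
                rev,
                -1000.0 if rev else 0.0,
                100.0,
                rtype=infer_rtype(stoich),
            )
        )
        made += 1
    return net
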