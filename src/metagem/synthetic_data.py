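"""Synthetic inputs with planted ground truth for every pipeline stage.

No deposited community network exists, so every input the pipeline consumes
is generated here with known answers: the degree-distribution exponents are
planted, the compartment assignment of every reaction is recorded, removed
reactions (planted gaps) are returned as a recovery key, and the ancillary
tables (localization scores, reference assignments, transport and candidate
databases) are all derived from that recorded truth.

Chemistry.  Metabolites live in a polymer world built from a CH2O unit:
a metabolite of size ``s`` with hydration ``h`` and charge ``q`` has
formula C_s H_(2s+2h+q) O_(s+h).  Every backbone reaction converts one
metabolite into another and is closed exactly with three carrier species —
the unit carrier (``fald``, CH2O), water and the proton — so elemental and
charge balance hold by construction, and the carriers double as the
currency hubs real metabolic networks have.  Dropping the H2O/H+ terms of
such a reaction produces exactly the repairable imbalances the balance
checker is designed to close.

Degrees.  Target in/out degree sequences are drawn from zipf(gamma_in) and
zipf(gamma_out).  Reversible reactions contribute an edge in both
directions, so reversibility is planted stub-aware: each node dedicates a
``p_reversible`` share of min(in, out) stubs to undirected (reversible)
pairings, and the remaining stubs are paired directionally.  The realized
in/out degree of every node then matches its planted target, up to carrier
and generic-participant edges which smear only the small-k end of the
distribution (fit recovery therefore uses k_min >= 3; see docs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model_core import (
    CompartmentalizedNetwork,
    Metabolite,
    Reaction,
    Species,
    format_formula,
    write_network,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_network",
    "plant_gaps",
    "generate_ancillary_tables",
    "generate_bundle",
    "toy_fatty_acid_model",
    "toy_tca_model",
    "PRESETS",
]

_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: Compartment mixture for metabolic reactions, mirroring the ranking of
#: compartment sizes in community-scale metabolic reconstructions
#: (cytoplasm >> mitochondrion > nucleus > peroxisome).
_DEFAULT_PROPORTIONS = {"c": 0.68, "m": 0.20, "n": 0.093, "x": 0.027}


class GeneratorConfig(BaseModel):
    """Stated world of the generator; identical seeds give identical bytes."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_metabolites: int = Field(150, ge=3)
    #: Total backbone reactions (generic ones included); None keeps every
    #: sampled stub pairing (used for exponent-recovery runs).
    n_reactions: int | None = None
    gamma_in: float = Field(1.8, gt=1.0)
    gamma_out: float = Field(2.0, gt=1.0)
    #: Share of backbone reactions planted as reversible (community-scale
    #: reconstructions typically report ~45% reversible).
    p_reversible: float = Field(0.45, ge=0.0, le=1.0)
    fraction_generic: float = Field(0.09, ge=0.0, le=0.5)
    #: Probability that a *reversible* reaction carries a (sub-threshold)
    #: Gibbs-energy estimate; irreversible reactions always carry one,
    #: since irreversibility is called from it.
    fraction_with_delta_g: float = Field(0.6, ge=0.0, le=1.0)
    compartment_proportions: dict[str, float] = Field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    #: Reactions planted in the negligible compartments (vacuole/lysosome),
    #: emulating the 7- and 20-reaction compartments that get pruned.
    n_vacuole: int = Field(7, ge=0)
    n_lysosome: int = Field(20, ge=0)
    n_exchange: int = Field(25, ge=1)
    planted_gap_count: int = Field(10, ge=0)
    decoy_db_size: int = Field(50, ge=0)
    #: Dirichlet concentration on the true compartment of the localization
    #: score tables (larger = cleaner predictor).
    localization_concentration: float = Field(15.0, gt=0.0)
    reference_fraction: float = Field(0.3, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        total = sum(self.compartment_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("compartment proportions must sum to 1")
        bad = set(self.compartment_proportions) - {"c", "m", "n", "x"}
        if bad:
            raise ValueError(f"proportions allowed only for c/m/n/x, got {bad}")
        return self


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline without re-deriving it."""

    gamma_in: float
    gamma_out: float
    carrier_ids: list[str] = dfield(default_factory=list)
    exchange_metabolites: list[str] = dfield(default_factory=list)
    generic_reaction_ids: list[str] = dfield(default_factory=list)
    true_compartment: dict[str, str] = dfield(default_factory=dict)
    n_backbone: int = 0
    removed_reaction_ids: list[str] = dfield(default_factory=list)
    induced_dead_ends: list[str] = dfield(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "gamma_in": self.gamma_in,
                "gamma_out": self.gamma_out,
                "carrier_ids": self.carrier_ids,
                "exchange_metabolites": self.exchange_metabolites,
                "generic_reaction_ids": self.generic_reaction_ids,
                "true_compartment": self.true_compartment,
                "n_backbone": self.n_backbone,
                "removed_reaction_ids": self.removed_reaction_ids,
                "induced_dead_ends": self.induced_dead_ends,
            },
            indent=0,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# degree machinery
# ---------------------------------------------------------------------------


def _sample_zipf(rng: np.random.Generator, gamma: float, n: int, kmax: int) -> np.ndarray:
    out = rng.zipf(gamma, size=n)
    for _ in range(100):
        mask = out > kmax
        if not mask.any():
            break
        out[mask] = rng.zipf(gamma, size=int(mask.sum()))
    out[out > kmax] = kmax
    return out.astype(int)


def _pair_stubs(rng, a_stubs: np.ndarray, b_stubs: np.ndarray):
    """Pair two stub multisets into (a, b) edges, best-effort avoiding a==b."""
    k = min(len(a_stubs), len(b_stubs))
    a = a_stubs[:k].copy()
    b = b_stubs[:k].copy()
    rng.shuffle(b)
    for _ in range(10):
        bad = np.flatnonzero(a == b)
        if bad.size == 0:
            break
        swap_with = rng.integers(0, k, size=bad.size)
        b[bad], b[swap_with] = b[swap_with].copy(), b[bad].copy()
    keep = a != b
    return list(zip(a[keep].tolist(), b[keep].tolist()))


def _planted_edges(rng, config: GeneratorConfig):
    """(reversible_edges, directed_edges) realizing the planted sequences."""
    n = config.n_metabolites
    kmax = max(2, n // 4)
    t_in = _sample_zipf(rng, config.gamma_in, n, kmax)
    t_out = _sample_zipf(rng, config.gamma_out, n, kmax)
    b = np.floor(config.p_reversible * np.minimum(t_in, t_out)).astype(int)
    if b.sum() % 2:
        j = int(rng.choice(np.flatnonzero(b > 0))) if (b > 0).any() else 0
        b[j] = max(0, b[j] - 1)
    rev_stubs = np.repeat(np.arange(n), b)
    rng.shuffle(rev_stubs)
    half = len(rev_stubs) // 2
    rev_edges = _pair_stubs(rng, rev_stubs[:half], rev_stubs[half : 2 * half])
    in_rem = t_in - b
    out_rem = t_out - b
    # equalize directed stub totals by dropping a uniform subset of the
    # larger side (thinning preserves the planted exponent, padding with
    # unit stubs would flatten it)
    out_stubs = np.repeat(np.arange(n), out_rem)
    in_stubs = np.repeat(np.arange(n), in_rem)
    k = min(len(out_stubs), len(in_stubs))
    rng.shuffle(out_stubs)
    rng.shuffle(in_stubs)
    dir_edges = _pair_stubs(rng, out_stubs[:k], in_stubs[:k])
    return rev_edges, dir_edges


# ---------------------------------------------------------------------------
# network generation
# ---------------------------------------------------------------------------


def _carrier_metabolites() -> list[Metabolite]:
    return [
        Metabolite("fald", "one-carbon unit carrier", {"C": 1, "H": 2, "O": 1}, 0, 30.026),
        Metabolite("h2o", "water", {"H": 2, "O": 1}, 0, 18.015),
        Metabolite("h", "proton", {"H": 1}, 1, 1.008),
    ]


def _backbone_stoichiometry(
    a: Metabolite, b: Metabolite, comp: str = "c"
) -> dict[str, float]:
    """A -> B closed with fald/h2o/h carriers so balance is exact."""
    stoich = {f"{a.id}@{comp}": -1.0, f"{b.id}@{comp}": 1.0}
    d = {el: b.formula.get(el, 0) - a.formula.get(el, 0) for el in ("C", "H", "O")}
    dq = (b.charge or 0) - (a.charge or 0)
    t_f = -d["C"]  # fald units on the product side
    t_w = -(d["O"] - d["C"])  # after fald, remaining O
    t_h = -dq
    for cid, t in (("fald", t_f), ("h2o", t_w), ("h", t_h)):
        if t:
            sid = f"{cid}@{comp}"
            stoich[sid] = stoich.get(sid, 0.0) + float(t)
    return {s: c for s, c in stoich.items() if abs(c) > 1e-9}


def generate_network(
    config: GeneratorConfig,
) -> tuple[CompartmentalizedNetwork, GroundTruth]:
    """Generate a connected, mass/charge-balanced synthetic network.

    All metabolic reactions start in the cytoplasm; exchange and transport
    scaffolding connects the extracellular space.  The ground truth records
    the planted exponents, the true compartment of every metabolic reaction
    (used to derive localization/reference tables), generic reaction ids
    and the carrier/boundary metabolites.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_metabolites
    truth = GroundTruth(gamma_in=config.gamma_in, gamma_out=config.gamma_out)

    # metabolite pool
    sizes = np.where(
        rng.random(n) < 0.8, 5, rng.choice([4, 6], size=n)
    ).astype(int)
    hyd = (rng.random(n) < 0.15).astype(int)
    charge = -(rng.random(n) < 0.15).astype(int)
    mets: list[Metabolite] = []
    for i in range(n):
        s, hh, q = int(sizes[i]), int(hyd[i]), int(charge[i])
        formula = {"C": s, "H": 2 * s + 2 * hh + q, "O": s + hh}
        mass = sum(_ATOMIC_MASS[el] * cnt for el, cnt in formula.items())
        mets.append(
            Metabolite(
                f"met{i:04d}",
                f"synthetic compound {i}",
                formula,
                q,
                round(mass, 3),
            )
        )
    carriers = _carrier_metabolites()
    truth.carrier_ids = [m.id for m in carriers]

    rev_edges, dir_edges = _planted_edges(rng, config)
    edges = [(a, b, True) for a, b in rev_edges] + [(a, b, False) for a, b in dir_edges]
    if config.n_reactions is not None:
        if len(edges) > config.n_reactions:
            keep = rng.choice(len(edges), size=config.n_reactions, replace=False)
            edges = [edges[i] for i in sorted(keep)]
        else:
            while len(edges) < config.n_reactions:
                a, b = rng.integers(0, n, size=2)
                if a != b:
                    edges.append((int(a), int(b), bool(rng.random() < config.p_reversible)))

    n_backbone = len(edges)
    n_generic = int(round(config.fraction_generic * n_backbone))
    generic_rows = set(
        rng.choice(n_backbone, size=n_generic, replace=False).tolist()
    ) if n_generic else set()
    generic_mets = [
        Metabolite(gid, gname, None, None, None, True)
        for gid, gname in (
            ("generic_protein", "generic protein"),
            ("generic_rna", "generic RNA"),
            ("generic_dna", "generic DNA"),
            ("generic_glycan", "generic glycan"),
            ("generic_lipid", "generic lipid class"),
        )
    ]

    net = CompartmentalizedNetwork()
    for met in mets + carriers + generic_mets:
        net.add_metabolite(met)

    # backbone reactions
    comp_codes = sorted(config.compartment_proportions)
    comp_p = np.array([config.compartment_proportions[c] for c in comp_codes])
    for k, (a, b, rev) in enumerate(edges):
        rid = f"rxn{k:05d}"
        stoich = _backbone_stoichiometry(mets[a], mets[b])
        if k in generic_rows:
            g = generic_mets[k % len(generic_mets)]
            stoich[f"{g.id}@c"] = stoich.get(f"{g.id}@c", 0.0) - 1.0
            stoich[f"{g.id}_mod@c"] = 1.0
            mod_id = f"{g.id}_mod"
            if mod_id not in net.metabolites:
                net.add_metabolite(
                    Metabolite(mod_id, f"{g.name} (modified)", None, None, None, True)
                )
            truth.generic_reaction_ids.append(rid)
        if rev:
            delta_g = (
                float(np.round(rng.uniform(-25.0, 25.0), 2))
                if rng.random() < config.fraction_with_delta_g
                else None
            )
            lb, ub = -1000.0, 100.0
        else:
            delta_g = float(np.round(-30.0 - rng.exponential(25.0), 2))
            lb, ub = 0.0, 100.0
        ec = f"{rng.integers(1, 7)}.{rng.integers(1, 10)}.{rng.integers(1, 10)}.{rng.integers(1, 99)}"
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=rev,
                lower_bound=lb,
                upper_bound=ub,
                delta_g=delta_g,
                ec_numbers=frozenset([ec]),
                rtype="metabolic",
            )
        )
        truth.true_compartment[rid] = str(rng.choice(comp_codes, p=comp_p))
    truth.n_backbone = n_backbone

    # plant the negligible compartments (pruned downstream)
    metabolic_ids = sorted(truth.true_compartment)
    n_vl = config.n_vacuole + config.n_lysosome
    if 0 < n_vl <= len(metabolic_ids) // 4:
        picked = rng.choice(len(metabolic_ids), size=n_vl, replace=False)
        for idx, rid_i in enumerate(sorted(picked.tolist())):
            rid = metabolic_ids[rid_i]
            truth.true_compartment[rid] = "v" if idx < config.n_vacuole else "l"

    # connectivity: bridge weakly connected components of the backbone
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for a, b, _ in edges:
        union(a, b)
    roots = sorted({find(i) for i in range(n)})
    main = roots[0]
    link_k = 0
    for r in roots[1:]:
        a = r
        b = main
        rid = f"link{link_k:03d}"
        link_k += 1
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=_backbone_stoichiometry(mets[a], mets[b]),
                reversible=True,
                rtype="metabolic",
            )
        )
        truth.true_compartment[rid] = "c"
        union(a, b)

    # boundary scaffolding: exchanges + cytoplasm<->extracellular transport
    degree = np.zeros(n, dtype=int)
    for a, b, _ in edges:
        degree[a] += 1
        degree[b] += 1
    ranked = np.argsort(-degree, kind="stable")
    n_ex = min(config.n_exchange, n)
    boundary = [mets[int(i)].id for i in ranked[:n_ex]] + [m.id for m in carriers]
    for mid in sorted(set(boundary)):
        net.ensure_species(mid, "e")
        net.add_reaction(
            Reaction(
                id=f"T_{mid}_ec",
                stoichiometry={f"{mid}@e": -1.0, f"{mid}@c": 1.0},
                reversible=True,
                rtype="transport",
            )
        )
        net.add_reaction(
            Reaction(
                id=f"EX_{mid}",
                stoichiometry={f"{mid}@e": -1.0},
                reversible=True,
                rtype="exchange",
            )
        )
    truth.exchange_metabolites = sorted(set(boundary))

    net.validate()
    net.log(f"generate_network: seed={config.seed}")
    return net, truth


# ---------------------------------------------------------------------------
# planted gaps
# ---------------------------------------------------------------------------


def _producer_counts(network: CompartmentalizedNetwork) -> dict[str, list[str]]:
    """species -> reactions that can produce it (structurally)."""
    prod: dict[str, list[str]] = {s: [] for s in network.species}
    for rid in sorted(network.reactions):
        r = network.reactions[rid]
        for sid, coeff in r.stoichiometry.items():
            if (coeff > 0 and r.upper_bound > 0) or (coeff < 0 and r.lower_bound < 0):
                prod[sid].append(rid)
    return prod


def plant_gaps(
    network: CompartmentalizedNetwork, k: int, seed: int
) -> tuple[CompartmentalizedNetwork, list[Reaction], list[str]]:
    """Remove k metabolic reactions whose removal provably creates dead ends.

    Every candidate removal is checked with the gap finder: it is accepted
    only if it turns at least one previously connected species into a dead
    end.  Such species are exactly restorable by re-adding the removed
    reaction, so every planted gap is jointly resolvable (producible and
    consumable again) once the removal key is offered back in a candidate
    database.  Returns the gapped network, the removed reactions (the
    recovery key) and the sorted list of induced dead-end species.
    """
    from .curation import gapfind

    rng = np.random.default_rng(seed)
    out = network.copy()
    removed: list[Reaction] = []
    induced: list[str] = []
    if k == 0:
        return out, removed, induced
    baseline = gapfind(out)
    base_dead = baseline.problem_species()

    def candidate_order() -> list[str]:
        # structurally promising first: sole producers / sole consumers
        prod = _producer_counts(out)
        cons = _producer_counts(_sign_reversed(out))
        promising = {
            producers[0]
            for counts in (prod, cons)
            for producers in counts.values()
            if len(producers) == 1
        }
        pool = [
            r
            for r in out.reactions
            if out.reactions[r].rtype == "metabolic" and r not in rejected
        ]
        rng.shuffle(pool)
        return sorted(
            pool, key=lambda r: (r not in promising, pool.index(r))
        )

    rejected: set[str] = set()
    while len(removed) < k:
        candidates = candidate_order()
        if not candidates:
            break
        accepted = False
        for rid in candidates:
            tentative = out.copy()
            tentative.remove_reactions([rid], drop_orphans=False)
            report = gapfind(tentative)
            new_dead = sorted(
                (report.problem_species() - base_dead)
                & set(tentative.species)
            )
            # species connected at baseline and dead now are exactly
            # restorable by re-adding the removed reaction, hence jointly
            # resolvable from a candidate database containing it
            if new_dead:
                removed.append(out.reactions[rid])
                induced.extend(new_dead)
                out = tentative
                base_dead = report.problem_species()
                accepted = True
                break
            rejected.add(rid)
        if not accepted:
            break
    if len(removed) < k:
        raise ValueError(f"could only plant {len(removed)} of {k} requested gaps")
    out.log(f"plant_gaps: removed {len(removed)} reactions")
    return out, removed, sorted(set(induced))


def _sign_reversed(network: CompartmentalizedNetwork) -> CompartmentalizedNetwork:
    out = network.copy()
    for rid, r in list(out.reactions.items()):
        out.reactions[rid] = Reaction(
            id=r.id,
            stoichiometry={s: -c for s, c in r.stoichiometry.items()},
            reversible=r.reversible,
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            delta_g=r.delta_g,
            ec_numbers=r.ec_numbers,
            rtype=r.rtype,
        )
    return out


# ---------------------------------------------------------------------------
# ancillary tables
# ---------------------------------------------------------------------------

_LOC_COMPARTMENTS = ("c", "m", "n", "x", "v", "l")


def generate_ancillary_tables(
    network: CompartmentalizedNetwork,
    config: GeneratorConfig,
    truth: GroundTruth,
    removed: list[Reaction] | None = None,
) -> dict[str, object]:
    """Localization scores, reference assignments, transport db, candidate db.

    Localization scores are Dirichlet draws concentrated on the true
    compartment; the reference table reports the true compartment for a
    random subset of reactions; the transport database proposes
    cytoplasm<->inner templates for metabolites whose true reactions span
    several compartments (plus carriers everywhere); the candidate database
    is the removed-reaction recovery key plus balanced decoys.
    """
    rng = np.random.default_rng(config.seed + 1)
    import pandas as pd

    rows = []
    for rid in sorted(truth.true_compartment):
        if rid not in network.reactions:
            continue
        true_c = truth.true_compartment[rid]
        alpha = np.ones(len(_LOC_COMPARTMENTS))
        alpha[_LOC_COMPARTMENTS.index(true_c)] = config.localization_concentration
        scores = rng.dirichlet(alpha)
        row = {"reaction_id": rid}
        vals = [float(np.round(s, 9)) for s in scores]
        vals[int(np.argmax(vals))] += 1.0 - sum(vals)  # exact unit sum
        for comp, val in zip(_LOC_COMPARTMENTS, vals):
            row[comp] = f"{val:.9f}"
        rows.append(row)
    localization = pd.DataFrame(rows, columns=["reaction_id", *_LOC_COMPARTMENTS])

    ref_rows = []
    for rid in sorted(truth.true_compartment):
        if rid not in network.reactions:
            continue
        if truth.true_compartment[rid] in ("v", "l"):
            continue
        if rng.random() < config.reference_fraction:
            ref_rows.append(
                {
                    "reaction_id": rid,
                    "compartment": truth.true_compartment[rid],
                    "source_model": "ref_model_A" if rng.random() < 0.5 else "ref_model_B",
                }
            )
    references = pd.DataFrame(
        ref_rows, columns=["reaction_id", "compartment", "source_model"]
    )

    # transport templates
    met_comps: dict[str, set[str]] = {}
    for rid, comp in truth.true_compartment.items():
        if rid not in network.reactions or comp in ("v", "l"):
            continue
        for sid in network.reactions[rid].stoichiometry:
            met_comps.setdefault(Species.from_id(sid).metabolite_id, set()).add(comp)
    transport: list[Reaction] = []
    inner = ("m", "n", "x")
    for mid in sorted(met_comps):
        comps = met_comps[mid]
        for k in inner:
            if k in comps and ("c" in comps or mid in truth.carrier_ids):
                transport.append(
                    Reaction(
                        id=f"T_{mid}_c_{k}",
                        stoichiometry={f"{mid}@c": -1.0, f"{mid}@{k}": 1.0},
                        reversible=True,
                        rtype="transport",
                    )
                )
    for mid in truth.carrier_ids:
        for k in inner:
            rid = f"T_{mid}_c_{k}"
            if not any(t.id == rid for t in transport):
                transport.append(
                    Reaction(
                        id=rid,
                        stoichiometry={f"{mid}@c": -1.0, f"{mid}@{k}": 1.0},
                        reversible=True,
                        rtype="transport",
                    )
                )

    # candidate database: recovery key + balanced decoys
    candidates: list[Reaction] = [r for r in (removed or [])]
    mets = [
        network.metabolites[m]
        for m in sorted(network.metabolites)
        if network.metabolites[m].formula and m not in truth.carrier_ids
    ]
    k = 0
    while k < config.decoy_db_size and len(mets) >= 2:
        i, j = rng.integers(0, len(mets), size=2)
        if i == j:
            continue
        rev = bool(rng.random() < 0.5)
        candidates.append(
            Reaction(
                id=f"decoy{k:03d}",
                stoichiometry=_backbone_stoichiometry(mets[int(i)], mets[int(j)]),
                reversible=rev,
                lower_bound=-1000.0 if rev else 0.0,
                rtype="metabolic",
            )
        )
        k += 1
    return {
        "localization": localization,
        "references": references,
        "transport_db": transport,
        "candidate_db": candidates,
    }


def generate_bundle(config: GeneratorConfig, outdir: str | Path) -> GroundTruth:
    """Write the full input bundle (TSVs + ground truth JSON) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, truth = generate_network(config)
    gapped, removed, dead = (
        plant_gaps(net, config.planted_gap_count, config.seed + 2)
        if config.planted_gap_count
        else (net, [], [])
    )
    truth.removed_reaction_ids = sorted(r.id for r in removed)
    truth.induced_dead_ends = dead
    tables = generate_ancillary_tables(gapped, config, truth, removed)
    write_network(gapped, outdir / "reactions.tsv", outdir / "metabolites.tsv")
    tables["localization"].to_csv(outdir / "localization.tsv", sep="\t", index=False)
    tables["references"].to_csv(outdir / "references.tsv", sep="\t", index=False)
    _write_reaction_list(tables["transport_db"], outdir / "transport_db.tsv")
    _write_reaction_list(tables["candidate_db"], outdir / "candidate_db.tsv")
    (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return truth


def _write_reaction_list(reactions: list[Reaction], path: Path) -> None:
    import pandas as pd

    from .model_core import REACTION_COLUMNS, format_equation

    rows = [
        {
            "reaction_id": r.id,
            "equation": format_equation(r),
            "ec_numbers": ";".join(sorted(r.ec_numbers)),
            "delta_g": "" if r.delta_g is None else f"{r.delta_g:.4f}",
            "rtype": r.rtype,
        }
        for r in sorted(reactions, key=lambda r: r.id)
    ]
    pd.DataFrame(rows, columns=REACTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# toy compartment-coupling fixtures
# ---------------------------------------------------------------------------


def _toy_base(met_ids: list[str]) -> CompartmentalizedNetwork:
    net = CompartmentalizedNetwork()
    for mid in met_ids:
        formula = {"h2o": {"H": 2, "O": 1}, "h": {"H": 1}}.get(mid, {"C": 1})
        net.add_metabolite(Metabolite(mid, mid, formula, 0, None))
    return net


def _rxn(
    rid: str, equation: str, *, irreversible: bool = False, upper: float = 100.0
) -> Reaction:
    from .model_core import infer_rtype, parse_equation

    stoich, reversible = parse_equation(equation)
    if irreversible:
        reversible = False
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        reversible=reversible,
        lower_bound=-1000.0 if reversible else 0.0,
        upper_bound=upper,
        rtype=infer_rtype(stoich, rid=rid),
    )


def toy_fatty_acid_model() -> CompartmentalizedNetwork:
    """Minimal compartmentalized model of mitochondrial fatty-acid
    elongation.

    Acetyl-CoA is made only in the cytoplasm (from an acetate uptake);
    elongation runs only in the mitochondrion, where the CoA pool is closed
    (regenerated exclusively by elongation), so the whole block carries flux
    iff the acetyl-CoA cytoplasm<->mitochondrion transport is available.
    """
    net = _toy_base(
        ["ac", "accoa", "hdca", "atp", "amp", "ppi", "coa", "pmtcoa", "oxoacoa"]
    )
    for eq in [
        ("EX_ac", "ac@e <=>"),
        ("T_ac_ec", "ac@e <=> ac@c"),
        ("EX_hdca", "hdca@e <=>"),
        ("T_hdca_em", "hdca@e <=> hdca@m"),
        ("EX_atp", "atp@e <=>"),
        ("T_atp_em", "atp@e <=> atp@m"),
        ("EX_amp", "amp@e <=>"),
        ("T_amp_me", "amp@m <=> amp@e"),
        ("EX_ppi", "ppi@e <=>"),
        ("T_ppi_me", "ppi@m <=> ppi@e"),
        ("T_accoa_cm", "accoa@c <=> accoa@m"),
        ("T_oxo_me", "oxoacoa@m <=> oxoacoa@e"),
        ("EX_oxo", "oxoacoa@e <=>"),
        ("FACOAL160@m", "atp@m + hdca@m + coa@m <=> amp@m + pmtcoa@m + ppi@m"),
        ("ELONG@m", "pmtcoa@m + accoa@m <=> coa@m + oxoacoa@m"),
    ]:
        net.add_reaction(_rxn(*eq))
    net.add_reaction(_rxn("ACS@c", "ac@c => accoa@c", irreversible=True))
    net.log("toy_fatty_acid_model")
    return net


def toy_tca_model() -> CompartmentalizedNetwork:
    """Minimal compartmentalized TCA-related model.

    The TCA-block reactions are duplicated in cytoplasm and mitochondrion;
    three cross-compartment exchanges (oxaloacetate, acetyl-CoA,
    2-oxoglutarate) couple the copies.  The objective over the whole block
    is strictly larger with the exchanges than without them, and larger
    without them than on the flattened (single-compartment, deduplicated)
    network.
    """
    met_ids = [
        "acp", "adp", "ac", "atp", "cit", "coa", "accoa", "h2o",
        "oaa", "pep", "co2", "akg", "dhlam", "adhlam",
    ]
    net = _toy_base(met_ids)
    uptakes = ["acp", "adp", "cit", "coa", "dhlam", "akg", "oaa", "atp", "accoa"]
    # scaffolding gets a wide upper bound so the objective members (at the
    # standard policy caps) are the only binding constraints
    for mid in met_ids:
        net.add_reaction(_rxn(f"EX_{mid}", f"{mid}@e <=>", upper=1000.0))
    for mid in uptakes:
        net.add_reaction(_rxn(f"T_{mid}_ec", f"{mid}@e <=> {mid}@c", upper=1000.0))
    for mid in ["ac", "pep", "co2", "h2o", "adhlam"]:
        net.add_reaction(_rxn(f"T_{mid}_ce", f"{mid}@c <=> {mid}@e", upper=1000.0))
    # scaffold transports cytoplasm<->mitochondrion (never excluded)
    for mid in ["cit", "coa", "atp", "adp", "dhlam", "adhlam", "h2o", "pep", "co2"]:
        net.add_reaction(_rxn(f"T_{mid}_cm_s", f"{mid}@c <=> {mid}@m", upper=1000.0))
    # mitochondrial overflow routes to the environment
    for mid in ["accoa", "oaa", "akg"]:
        net.add_reaction(_rxn(f"T_{mid}_me", f"{mid}@m <=> {mid}@e", upper=1000.0))
    # objective exchanges
    net.add_reaction(_rxn("T_oaa_cm", "oaa@c <=> oaa@m"))
    net.add_reaction(_rxn("T_accoa_cm", "accoa@c <=> accoa@m"))
    net.add_reaction(_rxn("T_akg_cm", "akg@c <=> akg@m"))
    # pathway copies
    net.add_reaction(_rxn("ACKr@c", "acp@c + adp@c <=> ac@c + atp@c"))
    for comp in ("c", "m"):
        net.add_reaction(
            _rxn(
                f"CITL@{comp}",
                f"cit@{comp} + coa@{comp} <=> accoa@{comp} + h2o@{comp} + oaa@{comp}",
            )
        )
        net.add_reaction(
            _rxn(
                f"PEPCK@{comp}",
                f"atp@{comp} + oaa@{comp} <=> adp@{comp} + pep@{comp} + co2@{comp}",
            )
        )
        net.add_reaction(
            _rxn(
                f"PDHL@{comp}",
                f"accoa@{comp} + dhlam@{comp} <=> coa@{comp} + adhlam@{comp}",
            )
        )
    net.log("toy_tca_model")
    return net


PRESETS: dict[str, GeneratorConfig] = {
    "paper-like": GeneratorConfig(n_metabolites=150, n_reactions=500),
    "tiny": GeneratorConfig(
        n_metabolites=20,
        n_reactions=40,
        n_vacuole=0,
        n_lysosome=0,
        n_exchange=5,
        planted_gap_count=3,
        decoy_db_size=10,
    ),
    "exponent-recovery": GeneratorConfig(
        n_metabolites=2000, planted_gap_count=0, n_vacuole=0, n_lysosome=0
    ),
}
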