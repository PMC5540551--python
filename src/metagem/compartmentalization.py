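"""Stage 2 — compartment assignment, pruning and transport injection.

Reactions are localized by a consensus of (a) per-reaction subcellular
localization probabilities, as produced by sequence-based predictors of the
CELLO family, and (b) compartment assignments mined from published
compartmentalized reconstructions of taxa present in the community profile.
The consensus is the union of the high-scoring compartments and the
reference compartments; compartments that end up with a negligible number
of reactions (vacuole, lysosome in typical community-scale models) are
pruned and their reactions reassigned.  Finally the network is expanded so
that each reaction has one copy per assigned compartment, and
transport/exchange reactions from a curated database are injected whenever
every species they reference already exists in the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model_core import (
    COMPARTMENT_PRIORITY,
    CompartmentalizedNetwork,
    NetworkError,
    Reaction,
    Species,
    infer_rtype,
)

__all__ = [
    "LocalizationScores",
    "ReferenceAssignment",
    "TransportDB",
    "read_localization_table",
    "read_reference_table",
    "consensus_localization",
    "prune_compartments",
    "compartmentalize_network",
    "inject_transport",
]

#: Consensus defaults: a predictor compartment is accepted at probability
#: >= MIN_SCORE; compartments with fewer than MIN_REACTIONS assigned
#: reactions are pruned (discards the 7-reaction vacuole and 20-reaction
#: lysosome compartments typical of community-scale models, keeping >= 25).
DEFAULT_MIN_SCORE = 0.3
DEFAULT_MIN_REACTIONS = 25


@dataclass
class LocalizationScores:
    """Per-reaction subcellular localization probability distribution."""

    reaction_id: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.scores.values()):
            raise NetworkError(f"{self.reaction_id}: negative localization score")
        total = sum(self.scores.values())
        if abs(total - 1.0) > 1e-6:
            raise NetworkError(
                f"{self.reaction_id}: localization scores sum to {total}, not 1"
            )

    def argmax(self, among: set[str] | None = None) -> str:
        cands = {
            c: p for c, p in self.scores.items() if among is None or c in among
        }
        if not cands:
            return "c"
        best = max(cands.values())
        tied = [c for c, p in cands.items() if abs(p - best) < 1e-12]
        return min(tied, key=lambda c: COMPARTMENT_PRIORITY.get(c, 99))


@dataclass
class ReferenceAssignment:
    """Compartments a reference reconstruction places a reaction in."""

    reaction_id: str
    compartments: set[str]
    source_model: str = ""

    def __post_init__(self) -> None:
        if not self.compartments:
            raise NetworkError(f"{self.reaction_id}: empty reference compartment set")


@dataclass
class TransportDB:
    """A database of transport and exchange reaction templates."""

    templates: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.templates:
            if t.rtype not in ("transport", "exchange"):
                raise NetworkError(
                    f"transport db template {t.id} has rtype {t.rtype!r}"
                )


def read_localization_table(path) -> dict[str, LocalizationScores]:
    """Read a CELLO-like TSV: reaction_id column + one score column per
    compartment code."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "reaction_id" not in df.columns:
        raise NetworkError(f"{path}: missing reaction_id column")
    comp_cols = [c for c in df.columns if c != "reaction_id"]
    out = {}
    for row in df.itertuples(index=False):
        rid = row.reaction_id
        scores = {
            c: float(getattr(row, c)) for c in comp_cols if str(getattr(row, c)).strip()
        }
        out[rid] = LocalizationScores(rid, scores)
    return out


def read_reference_table(path) -> dict[str, ReferenceAssignment]:
    """Read reference assignments (reaction_id, compartment, source_model);
    multiple rows per reaction are merged."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("reaction_id", "compartment", "source_model"):
        if col not in df.columns:
            raise NetworkError(f"{path}: missing column {col}")
    out: dict[str, ReferenceAssignment] = {}
    for row in df.itertuples(index=False):
        ref = out.get(row.reaction_id)
        if ref is None:
            out[row.reaction_id] = ReferenceAssignment(
                row.reaction_id, {row.compartment}, row.source_model
            )
        else:
            ref.compartments.add(row.compartment)
    return out


def consensus_localization(
    loc: dict[str, LocalizationScores],
    refs: dict[str, ReferenceAssignment] | None = None,
    *,
    reaction_ids: list[str] | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> dict[str, set[str]]:
    """Union of predictor compartments scoring >= min_score and reference
    compartments; argmax fallback (priority tie-break c > m > n > x > e)
    when the union is empty.

    Raises for any requested reaction with neither scores nor a reference
    entry.
    """
    refs = refs or {}
    ids = reaction_ids if reaction_ids is not None else sorted(set(loc) | set(refs))
    missing = [rid for rid in ids if rid not in loc and rid not in refs]
    if missing:
        raise NetworkError(
            f"no localization evidence for reactions: {', '.join(sorted(missing))}"
        )
    out: dict[str, set[str]] = {}
    for rid in ids:
        comps: set[str] = set()
        if rid in loc:
            comps |= {c for c, p in loc[rid].scores.items() if p >= min_score}
        if rid in refs:
            comps |= set(refs[rid].compartments)
        if not comps:
            comps = {loc[rid].argmax()}
        out[rid] = comps
    return out


@dataclass
class PruneReport:
    discarded: dict[str, int] = field(default_factory=dict)  # compartment -> n reactions
    reassigned: dict[str, str] = field(default_factory=dict)  # reaction -> new compartment


def prune_compartments(
    assignments: dict[str, set[str]],
    *,
    min_reactions: int = DEFAULT_MIN_REACTIONS,
    scores: dict[str, LocalizationScores] | None = None,
) -> tuple[dict[str, set[str]], PruneReport]:
    """Remove compartments with fewer than ``min_reactions`` reactions.

    Reactions left without a compartment are reassigned to their next-best
    surviving compartment by predictor score, with cytoplasm as the final
    fallback.  Cytoplasm and the extracellular space cannot be pruned.
    """
    counts: dict[str, int] = {}
    for comps in assignments.values():
        for c in comps:
            counts[c] = counts.get(c, 0) + 1
    doomed = {c for c, n in counts.items() if n < min_reactions}
    if doomed & {"c", "e"}:
        raise NetworkError("pruning the cytoplasm or extracellular space is forbidden")
    report = PruneReport(discarded={c: counts[c] for c in sorted(doomed)})
    surviving = set(counts) - doomed
    out: dict[str, set[str]] = {}
    for rid in sorted(assignments):
        comps = assignments[rid] - doomed
        if not comps:
            if scores and rid in scores:
                comps = {scores[rid].argmax(among=surviving)}
            else:
                comps = {"c"}
            report.reassigned[rid] = next(iter(comps))
        out[rid] = comps
    return out, report


def compartmentalize_network(
    network: CompartmentalizedNetwork, assignments: dict[str, set[str]]
) -> CompartmentalizedNetwork:
    """Duplicate each reaction into every assigned compartment.

    The copy for compartment ``k`` carries all of its species in ``k``
    (reaction copy ids are ``<rid>@<k>``); transport and exchange reactions
    are structural and kept as-is.  The set of unique metabolite ids is
    preserved exactly.
    """
    out = CompartmentalizedNetwork()
    for met in network.metabolites.values():
        out.add_metabolite(met)
    for rid in sorted(network.reactions):
        rxn = network.reactions[rid]
        if rxn.rtype in ("transport", "exchange"):
            out.add_reaction(rxn)
            continue
        comps = assignments.get(rid)
        if not comps:
            raise NetworkError(f"reaction {rid} has no compartment assignment")
        for comp in sorted(comps):
            stoich = {
                f"{Species.from_id(s).metabolite_id}@{comp}": coeff
                for s, coeff in rxn.stoichiometry.items()
            }
            copy_id = rid if comps == {"c"} else f"{rid}@{comp}"
            out.add_reaction(
                Reaction(
                    id=copy_id,
                    stoichiometry=stoich,
                    reversible=rxn.reversible,
                    lower_bound=rxn.lower_bound,
                    upper_bound=rxn.upper_bound,
                    delta_g=rxn.delta_g,
                    ec_numbers=rxn.ec_numbers,
                    rtype="metabolic",
                )
            )
    out.log(
        "compartmentalize_network: "
        + ", ".join(
            f"{c}={len(s)}" for c, s in sorted(out.species_by_compartment().items())
        )
    )
    return out


def inject_transport(
    network: CompartmentalizedNetwork, db: TransportDB
) -> tuple[CompartmentalizedNetwork, list[str], dict[str, int]]:
    """Add every template whose species all already exist in the network.

    Returns the augmented network, the added ids, and the additions
    partitioned into cytoplasm<->extracellular versus cytoplasm<->inner
    transports (exchanges count toward the extracellular class).
    """
    out = network.copy()
    added: list[str] = []
    counts = {"cytoplasm_extracellular": 0, "cytoplasm_inner": 0}
    for template in sorted(db.templates, key=lambda t: t.id):
        if template.id in out.reactions:
            continue
        if not all(sid in out.species for sid in template.stoichiometry):
            continue
        out.add_reaction(template, allow_new_species=False)
        added.append(template.id)
        comps = template.compartments()
        if "e" in comps:
            counts["cytoplasm_extracellular"] += 1
        else:
            counts["cytoplasm_inner"] += 1
    out.log(
        f"inject_transport: +{len(added)} "
        f"(c<->e {counts['cytoplasm_extracellular']}, "
        f"c<->inner {counts['cytoplasm_inner']})"
    )
    return out, added, counts
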