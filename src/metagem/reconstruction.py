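"""Stage 1 — draft network reconstruction and refinement.

Four refinement steps turn an annotation-derived reaction set into a usable
draft: (i) metabolite mass/charge/formula properties are attached (stated at
intracellular pH 7.2; this module consumes them, it does not recompute
protonation states); (ii) reactions touching *generic* metabolites (DNA,
RNA, proteins, glycans, generic lipid classes — compounds without a fully
specified formula) are removed; (iii) every reaction is checked for
elemental and charge balance, repairing imbalances that are expressible as
an integer combination of protons and water (both are routinely omitted by
upstream databases); (iv) directionality is assigned from the standard
transformed Gibbs energy, defaulting to reversible when no estimate exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model_core import (
    DEFAULT_UPPER_BOUND,
    REVERSIBLE_LOWER_BOUND,
    CompartmentalizedNetwork,
    Metabolite,
    Reaction,
    Species,
)

__all__ = [
    "BalanceReport",
    "DirectionalityPolicy",
    "remove_generic_reactions",
    "check_and_repair_balance",
    "apply_repair",
    "balance_network",
    "assign_directionality",
]

#: Default |delta_g| (kJ/mol) above which a reaction is called irreversible.
#: The directionality call from thermodynamics needs a cutoff; 30 kJ/mol is a
#: common practice value and is exposed in the policy because the choice is
#: genuinely open.
DEFAULT_DIRECTIONALITY_THRESHOLD = 30.0


@dataclass
class BalanceReport:
    """Outcome of the mass/charge balance check for one reaction.

    ``element_imbalance`` is the net elemental count (products minus
    substrates) before any repair; ``charge_imbalance`` likewise.  When the
    imbalance is closable with protons/water, ``repaired`` is set and
    ``repair_terms`` records the signed coefficients added (positive =
    product side).  ``status`` is one of ``balanced`` / ``repaired`` /
    ``unbalanced`` / ``unverifiable`` (a participant lacks a formula).
    """

    reaction_id: str
    element_imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0
    repaired: bool = False
    repair_terms: dict[str, float] = field(default_factory=dict)
    status: str = "balanced"

    @property
    def balanced(self) -> bool:
        return self.status in ("balanced", "repaired")


def remove_generic_reactions(
    network: CompartmentalizedNetwork,
) -> tuple[CompartmentalizedNetwork, list[str]]:
    """Drop every reaction that touches a generic metabolite.

    Returns the filtered network and the sorted list of removed reaction
    ids.  Species orphaned by the removal are dropped.  Idempotent.
    """
    removed = []
    for rid, rxn in network.reactions.items():
        for sid in rxn.stoichiometry:
            met = network.metabolites[Species.from_id(sid).metabolite_id]
            if met.is_generic:
                removed.append(rid)
                break
    out = network.copy()
    out.remove_reactions(removed, drop_orphans=True)
    out.log(f"remove_generic_reactions: removed {len(removed)}")
    return out, sorted(removed)


def _net_balance(
    reaction: Reaction, metabolites: dict[str, Metabolite]
) -> tuple[dict[str, float], float] | None:
    """Net (products - substrates) elemental and charge totals, or None if
    some participant has no formula."""
    elements: dict[str, float] = {}
    charge = 0.0
    for sid, coeff in reaction.stoichiometry.items():
        met = metabolites[Species.from_id(sid).metabolite_id]
        if met.formula is None or met.charge is None:
            return None
        for el, n in met.formula.items():
            elements[el] = elements.get(el, 0.0) + coeff * n
        charge += coeff * met.charge
    elements = {el: v for el, v in elements.items() if abs(v) > 1e-9}
    return elements, charge


def check_and_repair_balance(
    reaction: Reaction,
    metabolites: dict[str, Metabolite],
    *,
    water_id: str = "h2o",
    proton_id: str = "h",
) -> BalanceReport:
    """Check elemental/charge balance; propose a H2O/H+ repair if possible.

    The repair solves for signed water and proton coefficients ``t_w``,
    ``t_h`` such that adding ``t_w`` H2O and ``t_h`` H+ on the product side
    zeroes every element and the charge:

    * oxygen fixes ``t_w = -dO``,
    * hydrogen then fixes ``t_h = -(dH + 2 t_w)``,
    * the repair is valid only if ``t_h`` also cancels the charge imbalance
      and no other element is off.

    Exchange reactions are exempt (they are boundary terms, imbalanced by
    construction).  Missing formulas yield status ``unverifiable``.
    """
    report = BalanceReport(reaction_id=reaction.id)
    if reaction.rtype == "exchange":
        report.status = "balanced"
        return report
    totals = _net_balance(reaction, metabolites)
    if totals is None:
        report.status = "unverifiable"
        return report
    elements, charge = totals
    report.element_imbalance = dict(elements)
    report.charge_imbalance = charge
    if not elements and abs(charge) < 1e-9:
        report.status = "balanced"
        return report
    # candidate repair
    d_o = elements.get("O", 0.0)
    d_h = elements.get("H", 0.0)
    t_w = -d_o
    t_h = -(d_h + 2.0 * t_w)
    others_clean = all(el in ("H", "O") for el in elements)
    charge_clean = abs(charge + t_h) < 1e-9
    integral = abs(t_w - round(t_w)) < 1e-9 and abs(t_h - round(t_h)) < 1e-9
    if others_clean and charge_clean and integral and (t_w or t_h):
        comps = sorted(reaction.compartments() - {"e"}) or ["c"]
        comp = comps[0]
        terms: dict[str, float] = {}
        if abs(t_w) > 1e-9:
            terms[f"{water_id}@{comp}"] = round(t_w)
        if abs(t_h) > 1e-9:
            terms[f"{proton_id}@{comp}"] = round(t_h)
        report.repair_terms = terms
        report.repaired = True
        report.status = "repaired"
    else:
        report.status = "unbalanced"
    return report


def apply_repair(reaction: Reaction, report: BalanceReport) -> Reaction:
    """Merge the report's repair terms into the reaction stoichiometry."""
    if not report.repaired:
        return reaction
    stoich = dict(reaction.stoichiometry)
    for sid, coeff in report.repair_terms.items():
        stoich[sid] = stoich.get(sid, 0.0) + coeff
    return replace(reaction, stoichiometry=stoich)


def balance_network(
    network: CompartmentalizedNetwork,
    *,
    water_id: str = "h2o",
    proton_id: str = "h",
    strict: bool = False,
) -> tuple[CompartmentalizedNetwork, list[BalanceReport]]:
    """Run the balance check over every reaction, applying repairs.

    Unrepairable reactions are retained and flagged rather than silently
    dropped; ``strict=True`` drops them instead.
    """
    out = network.copy()
    reports = []
    dropped = []
    for rid in sorted(out.reactions):
        rxn = out.reactions[rid]
        report = check_and_repair_balance(
            rxn, out.metabolites, water_id=water_id, proton_id=proton_id
        )
        reports.append(report)
        if report.repaired:
            repaired = apply_repair(rxn, report)
            for sid in repaired.stoichiometry:
                spec = Species.from_id(sid)
                out.ensure_species(spec.metabolite_id, spec.compartment)
            out.reactions[rid] = repaired
        elif report.status == "unbalanced" and strict:
            dropped.append(rid)
    if dropped:
        out.remove_reactions(dropped)
    out.log(
        "balance_network: "
        f"{sum(r.status == 'repaired' for r in reports)} repaired, "
        f"{sum(r.status == 'unbalanced' for r in reports)} unbalanced"
        + (f", {len(dropped)} dropped" if dropped else "")
    )
    return out, reports


def write_balance_reports(reports: list[BalanceReport], path) -> None:
    import pandas as pd

    rows = [
        {
            "reaction_id": r.reaction_id,
            "status": r.status,
            "imbalance": ";".join(
                f"{el}:{v:g}" for el, v in sorted(r.element_imbalance.items())
            )
            + (f";charge:{r.charge_imbalance:g}" if r.charge_imbalance else ""),
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=["reaction_id", "status", "imbalance"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class DirectionalityPolicy:
    """Thermodynamic directionality call and the global bound policy."""

    threshold: float = DEFAULT_DIRECTIONALITY_THRESHOLD
    upper_bound: float = DEFAULT_UPPER_BOUND
    reversible_lower_bound: float = REVERSIBLE_LOWER_BOUND


def assign_directionality(
    reaction: Reaction, policy: DirectionalityPolicy | None = None
) -> Reaction:
    """Set reversibility and bounds from the reaction's delta_g.

    * no estimate -> reversible, bounds (-1000, 100);
    * delta_g <= -threshold -> irreversible forward, bounds (0, 100);
    * delta_g >= +threshold -> the reaction is flipped (substrates and
      products swapped, delta_g negated) and made irreversible;
    * otherwise -> reversible.
    """
    policy = policy or DirectionalityPolicy()
    rxn = reaction
    if rxn.delta_g is not None and rxn.delta_g >= policy.threshold:
        rxn = replace(rxn.flipped(), delta_g=-rxn.delta_g)
    if rxn.delta_g is not None and rxn.delta_g <= -policy.threshold:
        return replace(
            rxn, reversible=False, lower_bound=0.0, upper_bound=policy.upper_bound
        )
    return replace(
        rxn,
        reversible=True,
        lower_bound=policy.reversible_lower_bound,
        upper_bound=policy.upper_bound,
    )


def assign_network_directionality(
    network: CompartmentalizedNetwork, policy: DirectionalityPolicy | None = None
) -> CompartmentalizedNetwork:
    out = network.copy()
    for rid in sorted(out.reactions):
        rxn = out.reactions[rid]
        if rxn.rtype != "metabolic":
            continue  # boundary/transport bounds are policy-set elsewhere
        out.reactions[rid] = assign_directionality(rxn, policy)
    out.log("assign_network_directionality")
    return out
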