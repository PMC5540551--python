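"""Core domain types and I/O for compartmentalized metabolic networks.

The package models a microbial community as a single *meta-organism*: one
shared reaction pool whose species are partitioned over subcellular
compartments (cytoplasm ``c``, mitochondrion ``m``, nucleus ``n``,
peroxisome ``x``, extracellular space ``e``; vacuole ``v`` and lysosome
``l`` are admissible only before compartment pruning).  The same metabolite
present in two compartments is two distinct species, written
``<metabolite_id>@<compartment>``.

This module owns:

* the :class:`Metabolite` / :class:`Species` / :class:`Reaction` /
  :class:`CompartmentalizedNetwork` containers shared by every pipeline
  stage,
* the tab-separated table dialect used for all inputs (reaction tables,
  metabolite property tables, transport/candidate databases),
* the stoichiometric matrix builder (deterministic, lexicographic row and
  column order), and
* lossless SBML Level 3 export/import (bounds, reaction type and
  thermodynamic annotations ride in a custom annotation namespace).
"""

from __future__ import annotations

import copy as _copy
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "COMPARTMENTS",
    "CORE_COMPARTMENTS",
    "COMPARTMENT_NAMES",
    "COMPARTMENT_PRIORITY",
    "DEFAULT_UPPER_BOUND",
    "REVERSIBLE_LOWER_BOUND",
    "PH",
    "COEFF_TOL",
    "Metabolite",
    "Species",
    "Reaction",
    "CompartmentalizedNetwork",
    "StoichiometricMatrix",
    "NetworkError",
    "SBMLError",
    "infer_rtype",
    "parse_formula",
    "format_formula",
    "parse_equation",
    "format_equation",
    "read_network",
    "write_network",
    "read_reaction_table",
    "build_stoichiometric_matrix",
    "export_sbml",
    "import_sbml",
    "flatten_network",
]

#: Intracellular pH at which metabolite formula/charge tables are stated.
PH = 7.2

#: Default flux bounds, mmol gDW^-1 h^-1.  Irreversible reactions get
#: (0, 100); reversible reactions get (-1000, 100).
DEFAULT_UPPER_BOUND = 100.0
REVERSIBLE_LOWER_BOUND = -1000.0

#: Tolerance for exact comparison of stoichiometric coefficients.
COEFF_TOL = 1e-9

CORE_COMPARTMENTS = ("c", "m", "n", "x", "e")
COMPARTMENTS = CORE_COMPARTMENTS + ("v", "l")
COMPARTMENT_NAMES = {
    "c": "cytoplasm",
    "m": "mitochondrion",
    "n": "nucleus",
    "x": "peroxisome",
    "e": "extracellular",
    "v": "vacuole",
    "l": "lysosome",
}
#: Fixed tie-break priority for compartment assignment.
COMPARTMENT_PRIORITY = {"c": 0, "m": 1, "n": 2, "x": 3, "e": 4, "v": 5, "l": 6}

RTYPES = ("metabolic", "transport", "exchange")


class NetworkError(ValueError):
    """Malformed network input (dangling species, duplicate ids, bad equation)."""


class SBMLError(RuntimeError):
    """SBML document failed to parse or validate."""


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int] | None:
    """Parse an elemental formula string like ``C6H12O6`` into a dict.

    Empty strings and the placeholders ``-``/``NA``/``none`` yield ``None``
    (no fully specified composition, i.e. a generic compound).
    """
    text = (text or "").strip()
    if not text or text.lower() in {"-", "na", "none", "null"}:
        return None
    pos = 0
    out: dict[str, int] = {}
    for match in _FORMULA_RE.finditer(text):
        if match.start() != pos:
            raise NetworkError(f"malformed formula {text!r}")
        pos = match.end()
        element, count = match.group(1), match.group(2)
        out[element] = out.get(element, 0) + (int(count) if count else 1)
    if pos != len(text):
        raise NetworkError(f"malformed formula {text!r}")
    return {el: n for el, n in out.items() if n != 0}


def format_formula(formula: Mapping[str, int] | None) -> str:
    """Render a composition map in Hill order (C, H, then alphabetical)."""
    if not formula:
        return ""
    keys = sorted(formula, key=lambda el: (el != "C", el != "H", el))
    return "".join(f"{el}{formula[el] if formula[el] != 1 else ''}" for el in keys)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    """A chemical compound, independent of compartment.

    ``is_generic`` marks compounds without a fully specified elemental
    formula (DNA, RNA, proteins, generic lipid classes, glycans); such
    compounds invalidate the reactions touching them and are removed in the
    reconstruction stage.  Charges are integer elementary charges at pH 7.2;
    masses are g/mol.
    """

    id: str
    name: str = ""
    formula: dict[str, int] | None = None
    charge: int | None = 0
    mass: float | None = None
    is_generic: bool = False

    def __post_init__(self) -> None:
        if self.mass is not None and not self.mass > 0:
            raise NetworkError(f"metabolite {self.id}: mass must be > 0")
        if self.is_generic != (self.formula is None):
            raise NetworkError(
                f"metabolite {self.id}: is_generic must hold exactly when the "
                "elemental formula is unspecified"
            )


@dataclass(frozen=True, order=True)
class Species:
    """A metabolite located in a compartment (the node unit of the network)."""

    metabolite_id: str
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkError(f"unknown compartment {self.compartment!r}")

    @property
    def id(self) -> str:
        return f"{self.metabolite_id}@{self.compartment}"

    @staticmethod
    def from_id(species_id: str) -> "Species":
        met, sep, comp = species_id.rpartition("@")
        if not sep or not met:
            raise NetworkError(f"species id {species_id!r} is not '<met>@<comp>'")
        return Species(met, comp)


@dataclass
class Reaction:
    """A (possibly cross-compartment) reaction over located species.

    ``stoichiometry`` maps species ids to signed coefficients (negative for
    substrates).  ``reversible`` is kept consistent with the bounds:
    ``reversible <=> lower_bound < 0``.  ``delta_g`` is the standard
    transformed Gibbs energy in kJ/mol when known; reactions without an
    estimate default to reversible.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = True
    lower_bound: float = REVERSIBLE_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    delta_g: float | None = None
    ec_numbers: frozenset[str] = field(default_factory=frozenset)
    rtype: str = "metabolic"

    def __post_init__(self) -> None:
        self.ec_numbers = frozenset(self.ec_numbers)
        self.stoichiometry = {
            s: float(c) for s, c in self.stoichiometry.items() if abs(c) > COEFF_TOL
        }
        if not self.stoichiometry:
            raise NetworkError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkError(f"reaction {self.id}: lower bound above upper bound")
        if self.reversible != (self.lower_bound < 0):
            raise NetworkError(
                f"reaction {self.id}: reversible flag inconsistent with bounds "
                f"({self.lower_bound}, {self.upper_bound})"
            )
        if self.rtype not in RTYPES:
            raise NetworkError(f"reaction {self.id}: unknown rtype {self.rtype!r}")
        inferred = self.infer_rtype()
        if self.rtype != inferred:
            raise NetworkError(
                f"reaction {self.id}: declared rtype {self.rtype!r} conflicts with "
                f"structure ({inferred!r})"
            )

    # -- structure ---------------------------------------------------------
    def substrates(self) -> dict[str, float]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}

    def compartments(self) -> set[str]:
        return {Species.from_id(s).compartment for s in self.stoichiometry}

    def is_one_sided(self) -> bool:
        return not self.substrates() or not self.products()

    def infer_rtype(self) -> str:
        return infer_rtype(self.stoichiometry, rid=self.id)

    def flipped(self) -> "Reaction":
        """Reaction with substrates and products swapped (orientation reversed)."""
        return replace(
            self,
            stoichiometry={s: -c for s, c in self.stoichiometry.items()},
        )


def infer_rtype(stoichiometry: Mapping[str, float], *, rid: str = "?") -> str:
    """Classify a stoichiometry as metabolic / transport / exchange.

    Exchange: one-sided, extracellular species only (an environment
    boundary).  Transport: species span >= 2 compartments.  One-sided
    reactions outside the extracellular space are rejected: demands and
    sinks must be routed through the environment.
    """
    comps = {Species.from_id(s).compartment for s in stoichiometry}
    one_sided = all(c < 0 for c in stoichiometry.values()) or all(
        c > 0 for c in stoichiometry.values()
    )
    if one_sided:
        if comps != {"e"}:
            raise NetworkError(
                f"reaction {rid}: one-sided reactions must act on extracellular "
                "species only (boundary exchange)"
            )
        return "exchange"
    if len(comps) >= 2:
        return "transport"
    return "metabolic"


@dataclass
class StoichiometricMatrix:
    """Sparse species x reaction matrix with deterministic index order."""

    S: sp.csc_matrix
    row_index: list[str]
    col_index: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape

    def dense(self) -> np.ndarray:
        return self.S.toarray()

    def row(self, species_id: str) -> int:
        return self.row_index.index(species_id)

    def col(self, reaction_id: str) -> int:
        return self.col_index.index(reaction_id)


class CompartmentalizedNetwork:
    """Species and reactions partitioned over compartments, with provenance.

    Invariants enforced on every mutation: reaction ids are unique, every
    species referenced by a reaction exists in the species set, and every
    species references a declared metabolite.
    """

    def __init__(self) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.species: dict[str, Species] = {}
        self.reactions: dict[str, Reaction] = {}
        self.provenance: list[str] = []

    # -- construction ------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def ensure_species(self, metabolite_id: str, compartment: str) -> Species:
        if metabolite_id not in self.metabolites:
            raise NetworkError(
                f"reaction references undeclared metabolite {metabolite_id!r}"
            )
        spec = Species(metabolite_id, compartment)
        return self.species.setdefault(spec.id, spec)

    def add_reaction(self, reaction: Reaction, *, allow_new_species: bool = True) -> None:
        if reaction.id in self.reactions:
            raise NetworkError(f"duplicate reaction id {reaction.id!r}")
        for sid in reaction.stoichiometry:
            spec = Species.from_id(sid)
            if allow_new_species:
                self.ensure_species(spec.metabolite_id, spec.compartment)
            elif sid not in self.species:
                raise NetworkError(f"reaction {reaction.id}: dangling species {sid!r}")
        self.reactions[reaction.id] = reaction

    def remove_reactions(self, ids: Iterable[str], *, drop_orphans: bool = True) -> None:
        for rid in ids:
            self.reactions.pop(rid, None)
        if drop_orphans:
            used = {s for r in self.reactions.values() for s in r.stoichiometry}
            self.species = {sid: s for sid, s in self.species.items() if sid in used}

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "CompartmentalizedNetwork":
        return _copy.deepcopy(self)

    # -- queries -----------------------------------------------------------
    def compartments(self) -> set[str]:
        return {s.compartment for s in self.species.values()}

    def species_by_compartment(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid in sorted(self.species):
            out.setdefault(self.species[sid].compartment, []).append(sid)
        return out

    def metabolite_ids(self) -> set[str]:
        """Unique metabolite ids, ignoring compartments."""
        return {s.metabolite_id for s in self.species.values()}

    def reactions_by_rtype(self) -> dict[str, int]:
        out = {t: 0 for t in RTYPES}
        for r in self.reactions.values():
            out[r.rtype] += 1
        return out

    def validate(self) -> None:
        for rid, r in self.reactions.items():
            for sid in r.stoichiometry:
                if sid not in self.species:
                    raise NetworkError(f"reaction {rid}: dangling species {sid!r}")
        for sid, spec in self.species.items():
            if spec.metabolite_id not in self.metabolites:
                raise NetworkError(f"species {sid}: undeclared metabolite")

    def equal_to(self, other: "CompartmentalizedNetwork") -> bool:
        """Field-by-field equality (used by round-trip tests)."""
        if set(self.species) != set(other.species):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for mid, met in self.metabolites.items():
            o = other.metabolites.get(mid)
            if o is None or (met.id, met.name, met.formula, met.charge, met.is_generic) != (
                o.id,
                o.name,
                o.formula,
                o.charge,
                o.is_generic,
            ):
                return False
            if (met.mass is None) != (o.mass is None):
                return False
            if met.mass is not None and abs(met.mass - o.mass) > 1e-9:
                return False
        for rid, r in self.reactions.items():
            o = other.reactions[rid]
            if (r.reversible, r.rtype, r.ec_numbers) != (o.reversible, o.rtype, o.ec_numbers):
                return False
            if abs(r.lower_bound - o.lower_bound) > 1e-9 or abs(r.upper_bound - o.upper_bound) > 1e-9:
                return False
            if (r.delta_g is None) != (o.delta_g is None):
                return False
            if r.delta_g is not None and abs(r.delta_g - o.delta_g) > 1e-9:
                return False
            if set(r.stoichiometry) != set(o.stoichiometry):
                return False
            if any(
                abs(c - o.stoichiometry[s]) > COEFF_TOL for s, c in r.stoichiometry.items()
            ):
                return False
        return True


# ---------------------------------------------------------------------------
# reaction equation dialect
# ---------------------------------------------------------------------------

# Accepted arrows: "<=>", "< = >", "<==>", "< = = >" (reversible), "=>", "->"
# (irreversible), and a bare "=" between spaces (reversible, as printed by
# several reaction databases).
_REV_ARROW = re.compile(r"<(?:\s*=)+\s*>|(?<=\s)=(?=\s)")
_IRR_ARROW = re.compile(r"=+\s*>|->")


def _split_equation(text: str) -> tuple[str, str, bool]:
    m = _REV_ARROW.search(text)
    if m:
        return text[: m.start()], text[m.end() :], True
    m = _IRR_ARROW.search(text)
    if m:
        return text[: m.start()], text[m.end() :], False
    raise NetworkError(f"equation {text!r} has no reaction arrow")


_TERM_RE = re.compile(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$")


def parse_equation(
    text: str, *, default_compartment: str = "c"
) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A@c + B@c <=> C@c"`` into a signed stoichiometry map.

    Species without an explicit ``@compartment`` suffix are placed in
    ``default_compartment``.  Duplicated species are merged by net
    coefficient.
    """
    lhs, rhs, reversible = _split_equation(text)
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, +1.0)):
        side = side.strip()
        if not side:
            continue
        for term in re.split(r"\s+\+\s+", side):
            term = term.strip()
            if not term:
                continue
            m = _TERM_RE.match(term)
            if not m:
                raise NetworkError(f"malformed stoichiometry term {term!r} in {text!r}")
            coeff = float(m.group(1)) if m.group(1) else 1.0
            token = m.group(2)
            if "@" not in token:
                token = f"{token}@{default_compartment}"
            Species.from_id(token)  # validates
            stoich[token] = stoich.get(token, 0.0) + sign * coeff
    stoich = {s: c for s, c in stoich.items() if abs(c) > COEFF_TOL}
    if not stoich:
        raise NetworkError(f"equation {text!r} has no net stoichiometry")
    return stoich, reversible


def _fmt_coeff(c: float) -> str:
    if abs(c - round(c)) < COEFF_TOL:
        c = int(round(c))
        return "" if c == 1 else f"{c} "
    return f"{c:g} "


def format_equation(reaction: Reaction) -> str:
    lhs = " + ".join(
        f"{_fmt_coeff(c)}{s}" for s, c in sorted(reaction.substrates().items())
    )
    rhs = " + ".join(
        f"{_fmt_coeff(c)}{s}" for s, c in sorted(reaction.products().items())
    )
    arrow = "<=>" if reaction.reversible else "=>"
    return f"{lhs} {arrow} {rhs}".strip()


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

METABOLITE_COLUMNS = ["metabolite_id", "name", "formula", "charge", "mass", "is_generic"]
REACTION_COLUMNS = ["reaction_id", "equation", "ec_numbers", "delta_g", "rtype"]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise NetworkError(f"{path}: missing columns {missing}")
    return df


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in {"1", "true", "yes", "y"}


def read_metabolite_table(path: str | Path) -> dict[str, Metabolite]:
    df = _read_tsv(path, METABOLITE_COLUMNS)
    mets: dict[str, Metabolite] = {}
    for row in df.itertuples(index=False):
        mid = row.metabolite_id.strip()
        if mid in mets:
            raise NetworkError(f"{path}: duplicate metabolite id {mid!r}")
        formula = parse_formula(row.formula)
        mets[mid] = Metabolite(
            id=mid,
            name=row.name.strip(),
            formula=formula,
            charge=int(row.charge) if row.charge.strip() else None,
            mass=float(row.mass) if row.mass.strip() else None,
            is_generic=_parse_bool(row.is_generic) if row.is_generic.strip() else formula is None,
        )
    return mets


def _reaction_from_row(row, *, default_compartment: str, line: int, path) -> Reaction:
    try:
        stoich, reversible = parse_equation(
            row.equation, default_compartment=default_compartment
        )
        lb = REVERSIBLE_LOWER_BOUND if reversible else 0.0
        declared = row.rtype.strip() if row.rtype.strip() else None
        rxn = Reaction(
            id=row.reaction_id.strip(),
            stoichiometry=stoich,
            reversible=reversible,
            lower_bound=lb,
            upper_bound=DEFAULT_UPPER_BOUND,
            delta_g=float(row.delta_g) if row.delta_g.strip() else None,
            ec_numbers=frozenset(
                ec.strip() for ec in row.ec_numbers.split(";") if ec.strip()
            ),
            rtype=declared or "metabolic",
        )
    except NetworkError as exc:
        raise NetworkError(f"{path} line {line}: {exc}") from exc
    return rxn


def read_reaction_table(
    path: str | Path, *, default_compartment: str = "c"
) -> list[Reaction]:
    """Read a reaction TSV into a list (used for transport/candidate dbs too)."""
    df = _read_tsv(path, REACTION_COLUMNS)
    out: list[Reaction] = []
    seen: set[str] = set()
    for line, row in enumerate(df.itertuples(index=False), start=2):
        rxn = _reaction_from_row(
            row, default_compartment=default_compartment, line=line, path=path
        )
        if rxn.id in seen:
            raise NetworkError(f"{path} line {line}: duplicate reaction id {rxn.id!r}")
        seen.add(rxn.id)
        out.append(rxn)
    return out


def read_network(
    reaction_table: str | Path,
    metabolite_table: str | Path,
    *,
    default_compartment: str = "c",
) -> CompartmentalizedNetwork:
    """Assemble a network from the reaction and metabolite property tables."""
    net = CompartmentalizedNetwork()
    for met in read_metabolite_table(metabolite_table).values():
        net.add_metabolite(met)
    for rxn in read_reaction_table(reaction_table, default_compartment=default_compartment):
        net.add_reaction(rxn)
    net.validate()
    net.log(f"read_network: {len(net.reactions)} reactions, {len(net.species)} species")
    return net


def write_network(
    network: CompartmentalizedNetwork,
    reaction_table: str | Path,
    metabolite_table: str | Path,
) -> None:
    """Write the network back to the TSV dialect (deterministic order)."""
    met_rows = []
    for mid in sorted(network.metabolites):
        met = network.metabolites[mid]
        met_rows.append(
            {
                "metabolite_id": met.id,
                "name": met.name,
                "formula": format_formula(met.formula),
                "charge": "" if met.charge is None else str(met.charge),
                "mass": "" if met.mass is None else f"{met.mass:.6f}",
                "is_generic": str(met.is_generic).lower(),
            }
        )
    pd.DataFrame(met_rows, columns=METABOLITE_COLUMNS).to_csv(
        metabolite_table, sep="\t", index=False
    )
    rxn_rows = []
    for rid in sorted(network.reactions):
        r = network.reactions[rid]
        rxn_rows.append(
            {
                "reaction_id": r.id,
                "equation": format_equation(r),
                "ec_numbers": ";".join(sorted(r.ec_numbers)),
                "delta_g": "" if r.delta_g is None else f"{r.delta_g:.4f}",
                "rtype": r.rtype,
            }
        )
    pd.DataFrame(rxn_rows, columns=REACTION_COLUMNS).to_csv(
        reaction_table, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(network: CompartmentalizedNetwork) -> StoichiometricMatrix:
    """Build S with rows = species, columns = reactions, both lexicographic."""
    network.validate()
    rows = sorted(network.species)
    cols = sorted(network.reactions)
    row_pos = {s: i for i, s in enumerate(rows)}
    data, ri, ci = [], [], []
    for j, rid in enumerate(cols):
        for sid, coeff in network.reactions[rid].stoichiometry.items():
            data.append(coeff)
            ri.append(row_pos[sid])
            ci.append(j)
    S = sp.csc_matrix(
        (data, (ri, ci)), shape=(len(rows), len(cols)), dtype=float
    )
    return StoichiometricMatrix(S=S, row_index=rows, col_index=cols)


# ---------------------------------------------------------------------------
# SBML Level 3 export / import
# ---------------------------------------------------------------------------

_ANN_NS = "urn:metagem:annotation"


def _sanitize_sid(raw: str) -> str:
    out = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not out or not (out[0].isalpha() or out[0] == "_"):
        out = "_" + out
    return out


def _kv_annotation(pairs: dict[str, str]) -> str:
    items = "".join(
        f'<metagem:kv key="{k}" value="{_xml_escape(v)}"/>' for k, v in pairs.items()
    )
    return f'<metagem:info xmlns:metagem="{_ANN_NS}">{items}</metagem:info>'


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")
    )


def _read_kv_annotation(node) -> dict[str, str]:
    raw = node.getAnnotationString()
    if not raw:
        return {}
    root = ET.fromstring(raw)
    out = {}
    for kv in root.iter(f"{{{_ANN_NS}}}kv"):
        # libsbml omits empty-string attributes when serializing
        out[kv.get("key")] = kv.get("value") or ""
    return out


def export_sbml(network: CompartmentalizedNetwork, path: str | Path) -> None:
    """Write the network as an SBML Level 3 Version 1 document.

    Attributes SBML core has no slot for (bounds, rtype, delta_g, EC
    numbers, elemental formula, charge, original ids) are carried as
    key/value pairs in a package annotation namespace so that import is a
    lossless inverse.
    """
    import libsbml

    network.validate()
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("metagem_model")
    for comp in sorted(network.compartments()):
        c = model.createCompartment()
        c.setId(f"comp_{comp}")
        c.setName(COMPARTMENT_NAMES[comp])
        c.setConstant(True)
    sid_of: dict[str, str] = {}
    for sid in sorted(network.species):
        spec = network.species[sid]
        met = network.metabolites[spec.metabolite_id]
        sbml_id = f"S_{_sanitize_sid(sid)}"
        base, k = sbml_id, 1
        while sbml_id in sid_of.values():
            sbml_id = f"{base}_{k}"
            k += 1
        sid_of[sid] = sbml_id
        s = model.createSpecies()
        s.setId(sbml_id)
        s.setName(met.name or met.id)
        s.setCompartment(f"comp_{spec.compartment}")
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
        s.setBoundaryCondition(False)
        pairs = {
            "metabolite_id": spec.metabolite_id,
            "compartment": spec.compartment,
            "formula": format_formula(met.formula),
            "charge": "" if met.charge is None else str(met.charge),
            "mass": "" if met.mass is None else repr(met.mass),
            "is_generic": str(met.is_generic).lower(),
            "met_name": met.name,
        }
        s.setAnnotation(_kv_annotation(pairs))
    for rid in sorted(network.reactions):
        rxn = network.reactions[rid]
        r = model.createReaction()
        r.setId(f"R_{_sanitize_sid(rid)}")
        r.setReversible(rxn.reversible)
        r.setFast(False)
        for sid, coeff in sorted(rxn.stoichiometry.items()):
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(sid_of[sid])
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        pairs = {
            "reaction_id": rid,
            "lower_bound": repr(rxn.lower_bound),
            "upper_bound": repr(rxn.upper_bound),
            "rtype": rxn.rtype,
            "delta_g": "" if rxn.delta_g is None else repr(rxn.delta_g),
            "ec_numbers": ";".join(sorted(rxn.ec_numbers)),
        }
        r.setAnnotation(_kv_annotation(pairs))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise SBMLError(doc.getErrorLog().toString())
    libsbml.writeSBMLToFile(doc, str(path))


def import_sbml(path: str | Path) -> CompartmentalizedNetwork:
    """Read an SBML document produced by :func:`export_sbml`."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise SBMLError(doc.getErrorLog().toString())
    model = doc.getModel()
    if model is None:
        raise SBMLError(f"{path}: no model element")
    net = CompartmentalizedNetwork()
    species_of_sbml: dict[str, str] = {}
    for i in range(model.getNumSpecies()):
        s = model.getSpecies(i)
        kv = _read_kv_annotation(s)
        mid = kv.get("metabolite_id", s.getId())
        comp = kv.get("compartment", s.getCompartment().removeprefix("comp_"))
        if mid not in net.metabolites:
            net.add_metabolite(
                Metabolite(
                    id=mid,
                    name=kv.get("met_name", s.getName() or ""),
                    formula=parse_formula(kv.get("formula", "")),
                    charge=int(kv["charge"]) if kv.get("charge") else None,
                    mass=float(kv["mass"]) if kv.get("mass") else None,
                    is_generic=kv.get("is_generic", "false") == "true",
                )
            )
        spec = net.ensure_species(mid, comp)
        species_of_sbml[s.getId()] = spec.id
    for i in range(model.getNumReactions()):
        r = model.getReaction(i)
        kv = _read_kv_annotation(r)
        stoich: dict[str, float] = {}
        for k in range(r.getNumReactants()):
            ref = r.getReactant(k)
            sid = species_of_sbml[ref.getSpecies()]
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for k in range(r.getNumProducts()):
            ref = r.getProduct(k)
            sid = species_of_sbml[ref.getSpecies()]
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()
        lb = float(kv.get("lower_bound", REVERSIBLE_LOWER_BOUND if r.getReversible() else 0.0))
        ub = float(kv.get("upper_bound", DEFAULT_UPPER_BOUND))
        net.add_reaction(
            Reaction(
                id=kv.get("reaction_id", r.getId()),
                stoichiometry=stoich,
                reversible=lb < 0,
                lower_bound=lb,
                upper_bound=ub,
                delta_g=float(kv["delta_g"]) if kv.get("delta_g") else None,
                ec_numbers=frozenset(
                    ec for ec in kv.get("ec_numbers", "").split(";") if ec
                ),
                rtype=kv.get("rtype", "metabolic"),
            )
        )
    net.validate()
    net.log(f"import_sbml: {path}")
    return net


# ---------------------------------------------------------------------------
# flattening (non-compartmentalized view)
# ---------------------------------------------------------------------------


def flatten_network(network: CompartmentalizedNetwork) -> CompartmentalizedNetwork:
    """Collapse all inner compartments onto the cytoplasm.

    Species ``X@m``/``X@n``/``X@x``/``X@v``/``X@l`` become ``X@c``;
    extracellular species are kept so that environment exchange survives.
    Transport reactions between collapsed compartments become net-zero
    self-loops and are dropped; reaction copies that become stoichiometrically
    identical (duplicated pathways across compartments) are merged, keeping
    the lexicographically smallest id.
    """
    flat = CompartmentalizedNetwork()
    for met in network.metabolites.values():
        flat.add_metabolite(_copy.deepcopy(met))
    seen_stoich: dict[tuple, str] = {}
    for rid in sorted(network.reactions):
        r = network.reactions[rid]
        stoich: dict[str, float] = {}
        for sid, coeff in r.stoichiometry.items():
            spec = Species.from_id(sid)
            comp = "e" if spec.compartment == "e" else "c"
            nid = f"{spec.metabolite_id}@{comp}"
            stoich[nid] = stoich.get(nid, 0.0) + coeff
        stoich = {s: c for s, c in stoich.items() if abs(c) > COEFF_TOL}
        if not stoich:
            continue  # intra-cellular transport collapsed to a self-loop
        key = tuple(sorted((s, round(c, 9)) for s, c in stoich.items())) + (r.reversible,)
        if key in seen_stoich:
            continue  # duplicate pathway copy
        seen_stoich[key] = rid
        flat.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                reversible=r.reversible,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                delta_g=r.delta_g,
                ec_numbers=r.ec_numbers,
                rtype=infer_rtype(stoich, rid=rid),
            )
        )
    flat.log("flatten_network")
    return flat
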