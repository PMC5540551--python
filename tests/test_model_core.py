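import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_network, rxn
from metagem.model_core import (
    CompartmentalizedNetwork,
    Metabolite,
    NetworkError,
    Reaction,
    build_stoichiometric_matrix,
    export_sbml,
    flatten_network,
    format_equation,
    format_formula,
    import_sbml,
    parse_equation,
    parse_formula,
    read_network,
    write_network,
)


# ---------------------------------------------------------------------------
# formulas and equations
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("NaCl", {"Na": 1, "Cl": 1}),
        ("", None),
        ("-", None),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text) == expected


def test_parse_formula_rejects_garbage():
    with pytest.raises(NetworkError):
        parse_formula("C6H12O6)")


def test_format_formula_hill_order():
    assert format_formula({"O": 6, "C": 6, "H": 12}) == "C6H12O6"


@pytest.mark.parametrize(
    "eq,n_sub,n_prod,rev",
    [
        ("2 A@c + B@c <=> C@c", 2, 1, True),
        ("A@c => B@c", 1, 1, False),
        ("A@e <=>", 1, 0, True),
        ("5 h@c + 1 no2@c + 2 focytc@c = 2 ficytc@c + 1 h2o@c + 1 nh2oh@c", 3, 3, True),
        ("accoa@c < = = > accoa@m", 1, 1, True),
        ("oaa@c < = > oaa@m", 1, 1, True),
    ],
)
def test_parse_equation_dialects(eq, n_sub, n_prod, rev):
    stoich, reversible = parse_equation(eq)
    assert reversible is rev
    assert sum(1 for c in stoich.values() if c < 0) == n_sub
    assert sum(1 for c in stoich.values() if c > 0) == n_prod


def test_parse_equation_default_compartment():
    stoich, _ = parse_equation("glc => g6p", default_compartment="m")
    assert set(stoich) == {"glc@m", "g6p@m"}


def test_parse_equation_no_arrow():
    with pytest.raises(NetworkError):
        parse_equation("A@c + B@c")


@settings(derandomize=True, max_examples=60)
@given(
    subs=st.dictionaries(
        st.sampled_from(["a@c", "b@c", "c@m", "d@e"]),
        st.integers(1, 9),
        min_size=1,
        max_size=3,
    ),
    prods=st.dictionaries(
        st.sampled_from(["w@c", "x@c", "y@m", "z@e"]),
        st.integers(1, 9),
        min_size=1,
        max_size=3,
    ),
    rev=st.booleans(),
)
def test_equation_roundtrip(subs, prods, rev):
    stoich = {s: -float(v) for s, v in subs.items()}
    stoich.update({s: float(v) for s, v in prods.items()})
    r = rxn("R", stoich, reversible=rev)
    parsed, parsed_rev = parse_equation(format_equation(r))
    assert parsed_rev is rev
    assert parsed == pytest.approx(stoich)


# ---------------------------------------------------------------------------
# reaction invariants
# ---------------------------------------------------------------------------


def test_reaction_invariants():
    with pytest.raises(NetworkError):
        Reaction("empty", {})
    with pytest.raises(NetworkError):
        Reaction("badbounds", {"a@c": -1, "b@c": 1}, True, 10.0, 5.0)
    with pytest.raises(NetworkError):  # reversible <=> lb < 0
        Reaction("badrev", {"a@c": -1, "b@c": 1}, True, 0.0, 100.0)
    with pytest.raises(NetworkError):  # one-sided must be extracellular
        Reaction("sink", {"a@m": -1.0}, True, -1000.0, 100.0, rtype="exchange")


def test_rtype_inference():
    assert rxn("t", {"a@c": -1.0, "a@m": 1.0}).rtype == "transport"
    assert rxn("x", {"a@e": -1.0}).rtype == "exchange"
    assert rxn("m", {"a@c": -1.0, "b@c": 1.0}).rtype == "metabolic"
    with pytest.raises(NetworkError):  # declared type conflicts with structure
        Reaction("lie", {"a@c": -1.0, "b@c": 1.0}, True, -1000.0, 100.0, rtype="transport")


def test_metabolite_invariants():
    with pytest.raises(NetworkError):
        Metabolite("neg", mass=-1.0, formula={"C": 1})
    with pytest.raises(NetworkError):  # generic iff no formula
        Metabolite("g", formula=None, is_generic=False)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

MET_TSV = (
    "metabolite_id\tname\tformula\tcharge\tmass\tis_generic\n"
    "A\tcompound A\tC6H12O6\t0\t180.16\tfalse\n"
    "B\tcompound B\tC6H12O6\t0\t180.16\tfalse\n"
    "C\tcompound C\tC6H12O6\t0\t180.16\tfalse\n"
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_read_network_toy(tmp_path):
    rxn_tsv = (
        "reaction_id\tequation\tec_numbers\tdelta_g\trtype\n"
        "R1\tA@c => B@c\t1.1.1.1\t-12.5\tmetabolic\n"
        "R2\tB@c <=> C@c\t\t\t\n"
    )
    net = read_network(
        _write(tmp_path, "r.tsv", rxn_tsv), _write(tmp_path, "m.tsv", MET_TSV)
    )
    assert len(net.species) == 3
    assert len(net.reactions) == 2
    assert net.reactions["R1"].delta_g == -12.5
    assert net.reactions["R1"].ec_numbers == frozenset({"1.1.1.1"})
    assert net.reactions["R2"].reversible


def test_read_network_empty_reactions(tmp_path):
    rxn_tsv = "reaction_id\tequation\tec_numbers\tdelta_g\trtype\n"
    net = read_network(
        _write(tmp_path, "r.tsv", rxn_tsv), _write(tmp_path, "m.tsv", MET_TSV)
    )
    assert len(net.reactions) == 0


@pytest.mark.parametrize(
    "row,message",
    [
        ("R1\tA@c => Q@c\t\t\t\n", "undeclared metabolite"),
        ("R1\tA@c ++ B@c\t\t\t\n", "arrow"),
        ("R1\tA@c => B@c\t\t\t\nR1\tB@c => C@c\t\t\t\n", "duplicate"),
    ],
)
def test_read_network_errors(tmp_path, row, message):
    rxn_tsv = "reaction_id\tequation\tec_numbers\tdelta_g\trtype\n" + row
    with pytest.raises(NetworkError, match=message):
        read_network(
            _write(tmp_path, "r.tsv", rxn_tsv), _write(tmp_path, "m.tsv", MET_TSV)
        )


# ---------------------------------------------------------------------------
# stoichiometric matrix
# ---------------------------------------------------------------------------


def test_matrix_single_column():
    net = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [rxn("R", {"A@c": -1.0, "B@c": 1.0}, reversible=False)],
    )
    m = build_stoichiometric_matrix(net)
    assert m.row_index == ["A@c", "B@c"]
    assert m.dense().tolist() == [[-1.0], [1.0]]


def test_matrix_reversibility_lives_in_bounds():
    fwd = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [rxn("R", {"A@c": -1.0, "B@c": 1.0}, reversible=False)],
    )
    rev = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [rxn("R", {"A@c": -1.0, "B@c": 1.0}, reversible=True)],
    )
    assert (
        build_stoichiometric_matrix(fwd).dense().tolist()
        == build_stoichiometric_matrix(rev).dense().tolist()
    )


def test_matrix_roundtrip_through_tsv(tmp_path, rng):
    # random 20-metabolite / 30-reaction network: S after a write/read
    # round trip equals S built from the original reaction list
    from oracles import random_network

    net = random_network(5, max_reactions=30)
    write_network(net, tmp_path / "r.tsv", tmp_path / "m.tsv")
    back = read_network(tmp_path / "r.tsv", tmp_path / "m.tsv")
    m1 = build_stoichiometric_matrix(net)
    m2 = build_stoichiometric_matrix(back)
    assert m1.row_index == m2.row_index
    assert m1.col_index == m2.col_index
    assert np.allclose(m1.dense(), m2.dense())
    assert net.equal_to(back)


def test_matrix_columns_bijective(chain_network):
    m = build_stoichiometric_matrix(chain_network)
    assert m.col_index == sorted(chain_network.reactions)
    assert m.shape == (len(chain_network.species), len(chain_network.reactions))


# ---------------------------------------------------------------------------
# SBML round trip
# ---------------------------------------------------------------------------


def test_sbml_roundtrip_toy(tmp_path, chain_network):
    path = tmp_path / "model.sbml"
    export_sbml(chain_network, path)
    back = import_sbml(path)
    assert chain_network.equal_to(back)


def test_sbml_five_compartments(tmp_path):
    mets = [(f"x{i}", {"C": 1}, 0) for i in range(5)]
    reactions = [
        rxn("T1", {"x0@e": -1.0, "x0@c": 1.0}),
        rxn("T2", {"x1@c": -1.0, "x1@m": 1.0}),
        rxn("T3", {"x2@c": -1.0, "x2@n": 1.0}),
        rxn("T4", {"x3@c": -1.0, "x3@x": 1.0}),
        rxn("R", {"x0@c": -1.0, "x4@c": 1.0}),
    ]
    net = make_network(mets, reactions)
    path = tmp_path / "five.sbml"
    export_sbml(net, path)
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    assert doc.getModel().getNumCompartments() == 5
    assert import_sbml(path).equal_to(net)


def test_sbml_bounds_survive(tmp_path):
    net = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [rxn("R", {"A@c": -1.0, "B@c": 1.0}, reversible=True, lb=-1000.0, ub=100.0)],
    )
    path = tmp_path / "b.sbml"
    export_sbml(net, path)
    r = import_sbml(path).reactions["R"]
    assert (r.lower_bound, r.upper_bound) == (-1000.0, 100.0)


# ---------------------------------------------------------------------------
# flattening
# ---------------------------------------------------------------------------


def test_flatten_drops_transport_and_merges_duplicates():
    net = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [
            rxn("AB@c", {"A@c": -1.0, "B@c": 1.0}),
            rxn("AB@m", {"A@m": -1.0, "B@m": 1.0}),
            rxn("T_A", {"A@c": -1.0, "A@m": 1.0}),
            rxn("T_B_e", {"B@c": -1.0, "B@e": 1.0}),
        ],
    )
    flat = flatten_network(net)
    assert set(flat.reactions) == {"AB@c", "T_B_e"}
    assert {s for s in flat.species} == {"A@c", "B@c", "B@e"}
    assert flat.metabolite_ids() <= net.metabolite_ids()
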