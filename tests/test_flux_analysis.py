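import numpy as np
import pytest

from conftest import make_network, rxn
from oracles import dense_arrays, lp_max_by_vertex_enumeration, random_network
from metagem.flux_analysis import (
    BoundPolicy,
    ObjectiveFunction,
    active_flux_fraction,
    build_problem,
    exclude_reactions,
    instantiate_objective,
    objective_library,
    solve,
    steady_state_residual,
)
from metagem.synthetic_data import toy_fatty_acid_model, toy_tca_model
from metagem.model_core import flatten_network


def _chain():
    """uptake (<= 10) -> A -> B -> export."""
    return make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [
            rxn("EX_A", {"A@e": -1.0}, reversible=True, lb=-10.0),
            rxn("T_A", {"A@e": -1.0, "A@c": 1.0}),
            rxn("AB", {"A@c": -1.0, "B@c": 1.0}, reversible=False),
            rxn("T_B", {"B@c": -1.0, "B@e": 1.0}),
            rxn("EX_B", {"B@e": -1.0}, reversible=False),
        ],
    )


def test_chain_optimum_limited_by_uptake():
    net = _chain()
    problem = build_problem(net, ObjectiveFunction.for_reactions("export", ["EX_B"]))
    result = solve(problem)
    assert result.status == "optimal"
    assert result.Z == pytest.approx(10.0)
    assert steady_state_residual(problem, result) < 1e-6


def test_unreachable_objective_is_zero():
    net = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0), ("Q", {"C": 1}, 0), ("W", {"C": 1}, 0)],
        [
            rxn("EX_A", {"A@e": -1.0}),
            rxn("T_A", {"A@e": -1.0, "A@c": 1.0}),
            rxn("QW", {"Q@c": -1.0, "W@c": 1.0}, reversible=False),
        ],
    )
    result = solve(build_problem(net, ObjectiveFunction.for_reactions("o", ["QW"])))
    assert result.Z == pytest.approx(0.0)


def test_build_problem_policy_and_override():
    net = _chain()
    obj = ObjectiveFunction.for_reactions("export", ["EX_B"])
    p = build_problem(net, obj, BoundPolicy())
    j_rev = p.matrix.col("T_A")
    j_irr = p.matrix.col("AB")
    assert (p.lower[j_rev], p.upper[j_rev]) == (-1000.0, 100.0)
    assert (p.lower[j_irr], p.upper[j_irr]) == (0.0, 100.0)
    p2 = build_problem(net, obj, BoundPolicy(upper=1000.0))
    assert p2.upper.max() == 1000.0


def test_build_problem_rejects_absent_objective():
    with pytest.raises(KeyError):
        build_problem(_chain(), ObjectiveFunction.for_reactions("o", ["NOPE"]))


def test_exclude_reactions():
    net = _chain()
    problem = build_problem(net, ObjectiveFunction.for_reactions("export", ["EX_B"]))
    starved = exclude_reactions(problem, ["EX_A"])
    assert solve(starved).Z == pytest.approx(0.0)
    with pytest.raises(KeyError):
        exclude_reactions(problem, ["NOPE"])


def test_exclude_inactive_reaction_leaves_optimum():
    net = _chain()
    net.add_reaction(rxn("AB2", {"A@c": -1.0, "B@c": 1.0}, reversible=False))
    problem = build_problem(net, ObjectiveFunction.for_reactions("export", ["EX_B"]))
    base = solve(problem, stabilize=True)
    inactive = [
        r for r in ("AB", "AB2") if abs(base.fluxes[r]) < 1e-9
    ]
    if inactive:  # under degeneracy the stabilized solution picks one route
        assert solve(exclude_reactions(problem, inactive[:1])).Z == pytest.approx(base.Z)


# ---------------------------------------------------------------------------
# oracle equality and LP properties
# ---------------------------------------------------------------------------


def test_lp_matches_vertex_enumeration_on_small_fixtures():
    for seed in range(12):
        net = random_network(seed, max_reactions=9)
        while len(net.reactions) > 8:
            net.remove_reactions([sorted(net.reactions)[-1]])
        species, cols, S, lb, ub = dense_arrays(net)
        if not cols:
            continue
        obj = ObjectiveFunction.for_reactions("o", [cols[0]])
        problem = build_problem(net, obj)
        result = solve(problem)
        assert result.status == "optimal"
        c = np.zeros(len(cols))
        c[0] = 1.0
        brute = lp_max_by_vertex_enumeration(S, lb, ub, c)
        assert brute is not None
        assert result.Z == pytest.approx(brute, abs=1e-6)
        assert steady_state_residual(problem, result) < 1e-6


def test_tightening_bounds_never_increases_Z():
    net = _chain()
    obj = ObjectiveFunction.for_reactions("export", ["EX_B"])
    problem = build_problem(net, obj)
    z0 = solve(problem).Z
    for rid in net.reactions:
        tightened = exclude_reactions(problem, [rid])
        z = solve(tightened).Z
        if z is not None:
            assert z <= z0 + 1e-9


# ---------------------------------------------------------------------------
# active-flux fractions
# ---------------------------------------------------------------------------


def test_active_fraction_examples():
    net = _chain()
    problem = build_problem(net, ObjectiveFunction.for_reactions("export", ["EX_B"]))
    result = solve(problem)
    fractions = active_flux_fraction(
        result,
        {
            "all_active": ["EX_A", "T_A", "AB", "T_B"],
            "empty": [],
        },
    )
    assert fractions["all_active"] == pytest.approx(100.0)
    assert fractions["empty"] is None


def test_active_fraction_four_of_nine():
    # a 9-reaction scope with 4 active reactions reports 44.44%
    fluxes = {f"r{i}": (1.0 if i < 4 else 0.0) for i in range(9)}
    from metagem.flux_analysis import FluxResult

    result = FluxResult(Z=1.0, fluxes=fluxes, status="optimal")
    out = active_flux_fraction(result, {"denitrification": sorted(fluxes)})
    assert out["denitrification"] == pytest.approx(44.44, abs=0.01)


def test_zero_flux_solution_all_scopes_zero():
    net = make_network(
        [("Q", {"C": 1}, 0), ("W", {"C": 1}, 0)],
        [rxn("QW", {"Q@c": -1.0, "W@c": 1.0}, reversible=False)],
    )
    result = solve(build_problem(net, ObjectiveFunction.for_reactions("o", ["QW"])))
    out = active_flux_fraction(result, {"s": ["QW"]})
    assert out["s"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# objective library
# ---------------------------------------------------------------------------


def test_library_block_sizes():
    lib = objective_library()
    assert len(lib["nitrogen_cycle"].templates) == 4
    tca = lib["tca_cycle"].templates
    assert len(tca) == 7
    cross = [t for t in tca if "@m" in t.equation and "@c" in t.equation]
    assert len(cross) == 3


def test_library_unresolved_templates_reported():
    net = _chain()  # has none of the nitrogen-cycle species
    obj, unresolved = instantiate_objective(net, objective_library()["nitrogen_cycle"])
    assert obj is None
    assert set(unresolved) == {"NFIX", "HAO", "NIR", "NOR"}


def test_electron_acceptor_is_remappable():
    lib = objective_library(electron_acceptor="acceptor_x")
    assert any("acceptor_x" in t.equation for t in lib["nitrogen_cycle"].templates)


# ---------------------------------------------------------------------------
# compartment coupling (toy models)
# ---------------------------------------------------------------------------


def test_fatty_acid_transport_knockout_zeroes_objective():
    net = toy_fatty_acid_model()
    obj, unresolved = instantiate_objective(
        net, objective_library()["fatty_acid_elongation"]
    )
    assert unresolved == []
    problem = build_problem(net, obj)
    assert solve(problem).Z > 0
    assert solve(exclude_reactions(problem, ["T_accoa_cm"])).Z == pytest.approx(0.0)


def test_tca_coupling_ordering():
    net = toy_tca_model()
    lib = objective_library()
    obj, _ = instantiate_objective(net, lib["tca_cycle"])
    problem = build_problem(net, obj)
    z_with = solve(problem).Z
    z_without = solve(
        exclude_reactions(problem, ["T_oaa_cm", "T_accoa_cm", "T_akg_cm"])
    ).Z
    flat = flatten_network(net)
    obj_flat, unresolved = instantiate_objective(flat, lib["tca_cycle"])
    assert set(unresolved) == {"T_oaa_cm", "T_accoa_cm", "T_akg_cm"}
    z_flat = solve(build_problem(flat, obj_flat)).Z
    assert z_with > z_without > z_flat > 0


def test_fba_against_cobra():
    """Independent implementation check: the same chain model solved by
    cobrapy gives the same optimum."""
    cobra = pytest.importorskip("cobra")
    net = _chain()
    model = cobra.Model("chain")
    mets = {
        sid: cobra.Metabolite(sid.replace("@", "_"), compartment=sid.split("@")[1])
        for sid in net.species
    }
    for rid, r in net.reactions.items():
        reaction = cobra.Reaction(rid)
        reaction.lower_bound = r.lower_bound
        reaction.upper_bound = r.upper_bound
        model.add_reactions([reaction])
        reaction.add_metabolites(
            {mets[sid]: coeff for sid, coeff in r.stoichiometry.items()}
        )
    model.objective = "EX_B"
    sol = model.optimize()
    ours = solve(build_problem(net, ObjectiveFunction.for_reactions("o", ["EX_B"])))
    assert ours.Z == pytest.approx(sol.objective_value, abs=1e-6)


def test_objective_template_file(tmp_path):
    from metagem.flux_analysis import write_objective_templates
    from metagem.model_core import parse_equation

    path = tmp_path / "objectives.txt"
    write_objective_templates(path)
    text = path.read_text()
    assert "# nitrogen_cycle" in text
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rid, equation = line.split("\t")
        parse_equation(equation)  # every template is in the standard dialect
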