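import pytest

from conftest import make_network, rxn
from oracles import gap_oracle
from metagem.curation import (
    GapConfig,
    GapReport,
    curate_compartmentalized,
    gapfill,
    gapfill_batch,
    gapfind,
    reconnection_percentage,
)


# ---------------------------------------------------------------------------
# GapFind
# ---------------------------------------------------------------------------


def test_chain_no_outlet_flags_terminal_species(chain_network):
    report = gapfind(chain_network)
    assert "C@c" in report.non_consumed
    assert "C@c" not in report.non_produced  # producible via the chain
    assert "A@c" not in report.non_produced  # fed from the exchange


def test_chain_without_inlet_flags_source():
    net = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0), ("C", {"C": 1}, 0)],
        [
            rxn("AB", {"A@c": -1.0, "B@c": 1.0}, reversible=False),
            rxn("BC", {"B@c": -1.0, "C@c": 1.0}, reversible=False),
        ],
    )
    report = gapfind(net)
    assert "A@c" in report.non_produced
    assert "C@c" in report.non_consumed


def test_cycle_with_boundary_has_no_gaps(cycle_network):
    report = gapfind(cycle_network)
    assert report.non_produced == set()
    assert report.non_consumed == set()


def test_gapfind_matches_lp_oracle_battery():
    """MILP dead-end sets equal the per-pair LP enumeration oracle on a
    battery of small random networks (the full 100-network battery runs in
    the acceptance suite)."""
    from oracles import random_network

    cfg = GapConfig()
    for seed in range(15):
        net = random_network(seed)
        report = gapfind(net, cfg)
        non_p, non_c = gap_oracle(net, cfg.eps)
        assert report.non_produced == non_p, f"seed {seed}"
        assert report.non_consumed == non_c, f"seed {seed}"


def test_gapfind_compartment_bookkeeping():
    net = make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [
            rxn("AB@c", {"A@c": -1.0, "B@c": 1.0}, reversible=False),
            rxn("AB@m", {"A@m": -1.0, "B@m": 1.0}, reversible=False),
        ],
    )
    report = gapfind(net)
    # A is non-produced and B non-consumed in both compartments
    assert report.per_compartment_counts["c"]["problem"] == 2
    assert report.per_compartment_counts["m"]["problem"] == 2
    assert report.common_gaps[("c", "m")] == 2


# ---------------------------------------------------------------------------
# GapFill
# ---------------------------------------------------------------------------


def _gap_net():
    """A -> B producible; C isolated except through candidate reactions."""
    return make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0), ("C", {"C": 1}, 0), ("D", {"C": 1}, 0)],
        [
            rxn("EX_A", {"A@e": -1.0}),
            rxn("T_A", {"A@e": -1.0, "A@c": 1.0}),
            rxn("AB", {"A@c": -1.0, "B@c": 1.0}, reversible=False),
            # export-only routes: C stays non-producible until a fill arrives
            rxn("T_C", {"C@c": -1.0, "C@e": 1.0}, reversible=False),
            rxn("EX_C", {"C@e": -1.0}, reversible=False),
        ],
    )


def test_gapfill_adds_exactly_the_missing_reaction():
    net = _gap_net()
    db = [rxn("BC", {"B@c": -1.0, "C@c": 1.0})]
    (sol,) = gapfill(net, ["C@c"], db)
    assert sol.feasible
    assert sol.added_reaction_ids == ["BC"]


def test_gapfill_prefers_shorter_route():
    net = _gap_net()
    db = [
        rxn("AC", {"A@c": -1.0, "C@c": 1.0}),  # length-1 route
        rxn("AD", {"A@c": -1.0, "D@c": 1.0}),  # length-2 route, part 1
        rxn("DC", {"D@c": -1.0, "C@c": 1.0}),  # length-2 route, part 2
    ]
    (sol,) = gapfill(net, ["C@c"], db)
    assert sol.feasible
    assert sol.n_added == 1
    assert sol.added_reaction_ids == ["AC"]


def test_gapfill_empty_db_all_infeasible():
    net = _gap_net()
    solutions = gapfill(net, ["C@c", "D@c"], [])
    assert [s.feasible for s in solutions] == [False, False]
    assert [s.target_species for s in solutions] == ["C@c", "D@c"]


def test_gapfill_batch_never_sacrifices_a_target():
    net = _gap_net()
    db = [
        rxn("AC", {"A@c": -1.0, "C@c": 1.0}),
        rxn("BD", {"B@c": -1.0, "D@c": 1.0}),
        rxn("T_D", {"D@c": -1.0, "D@e": 1.0}, reversible=False),
        rxn("EX_D", {"D@e": -1.0}, reversible=False),
    ]
    added, resolved = gapfill_batch(net, ["C@c", "D@c"], db)
    assert resolved == {"C@c": True, "D@c": True}
    assert set(added) == {"AC", "BD", "EX_D", "T_D"}


# ---------------------------------------------------------------------------
# three-step compartmentalized curation
# ---------------------------------------------------------------------------


def test_exchange_step_alone_resolves_shared_inner_gap():
    """Mitochondrial X is dead but cytosolic X is fine: a single
    cytoplasm<->mitochondrion exchange fixes it (step 2)."""
    net = make_network(
        [("X", {"C": 1}, 0), ("Y", {"C": 1}, 0)],
        [
            rxn("EX_X", {"X@e": -1.0}),
            rxn("T_X", {"X@e": -1.0, "X@c": 1.0}),
            rxn("XY@m", {"X@m": -1.0, "Y@m": 1.0}, reversible=False),
            rxn("T_Y", {"Y@m": -1.0, "Y@e": 1.0}),
            rxn("EX_Y", {"Y@e": -1.0}),
        ],
    )
    before = gapfind(net)
    assert "X@m" in before.non_produced
    curated, stats = curate_compartmentalized(net, candidate_db=[])
    assert stats.added_by_step["cytoplasm"] == []
    assert stats.added_by_step["exchanges"] == ["XCH_X_c_m"]
    after = gapfind(curated)
    assert "X@m" not in after.non_produced


def test_consistent_network_needs_no_additions(cycle_network):
    curated, stats = curate_compartmentalized(cycle_network, candidate_db=[])
    assert stats.total_added == 0
    assert stats.per_compartment_before == stats.per_compartment_after


def test_common_gap_counting_between_cytoplasm_and_mitochondrion():
    mets = [(f"g{i}", {"C": 1}, 0) for i in range(5)] + [("s", {"C": 1}, 0)]
    reactions = []
    for comp in ("c", "m"):
        for i in range(5):
            # g_i is consumed but never produced, in both compartments
            reactions.append(
                rxn(f"R{i}@{comp}", {f"g{i}@{comp}": -1.0, f"s@{comp}": 1.0}, reversible=False)
            )
    net = make_network(mets, reactions)
    report = gapfind(net)
    assert report.common_gaps[("c", "m")] >= 5
    problem_mets_c = {
        s for s in report.problem_species() if s.endswith("@c") and s.startswith("g")
    }
    assert len(problem_mets_c) == 5


# ---------------------------------------------------------------------------
# reconnection percentages
# ---------------------------------------------------------------------------


def test_reconnection_percentage_example():
    mets = [(f"x{i}", {"C": 1}, 0) for i in range(10)]
    reactions = [
        rxn(f"R{i}", {f"x{i}@c": -1.0, f"x{(i + 1) % 10}@c": 1.0}) for i in range(10)
    ]
    net = make_network(mets, reactions)
    universe = set(net.species)
    before = GapReport(non_produced={"x0@c", "x1@c", "x2@c", "x3@c"})
    after = GapReport(non_produced={"x0@c"})
    stats = reconnection_percentage(before, after, net)
    assert stats.per_compartment_before["c"] == pytest.approx(60.0)
    assert stats.per_compartment_after["c"] == pytest.approx(90.0)
    assert universe == set(net.species)


def test_reconnection_percentage_empty_compartment_is_na(cycle_network):
    stats = reconnection_percentage(GapReport(), GapReport(), cycle_network)
    assert "m" not in stats.per_compartment_before  # absent compartment: no row
    assert stats.per_compartment_before["c"] == 100.0
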