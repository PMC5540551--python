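import numpy as np
import pytest

from conftest import make_network, rxn
from metagem.model_core import build_stoichiometric_matrix, flatten_network, Species
from metagem.network_topology import (
    DegreeDistribution,
    build_metabolite_graph,
    degree_distributions,
    fit_power_law,
    rank_central_metabolites,
    topology_summary,
)


def _net(reactions, n_mets=8):
    mets = [(f"v{i}", {"C": 1}, 0) for i in range(n_mets)]
    return make_network(mets, reactions)


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def test_multi_substrate_edges():
    net = _net([rxn("R", {"v0@c": -1.0, "v1@c": -1.0, "v2@c": 1.0}, reversible=False)])
    g = build_metabolite_graph(net)
    assert set(g.edges()) == {("v0@c", "v2@c"), ("v1@c", "v2@c")}


def test_reversible_adds_both_directions():
    net = _net([rxn("R", {"v0@c": -1.0, "v1@c": 1.0}, reversible=True)])
    g = build_metabolite_graph(net)
    assert set(g.edges()) == {("v0@c", "v1@c"), ("v1@c", "v0@c")}


def test_exchange_contributes_no_edge():
    net = _net([rxn("EX", {"v0@e": -1.0})])
    g = build_metabolite_graph(net)
    assert g.number_of_edges() == 0
    assert g.number_of_nodes() == 1  # the species itself is still a node


def test_node_count_equals_species_count():
    net = _net(
        [
            rxn("R1", {"v0@c": -1.0, "v1@c": 1.0}),
            rxn("T", {"v1@c": -1.0, "v1@m": 1.0}),
        ]
    )
    g = build_metabolite_graph(net)
    assert g.number_of_nodes() == len(net.species)


# ---------------------------------------------------------------------------
# degree distributions and power-law fits
# ---------------------------------------------------------------------------


def test_cycle_degrees():
    net = _net(
        [
            rxn(f"R{i}", {f"v{i}@c": -1.0, f"v{(i + 1) % 3}@c": 1.0}, reversible=False)
            for i in range(3)
        ],
        n_mets=3,
    )
    din, dout = degree_distributions(build_metabolite_graph(net))
    assert din.k.tolist() == [1] and din.pk.tolist() == [1.0]
    assert dout.k.tolist() == [1] and dout.pk.tolist() == [1.0]


def test_star_out_degrees():
    net = _net(
        [rxn(f"R{i}", {"v0@c": -1.0, f"v{i}@c": 1.0}, reversible=False) for i in range(1, 6)],
        n_mets=6,
    )
    _, dout = degree_distributions(build_metabolite_graph(net))
    assert dout.k.tolist() == [5]  # only positive out-degrees are tabulated
    assert dout.counts.tolist() == [1]


def test_fit_exact_inverse_square_histogram():
    k = np.arange(1, 201)
    weights = k**-2.0
    counts = np.round(weights / weights.sum() * 1_000_000).astype(int)
    counts[counts == 0] = 1
    dist = DegreeDistribution(k=k, pk=counts / counts.sum(), counts=counts)
    fit = fit_power_law(dist, k_min=1)
    assert fit.gamma == pytest.approx(2.0, abs=0.05)
    assert fit.gamma_regression == pytest.approx(2.0, abs=0.1)


def test_fit_uniform_degrees_flagged_poor():
    dist = DegreeDistribution(
        k=np.array([4, 5, 6]),
        pk=np.array([1 / 3, 1 / 3, 1 / 3]),
        counts=np.array([10, 10, 10]),
    )
    fit = fit_power_law(dist, k_min=1)
    assert fit.poor_fit


def test_fit_degenerate_support_raises():
    dist = DegreeDistribution(
        k=np.array([1, 2]), pk=np.array([0.5, 0.5]), counts=np.array([5, 5])
    )
    with pytest.raises(ValueError):
        fit_power_law(dist, k_min=1)


def test_planted_exponent_recovered():
    from metagem.synthetic_data import PRESETS, generate_network

    cfg = PRESETS["exponent-recovery"].model_copy(update={"seed": 77})
    net, truth = generate_network(cfg)
    din, dout = degree_distributions(build_metabolite_graph(net))
    assert fit_power_law(din, k_min=None).gamma == pytest.approx(truth.gamma_in, abs=0.2)
    assert fit_power_law(dout, k_min=None).gamma == pytest.approx(truth.gamma_out, abs=0.2)


# ---------------------------------------------------------------------------
# global metrics
# ---------------------------------------------------------------------------


def test_triangle_metrics():
    net = _net(
        [
            rxn("R1", {"v0@c": -1.0, "v1@c": 1.0}),
            rxn("R2", {"v1@c": -1.0, "v2@c": 1.0}),
            rxn("R3", {"v2@c": -1.0, "v0@c": 1.0}),
        ],
        n_mets=3,
    )
    s = topology_summary(build_metabolite_graph(net))
    assert s.clustering_coefficient == pytest.approx(1.0)
    assert s.network_diameter == 1
    assert s.network_radius == 1
    assert s.node_count == 3


def test_path_metrics():
    net = _net(
        [
            rxn("R1", {"v0@c": -1.0, "v1@c": 1.0}, reversible=False),
            rxn("R2", {"v1@c": -1.0, "v2@c": 1.0}, reversible=False),
        ],
        n_mets=3,
    )
    s = topology_summary(build_metabolite_graph(net))
    # reachable ordered pairs: 0->1 (1), 1->2 (1), 0->2 (2)
    assert s.characteristic_path_length == pytest.approx(4 / 3)
    assert s.network_diameter == 2


def test_erdos_renyi_against_igraph(rng):
    igraph = pytest.importorskip("igraph")
    import networkx as nx

    g_nx = nx.gnp_random_graph(60, 0.08, seed=7, directed=True)
    g = nx.MultiDiGraph(g_nx)
    s = topology_summary(g)
    ig = igraph.Graph(directed=True)
    ig.add_vertices(60)
    ig.add_edges(list(g_nx.edges()))
    assert s.characteristic_path_length == pytest.approx(
        ig.average_path_length(directed=True, unconn=True), abs=1e-9
    )
    assert s.network_diameter == ig.diameter(directed=True, unconn=True)
    local = [
        c
        for v, c in enumerate(ig.transitivity_local_undirected(mode="nan"))
        if not np.isnan(c)
    ]
    assert s.clustering_coefficient == pytest.approx(float(np.mean(local)), abs=1e-9)


# ---------------------------------------------------------------------------
# centrality ranking
# ---------------------------------------------------------------------------


def _hub_net():
    # hub v0 feeds five spokes and receives from three others
    reactions = [
        rxn(f"O{i}", {"v0@c": -1.0, f"v{i}@c": 1.0}, reversible=False) for i in range(1, 6)
    ] + [
        rxn(f"I{i}", {f"v{i}@c": -1.0, "v0@c": 1.0}, reversible=False) for i in range(6, 8)
    ]
    return _net(reactions)


def test_hub_ranks_first():
    net = _hub_net()
    df = rank_central_metabolites(
        build_metabolite_graph(net), build_stoichiometric_matrix(net)
    )
    assert df.iloc[0]["species"] == "v0@c"


def test_currency_hub_in_top_ranking():
    from metagem.synthetic_data import GeneratorConfig, generate_network

    net, truth = generate_network(
        GeneratorConfig(seed=6, n_metabolites=60, n_reactions=250)
    )
    df = rank_central_metabolites(
        build_metabolite_graph(net), build_stoichiometric_matrix(net)
    )
    top10 = {Species.from_id(s).metabolite_id for s in df.head(10)["species"]}
    assert top10 & set(truth.carrier_ids), "currency carriers should rank as hubs"


def test_ranking_order_invariance():
    net = _hub_net()
    df1 = rank_central_metabolites(
        build_metabolite_graph(net), build_stoichiometric_matrix(net)
    )
    # rebuild the same network with reactions inserted in reverse order
    net2 = _net(
        [net.reactions[rid] for rid in sorted(net.reactions, reverse=True)]
    )
    df2 = rank_central_metabolites(
        build_metabolite_graph(net2), build_stoichiometric_matrix(net2)
    )
    assert df1["species"].tolist() == df2["species"].tolist()


def test_flatten_graph_is_quotient():
    from metagem.synthetic_data import toy_tca_model

    net = toy_tca_model()
    flat = flatten_network(net)
    g = build_metabolite_graph(net)
    g_flat = build_metabolite_graph(flat)

    def strip(sid):
        spec = Species.from_id(sid)
        comp = "e" if spec.compartment == "e" else "c"
        return f"{spec.metabolite_id}@{comp}"

    quotient_edges = {
        (strip(a), strip(b)) for a, b in g.edges() if strip(a) != strip(b)
    }
    assert set(g_flat.edges()) <= quotient_edges


def test_graph_exports(tmp_path):
    net = _net(
        [
            rxn("R1", {"v0@c": -1.0, "v1@c": 1.0}, reversible=False),
            rxn("R2", {"v1@c": -1.0, "v2@c": 1.0}),
        ],
        n_mets=3,
    )
    from metagem.network_topology import write_edge_list, write_graphml

    g = build_metabolite_graph(net)
    write_edge_list(g, tmp_path / "edges.tsv")
    lines = (tmp_path / "edges.tsv").read_text().splitlines()
    assert lines[0] == "source\ttarget\treaction"
    assert len(lines) == 1 + g.number_of_edges()
    write_graphml(g, tmp_path / "g.graphml")
    import networkx as nx

    back = nx.read_graphml(tmp_path / "g.graphml")
    assert back.number_of_edges() == g.number_of_edges()
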