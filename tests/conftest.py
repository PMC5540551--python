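import numpy as np
import pytest

from metagem.model_core import (
    CompartmentalizedNetwork,
    Metabolite,
    Reaction,
)


def make_network(metabolites, reactions) -> CompartmentalizedNetwork:
    """Build a network from (id, formula, charge) triples and Reaction kwargs."""
    net = CompartmentalizedNetwork()
    for spec in metabolites:
        if isinstance(spec, Metabolite):
            net.add_metabolite(spec)
        else:
            mid, formula, charge = spec
            net.add_metabolite(Metabolite(mid, mid, formula, charge, None, formula is None))
    for rxn in reactions:
        net.add_reaction(rxn if isinstance(rxn, Reaction) else Reaction(**rxn))
    net.validate()
    return net


def rxn(rid, stoich, reversible=True, lb=None, ub=100.0, rtype=None, **kw) -> Reaction:
    from metagem.model_core import infer_rtype

    if lb is None:
        lb = -1000.0 if reversible else 0.0
    return Reaction(
        id=rid,
        stoichiometry=stoich,
        reversible=reversible,
        lower_bound=lb,
        upper_bound=ub,
        rtype=rtype or infer_rtype(stoich, rid=rid),
        **kw,
    )


@pytest.fixture
def chain_network():
    """e -> A -> B -> C, no outlet for C (C should be non-consumed)."""
    return make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0), ("C", {"C": 1}, 0)],
        [
            rxn("EX_A", {"A@e": -1.0}),
            rxn("T_A", {"A@e": -1.0, "A@c": 1.0}),
            rxn("AB", {"A@c": -1.0, "B@c": 1.0}, reversible=False),
            rxn("BC", {"B@c": -1.0, "C@c": 1.0}, reversible=False),
        ],
    )


@pytest.fixture
def cycle_network():
    """Connected cycle with exchange in and out: no dead ends."""
    return make_network(
        [("A", {"C": 1}, 0), ("B", {"C": 1}, 0)],
        [
            rxn("EX_A", {"A@e": -1.0}),
            rxn("T_A", {"A@e": -1.0, "A@c": 1.0}),
            rxn("AB", {"A@c": -1.0, "B@c": 1.0}),
            rxn("T_B", {"B@c": -1.0, "B@e": 1.0}),
            rxn("EX_B", {"B@e": -1.0}),
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
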