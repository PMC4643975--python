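"""Shared fixtures: programmatically generated toy models.

All fixtures are built at test time from the synthetic generator or by
direct construction — no data files are read.
"""

from __future__ import annotations

import pytest

from gemscreen import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyModelSpec,
    generate_toy_model,
    parse_gpr,
)

DEFAULT_SPEC = ToyModelSpec(seed=1)

# 12 genes: 9 pathway steps, 2 complex steps (+2 genes), 1 isozyme step
# (+1 gene); small enough for an exhaustive double-deletion oracle.
SMALL_SPEC = ToyModelSpec(
    n_linear_pathways=3,
    pathway_length=3,
    n_isozyme_pairs=1,
    n_complexes=2,
    n_parallel_routes=1,
    n_dead_ends=1,
    n_blocked=1,
    seed=5,
)


@pytest.fixture(scope="session")
def toy():
    """Default-scale toy model with planted truth (~60 genes)."""
    return generate_toy_model(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def small_toy():
    """12-gene toy model for exhaustive pairwise oracles."""
    return generate_toy_model(SMALL_SPEC)


@pytest.fixture(scope="session")
def toy_screens(toy):
    """Single + double screens of the default toy, shared read-only."""
    from gemscreen import double_deletion_screen, single_deletion_screen

    model, _ = toy
    singles = single_deletion_screen(model)
    doubles = double_deletion_screen(model)
    doubles.singles = singles
    return singles, doubles


def build_chain_model(ex_lb: float = -10.0, mid_ub: float = 5.0) -> MetabolicModel:
    """Linear chain EX_A -> A -> B -> biomass with a bottleneck on A->B."""
    return MetabolicModel(
        model_id="chain",
        metabolites={
            "A": Metabolite(id="A", compartment="c"),
            "B": Metabolite(id="B", compartment="c"),
        },
        reactions={
            "EX_A": Reaction(
                id="EX_A", stoichiometry={"A": -1.0},
                lower_bound=ex_lb, upper_bound=1000.0,
            ),
            "AtoB": Reaction(
                id="AtoB", stoichiometry={"A": -1.0, "B": 1.0},
                lower_bound=0.0, upper_bound=mid_ub,
                gpr=parse_gpr("G1"),
            ),
            "biomass": Reaction(
                id="biomass", stoichiometry={"B": -1.0},
                lower_bound=0.0, upper_bound=1000.0,
            ),
        },
        genes={"G1"},
        objective_reaction_id="biomass",
    )


def build_branched_model() -> MetabolicModel:
    """8-reaction branched network for the vertex-enumeration oracle.

    A is taken up (<= 6), split to B and C (capacities 8 and 4), with a
    B<->C shuttle; biomass consumes B and C 1:1, so the optimum balances
    the branches at 3.0.
    """
    mets = {m: Metabolite(id=m, compartment="c") for m in "ABC"}
    rxns = {
        "EX_A": Reaction(id="EX_A", stoichiometry={"A": -1.0},
                         lower_bound=-6.0, upper_bound=0.0),
        "AtoB": Reaction(id="AtoB", stoichiometry={"A": -1.0, "B": 1.0},
                         lower_bound=0.0, upper_bound=8.0),
        "AtoC": Reaction(id="AtoC", stoichiometry={"A": -1.0, "C": 1.0},
                         lower_bound=0.0, upper_bound=4.0),
        "BtoC": Reaction(id="BtoC", stoichiometry={"B": -1.0, "C": 1.0},
                         lower_bound=0.0, upper_bound=10.0),
        "CtoB": Reaction(id="CtoB", stoichiometry={"C": -1.0, "B": 1.0},
                         lower_bound=0.0, upper_bound=3.0),
        "EX_B": Reaction(id="EX_B", stoichiometry={"B": -1.0},
                         lower_bound=0.0, upper_bound=1000.0),
        "EX_C": Reaction(id="EX_C", stoichiometry={"C": -1.0},
                         lower_bound=0.0, upper_bound=1000.0),
        "biomass": Reaction(id="biomass",
                            stoichiometry={"B": -1.0, "C": -1.0},
                            lower_bound=0.0, upper_bound=1000.0),
    }
    return MetabolicModel(
        model_id="branched", metabolites=mets, reactions=rxns,
        genes=set(), objective_reaction_id="biomass",
    )


@pytest.fixture()
def chain_model():
    return build_chain_model()


@pytest.fixture()
def branched_model():
    return build_branched_model()
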