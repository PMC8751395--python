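import numpy as np
import pytest

from rhizoflux import Metabolite, MetabolicModel, Reaction


def linear_chain_model(uptake: float = 10.0, yield_: float = 1.0):
    """EX_A -> A -> B -> biomass; unique optimal flux vector."""
    return MetabolicModel(
        id="chain",
        metabolites=[
            Metabolite("A_e", compartment="e0"),
            Metabolite("A_c", compartment="c0"),
            Metabolite("B_c", compartment="c0"),
        ],
        reactions=[
            Reaction(id="EX_A", stoichiometry={"A_e": -1.0},
                     lower_bound=-uptake, upper_bound=1000.0,
                     kind="exchange"),
            Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, gpr="gT",
                     kind="transport"),
            Reaction(id="A_to_B", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, gpr="g1 and g2"),
            Reaction(id="BIOMASS", stoichiometry={"B_c": -1.0 / yield_},
                     lower_bound=0.0, upper_bound=1000.0,
                     kind="objective-support"),
        ],
        genes=["gT", "g1", "g2"],
        objective={"BIOMASS": 1.0},
    )


def diamond_model():
    """A -> B directly (1 step) or via C (2 steps); pFBA prefers the
    direct route."""
    return MetabolicModel(
        id="diamond",
        metabolites=[
            Metabolite("A_e", compartment="e0"),
            Metabolite("A_c", compartment="c0"),
            Metabolite("B_c", compartment="c0"),
            Metabolite("C_c", compartment="c0"),
        ],
        reactions=[
            Reaction(id="EX_A", stoichiometry={"A_e": -1.0},
                     lower_bound=-10.0, upper_bound=1000.0, kind="exchange"),
            Reaction(id="T_A", stoichiometry={"A_e": -1.0, "A_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, kind="transport"),
            Reaction(id="DIRECT", stoichiometry={"A_c": -1.0, "B_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, gpr="gdir"),
            Reaction(id="VIA_C1", stoichiometry={"A_c": -1.0, "C_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, gpr="gc1"),
            Reaction(id="VIA_C2", stoichiometry={"C_c": -1.0, "B_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0, gpr="gc2"),
            Reaction(id="BIOMASS", stoichiometry={"B_c": -1.0},
                     lower_bound=0.0, upper_bound=1000.0,
                     kind="objective-support"),
        ],
        genes=["gdir", "gc1", "gc2"],
        objective={"BIOMASS": 1.0},
    )


@pytest.fixture
def chain_model():
    return linear_chain_model()


@pytest.fixture
def diamond():
    return diamond_model()


@pytest.fixture
def rng():
    return np.random.default_rng(42)
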