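"""Shared fixtures: toy cobra models and preprocessed synthetic scenarios."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from cobra import Metabolite, Model, Reaction

import fluxrevert as fr
from fluxrevert.expression import map_expression_to_reactions, preprocess
from fluxrevert.modules import lp_flux_state
from fluxrevert.perturbation import perturbed_reactions


def build_model(mets, rxns, model_id="toy"):
    """mets: {id: formula}; rxns: {id: (stoich, lb, ub)} or (stoich, lb, ub, gpr)."""
    model = Model(model_id)
    model.add_metabolites(
        [Metabolite(m, formula=f, compartment="c") for m, f in mets.items()]
    )
    objs = []
    for rid, spec in rxns.items():
        stoich, lb, ub = spec[:3]
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(
            {model.metabolites.get_by_id(m): c for m, c in stoich.items()}
        )
        if len(spec) > 3 and spec[3]:
            r.gene_reaction_rule = spec[3]
        objs.append(r)
    model.add_reactions(objs)
    model.solver = "glpk"
    return model


@pytest.fixture(scope="session")
def linear_chain():
    """EX_a -> A -> B -> EX_b : fully consistent 4-reaction chain."""
    return build_model(
        {"a": "C6H12O6", "b": "C3H4O3"},
        {
            "EX_a": ({"a": -1}, -10, 0),
            "R1": ({"a": -1, "b": 1}, 0, 1000),
            "EX_b": ({"b": -1}, 0, 1000),
        },
        "chain",
    )


@pytest.fixture(scope="session")
def dead_end_chain():
    """A -> B -> C with C undrained: the whole chain is blocked."""
    return build_model(
        {"a": "C6H12O6", "b": "C3H4O3", "c": "C2H4O2"},
        {
            "EX_a": ({"a": -1}, -10, 1000),
            "R1": ({"a": -1, "b": 1}, 0, 1000),
            "R2": ({"b": -1, "c": 1}, 0, 1000),
        },
        "deadend",
    )


@pytest.fixture(scope="session")
def branched_net():
    """12-reaction network with two alternative support paths and a dead end."""
    return build_model(
        {
            "a": "C6H12O6", "b": "C3H4O3", "c": "C2H4O2",
            "d": "C4H6O4", "e": "C5H10O5", "x": "CH4",
        },
        {
            "EX_a": ({"a": -1}, -10, 0),
            "T1": ({"a": -1, "b": 1}, 0, 1000),
            "ALT1": ({"b": -1, "c": 1}, 0, 1000),
            "ALT2a": ({"b": -1, "d": 1}, 0, 1000),
            "ALT2b": ({"d": -1, "c": 1}, -1000, 1000),
            "CORE": ({"c": -1, "e": 1}, 0, 1000),
            "EX_e": ({"e": -1}, 0, 1000),
            "DEAD1": ({"b": -1, "x": 1}, 0, 1000),  # x has no drain
            "REV": ({"d": -1, "e": 1}, -1000, 1000),
            "EX_d": ({"d": -1}, 0, 0),  # closed exchange: blocked
            "LOOPF": ({"c": -1, "d": 1}, 0, 1000),
            "EX_c": ({"c": -1}, 0, 5),
        },
        "branched",
    )


@pytest.fixture(scope="session")
def scenario():
    return fr.make_scenario(seed=1)


@pytest.fixture(scope="session")
def scenario_states(scenario):
    """Preprocessed expression, reaction expression, and LP stage states."""
    vals = preprocess(scenario.expression, scenario.model)
    rexp = {s: map_expression_to_reactions(scenario.model, vals[s]) for s in vals}
    states = {s: lp_flux_state(scenario.model, rexp[s]) for s in rexp}
    report = perturbed_reactions(
        states["monolayer"], states["moruloid"], transition="t1"
    )
    return {
        "values": vals,
        "rexp": rexp,
        "states": states,
        "report": report,
    }
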