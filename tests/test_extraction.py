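"""Threshold schemes and the three extraction methods against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog

from fluxrevert.extraction import (
    compute_thresholds,
    extract_context_model,
    fastcore_extract,
    imat_extract,
    imat_objective,
    init_extract,
    init_objective_of_set,
    init_weights,
)
from fluxrevert.network import flux_consistent_subnetwork

from conftest import build_model

EPS = 1e-3


class TestThresholds:
    def test_imat_th1_decile(self):
        exp = pd.Series(np.arange(1.0, 101.0))
        ts = compute_thresholds(exp, "iMAT", "Th1")
        assert ts.lower == 1 and ts.upper == 91

    def test_imat_th2_mean_std(self):
        rng = np.random.default_rng(0)
        exp = pd.Series(rng.normal(5, 2, 500))
        ts = compute_thresholds(exp, "iMAT", "Th2")
        assert ts.lower == pytest.approx(exp.mean() - exp.std(ddof=0))
        assert ts.upper == pytest.approx(exp.mean() + exp.std(ddof=0))

    def test_fastcore_schemes(self):
        exp = pd.Series(np.arange(1.0, 101.0))
        assert compute_thresholds(exp, "FASTCORE", "Th1").lower == 91
        assert compute_thresholds(exp, "FASTCORE", "Th2").lower == 1
        assert compute_thresholds(exp, "INIT", "Th1").lower == 91

    def test_too_few_scored(self):
        with pytest.raises(ValueError, match=">= 10"):
            compute_thresholds(pd.Series([1.0] * 9), "iMAT", "Th1")

    def test_constant_array_degenerates(self, caplog):
        ts = compute_thresholds(pd.Series([3.0] * 20), "iMAT", "Th1")
        assert ts.lower == ts.upper == 3.0

    def test_nan_ignored(self):
        exp = pd.Series(list(np.arange(1.0, 101.0)) + [np.nan] * 30)
        assert compute_thresholds(exp, "FASTCORE", "Th1").lower == 91


@pytest.fixture(scope="module")
def imat_net():
    """Small network with one preferred and one disfavoured route."""
    return build_model(
        {"a": "C6H12O6", "b": "C3H4O3", "c": "C2H4O2"},
        {
            "EX_a": ({"a": -1}, -10, 0),
            "HI1": ({"a": -1, "b": 1}, 0, 10),
            "LO1": ({"a": -1, "b": 1}, 0, 10),
            "HI2": ({"b": -1, "c": 1}, 0, 10),
            "LO2": ({"b": -1, "c": 1}, -10, 10),
            "EX_c": ({"c": -1}, 0, 10),
        },
        "imatnet",
    )


def _imat_bruteforce(model, high, low, eps):
    """Enumerate activity patterns; LP feasibility check per pattern."""
    S = create_stoichiometric_matrix(model)
    rids = [r.id for r in model.reactions]
    idx = {r: i for i, r in enumerate(rids)}
    lb0 = np.array([r.lower_bound for r in model.reactions], float)
    ub0 = np.array([r.upper_bound for r in model.reactions], float)
    best = -1
    hi_states = [("fwd",), ("rev",), ("free",)]
    for hi_pat in itertools.product(["fwd", "rev", "free"], repeat=len(high)):
        for lo_pat in itertools.product(["zero", "free"], repeat=len(low)):
            lb, ub = lb0.copy(), ub0.copy()
            score = 0
            ok = True
            for r, s in zip(high, hi_pat):
                j = idx[r]
                if s == "fwd":
                    lb[j] = max(lb[j], eps)
                    score += 1
                elif s == "rev":
                    ub[j] = min(ub[j], -eps)
                    score += 1
                if lb[j] > ub[j]:
                    ok = False
            for r, s in zip(low, lo_pat):
                j = idx[r]
                if s == "zero":
                    if lb[j] > 0 or ub[j] < 0:  # zero outside the bounds
                        ok = False
                    lb[j] = ub[j] = 0.0
                    score += 1
            if not ok or score <= best:
                continue
            res = linprog(np.zeros(len(rids)), A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(lb, ub)), method="highs")
            if res.success:
                best = score
    return best


class TestIMAT:
    def test_objective_matches_enumeration(self, imat_net):
        exp = pd.Series(
            {"HI1": 9.0, "HI2": 9.5, "LO1": 1.0, "LO2": 0.5, "EX_a": np.nan,
             "EX_c": np.nan}
        )
        obj, v = imat_objective(imat_net, exp, lower=2.0, upper=8.0, eps=EPS)
        brute = _imat_bruteforce(imat_net, ["HI1", "HI2"], ["LO1", "LO2"], EPS)
        assert obj == brute == 4

    def test_high_path_retained_low_removed(self, imat_net):
        exp = pd.Series({"HI1": 9.0, "HI2": 9.5, "LO1": 1.0, "LO2": 0.5})
        cm = imat_extract(imat_net, exp, lower=2.0, upper=8.0, eps=EPS)
        kept = cm.reaction_ids
        assert {"HI1", "HI2", "EX_a", "EX_c"} <= kept
        assert "LO1" not in kept and "LO2" not in kept

    def test_all_low_gives_small_model(self, imat_net):
        exp = pd.Series({r.id: 1.0 for r in imat_net.reactions})
        cm = imat_extract(imat_net, exp, lower=2.0, upper=8.0, eps=EPS)
        # nothing is required to be active; zero-flux solution is optimal
        assert cm.reaction_ids == set()

    def test_output_flux_consistent(self, imat_net):
        exp = pd.Series({"HI1": 9.0, "HI2": 9.5, "LO1": 1.0, "LO2": 0.5})
        cm = imat_extract(imat_net, exp, lower=2.0, upper=8.0, eps=EPS)
        again = flux_consistent_subnetwork(cm.model)
        assert {r.id for r in again.reactions} == cm.reaction_ids


def _min_support_bruteforce(model, core, eps):
    """Smallest reaction subset in which every core reaction can carry flux."""
    S = create_stoichiometric_matrix(model)
    rids = [r.id for r in model.reactions]
    others = [r for r in rids if r not in core]
    lb0 = np.array([r.lower_bound for r in model.reactions], float)
    ub0 = np.array([r.upper_bound for r in model.reactions], float)
    idx = {r: i for i, r in enumerate(rids)}
    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            members = set(core) | set(combo)
            lb, ub = lb0.copy(), ub0.copy()
            for r in rids:
                if r not in members:
                    lb[idx[r]] = ub[idx[r]] = 0.0
            feasible_all = True
            for r in core:
                l2 = lb.copy()
                l2[idx[r]] = max(l2[idx[r]], eps)
                res = linprog(np.zeros(len(rids)), A_eq=S,
                              b_eq=np.zeros(S.shape[0]),
                              bounds=list(zip(l2, ub)), method="highs")
                if not res.success:
                    feasible_all = False
                    break
            if feasible_all:
                return len(members)
    return len(rids)


class TestFastcore:
    def test_single_core_pulls_whole_chain(self, linear_chain):
        cm = fastcore_extract(linear_chain, {"R1"})
        assert cm.reaction_ids == {"EX_a", "R1", "EX_b"}

    def test_empty_core_empty_model(self, linear_chain):
        cm = fastcore_extract(linear_chain, set())
        assert cm.reaction_ids == set()

    def test_support_near_minimal_with_alternatives(self, branched_net):
        consistent = flux_consistent_subnetwork(branched_net)
        core = {"CORE"}
        cm = fastcore_extract(consistent, core, eps=EPS)
        assert core <= cm.reaction_ids
        brute = _min_support_bruteforce(consistent, core, EPS)
        assert len(cm.reaction_ids) <= brute + 2

    def test_core_always_contained(self, scenario):
        consistent = flux_consistent_subnetwork(scenario.model)
        core = {"P1", "Q3", "BM2", "GLCt"}
        cm = fastcore_extract(consistent, core, eps=EPS)
        assert core <= cm.reaction_ids

    def test_unknown_core_reaction(self, linear_chain):
        with pytest.raises(KeyError, match="ghost"):
            fastcore_extract(linear_chain, {"ghost"})


class TestInit:
    def test_weight_formula(self):
        exp = pd.Series({"a": 4.0, "b": 2.0, "c": np.nan})
        w = init_weights(exp, threshold=2.0)
        assert w["a"] == pytest.approx(5.0)  # 5*log2(2)
        assert w["b"] == pytest.approx(0.0)
        assert w["c"] == -2.0

    def test_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            init_weights(pd.Series({"a": 1.0}), threshold=0.0)

    def test_selected_set_beats_random_search(self, imat_net):
        w = pd.Series(
            {"EX_a": 1.0, "HI1": 6.0, "HI2": 6.0, "LO1": -4.0, "LO2": -4.0,
             "EX_c": 1.0}
        )
        cm = init_extract(imat_net, w, eps=EPS)
        got = init_objective_of_set(w, cm.reaction_ids)
        S = create_stoichiometric_matrix(imat_net)
        rids = [r.id for r in imat_net.reactions]
        idx = {r: i for i, r in enumerate(rids)}
        rng = np.random.default_rng(0)
        for _ in range(200):
            members = {r for r in rids if rng.random() < 0.5}
            lb = np.array([imat_net.reactions.get_by_id(r).lower_bound
                           if r in members else 0.0 for r in rids])
            ub = np.array([imat_net.reactions.get_by_id(r).upper_bound
                           if r in members else 0.0 for r in rids])
            # single-witness validity: every member active at eps at once
            lo = lb.copy()
            for r in members:
                if lb[idx[r]] >= 0:
                    lo[idx[r]] = max(lo[idx[r]], EPS)
            res = linprog(np.zeros(len(rids)), A_eq=S,
                          b_eq=np.zeros(S.shape[0]),
                          bounds=list(zip(lo, ub)), method="highs")
            if res.success and all(lb[idx[r]] >= 0 for r in members):
                assert got >= init_objective_of_set(w, members) - 1e-9

    def test_front_end_dispatch(self, scenario, scenario_states):
        exp = scenario_states["rexp"]["monolayer"]
        cm = extract_context_model(scenario.model, exp, "INIT", "Th2")
        assert cm.method == "INIT" and cm.scheme == "Th2"
        assert cm.reaction_ids <= {r.id for r in scenario.model.reactions}
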