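"""E-flux, essentiality, knockouts, drug inhibition and GDSC comparison."""

import numpy as np
import pandas as pd
import pytest

from fluxrevert.interventions import (
    DrugRecord,
    apply_drug,
    corr_log2fc,
    drug_pathway_overlap,
    drug_screen,
    drug_target_reactions,
    eflux_bounds,
    essentiality_screen,
    gdsc_zscore,
    gene_knockout,
    inhibition_scan,
    knockout_screen,
    nonessential_genes,
    quantile_normalize,
    read_drug_table,
    write_drug_table,
)
from fluxrevert.modules import make_evaluator

from conftest import build_model


@pytest.fixture(scope="module")
def gpr_model():
    return build_model(
        {"a": "C6H12O6", "b": "C3H4O3"},
        {
            "EX_a": ({"a": -1}, -10, 0),
            "CPLX": ({"a": -1, "b": 1}, 0, 100, "g1 and g2"),
            "ISO": ({"a": -1, "b": 1}, -100, 100, "g1 or g2"),
            "SOLO": ({"a": -1, "b": 1}, 0, 100, "g3"),
            "EX_b": ({"b": -1}, 0, 100),
        },
        "gprnet",
    )


class TestEflux:
    def test_scaling_anchor_and_direction(self, gpr_model):
        exp = pd.Series({"g1": 10.0, "g2": 4.0, "g3": 10.0})
        out = eflux_bounds(gpr_model, exp, b_max=1000)
        # ISO takes max(g1,g2)=10 = sample maximum -> full bounds, reversible
        assert out.reactions.ISO.bounds == (-1000.0, 1000.0)
        # CPLX takes min=4 -> scaled, irreversible keeps lb=0
        assert out.reactions.CPLX.bounds == (0.0, pytest.approx(400.0))
        # no GPR -> untouched
        assert out.reactions.EX_a.bounds == (-10.0, 0.0)

    def test_linear_in_expression(self, gpr_model):
        full = eflux_bounds(gpr_model, pd.Series({"g1": 8.0, "g2": 8.0, "g3": 4.0}))
        half = eflux_bounds(gpr_model, pd.Series({"g1": 8.0, "g2": 8.0, "g3": 2.0}))
        assert half.reactions.SOLO.upper_bound == pytest.approx(
            full.reactions.SOLO.upper_bound / 2
        )

    def test_all_zero_rejected(self, gpr_model):
        with pytest.raises(ValueError):
            eflux_bounds(gpr_model, pd.Series({"g1": 0.0, "g2": 0.0, "g3": 0.0}))


class TestQuantileNormalize:
    def test_identical_distributions(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.lognormal(1, 1, size=(40, 5)))
        qn = quantile_normalize(m)
        ref = np.sort(qn.iloc[:, 0].to_numpy())
        for c in qn.columns[1:]:
            assert np.allclose(np.sort(qn[c].to_numpy()), ref)

    def test_rank_order_preserved(self):
        m = pd.DataFrame({"s1": [1.0, 5.0, 3.0], "s2": [2.0, 0.5, 9.0]})
        qn = quantile_normalize(m)
        assert qn["s1"].idxmax() == 1 and qn["s2"].idxmax() == 2


class TestKnockout:
    def test_complex_disabled_isozyme_survives(self, gpr_model):
        out = gene_knockout(gpr_model, "g1")
        assert out.reactions.CPLX.bounds == (0.0, 0.0)
        assert out.reactions.ISO.bounds == (-100.0, 100.0)

    def test_idempotent(self, gpr_model):
        once = gene_knockout(gpr_model, "g1")
        twice = gene_knockout(once, "g1")
        assert [r.bounds for r in twice.reactions] == [r.bounds for r in once.reactions]

    def test_unknown_gene(self, gpr_model):
        with pytest.raises(KeyError):
            gene_knockout(gpr_model, "ghost")


class TestEssentiality:
    def test_planted_essentials_recovered(self, scenario):
        table = essentiality_screen(
            scenario.normal_expression, scenario.model, scenario.biomass_id
        )
        ratios = table.drop(columns="non_essential")
        assert (ratios.fillna(0) >= -1e-9).all().all()
        assert (ratios.fillna(0) <= 1 + 1e-6).all().all()
        essential = set(table.index[~table["non_essential"]])
        assert essential == set(scenario.essential_genes)

    def test_non_gpr_gene_ratio_one(self, scenario):
        table = essentiality_screen(
            scenario.normal_expression,
            scenario.model,
            scenario.biomass_id,
            genes=["gB3"],
        )
        assert (table.loc["gB3"].drop("non_essential") == 1.0).all()
        assert "gB3" in nonessential_genes(table)


class TestDrugApplication:
    def test_half_inhibition_halves_bounds(self, gpr_model):
        drug = DrugRecord("D1", "one", ("g3",))
        out = apply_drug(gpr_model, drug, 0.5)
        assert out.reactions.SOLO.upper_bound == pytest.approx(50.0)

    def test_membership_rule_hits_isozymes(self, gpr_model):
        drug = DrugRecord("D1", "one", ("g1",))
        assert set(drug_target_reactions(gpr_model, drug)) == {"CPLX", "ISO"}
        out = apply_drug(gpr_model, drug, 0.5)
        assert out.reactions.ISO.bounds == (-50.0, 50.0)

    def test_full_inhibition_matches_knockout_on_single_gene_gpr(self, gpr_model):
        drug = DrugRecord("D3", "three", ("g3",))
        drugged = apply_drug(gpr_model, drug, 1.0)
        knocked = gene_knockout(gpr_model, "g3")
        assert drugged.reactions.SOLO.bounds == knocked.reactions.SOLO.bounds == (0, 0)

    def test_disjoint_drugs_commute(self, gpr_model):
        d1 = DrugRecord("D1", "one", ("g1",))
        d3 = DrugRecord("D3", "three", ("g3",))
        ab = apply_drug(apply_drug(gpr_model, d1, 0.3), d3, 0.6)
        ba = apply_drug(apply_drug(gpr_model, d3, 0.6), d1, 0.3)
        assert [r.bounds for r in ab.reactions] == [r.bounds for r in ba.reactions]

    @pytest.mark.parametrize("frac", [0.0, -0.1, 1.5])
    def test_invalid_inhibition(self, gpr_model, frac):
        with pytest.raises(ValueError):
            apply_drug(gpr_model, DrugRecord("D", "d", ("g1",)), frac)


class TestScreens:
    @pytest.fixture(scope="class")
    def setup(self, scenario, scenario_states):
        rep = scenario_states["report"]
        ev = make_evaluator(
            scenario.model, scenario_states["rexp"]["moruloid"], "lp"
        )
        return {
            "model": scenario.model,
            "init": scenario_states["states"]["monolayer"],
            "perturbed": rep.perturbed_ids,
            "baseline": rep.baseline_correlation,
            "ev": ev,
        }

    def test_knockout_screen_ranks_drivers_first(self, scenario, setup):
        cands = [g.id for g in scenario.model.genes
                 if g.id not in scenario.essential_genes]
        results = knockout_screen(
            setup["model"], cands, setup["init"], setup["perturbed"],
            setup["ev"], setup["baseline"],
        )
        ranked = [r.intervention for r in results]
        assert set(ranked[:4]) == set(scenario.planted_genes)

    def test_knockout_of_unrelated_gene_is_baseline(self, scenario, setup):
        results = knockout_screen(
            setup["model"], ["gB3"], setup["init"], setup["perturbed"],
            setup["ev"], setup["baseline"],
        )
        assert results[0].correlation == pytest.approx(setup["baseline"], abs=1e-6)

    def test_drug_screen_finds_planted_drug(self, scenario, setup):
        results = drug_screen(
            setup["model"], scenario.drugs, setup["init"], setup["perturbed"],
            setup["ev"], setup["baseline"],
        )
        by_id = {r.intervention: r for r in results}
        assert by_id[scenario.true_drug_id].extra["passes_filter"]
        decoys_failing = [
            r for r in results
            if r.intervention.startswith("DECOY") and not r.extra["passes_filter"]
        ]
        assert len(decoys_failing) >= 3

    def test_drug_screen_empty_table(self, setup):
        assert drug_screen(
            setup["model"], [], setup["init"], setup["perturbed"],
            setup["ev"], setup["baseline"],
        ) == []

    def test_non_inhibitor_skipped(self, scenario, setup):
        agonist = DrugRecord("D_AG", "agonine", ("gQ1",), inhibitor=False)
        results = drug_screen(
            setup["model"], [agonist], setup["init"], setup["perturbed"],
            setup["ev"], setup["baseline"],
        )
        assert results == []

    def test_inhibition_scan_plateau(self, scenario, setup):
        true_drug = next(
            d for d in scenario.drugs if d.drug_id == scenario.true_drug_id
        )
        curve = inhibition_scan(
            setup["model"], true_drug, setup["init"], setup["perturbed"],
            setup["ev"],
        )
        assert len(curve) == 10
        # correlation is non-decreasing up to its plateau, full inhibition
        # sits within the plateau tolerance of the maximum, and exactly one
        # minimal effective level is flagged
        corr = curve["correlation"].to_numpy()
        assert (np.diff(corr) >= -0.01).all()
        assert corr[-1] >= corr.max() - 0.01
        assert curve["minimal_effective"].sum() == 1
        level = curve.loc[curve["minimal_effective"], "inhibition"].iloc[0]
        assert corr[curve["inhibition"].tolist().index(level)] >= corr.max() - 0.01

    def test_unmapped_drug_flat_curve(self, setup):
        ghost = DrugRecord("D_G", "ghostine", ("not_a_gene",))
        curve = inhibition_scan(
            setup["model"], ghost, setup["init"], setup["perturbed"], setup["ev"]
        )
        assert curve["correlation"].nunique() == 1

    def test_screen_deterministic_at_fixed_seed(self, scenario, scenario_states):
        rep = scenario_states["report"]
        runs = []
        for _ in range(2):
            ev = make_evaluator(
                scenario.model, scenario_states["rexp"]["moruloid"], "achr",
                n_points=40, base_seed=9,
            )
            res = knockout_screen(
                scenario.model, ["gQ1", "gQ2", "gB3"],
                scenario_states["states"]["monolayer"], rep.perturbed_ids,
                ev, rep.baseline_correlation,
            )
            runs.append([(r.intervention, r.correlation) for r in res])
        assert runs[0] == runs[1]


class TestGdscZscore:
    def test_standard_cases(self):
        vec = [1.0, 2.0, 3.0]
        mu, sigma = np.mean(vec), np.std(vec)
        assert gdsc_zscore(mu, vec) == pytest.approx(0.0)
        assert gdsc_zscore(mu + sigma, vec) == pytest.approx(1.0)
        assert gdsc_zscore(3.0, vec) == pytest.approx(1.2247, abs=1e-4)

    def test_printed_variance_mode(self):
        vec = [1.0, 2.0, 3.0]
        z_sigma = gdsc_zscore(3.0, vec)
        z_var = gdsc_zscore(3.0, vec, printed_variance_denominator=True)
        assert z_var == pytest.approx(z_sigma / np.std(vec))

    def test_zero_variance(self):
        with pytest.raises(ValueError):
            gdsc_zscore(1.0, [2.0, 2.0])


class TestPathwayOverlap:
    def test_ratios(self, scenario):
        drug = DrugRecord("D", "d", ("gQ1", "gQ2", "gQ3", "gQ4"))
        table = drug_pathway_overlap(drug, scenario.model)
        row = table[table["subsystem"] == "Pentose phosphate pathway"].iloc[0]
        assert row["targeted"] == 4 and row["pathway_size"] == 5
        assert row["overlap_value"] == pytest.approx(0.8)

    def test_full_subsystem_coverage(self, gpr_model):
        for r in gpr_model.reactions:
            r.subsystem = "S"
        drug = DrugRecord("D", "d", ("g1", "g2", "g3"))
        table = drug_pathway_overlap(drug, gpr_model)
        assert table.iloc[0]["overlap_value"] == pytest.approx(3 / 5)

    def test_accounting_identity(self, scenario):
        drug = DrugRecord("D", "d", ("gQ1", "gB3", "gE1"))
        table = drug_pathway_overlap(drug, scenario.model)
        total = (table["overlap_value"] * table["pathway_size"]).sum()
        assert total == pytest.approx(
            len(drug_target_reactions(scenario.model, drug))
        )


class TestTables:
    def test_drug_table_round_trip(self, scenario, tmp_path):
        write_drug_table(scenario.drugs, tmp_path / "drugs.tsv")
        back = read_drug_table(tmp_path / "drugs.tsv")
        assert [(d.drug_id, d.targets, d.inhibitor) for d in back] == [
            (d.drug_id, d.targets, d.inhibitor) for d in scenario.drugs
        ]

    def test_corr_log2fc_floor(self):
        assert corr_log2fc(0.8, 0.01) == pytest.approx(np.log2(80))
        assert corr_log2fc(-0.5, -0.9) == 0.0
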