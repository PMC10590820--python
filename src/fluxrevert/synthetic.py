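"""Toy metabolic scenarios with planted ground truth.

The generated network is a two-route carbon backbone built to mimic, at toy
scale, the situation the pipeline is designed for: a fixed glucose uptake is
routed from a hub metabolite to a biomass precursor through two parallel
pathways — a "baseline" route P (glycolysis-like) and an "alternative" route
Q (pentose-phosphate-like) — followed by a linear biomass chain and a set of
optional secreted side branches.  Stage-wise expression swaps the two routes:
the P genes fall and the Q genes rise by a planted fold factor at every
consecutive stage, so the expression-optimal flux state migrates from P to Q.
The Q reactions are therefore the planted perturbed module: clamping them to
their initial-stage (near-zero) fluxes, knocking out their genes, or
inhibiting them with the planted true-positive drug all force flux back
through P and restore the initial-stage profile.

Planted essential genes are the sole catalysts of the uptake/hub/biomass
chain; branch genes (including an isozyme pair and an enzyme complex) are
non-essential decoy targets.  All artifacts serialise in the exact formats
the pipeline reads (BiGG-style JSON, TSV), so fixtures double as format
documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .expression import STAGES
from .interventions import DrugRecord, write_drug_table
from .network import _configure, save_model

#: abundance scale of the log-normal proteomic baseline
BASE_LOG_MEAN = np.log(100.0)
BASE_LOG_SD = 1.0

#: planted flux/expression fold between consecutive stages
DEFAULT_EFFECT = 4.0
DEFAULT_NOISE_CV = 0.1
DEFAULT_MISSINGNESS = 0.05

_FORMULAS = ["C6H12O6", "C6H13O9P", "C3H4O3", "C5H10O5", "C4H6O4", "C3H7NO2"]


@dataclass
class SyntheticScenario:
    """A complete toy study: model, expression, ground truth and drug tables."""

    model: Model
    expression: pd.DataFrame  # (stage, replicate) MultiIndex columns
    planted_module: list[str]  # reaction ids (the Q route)
    planted_genes: list[str]
    essential_genes: list[str]
    essential_metabolites: list[str]  # sink candidates for functionality scoring
    biomass_id: str
    drugs: list[DrugRecord] = field(default_factory=list)
    true_drug_id: str = ""
    ic50: Optional[pd.DataFrame] = None
    normal_expression: Optional[pd.DataFrame] = None
    seed: int = 0

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model(self.model, outdir / "model.json")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        write_drug_table(self.drugs, outdir / "drugs.tsv")
        if self.ic50 is not None:
            self.ic50.to_csv(outdir / "ic50.tsv", sep="\t", index=False)
        if self.normal_expression is not None:
            self.normal_expression.to_csv(outdir / "normal_expression.tsv", sep="\t")
        (outdir / "essential_metabolites.txt").write_text(
            "\n".join(self.essential_metabolites) + "\n"
        )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def make_network(n_core: int = 4, n_branch: int = 4, seed: int = 0) -> Model:
    """Two-route toy network with GPRs, subsystems and carbon formulas.

    ``n_core`` is the length of each parallel route (P and Q); ``n_branch``
    the number of secreted side branches.  The network is connected and
    flux-consistent by construction: glucose uptake is fixed at 10
    mmol·gDW⁻¹·h⁻¹ and every internal reaction lies on a path from uptake to
    a drain.  Deterministic for a given parameter set.
    """
    if n_core < 2 or n_branch < 1:
        raise ValueError("need n_core >= 2 and n_branch >= 1 for a consistent net")
    model = Model(f"toynet_c{n_core}_b{n_branch}")

    def met(mid, formula, comp="c"):
        m = Metabolite(mid, formula=formula, compartment=comp)
        model.add_metabolites([m])
        return m

    glc_e = met("glc_e", "C6H12O6", "e")
    glc_c = met("glc_c", "C6H12O6")
    hub = met("hub_c", "C6H13O9P")
    bm = met("bm_c", "C3H4O3")
    z1 = met("z1_c", "C4H6O4")
    z2 = met("z2_c", "C5H10O5")
    bio = met("bio_c", "C10H16N5O13P3")
    seg = [hub] + [
        met(f"p{i}_c", _FORMULAS[i % len(_FORMULAS)]) for i in range(1, n_core)
    ] + [bm]
    b_mets = [met(f"br{i}_c", "C3H7NO2") for i in range(1, n_branch + 1)]

    def rxn(rid, stoich, lb, ub, gpr, subsystem):
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites(stoich)
        if gpr:
            r.gene_reaction_rule = gpr
        r.subsystem = subsystem
        model.add_reactions([r])
        return r

    rxn("EX_glc_e", {glc_e: -1}, -10, -10, "", "Exchange/demand reaction")
    rxn("GLCt", {glc_e: -1, glc_c: 1}, -1000, 1000, "gT1", "Transport, extracellular")
    rxn("HUB", {glc_c: -1, hub: 1}, -1000, 1000, "gE4", "Glycolysis/gluconeogenesis")

    # n_core serial segments, each catalysable by a baseline enzyme P_i or an
    # independent capacity-limited alternative enzyme Q_i (the planted
    # module); both kept irreversible so the parallel pairs admit no futile
    # cycle that an extreme flux state could inflate
    for i in range(n_core):
        rxn(f"P{i + 1}", {seg[i]: -1, seg[i + 1]: 1}, 0, 1000, f"gP{i + 1}",
            "Glycolysis/gluconeogenesis")
        rxn(f"Q{i + 1}", {seg[i]: -1, seg[i + 1]: 1}, 0, 8,
            f"gQ{i + 1}", "Pentose phosphate pathway")

    # small reversible isomerase shunt off the first segment metabolite:
    # gives the pentose subsystem a reversible member without a cycle
    pent = met("pent_c", "C5H10O5")
    rxn("QISO", {seg[1]: -1, pent: 1}, -0.5, 0.5, "gS1",
        "Pentose phosphate pathway")
    rxn("EX_pent_c", {pent: -1}, 0, 1000, "", "Exchange/demand reaction")

    rxn("BM1", {bm: -1, z1: 1}, 0, 1000, "gE1", "Biomass synthesis")
    rxn("BM2", {z1: -1, z2: 1}, -1000, 1000, "gE2", "Biomass synthesis")
    rxn("BM3", {z2: -1, bio: 1}, 0, 1000, "gE3", "Biomass synthesis")
    rxn("DM_bio_c", {bio: -1}, 0, 1000, "", "Exchange/demand reaction")

    # constitutive secreted side branches: the fixed drains keep them out of
    # the stage-to-stage flux contrast; the first branch doubles as the
    # irreversible member of the transport subsystem
    branch_gprs = ["gB1a or gB1b", "gB2a and gB2b"] + [
        f"gB{i}" for i in range(3, n_branch + 1)
    ]
    for i, bmet in enumerate(b_mets, start=1):
        subsystem = "Transport, extracellular" if i == 1 else "Lipid metabolism"
        rxn(f"B{i}", {bm: -1, bmet: 1}, 0.5, 0.5, branch_gprs[i - 1], subsystem)
        rxn(f"EX_br{i}_c", {bmet: -1}, -0.5 if i == 2 else 0.0, 1000, "",
            "Exchange/demand reaction")
    if n_branch >= 4:
        # reversible shuttle between two branch products: the lipid
        # subsystem's reversible member, introducing no new carbon source
        rxn("BISO", {b_mets[2]: -1, b_mets[3]: 1}, -0.5, 0.5, "gB5",
            "Lipid metabolism")

    model.objective = "DM_bio_c"
    return _configure(model)


def planted_module_ids(n_core: int = 4) -> list[str]:
    return [f"Q{i}" for i in range(1, n_core + 1)]


# ---------------------------------------------------------------------------
# stage expression
# ---------------------------------------------------------------------------

def make_stage_expression(
    model: Model,
    planted_genes: list[str],
    counter_genes: list[str],
    effect: float = DEFAULT_EFFECT,
    noise_cv: float = DEFAULT_NOISE_CV,
    missingness: float = DEFAULT_MISSINGNESS,
    n_replicates: int = 3,
    seed: int = 0,
    extra_proteins: int = 6,
) -> pd.DataFrame:
    """Three-stage replicate abundance matrix with a planted expression swap.

    Planted (Q-route) genes rise by *effect* per consecutive stage while the
    counter (P-route) genes fall by the same factor; all other genes are flat.
    Multiplicative log-normal noise with the stated CV; missing-at-random plus
    low-abundance-biased missingness on the non-planted rows, and a few extra
    non-model proteins exercising the replicate-filter edge cases (an
    all-missing row, a one-stage-only row, a below-50%-everywhere row).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(g.id for g in model.genes)
    base_draw = np.exp(rng.normal(BASE_LOG_MEAN, BASE_LOG_SD, size=len(genes)))
    base = dict(zip(genes, base_draw))
    # paired routes share a baseline: the planted/counter contrast is then the
    # planted fold itself, not an accident of which enzyme is more abundant
    for pg, cg in zip(planted_genes, counter_genes):
        if pg in base and cg in base:
            base[cg] = base[pg]
    stage_mult = {}
    # the planted genes rise (and the counter genes fall) by `effect` at each
    # consecutive transition; the half-step offset makes every stage decisive
    # (planted/counter expression ratio = effect already at the middle stage)
    for gi, g in enumerate(genes):
        if g in planted_genes:
            mult = [effect ** (s - 0.5) for s in range(3)]
        elif g in counter_genes:
            mult = [effect ** (0.5 - s) for s in range(3)]
        else:
            mult = [1.0, 1.0, 1.0]
        stage_mult[g] = mult

    sigma = np.sqrt(np.log(1 + noise_cv**2))
    cols = pd.MultiIndex.from_product(
        [STAGES, [f"rep{i + 1}" for i in range(n_replicates)]],
        names=["stage", "replicate"],
    )
    data = np.empty((len(genes), 3 * n_replicates))
    for gi, g in enumerate(genes):
        for s in range(3):
            mean = base[g] * stage_mult[g][s]
            noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=n_replicates))
            data[gi, s * n_replicates : (s + 1) * n_replicates] = mean * noise
    m = pd.DataFrame(data, index=genes, columns=cols)

    if missingness > 0:
        protected = set(planted_genes) | set(counter_genes)
        base_arr = np.array([base[g] for g in genes])
        low = np.argsort(base_arr)  # low-abundance rows miss more often
        bias = np.linspace(2.0, 0.5, len(genes))
        for rank, gi in enumerate(low):
            g = genes[gi]
            if g in protected:
                continue
            p = min(0.3, missingness * bias[rank])
            drop = rng.random(m.shape[1]) < p
            # never blank a full stage of a model gene: keep >= 2 observed reps
            for s in range(3):
                block = drop[s * n_replicates : (s + 1) * n_replicates]
                while block.sum() > n_replicates - 2:
                    block[rng.integers(0, n_replicates)] = False
            m.iloc[gi, np.flatnonzero(drop)] = np.nan

    if extra_proteins:
        extra = {}
        vals = np.exp(rng.normal(BASE_LOG_MEAN, BASE_LOG_SD, size=extra_proteins))
        for k in range(extra_proteins):
            row = np.full(3 * n_replicates, vals[k])
            if k == 0:
                row[:] = np.nan  # absent everywhere -> dropped first
            elif k == 1:
                row[n_replicates:] = np.nan  # one full stage only -> kept
            elif k == 2:
                # one observed replicate per stage -> fails the 50% rule
                for s in range(3):
                    row[s * n_replicates + 1 : (s + 1) * n_replicates] = np.nan
            extra[f"prot_extra{k + 1}"] = row
        m = pd.concat([m, pd.DataFrame(extra, index=m.columns).T])
    return m


def make_normal_expression(
    model: Model, n_samples: int = 12, seed: int = 0
) -> pd.DataFrame:
    """Normal-tissue gene expression panel (genes × samples), tight spread.

    The spread is kept narrow so that E-flux bounds never throttle the fixed
    glucose uptake and essentiality reflects topology, not noise.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(g.id for g in model.genes)
    base = np.exp(rng.normal(BASE_LOG_MEAN, 0.3, size=len(genes)))
    data = base[:, None] * np.exp(rng.normal(0, 0.2, size=(len(genes), n_samples)))
    return pd.DataFrame(
        data, index=genes, columns=[f"normal{i + 1}" for i in range(n_samples)]
    )


# ---------------------------------------------------------------------------
# drug and IC50 tables
# ---------------------------------------------------------------------------

def make_drug_table(
    model: Model,
    module_genes: list[str],
    n_decoys: int = 4,
    seed: int = 0,
) -> tuple[list[DrugRecord], str]:
    """One true-positive drug targeting the planted module plus decoys.

    Decoy targets are drawn from genes outside the planted module (and outside
    the essential chain, so decoys are screenable); all records are
    inhibitors.  Returns (records, true drug id).
    """
    rng = np.random.default_rng(seed)
    module = set(module_genes)
    pool = sorted(
        g.id
        for g in model.genes
        if g.id not in module and not g.id.startswith(("gE", "gT"))
    )
    drugs = [
        DrugRecord("DRUG_TP", "revertium", tuple(sorted(module)), inhibitor=True)
    ]
    for k in range(n_decoys):
        target = pool[int(rng.integers(0, len(pool)))]
        drugs.append(
            DrugRecord(f"DECOY_{k + 1}", f"decoyine-{k + 1}", (target,), True)
        )
    return drugs, "DRUG_TP"


def make_ic50_table(
    drugs: list[DrugRecord],
    true_drug_id: str,
    n_cell_lines: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """GDSC-like IC50 table; the true drug is most potent in the study line."""
    rng = np.random.default_rng(seed)
    lines = ["OVCAR-3"] + [f"line{i + 1}" for i in range(n_cell_lines - 1)]
    rows = []
    for d in drugs:
        base = np.exp(rng.normal(np.log(10.0), 0.8, size=n_cell_lines))
        if d.drug_id == true_drug_id:
            base[0] = base.min() / 4  # sensitive study line -> negative z-score
        for line, v in zip(lines, base):
            rows.append({"drug_id": d.drug_id, "cell_line": line, "ic50": v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------

def make_scenario(
    seed: int = 0,
    n_core: int = 4,
    n_branch: int = 4,
    effect: float = DEFAULT_EFFECT,
    noise_cv: float = DEFAULT_NOISE_CV,
    missingness: float = DEFAULT_MISSINGNESS,
    n_normal_samples: int = 12,
) -> SyntheticScenario:
    """Assemble the full toy study for one seed."""
    model = make_network(n_core=n_core, n_branch=n_branch, seed=seed)
    module = planted_module_ids(n_core)
    planted_genes = [f"gQ{i}" for i in range(1, n_core + 1)]
    counter_genes = [f"gP{i}" for i in range(1, n_core + 1)]
    expression = make_stage_expression(
        model,
        planted_genes,
        counter_genes,
        effect=effect,
        noise_cv=noise_cv,
        missingness=missingness,
        seed=seed,
    )
    drugs, true_id = make_drug_table(model, planted_genes, seed=seed)
    return SyntheticScenario(
        model=model,
        expression=expression,
        planted_module=module,
        planted_genes=planted_genes,
        essential_genes=["gT1", "gE1", "gE2", "gE3", "gE4"],
        essential_metabolites=["bm_c", "z1_c", "z2_c", "bio_c", "br1_c"],
        biomass_id="DM_bio_c",
        drugs=drugs,
        true_drug_id=true_id,
        ic50=make_ic50_table(drugs, true_id, seed=seed),
        normal_expression=make_normal_expression(model, n_normal_samples, seed=seed),
        seed=seed,
    )
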