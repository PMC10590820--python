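"""End-to-end orchestration: configuration, staged execution, provenance.

The pipeline runs the analysis stages in order, each stage reading the
previous stage's on-disk outputs, so any stage can be re-run in isolation
(resume) and every output depends only on the declared inputs plus the
master seed.  The master seed fans out deterministically to per-stage seeds.

Stage order::

    preprocess → extract → sample → functionality → perturb
               → essentiality → modules → knockout → drugs

Outputs are TSV/JSON under the configured output directory plus a
``manifest.json`` echoing the full configuration, the derived seeds and the
completion status of every stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .expression import (
    STAGES,
    map_expression_to_reactions,
    preprocess,
    read_stage_matrix,
)
from .extraction import DEFAULT_EPS, extract_context_model
from .interventions import (
    DEFAULT_INHIBITION,
    drug_screen,
    essentiality_screen,
    gdsc_zscore,
    knockout_screen,
    nonessential_genes,
    read_drug_table,
    read_ic50_table,
    results_table,
)
from .modules import (
    EXTERNAL_CUTOFF,
    INTERNAL_CUTOFF,
    N_STRATEGIES,
    greedy_module_search,
    lp_flux_state,
    make_evaluator,
    strategies_table,
    targetability,
)
from .network import (
    ACTIVITY_TOL,
    add_sink_reactions,
    fix_carbon_bounds,
    flux_consistent_subnetwork,
    load_model,
    remove_objective_reaction,
    save_model,
    sink_ids,
)
from .perturbation import FOLD_CUTOFF, perturbed_reactions, subsystem_enrichment
from .sampling import (
    FluxState,
    functionality_score,
    functionality_significance,
    sample_fluxes,
    select_optimal_state,
)

logger = logging.getLogger("fluxrevert")

STAGE_ORDER = (
    "preprocess",
    "extract",
    "sample",
    "functionality",
    "perturb",
    "essentiality",
    "modules",
    "knockout",
    "drugs",
)


@dataclass
class PipelineConfig:
    """All inputs and tunables; defaults are the published study settings."""

    model_path: str = ""
    expression_path: str = ""
    metabolite_list_path: str = ""
    drug_table_path: str = ""
    ic50_table_path: str = ""
    normal_expression_path: str = ""
    outdir: str = "fluxrevert_out"
    # method selection
    extraction_method: str = "iMAT"
    threshold_scheme: str = "Th1"
    state_method: str = "achr"  # achr | lp
    study_cell_line: str = "OVCAR-3"  # line whose IC50 is z-scored
    # tunables (study defaults)
    eps: float = DEFAULT_EPS
    activity_tol: float = ACTIVITY_TOL
    carbon_uptake_limit: float = 10.0
    fold_cutoff: float = FOLD_CUTOFF
    internal_cutoff: float = INTERNAL_CUTOFF
    external_cutoff: float = EXTERNAL_CUTOFF
    n_strategies: int = N_STRATEGIES
    inhibition: float = DEFAULT_INHIBITION
    significance_iterations: int = 1000
    n_points_multiplier: int = 2
    seed: int = 0
    stages: tuple[str, ...] = field(default_factory=lambda: tuple(STAGES))

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 10_007 + STAGE_ORDER.index(stage) + 1) % (2**31 - 1)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run(
    config: PipelineConfig,
    stages: Optional[list[str]] = None,
    resume: bool = False,
) -> Path:
    """Execute the pipeline and return the provenance-stamped output directory.

    ``stages`` restricts execution (later stages then expect earlier outputs
    on disk); with ``resume=True`` a stage whose outputs already exist is
    skipped.  A stage failure halts the run naming the stage and cause.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    todo = list(stages) if stages else list(STAGE_ORDER)
    for s in todo:
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage {s!r}")
    manifest_path = out / "manifest.json"
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGE_ORDER},
        "stages_completed": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if resume and manifest_path.exists():
        manifest["stages_completed"] = json.loads(manifest_path.read_text()).get(
            "stages_completed", []
        )

    state: dict = {}
    for stage in STAGE_ORDER:
        if stage not in todo:
            continue
        if resume and stage in manifest["stages_completed"]:
            logger.info("stage %s: resumed from existing outputs", stage)
            continue
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - halt with stage context
            raise PipelineError(stage, str(exc)) from exc
        if stage not in manifest["stages_completed"]:
            manifest["stages_completed"].append(stage)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_parent(config: PipelineConfig, state: dict):
    if "model" not in state:
        model = load_model(config.model_path)
        model = fix_carbon_bounds(model, config.carbon_uptake_limit)
        state["model"] = flux_consistent_subnetwork(model, config.activity_tol)
    return state["model"]


def _stage_preprocess(config: PipelineConfig, out: Path, state: dict) -> None:
    model = _load_parent(config, state)
    matrix = read_stage_matrix(config.expression_path)
    values = preprocess(matrix, model)
    _write_tsv(values, out / "gene_expression.tsv")
    rexp = {}
    for stage in config.stages:
        rexp[stage] = map_expression_to_reactions(model, values[stage])
    _write_tsv(pd.DataFrame(rexp), out / "reaction_expression.tsv")
    state["gene_values"] = values
    state["rexp"] = rexp


def _get_rexp(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "rexp" not in state:
        df = pd.read_csv(out / "reaction_expression.tsv", sep="\t", index_col=0)
        state["rexp"] = {s: df[s] for s in df.columns}
    return state["rexp"]


def _stage_extract(config: PipelineConfig, out: Path, state: dict) -> None:
    model = _load_parent(config, state)
    rexp = _get_rexp(config, out, state)
    state["context"] = {}
    for stage in config.stages:
        cm = extract_context_model(
            model,
            rexp[stage],
            config.extraction_method,
            config.threshold_scheme,
            eps=config.eps,
            tol=config.activity_tol,
        )
        save_model(cm.model, out / f"context_{stage}.json")
        state["context"][stage] = cm.model


def _get_context(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "context" not in state:
        state["context"] = {
            s: load_model(out / f"context_{s}.json") for s in config.stages
        }
    return state["context"]


def _stage_sample(config: PipelineConfig, out: Path, state: dict) -> None:
    context = _get_context(config, out, state)
    rexp = _get_rexp(config, out, state)
    seed = PipelineConfig.stage_seed(config, "sample")
    state["states"] = {}
    for i, stage in enumerate(config.stages):
        model = context[stage]
        exp = rexp[stage]
        if config.state_method == "lp":
            fs = lp_flux_state(model, exp)
        else:
            samples = sample_fluxes(
                model,
                n_points=config.n_points_multiplier * len(model.reactions),
                seed=seed + i,
            )
            fs = select_optimal_state(samples, exp)
        fs.fluxes.rename("flux").to_csv(out / f"state_{stage}.tsv", sep="\t")
        state["states"][stage] = fs


def _get_states(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "states" not in state:
        state["states"] = {}
        for s in config.stages:
            ser = pd.read_csv(out / f"state_{s}.tsv", sep="\t", index_col=0)["flux"]
            state["states"][s] = FluxState(fluxes=ser)
    return state["states"]


def _stage_functionality(config: PipelineConfig, out: Path, state: dict) -> None:
    model = _load_parent(config, state)
    context = _get_context(config, out, state)
    mets = []
    if config.metabolite_list_path:
        mets = [
            line.strip()
            for line in Path(config.metabolite_list_path).read_text().splitlines()
            if line.strip()
        ]
    if not mets:
        logger.warning("no essential-metabolite list; functionality stage skipped")
        return
    parent = add_sink_reactions(remove_objective_reaction(model), mets)
    sinks = sink_ids(mets)
    seed = config.stage_seed("functionality")
    report = {}
    for stage in config.stages:
        ctx_ids = {r.id for r in context[stage].reactions} | set(sinks)
        score = functionality_score(
            add_sink_reactions(remove_objective_reaction(context[stage]), mets),
            sinks,
            config.activity_tol,
        )
        sig = functionality_significance(
            parent,
            ctx_ids,
            sinks,
            iterations=config.significance_iterations,
            seed=seed,
            activity_tol=config.activity_tol,
        )
        report[stage] = {
            "met_score": score.met_score,
            "max_score": len(sinks),
            "p_value": sig.p_value,
        }
    (out / "functionality.json").write_text(json.dumps(report, indent=2))
    state["functionality"] = report


def _transitions(config: PipelineConfig) -> list[tuple[str, str, str]]:
    stages = list(config.stages)
    return [
        (f"t{i + 1}", stages[i], stages[i + 1]) for i in range(len(stages) - 1)
    ]


def _stage_perturb(config: PipelineConfig, out: Path, state: dict) -> None:
    model = _load_parent(config, state)
    states = _get_states(config, out, state)
    state["transitions"] = {}
    for name, a, b in _transitions(config):
        rep = perturbed_reactions(
            states[a],
            states[b],
            fold_cutoff=config.fold_cutoff,
            eps=config.activity_tol,
            transition=name,
        )
        _write_tsv(rep.perturbed, out / f"perturbed_{name}.tsv")
        enr = subsystem_enrichment(rep.perturbed_ids, model, rep.common_reactions)
        _write_tsv(enr, out / f"enrichment_{name}.tsv", index=False)
        state["transitions"][name] = rep


def _get_transitions(config: PipelineConfig, out: Path, state: dict) -> dict:
    if "transitions" not in state:
        states = _get_states(config, out, state)
        state["transitions"] = {}
        for name, a, b in _transitions(config):
            state["transitions"][name] = perturbed_reactions(
                states[a], states[b], config.fold_cutoff,
                config.activity_tol, name,
            )
    return state["transitions"]


def _evaluator_for(config: PipelineConfig, model, exp, stage_name: str):
    if config.state_method == "lp":
        return make_evaluator(model, exp, "lp")
    return make_evaluator(
        model,
        exp,
        "achr",
        n_points=config.n_points_multiplier * len(model.reactions),
        base_seed=config.stage_seed(stage_name),
    )


def _stage_modules(config: PipelineConfig, out: Path, state: dict) -> None:
    context = _get_context(config, out, state)
    rexp = _get_rexp(config, out, state)
    states = _get_states(config, out, state)
    transitions = _get_transitions(config, out, state)
    state["strategies"] = {}
    for name, a, b in _transitions(config):
        rep = transitions[name]
        later = context[b]
        ev = _evaluator_for(config, later, rexp[b], "modules")
        strats = greedy_module_search(
            later,
            states[a],
            rep.perturbed_ids,
            ev,
            internal_cutoff=config.internal_cutoff,
            external_cutoff=config.external_cutoff,
            n_strategies=config.n_strategies,
        )
        nonessential = _get_nonessential(config, out, state)
        for strat in strats:
            targetability(strat, nonessential, later)
        _write_tsv(strategies_table(strats), out / f"strategies_{name}.tsv", index=False)
        state["strategies"][name] = strats


def _stage_essentiality(config: PipelineConfig, out: Path, state: dict) -> None:
    if not config.normal_expression_path:
        logger.warning("no normal-tissue matrix; essentiality stage skipped")
        return
    model = _load_parent(config, state)
    biomass = [r for r in model.reactions if r.objective_coefficient]
    if not biomass:
        logger.warning("parent model has no objective; essentiality stage skipped")
        return
    normal = pd.read_csv(config.normal_expression_path, sep="\t", index_col=0)
    table = essentiality_screen(normal, model, biomass[0].id)
    _write_tsv(table, out / "essentiality.tsv")
    state["nonessential"] = nonessential_genes(table)


def _get_nonessential(config: PipelineConfig, out: Path, state: dict) -> set[str]:
    if "nonessential" not in state:
        path = out / "essentiality.tsv"
        if path.exists():
            table = pd.read_csv(path, sep="\t", index_col=0)
            state["nonessential"] = set(table.index[table["non_essential"]])
        else:
            model = _load_parent(config, state)
            state["nonessential"] = {g.id for g in model.genes}
    return state["nonessential"]


def _stage_knockout(config: PipelineConfig, out: Path, state: dict) -> None:
    context = _get_context(config, out, state)
    rexp = _get_rexp(config, out, state)
    states = _get_states(config, out, state)
    transitions = _get_transitions(config, out, state)
    nonessential = _get_nonessential(config, out, state)
    for name, a, b in _transitions(config):
        rep = transitions[name]
        later = context[b]
        genes = set()
        for rid in rep.perturbed_ids:
            if rid in later.reactions:
                genes |= set(later.reactions.get_by_id(rid).gpr.genes)
        candidates = sorted(genes & nonessential)
        ev = _evaluator_for(config, later, rexp[b], "knockout")
        results = knockout_screen(
            later, candidates, states[a], rep.perturbed_ids, ev,
            rep.baseline_correlation,
        )
        _write_tsv(results_table(results), out / f"knockout_{name}.tsv", index=False)


def _stage_drugs(config: PipelineConfig, out: Path, state: dict) -> None:
    if not config.drug_table_path:
        logger.warning("no drug table; drug stage skipped")
        return
    context = _get_context(config, out, state)
    rexp = _get_rexp(config, out, state)
    states = _get_states(config, out, state)
    transitions = _get_transitions(config, out, state)
    drugs = read_drug_table(config.drug_table_path)
    ic50 = (
        read_ic50_table(config.ic50_table_path)
        if config.ic50_table_path
        else None
    )
    for name, a, b in _transitions(config):
        rep = transitions[name]
        later = context[b]
        ev = _evaluator_for(config, later, rexp[b], "drugs")
        results = drug_screen(
            later, drugs, states[a], rep.perturbed_ids, ev,
            rep.baseline_correlation, inhibition=config.inhibition,
        )
        table = results_table(results)
        if ic50 is not None and len(table):
            zs = {}
            for drug_id in table["intervention"]:
                sub = ic50[ic50["drug_id"] == drug_id]
                row = sub[sub["cell_line"] == config.study_cell_line]
                if len(sub) > 1 and len(row):
                    zs[drug_id] = gdsc_zscore(
                        float(row["ic50"].iloc[0]), sub["ic50"].to_numpy()
                    )
            table["gdsc_zscore"] = table["intervention"].map(zs)
        _write_tsv(table, out / f"drugs_{name}.tsv", index=False)


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "extract": _stage_extract,
    "sample": _stage_sample,
    "functionality": _stage_functionality,
    "perturb": _stage_perturb,
    "modules": _stage_modules,
    "essentiality": _stage_essentiality,
    "knockout": _stage_knockout,
    "drugs": _stage_drugs,
}
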