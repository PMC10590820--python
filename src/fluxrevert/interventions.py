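"""In-silico intervention screens: essentiality, gene knockout, drug inhibition.

Candidate targets are genes catalysing transition-perturbed reactions.  To
avoid hitting cell-survival genes, essentiality is assessed on normal-tissue
expression: each normal sample yields an E-flux model (reaction bounds scaled
to the expression of the catalysing genes) and a gene is *non-essential* when
knocking it out leaves the biomass growth rate unchanged (ratio 1) in at
least a third of the normal models.

Knockouts use boolean GPR evaluation (a reaction is disabled only when its
rule evaluates false without the gene), whereas drug inhibition scales the
bounds of every reaction whose GPR *mentions* a target gene — partial
inhibition must dampen isozyme-backed reactions too.  Both screens re-estimate
the later-stage flux state and report the correlation with the initial-stage
state over the perturbed reactions, plus its log2 fold-change against the
transition baseline (correlations are floored at a small positive value so
the fold-change is defined when the baseline is near zero or negative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cobra import Model

from ._lp import LinearNetwork
from .expression import evaluate_gpr
from .modules import _NEG_INF, clamp_bounds, evaluate_modulated
from .network import ACTIVITY_TOL
from .sampling import FluxState

logger = logging.getLogger("fluxrevert")

#: E-flux maximum bound (model default bound scale)
B_MAX: float = 1000.0

#: floor applied to correlations before fold-changes, so log2 ratios exist
CORR_FLOOR: float = 0.01

#: default fractional bound reduction for the drug screen
DEFAULT_INHIBITION: float = 0.5

LOG2FC_FILTER: float = 2.0


@dataclass
class DrugRecord:
    """One drug with its target genes; only inhibitors are screened."""

    drug_id: str
    name: str
    targets: tuple[str, ...]
    inhibitor: bool = True

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"drug {self.drug_id} has no targets")


@dataclass
class InterventionResult:
    intervention: str  # gene or drug id
    kind: str  # "knockout" | "drug"
    targets: tuple[str, ...]
    affected_reactions: tuple[str, ...]
    inhibition: float
    correlation: float
    log2fc: float
    extra: dict = field(default_factory=dict)


def corr_log2fc(corr: float, baseline: float, floor: float = CORR_FLOOR) -> float:
    """log2 fold-change of correlation vs baseline, floored at *floor*."""
    return math.log2(max(corr, floor) / max(baseline, floor))


# ---------------------------------------------------------------------------
# E-flux and essentiality
# ---------------------------------------------------------------------------

def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Average-rank quantile normalization: identical distributions per column."""
    reference = np.sort(m.to_numpy(dtype=float), axis=0).mean(axis=1)
    ranks = np.arange(1, len(reference) + 1)
    return m.rank(method="average").apply(lambda col: np.interp(col, ranks, reference))


def eflux_bounds(
    model: Model, gene_expression: pd.Series, b_max: float = B_MAX
) -> Model:
    """Scale reaction bounds in proportion to catalysing-gene expression.

    Per reaction the GPR-evaluated expression e is mapped to an upper bound
    ``b = b_max * e / max(e over scored reactions)``; reversible reactions get
    ``lb = -b``, irreversible ``lb = 0``.  Reactions without expression keep
    their default bounds.  Raises when every gene is zero.
    """
    if (gene_expression.fillna(0) <= 0).all():
        raise ValueError("all-zero expression; E-flux bounds undefined")
    values = gene_expression.dropna().to_dict()
    rxn_exp = {}
    for rxn in model.reactions:
        e = evaluate_gpr(rxn.gpr, values)
        if not np.isnan(e):
            rxn_exp[rxn.id] = e
    if not rxn_exp:
        raise ValueError("no reaction obtained an expression value")
    scale = max(rxn_exp.values())
    if scale <= 0:
        raise ValueError("maximum reaction expression is non-positive")
    model = model.copy()
    for rxn in model.reactions:
        if rxn.id not in rxn_exp:
            continue
        b = b_max * rxn_exp[rxn.id] / scale
        reversible = rxn.lower_bound < 0
        rxn.lower_bound = -b if reversible else 0.0
        rxn.upper_bound = b
    return model


def _knockout_mask(model: Model, genes: Sequence[str]) -> np.ndarray:
    """Boolean array: True where the reaction's GPR evaluates false with
    *genes* knocked out (reaction disabled)."""
    ko = set(genes)
    out = np.zeros(len(model.reactions), dtype=bool)
    for i, rxn in enumerate(model.reactions):
        if rxn.gpr.body is None:
            continue
        if ko & set(rxn.gpr.genes) and not rxn.gpr.eval(knockouts=ko):
            out[i] = True
    return out


def gene_knockout(model: Model, gene: str) -> Model:
    """Copy of *model* with reactions requiring *gene* (GPR false) zeroed."""
    if gene not in {g.id for g in model.genes}:
        raise KeyError(f"unknown gene {gene!r}")
    model = model.copy()
    for rxn, dead in zip(model.reactions, _knockout_mask(model, [gene])):
        if dead:
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return model


def essentiality_screen(
    normal_expression: pd.DataFrame,
    model: Model,
    biomass_id: str,
    genes: Optional[Sequence[str]] = None,
    b_max: float = B_MAX,
    ratio_tol: float = 1e-6,
    normalize: bool = True,
) -> pd.DataFrame:
    """Growth-rate-ratio essentiality over a panel of normal-tissue samples.

    For every sample an E-flux model is built and the biomass maximum computed
    before and after each gene knockout.  Output: genes × samples frame of
    ratios plus a ``non_essential`` column — true when the ratio is 1 (within
    *ratio_tol*) in at least ⌈samples/3⌉ models.  Samples with zero baseline
    growth are skipped (logged).
    """
    if normalize:
        normal_expression = quantile_normalize(normal_expression)
    if genes is None:
        genes = [g.id for g in model.genes]
    ratios = pd.DataFrame(
        np.nan, index=list(genes), columns=list(normal_expression.columns)
    )
    for sample in normal_expression.columns:
        emodel = eflux_bounds(model, normal_expression[sample], b_max=b_max)
        net = LinearNetwork.from_model(emodel)
        j = net.index[biomass_id]
        full = np.ones(net.n, dtype=bool)
        base, _ = net.optimize(full, j, sense=-1)
        if np.isnan(base) or base <= ACTIVITY_TOL:
            logger.warning("sample %s: zero baseline growth; skipped", sample)
            continue
        lb0, ub0 = net.lb.copy(), net.ub.copy()
        for gene in genes:
            dead = _knockout_mask(emodel, [gene])
            if not dead.any():
                ratios.loc[gene, sample] = 1.0
                continue
            net.lb, net.ub = lb0.copy(), ub0.copy()
            net.lb[dead] = 0.0
            net.ub[dead] = 0.0
            after, _ = net.optimize(full, j, sense=-1)
            net.lb, net.ub = lb0, ub0
            ratios.loc[gene, sample] = 0.0 if np.isnan(after) else after / base
    n_models = ratios.notna().any(axis=0).sum()
    need = math.ceil(n_models / 3)
    is_one = (ratios - 1.0).abs() <= ratio_tol
    ratios["non_essential"] = is_one.sum(axis=1) >= need
    return ratios


def nonessential_genes(essentiality: pd.DataFrame) -> set[str]:
    return set(essentiality.index[essentiality["non_essential"]])


# ---------------------------------------------------------------------------
# knockout screen
# ---------------------------------------------------------------------------

def knockout_screen(
    context_model: Model,
    candidate_genes: Sequence[str],
    initial_state: FluxState,
    perturbed: Sequence[str],
    evaluator,
    baseline_correlation: float,
) -> list[InterventionResult]:
    """Evaluate single-gene knockouts by their power to restore the initial state.

    Candidates should be pre-filtered to non-essential genes catalysing
    perturbed reactions.  Per gene: disable GPR-false reactions, re-estimate
    the flux state, correlate with the initial state over the perturbed set,
    rank descending by correlation.  Deterministic at a fixed evaluator seed.
    """
    lb0 = np.array([r.lower_bound for r in context_model.reactions])
    ub0 = np.array([r.upper_bound for r in context_model.reactions])
    rids = [r.id for r in context_model.reactions]
    results = []
    for gene in sorted(candidate_genes):
        dead = _knockout_mask(context_model, [gene])
        lb, ub = lb0.copy(), ub0.copy()
        lb[dead] = 0.0
        ub[dead] = 0.0
        corr = evaluate_modulated(evaluator, lb, ub, initial_state, perturbed)
        if corr == _NEG_INF:
            logger.info("knockout of %s infeasible; skipped", gene)
            continue
        results.append(
            InterventionResult(
                intervention=gene,
                kind="knockout",
                targets=(gene,),
                affected_reactions=tuple(np.array(rids)[dead]),
                inhibition=1.0,
                correlation=corr,
                log2fc=corr_log2fc(corr, baseline_correlation),
            )
        )
    results.sort(key=lambda r: (-r.correlation, r.intervention))
    return results


# ---------------------------------------------------------------------------
# drug screens
# ---------------------------------------------------------------------------

def drug_target_reactions(model: Model, drug: DrugRecord) -> list[str]:
    """Reactions whose GPR mentions any target gene (membership, not boolean)."""
    targets = set(drug.targets)
    return [r.id for r in model.reactions if targets & set(r.gpr.genes)]


def apply_drug(model: Model, drug: DrugRecord, inhibition: float) -> Model:
    """Scale both bounds of every target-catalysed reaction by (1 − inhibition)."""
    if not (0.0 < inhibition <= 1.0):
        raise ValueError("inhibition fraction must be in (0, 1]")
    model = model.copy()
    for rid in drug_target_reactions(model, drug):
        rxn = model.reactions.get_by_id(rid)
        rxn.lower_bound *= 1.0 - inhibition
        rxn.upper_bound *= 1.0 - inhibition
    return model


def _drug_bounds(
    context_model: Model, drug: DrugRecord, inhibition: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    lb = np.array([r.lower_bound for r in context_model.reactions])
    ub = np.array([r.upper_bound for r in context_model.reactions])
    hit = drug_target_reactions(context_model, drug)
    idx = {r.id: i for i, r in enumerate(context_model.reactions)}
    for rid in hit:
        lb[idx[rid]] *= 1.0 - inhibition
        ub[idx[rid]] *= 1.0 - inhibition
    return lb, ub, hit


def inhibition_scan(
    context_model: Model,
    drug: DrugRecord,
    initial_state: FluxState,
    perturbed: Sequence[str],
    evaluator,
    levels: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    plateau_tol: float = 0.01,
) -> pd.DataFrame:
    """Correlation as a function of percentage bound inhibition (10%…100%).

    The returned frame carries a ``minimal_effective`` flag on the smallest
    level whose correlation is within *plateau_tol* of the curve's plateau
    (its maximum over the scanned levels).
    """
    rows = []
    for level in levels:
        lb, ub, hit = _drug_bounds(context_model, drug, float(level))
        corr = evaluate_modulated(evaluator, lb, ub, initial_state, perturbed)
        rows.append({"inhibition": float(level), "correlation": corr})
    out = pd.DataFrame(rows)
    finite = out["correlation"].replace(_NEG_INF, np.nan)
    plateau = finite.max()
    out["minimal_effective"] = False
    ok = finite >= plateau - plateau_tol
    if ok.any():
        out.loc[ok.idxmax(), "minimal_effective"] = True
    return out


def drug_screen(
    context_model: Model,
    drugs: Sequence[DrugRecord],
    initial_state: FluxState,
    perturbed: Sequence[str],
    evaluator,
    baseline_correlation: float,
    inhibition: float = DEFAULT_INHIBITION,
    log2fc_filter: float = LOG2FC_FILTER,
) -> list[InterventionResult]:
    """Screen inhibitor drugs at a fixed bound inhibition (default 50%).

    Non-inhibitors are skipped (logged); drugs with no target mapping to
    model reactions are skipped.  Each result carries the achieved correlation
    and its log2 fold-change vs baseline; ``extra['passes_filter']`` flags
    log2FC > *log2fc_filter* and ``extra['multi_target']`` the target count.
    """
    results = []
    for drug in drugs:
        if not drug.inhibitor:
            logger.info("drug %s is not an inhibitor; skipped", drug.drug_id)
            continue
        lb, ub, hit = _drug_bounds(context_model, drug, inhibition)
        if not hit:
            continue
        corr = evaluate_modulated(evaluator, lb, ub, initial_state, perturbed)
        if corr == _NEG_INF:
            logger.info("drug %s renders the model infeasible; skipped", drug.drug_id)
            continue
        fc = corr_log2fc(corr, baseline_correlation)
        results.append(
            InterventionResult(
                intervention=drug.drug_id,
                kind="drug",
                targets=drug.targets,
                affected_reactions=tuple(hit),
                inhibition=inhibition,
                correlation=corr,
                log2fc=fc,
                extra={
                    "name": drug.name,
                    "passes_filter": fc > log2fc_filter,
                    "multi_target": len(drug.targets) > 1,
                },
            )
        )
    results.sort(key=lambda r: (-r.correlation, r.intervention))
    return results


# ---------------------------------------------------------------------------
# GDSC comparison and pathway overlap
# ---------------------------------------------------------------------------

def gdsc_zscore(
    ic50_value: float,
    ic50_all_cell_lines: Sequence[float],
    printed_variance_denominator: bool = False,
) -> float:
    """Standardized IC50 of a drug for one cell line vs all screened lines.

    The standard z-score ``(x − μ)/σ`` with the population σ.  The audit mode
    ``printed_variance_denominator=True`` divides by σ² instead.
    """
    arr = np.asarray(ic50_all_cell_lines, dtype=float)
    mu, sigma = arr.mean(), arr.std()
    if sigma == 0:
        raise ValueError("zero variance of IC50 across cell lines")
    denom = sigma**2 if printed_variance_denominator else sigma
    return float((ic50_value - mu) / denom)


def drug_pathway_overlap(drug: DrugRecord, model: Model) -> pd.DataFrame:
    """Per subsystem: fraction of its reactions targeted by the drug.

    Only subsystems containing at least one targeted reaction appear; the
    overlap value lies in (0, 1].
    """
    hit = set(drug_target_reactions(model, drug))
    rows = []
    subsystems: dict[str, list[str]] = {}
    for rxn in model.reactions:
        subsystems.setdefault(rxn.subsystem or "unassigned", []).append(rxn.id)
    for lab, members in sorted(subsystems.items()):
        k = len(hit & set(members))
        if k:
            rows.append(
                {"subsystem": lab, "targeted": k, "pathway_size": len(members),
                 "overlap_value": k / len(members)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_drug_table(path) -> list[DrugRecord]:
    """Drug TSV: drug_id, drug_name, action, target_gene_ids (semicolon list)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            DrugRecord(
                drug_id=row["drug_id"],
                name=row.get("drug_name", row["drug_id"]),
                targets=tuple(t for t in str(row["target_gene_ids"]).split(";") if t),
                inhibitor=str(row.get("action", "inhibitor")).lower() == "inhibitor",
            )
        )
    return out


def write_drug_table(drugs: Sequence[DrugRecord], path) -> None:
    pd.DataFrame(
        {
            "drug_id": [d.drug_id for d in drugs],
            "drug_name": [d.name for d in drugs],
            "action": ["inhibitor" if d.inhibitor else "other" for d in drugs],
            "target_gene_ids": [";".join(d.targets) for d in drugs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_ic50_table(path) -> pd.DataFrame:
    """IC50 TSV: drug_id, cell_line, ic50."""
    df = pd.read_csv(path, sep="\t")
    df["ic50"] = df["ic50"].astype(float)
    return df


def results_table(results: Sequence[InterventionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "intervention": r.intervention,
            "kind": r.kind,
            "targets": ";".join(r.targets),
            "n_affected_reactions": len(r.affected_reactions),
            "inhibition": r.inhibition,
            "correlation": r.correlation,
            "log2fc": r.log2fc,
        }
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows)
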