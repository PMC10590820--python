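"""Stage-wise proteomic preprocessing and GPR-based reaction expression.

The abundance matrix is a :class:`pandas.DataFrame` with protein/gene ids in
the index and a two-level column MultiIndex ``(stage, replicate)``; stages are
ordered (here monolayer → moruloid → blastuloid).  The preprocessing order is
fixed:

    drop all-missing rows → 50%-replicate filter → per-stage imputation →
    replicate merge (mean) → log10 → intersect with model genes

after which :func:`map_expression_to_reactions` evaluates each reaction's GPR
rule over the gene values (AND = min over scored children, OR = max) to yield
the per-reaction expression array used by every extraction method.
"""

from __future__ import annotations

import ast
import logging
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd
from cobra import Model
from cobra.core.gene import GPR
from scipy import stats

logger = logging.getLogger("fluxrevert")

STAGES = ("monolayer", "moruloid", "blastuloid")


def _check_matrix(m: pd.DataFrame) -> None:
    if not isinstance(m.columns, pd.MultiIndex) or m.columns.nlevels != 2:
        raise ValueError("expected a (stage, replicate) column MultiIndex")
    for stage in m.columns.get_level_values(0).unique():
        if m[stage].shape[1] < 1:
            raise ValueError(f"stage {stage!r} has no replicates")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def filter_proteins(m: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins observed in ≥50% of the replicates of at least one stage.

    Rows missing in every sample are removed first; an empty result is legal
    (logged).
    """
    _check_matrix(m)
    m = m.loc[~m.isna().all(axis=1)]
    keep = pd.Series(False, index=m.index)
    for stage in m.columns.get_level_values(0).unique():
        block = m[stage]
        frac = block.notna().sum(axis=1) / block.shape[1]
        keep |= frac >= 0.5
    out = m.loc[keep]
    if out.empty:
        logger.warning("replicate filter removed every protein")
    return out


def impute(m: pd.DataFrame, replace_whole_stage: bool = True) -> pd.DataFrame:
    """Fill missing abundances stage by stage.

    For each protein and stage: if the protein is observed in ≥50% of that
    stage's replicates, missing cells become the mean of the observed
    replicates; otherwise the stage's cells are set to the global minimum of
    the filtered matrix.  With ``replace_whole_stage=False`` an observed
    singleton in a failing stage keeps its value and only the missing cells
    take the global minimum.
    """
    _check_matrix(m)
    out = m.copy().astype(float)
    global_min = np.nanmin(m.to_numpy(dtype=float)) if m.size else np.nan
    for stage in m.columns.get_level_values(0).unique():
        block = out[stage]
        n_rep = block.shape[1]
        frac = block.notna().sum(axis=1) / n_rep
        good = frac >= 0.5
        # mean-impute within stages that pass the 50% rule
        means = block.loc[good].mean(axis=1).reindex(block.index)
        for col in block.columns:
            mask = good & block[col].isna()
            out.loc[mask, (stage, col)] = means[mask]
        bad = ~good
        if replace_whole_stage:
            for col in block.columns:
                out.loc[bad, (stage, col)] = global_min
        else:
            for col in block.columns:
                mask = bad & block[col].isna()
                out.loc[mask, (stage, col)] = global_min
    assert not out.isna().any().any()
    return out


def collapse_and_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Merge replicates by their mean per stage, then log10.

    Returns an entity × stage frame.  Raises if any merged value is
    non-positive (cannot occur after imputation of a positive matrix).
    """
    _check_matrix(m)
    merged = m.T.groupby(level=0, sort=False).mean().T
    stages = list(dict.fromkeys(m.columns.get_level_values(0)))
    merged = merged[stages]
    if (merged <= 0).any().any():
        raise ValueError("non-positive merged abundance at log10 step")
    return np.log10(merged)


def intersect_model_genes(values: pd.DataFrame, model: Model) -> pd.DataFrame:
    """Restrict a per-stage value frame to genes present in the model."""
    gene_ids = [g.id for g in model.genes]
    return values.loc[values.index.intersection(gene_ids)]


def preprocess(
    m: pd.DataFrame, model: Optional[Model] = None, replace_whole_stage: bool = True
) -> pd.DataFrame:
    """Run the full preprocessing chain; returns log10 entity × stage values."""
    out = collapse_and_normalize(impute(filter_proteins(m), replace_whole_stage))
    if model is not None:
        out = intersect_model_genes(out, model)
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def differential_expression(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    log2fc_cutoff: float = 1.0,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-entity log2 fold-change (B vs A) and Welch t-test p-value.

    Entities are flagged up/down at ``|log2FC| >= log2fc_cutoff`` and
    ``p < alpha``.  Zero variance in both groups with equal means gives p = 1.
    ``adjust=True`` adds Benjamini–Hochberg adjusted p-values.
    """
    common = group_a.index.intersection(group_b.index)
    a = group_a.loc[common].to_numpy(dtype=float)
    b = group_b.loc[common].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_b / mean_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(tt.pvalue, dtype=float)
    degenerate = np.isnan(p)
    p[degenerate & np.isclose(mean_a, mean_b)] = 1.0
    out = pd.DataFrame({"log2fc": log2fc, "pvalue": p}, index=common)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        out["padj"] = multipletests(out["pvalue"].fillna(1.0), method="fdr_bh")[1]
    crit = out["padj"] if adjust else out["pvalue"]
    out["direction"] = np.select(
        [
            (out["log2fc"] >= log2fc_cutoff) & (crit < alpha),
            (out["log2fc"] <= -log2fc_cutoff) & (crit < alpha),
        ],
        ["up", "down"],
        default="ns",
    )
    return out


# ---------------------------------------------------------------------------
# GPR parsing and evaluation
# ---------------------------------------------------------------------------

def parse_gpr(rule: str) -> GPR:
    """Parse a GPR rule string into a boolean AST over gene ids.

    Supports parentheses and case-insensitive and/or.  The empty rule yields
    an empty AST; unbalanced parentheses raise ``ValueError``.
    """
    rule = (rule or "").strip()
    if not rule:
        return GPR()
    try:
        gpr = GPR.from_string(rule)
    except SyntaxError as exc:
        raise ValueError(f"malformed GPR rule {rule!r}: {exc}") from exc
    if rule and gpr.body is None:
        raise ValueError(f"malformed GPR rule {rule!r}")
    return gpr


def render_gpr(gpr: GPR) -> str:
    """Render an AST back to a rule string (round-trips through parse_gpr)."""
    return gpr.to_string()


def evaluate_gpr(
    gpr: GPR,
    gene_values: Mapping[str, float],
    and_func: Callable[[list[float]], float] = min,
    or_func: Callable[[list[float]], float] = max,
) -> float:
    """Evaluate a GPR AST over numeric gene values (AND=min, OR=max).

    Genes without data are ignored within an operator as long as at least one
    child is scored; the result is NaN only when no leaf has data (or the rule
    is empty).
    """
    if gpr.body is None:
        return float("nan")

    def walk(node: ast.AST) -> float:
        if isinstance(node, ast.Name):
            v = gene_values.get(node.id, float("nan"))
            return float(v) if v is not None else float("nan")
        if isinstance(node, ast.BoolOp):
            vals = [walk(c) for c in node.values]
            scored = [v for v in vals if not np.isnan(v)]
            if not scored:
                return float("nan")
            return and_func(scored) if isinstance(node.op, ast.And) else or_func(scored)
        if isinstance(node, ast.Expression):
            return walk(node.body)
        raise ValueError(f"unsupported GPR node {ast.dump(node)}")

    return walk(gpr.body)


def map_expression_to_reactions(
    model: Model,
    gene_values: Mapping[str, float] | pd.Series,
    and_func: Callable[[list[float]], float] = min,
    or_func: Callable[[list[float]], float] = max,
) -> pd.Series:
    """GPR-evaluate gene values into a per-reaction expression array.

    Reactions with an empty GPR, or whose genes all lack data, are NaN.  The
    mapping is monotone: raising a gene value never lowers any reaction value.
    """
    if isinstance(gene_values, pd.Series):
        gene_values = gene_values.dropna().to_dict()
    out = {}
    for rxn in model.reactions:
        out[rxn.id] = evaluate_gpr(rxn.gpr, gene_values, and_func, or_func)
    return pd.Series(out, name="reaction_expression", dtype=float)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_stage_matrix(path) -> pd.DataFrame:
    """Read a TSV abundance matrix with a two-level (stage, replicate) header."""
    m = pd.read_csv(path, sep="\t", header=[0, 1], index_col=0)
    _check_matrix(m)
    return m


def write_stage_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t")
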