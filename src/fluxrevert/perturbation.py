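"""Transition-perturbed reactions, baseline correlation, subsystem enrichment.

A phenotypic transition is compared through the flux states of its two stage
models.  On the reactions common to both models, a reaction is *perturbed*
when its flux magnitude changes by at least a two-fold cut-off (with an
activity noise floor ε below which fluxes count as zero), or when the flux
flips sign with both magnitudes above ε.  The Pearson correlation of the two
stages' flux profiles over the perturbed set is the transition's baseline —
a low value certifies a genuine metabolic shift that downstream modulation
tries to raise back towards 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model
from scipy import stats

from .network import ACTIVITY_TOL
from .sampling import FluxState

logger = logging.getLogger("fluxrevert")

FOLD_CUTOFF: float = 2.0


@dataclass
class TransitionReport:
    """Perturbation summary of one stage transition."""

    transition: str
    common_reactions: list[str]
    perturbed: pd.DataFrame  # index: reaction id; columns: flux_a, flux_b, log2fc
    baseline_correlation: float = float("nan")

    @property
    def perturbed_ids(self) -> list[str]:
        return list(self.perturbed.index)


def perturbed_reactions(
    state_a: FluxState,
    state_b: FluxState,
    fold_cutoff: float = FOLD_CUTOFF,
    eps: float = ACTIVITY_TOL,
    transition: str = "",
) -> TransitionReport:
    """Reactions whose flux changes ≥ *fold_cutoff* between two stage states.

    The ratio is taken on magnitudes floored at ε; the cut-off is inclusive in
    both directions.  A sign flip with both magnitudes above ε is perturbed
    regardless of the magnitude ratio.  The baseline correlation over the
    perturbed set is attached when it is defined.
    """
    common = [r for r in state_a.fluxes.index if r in state_b.fluxes.index]
    if not common:
        raise ValueError("stage flux states share no reactions")
    va = state_a.fluxes[common].to_numpy(dtype=float)
    vb = state_b.fluxes[common].to_numpy(dtype=float)
    ma, mb = np.maximum(np.abs(va), eps), np.maximum(np.abs(vb), eps)
    ratio = mb / ma
    fold = (ratio >= fold_cutoff) | (ratio <= 1.0 / fold_cutoff)
    sign_flip = (np.sign(va) * np.sign(vb) < 0) & (np.abs(va) > eps) & (np.abs(vb) > eps)
    mask = fold | sign_flip
    table = pd.DataFrame(
        {
            "flux_a": va[mask],
            "flux_b": vb[mask],
            "log2fc": np.log2(ratio[mask]),
        },
        index=pd.Index(np.asarray(common)[mask], name="reaction"),
    )
    report = TransitionReport(transition, common, table)
    if len(table) >= 3:
        try:
            report.baseline_correlation = baseline_correlation(
                state_a, state_b, list(table.index)
            )
        except ValueError as exc:
            logger.warning("baseline correlation undefined: %s", exc)
    return report


def baseline_correlation(
    state_a: FluxState, state_b: FluxState, reactions: list[str]
) -> float:
    """Pearson correlation of two flux vectors restricted to *reactions*."""
    if len(reactions) < 3:
        raise ValueError("need >= 3 reactions for a correlation")
    a = state_a.fluxes.reindex(reactions).to_numpy(dtype=float)
    b = state_b.fluxes.reindex(reactions).to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("reaction missing from one of the states")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero-variance flux profile")
    return float(np.corrcoef(a, b)[0, 1])


def subsystem_enrichment(
    perturbed: list[str] | set[str],
    model: Model,
    universe: list[str] | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of subsystems in the perturbed set.

    For each subsystem with K reactions in the universe (default: all model
    reactions) of size N, the p-value is the probability of seeing ≥ k
    perturbed reactions among K when n are perturbed overall.  Reactions
    without a subsystem pool under "unassigned".  Rows sorted by p.
    """
    subsys: dict[str, str] = {}
    for rxn in model.reactions:
        subsys[rxn.id] = rxn.subsystem or "unassigned"
    if universe is None:
        universe = list(subsys)
    universe = [r for r in universe if r in subsys]
    perturbed_set = {r for r in perturbed if r in universe}
    N, n = len(universe), len(perturbed_set)
    rows = []
    labels = sorted({subsys[r] for r in universe})
    for lab in labels:
        members = {r for r in universe if subsys[r] == lab}
        K = len(members)
        k = len(members & perturbed_set)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"subsystem": lab, "overlap": k, "pathway_size": K, "n_perturbed": n,
             "universe": N, "pvalue": p}
        )
    out = pd.DataFrame(rows).sort_values(["pvalue", "subsystem"]).reset_index(drop=True)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["padj"] < alpha
    elif len(out):
        out["significant"] = out["pvalue"] < alpha
    return out
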