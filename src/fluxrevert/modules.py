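"""Greedy search for reaction-modulation modules that revert a transition.

A transition's later-stage model is nudged back towards the initial stage by
*modulating* perturbed reactions: the bounds of a reaction are clamped to the
span of its flux in the initial-stage state (``ref``),

    ref < 0  →  (lb, ub) = (ref, 0)
    ref > 0  →  (lb, ub) = (0, ref)
    ref = 0  →  (0, 0)

after which the later-stage model's flux state is re-estimated and its
Pearson correlation with the initial-stage state over the perturbed set is
the figure of merit.  Single-reaction modulation ranks candidates; the greedy
multi-reaction search then grows modules from the top single modulations,
accepting a clamp only when it raises the correlation by at least the
internal cut-off (0.001) and iterating levels until the gain between
consecutive levels falls below the external cut-off (0.01).

Re-estimating the flux state after every candidate clamp is the cost centre.
Two evaluators are provided: a deterministic LP evaluator that picks the
expression-aligned extreme flux vector (one LP per candidate; the default),
and an ACHR sampling evaluator matching the stage-state protocol with a
configurable point budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cobra import Model
from scipy.optimize import linprog

from ._lp import LinearNetwork
from .sampling import FluxState, sample_fluxes, select_optimal_state

logger = logging.getLogger("fluxrevert")

INTERNAL_CUTOFF: float = 0.001
EXTERNAL_CUTOFF: float = 0.01
N_STRATEGIES: int = 20

_NEG_INF = float("-inf")


@dataclass
class ModulationStrategy:
    """An ordered set of clamped reactions and the correlation it achieves."""

    seed_reaction: str
    reactions: list[str]
    ref_fluxes: dict[str, float]
    correlation: float
    levels: int
    trace: list[float] = field(default_factory=list)
    targetability: Optional[float] = None

    def __len__(self) -> int:
        return len(self.reactions)


# ---------------------------------------------------------------------------
# clamping
# ---------------------------------------------------------------------------

def clamp_bounds(ref_flux: float) -> tuple[float, float]:
    """Bounds pinning a reaction to the direction and span of its reference flux."""
    if ref_flux < 0:
        return (float(ref_flux), 0.0)
    if ref_flux > 0:
        return (0.0, float(ref_flux))
    return (0.0, 0.0)


def clamp_to_reference(model: Model, reaction_id: str, ref_flux: float) -> Model:
    """Copy of *model* with one reaction clamped to its reference flux."""
    model = model.copy()
    rxn = model.reactions.get_by_id(reaction_id)  # raises on absent id
    rxn.lower_bound, rxn.upper_bound = clamp_bounds(ref_flux)
    return model


# ---------------------------------------------------------------------------
# state evaluators
# ---------------------------------------------------------------------------

class LPStateEvaluator:
    """Deterministic surrogate for the sampled expression-optimal state.

    Maximises the standardized-expression-weighted sum of fluxes over the
    scored reactions, so highly expressed reactions are pushed towards their
    bounds and lowly expressed ones towards zero — the extreme point the
    max-correlation selection gravitates to.  One LP per evaluation.
    """

    def __init__(self, model: Model, exp: pd.Series):
        self.net = LinearNetwork.from_model(model)
        scored = [r for r in self.net.rids if not pd.isna(exp.get(r, np.nan))]
        z = exp[scored].to_numpy(dtype=float)
        sd = z.std()
        z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
        self.c = np.zeros(self.net.n)
        for r, w in zip(scored, z):
            self.c[self.net.index[r]] = -w  # linprog minimises
        self.rids = self.net.rids

    def evaluate(self, lb: np.ndarray, ub: np.ndarray) -> Optional[np.ndarray]:
        res = linprog(
            self.c,
            A_eq=self.net.S,
            b_eq=np.zeros(self.net.S.shape[0]),
            bounds=list(zip(lb, ub)),
            method="highs",
        )
        if not res.success:
            return None
        return res.x


class SamplingStateEvaluator:
    """Sampling evaluator: resample the modulated model with the same ACHR
    protocol as the stage states and select the expression-optimal sample.
    Seeds derive deterministically from a base seed and an evaluation
    counter."""

    def __init__(
        self,
        model: Model,
        exp: pd.Series,
        n_points: int = 50,
        base_seed: int = 0,
        thinning: int = 10,
    ):
        self.template = model
        self.exp = exp
        self.n_points = n_points
        self.base_seed = base_seed
        self.thinning = thinning
        self.rids = [r.id for r in model.reactions]
        self._counter = 0

    def evaluate(self, lb: np.ndarray, ub: np.ndarray) -> Optional[np.ndarray]:
        self._counter += 1
        model = self.template.copy()
        for rxn, lo, hi in zip(model.reactions, lb, ub):
            rxn.lower_bound, rxn.upper_bound = float(lo), float(hi)
        seed = (self.base_seed * 1_000_003 + self._counter) % (2**31 - 1)
        try:
            samples = sample_fluxes(
                model, n_points=self.n_points, seed=seed, thinning=self.thinning
            )
            state = select_optimal_state(samples, self.exp)
        except (ValueError, RuntimeError) as exc:
            logger.debug("evaluator failed (%s); candidate rejected", exc)
            return None
        return state.fluxes.reindex(self.rids).to_numpy(dtype=float)


def make_evaluator(
    model: Model, exp_later: pd.Series, method: str = "lp", **kwargs
):
    if method == "lp":
        return LPStateEvaluator(model, exp_later)
    if method == "achr":
        return SamplingStateEvaluator(model, exp_later, **kwargs)
    raise ValueError(f"unknown evaluator method {method!r}")


def lp_flux_state(model: Model, exp: pd.Series) -> FluxState:
    """Deterministic stage flux state from the LP evaluator.

    The expression-aligned extreme point of the flux polytope; a fast,
    seed-free alternative to the sampled max-correlation state with the same
    interface.  Raises on an infeasible model.
    """
    ev = LPStateEvaluator(model, exp)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    v = ev.evaluate(lb, ub)
    if v is None:
        raise ValueError("model infeasible; no flux state")
    fluxes = pd.Series(v, index=ev.rids)
    scored = [r for r in exp.index if not pd.isna(exp[r]) and r in fluxes.index]
    corr = float("nan")
    if len(scored) >= 3:
        x = np.abs(fluxes[scored].to_numpy())
        e = exp[scored].to_numpy(dtype=float)
        if x.std() > 0 and e.std() > 0:
            corr = float(np.corrcoef(x, e)[0, 1])
    return FluxState(fluxes=fluxes, correlation=corr, sample_index=-1)


# ---------------------------------------------------------------------------
# correlation bookkeeping
# ---------------------------------------------------------------------------

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return _NEG_INF
    r = float(np.corrcoef(x, y)[0, 1])
    return r if not np.isnan(r) else _NEG_INF


def _corr_against_initial(
    v: Optional[np.ndarray],
    evaluator,
    initial_state: FluxState,
    perturbed: Sequence[str],
) -> float:
    if v is None:
        return _NEG_INF
    idx = {r: i for i, r in enumerate(evaluator.rids)}
    # canonical order: the float result must not depend on caller ordering
    cols = sorted(r for r in perturbed if r in idx)
    if len(cols) < 3:
        return _NEG_INF
    ref = initial_state.fluxes.reindex(cols).to_numpy(dtype=float)
    cur = np.array([v[idx[r]] for r in cols])
    return _pearson(cur, ref)


def evaluate_modulated(
    evaluator,
    lb: np.ndarray,
    ub: np.ndarray,
    initial_state: FluxState,
    perturbed: Sequence[str],
) -> float:
    """Correlation of the modulated model's re-estimated state with the
    initial-stage state over the perturbed set; −inf when the clamp makes the
    model infeasible or the correlation undefined (candidate rejected)."""
    return _corr_against_initial(
        evaluator.evaluate(lb, ub), evaluator, initial_state, perturbed
    )


# ---------------------------------------------------------------------------
# scans and greedy search
# ---------------------------------------------------------------------------

def _base_bounds(model: Model) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return lb, ub


def single_modulation_scan(
    later_model: Model,
    initial_state: FluxState,
    perturbed: Sequence[str],
    evaluator,
) -> pd.DataFrame:
    """Clamp each perturbed reaction individually and rank by correlation.

    Returns a frame (reaction, correlation) sorted descending, ties broken by
    reaction id; reactions whose clamp is infeasible are dropped (warning when
    none survive).
    """
    lb0, ub0 = _base_bounds(later_model)
    idx = {r.id: i for i, r in enumerate(later_model.reactions)}
    rows = []
    for rid in sorted(perturbed):
        if rid not in idx:
            continue
        ref = float(initial_state.fluxes.get(rid, np.nan))
        if np.isnan(ref):
            continue
        lb, ub = lb0.copy(), ub0.copy()
        lb[idx[rid]], ub[idx[rid]] = clamp_bounds(ref)
        corr = evaluate_modulated(evaluator, lb, ub, initial_state, perturbed)
        if corr == _NEG_INF:
            logger.debug("single modulation of %s infeasible/undefined", rid)
            continue
        rows.append({"reaction": rid, "correlation": corr})
    if not rows:
        logger.warning("every single modulation was infeasible")
        return pd.DataFrame(columns=["reaction", "correlation"])
    out = pd.DataFrame(rows).sort_values(
        ["correlation", "reaction"], ascending=[False, True]
    )
    return out.reset_index(drop=True)


def greedy_module_search(
    later_model: Model,
    initial_state: FluxState,
    perturbed: Sequence[str],
    evaluator,
    internal_cutoff: float = INTERNAL_CUTOFF,
    external_cutoff: float = EXTERNAL_CUTOFF,
    n_strategies: int = N_STRATEGIES,
    max_levels: int = 20,
    ranking: Optional[pd.DataFrame] = None,
) -> list[ModulationStrategy]:
    """Grow modulation modules greedily from the top single modulations.

    Each of the top ``n_strategies`` single modulations seeds one strategy.
    Within a level, candidates are attempted in single-scan rank order; a
    clamp is kept only if it raises the correlation by ``internal_cutoff``.
    Levels repeat until the inter-level gain drops below ``external_cutoff``.
    The recorded correlation trace is non-decreasing by construction.
    """
    if ranking is None:
        ranking = single_modulation_scan(later_model, initial_state, perturbed, evaluator)
    if ranking.empty:
        return []
    lb0, ub0 = _base_bounds(later_model)
    idx = {r.id: i for i, r in enumerate(later_model.reactions)}
    order = list(ranking["reaction"])
    strategies: list[ModulationStrategy] = []
    for _, seed_row in ranking.head(n_strategies).iterrows():
        seed = seed_row["reaction"]
        lb, ub = lb0.copy(), ub0.copy()
        ref = float(initial_state.fluxes[seed])
        lb[idx[seed]], ub[idx[seed]] = clamp_bounds(ref)
        corr = float(seed_row["correlation"])
        accepted = [seed]
        refs = {seed: ref}
        trace = [corr]
        levels = 0
        while levels < max_levels:
            levels += 1
            level_start = corr
            for rid in order:
                if rid in accepted:
                    continue
                r = float(initial_state.fluxes.get(rid, np.nan))
                if np.isnan(r):
                    continue
                lo, hi = clamp_bounds(r)
                old = (lb[idx[rid]], ub[idx[rid]])
                lb[idx[rid]], ub[idx[rid]] = lo, hi
                c = evaluate_modulated(evaluator, lb, ub, initial_state, perturbed)
                if c >= corr + internal_cutoff:
                    corr = c
                    accepted.append(rid)
                    refs[rid] = r
                    trace.append(c)
                else:
                    lb[idx[rid]], ub[idx[rid]] = old  # revert
            if corr - level_start < external_cutoff:
                break
        strategies.append(
            ModulationStrategy(
                seed_reaction=seed,
                reactions=accepted,
                ref_fluxes=refs,
                correlation=corr,
                levels=levels,
                trace=trace,
            )
        )
    strategies.sort(key=lambda s: (-s.correlation, s.seed_reaction))
    return strategies


def targetability(
    strategy: ModulationStrategy,
    nonessential_genes: set[str],
    model: Model,
) -> Optional[float]:
    """Percent of the strategy's catalysing genes that are non-essential.

    Genes are the union over the strategy's reactions' GPR rules; a strategy
    with no gene-associated reaction has an undefined score (None).
    """
    genes: set[str] = set()
    for rid in strategy.reactions:
        if rid in model.reactions:
            genes |= set(model.reactions.get_by_id(rid).gpr.genes)
    if not genes:
        return None
    score = 100.0 * len(genes & nonessential_genes) / len(genes)
    strategy.targetability = score
    return score


def strategies_table(strategies: list[ModulationStrategy]) -> pd.DataFrame:
    """Flatten strategies for TSV export."""
    rows = []
    for i, s in enumerate(strategies, start=1):
        rows.append(
            {
                "strategy": f"S{i}",
                "seed_reaction": s.seed_reaction,
                "n_reactions": len(s),
                "reactions": ";".join(s.reactions),
                "correlation": s.correlation,
                "levels": s.levels,
                "targetability": s.targetability,
            }
        )
    return pd.DataFrame(rows)
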