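"""Steady-state flux sampling, optimal-state selection and functionality score.

Context models are objective-free, so their behaviour is summarised by
uniformly sampling the steady-state polytope ``{v : S v = 0, lb <= v <= ub}``
with an artificial-centering hit-and-run sampler and then selecting, out of
the sample set ``E = {f_(i,j)}``, the single flux vector whose (Pearson)
correlation with the reaction-expression array is maximal.  That vector is
the stage's *flux state* F and every downstream comparison (perturbation
detection, modulation, intervention screens) is made between such states.

The metabolic functionality score counts how many growth-essential
metabolites (surrogate biomass components, exposed as sink reactions) the
model can produce above the activity threshold; its significance is assessed
against random same-size flux-consistent submodels of the parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cobra import Model
from cobra.sampling import ACHRSampler

from ._lp import LinearNetwork
from .network import ACTIVITY_TOL, _configure

logger = logging.getLogger("fluxrevert")

#: steady-state feasibility tolerance |S v| for sample validation
FEASIBILITY_TOL: float = 1e-6


@dataclass
class FluxSampleSet:
    """Sampled flux vectors: rows are samples, columns are reactions."""

    samples: pd.DataFrame
    seed: Optional[int] = None
    thinning: int = 1
    n_points: int = 0

    def __post_init__(self):
        self.n_points = len(self.samples)


@dataclass
class FluxState:
    """One flux value per reaction plus selection provenance."""

    fluxes: pd.Series
    correlation: float = float("nan")
    sample_index: int = -1
    seed: Optional[int] = None

    def restrict(self, reaction_ids: Sequence[str]) -> pd.Series:
        return self.fluxes.reindex(reaction_ids)


@dataclass
class FunctionalityResult:
    met_score: int
    per_sink_flux: pd.Series
    p_value: float = float("nan")
    random_scores: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_fluxes(
    model: Model,
    n_points: Optional[int] = None,
    seed: Optional[int] = None,
    thinning: int = 10,
    validate: bool = True,
) -> FluxSampleSet:
    """Uniformly sample the steady-state flux polytope (ACHR sampler).

    ``n_points`` defaults to twice the number of reactions; the chain is
    thinned (default 10) to decorrelate consecutive hit-and-run steps.  Samples violating
    feasibility at :data:`FEASIBILITY_TOL` are rejected and redrawn (logged).
    Reproducible bit-for-bit for a fixed seed.
    """
    if len(model.reactions) == 0:
        raise ValueError("cannot sample an empty model")
    if n_points is None:
        n_points = 2 * len(model.reactions)
    model = _configure(model.copy())
    if model.optimize(objective_sense=None).status == "infeasible":
        raise ValueError("model is infeasible; nothing to sample")
    sampler = ACHRSampler(model, thinning=thinning, seed=seed)
    draws = sampler.sample(n_points)
    if validate:
        codes = sampler.validate(draws.to_numpy())
        bad = codes != "v"
        n_retry = 0
        while bad.any() and n_retry < 5:
            n_retry += 1
            logger.warning(
                "%d sampled points escaped the polytope; redrawing", int(bad.sum())
            )
            redraw = sampler.sample(int(bad.sum()))
            draws.iloc[np.flatnonzero(bad)] = redraw.to_numpy()
            codes = sampler.validate(draws.to_numpy())
            bad = codes != "v"
        if bad.any():
            raise RuntimeError("sampler failed to produce feasible points")
    draws.index = range(len(draws))
    return FluxSampleSet(draws, seed=seed, thinning=thinning)


def select_optimal_state(
    samples: FluxSampleSet,
    exp: pd.Series,
    signed: bool = False,
    method: str = "pearson",
) -> FluxState:
    """Pick the sample whose correlation with the expression array is maximal.

    Correlation is computed between flux magnitudes (or signed fluxes with
    ``signed=True``) and expression over the scored reactions; at least three
    are required.  Zero-variance flux vectors are skipped (logged); ties go to
    the lowest sample index.
    """
    if len(samples.samples) == 0:
        raise ValueError("empty sample set")
    scored = [r for r in exp.index if not pd.isna(exp[r]) and r in samples.samples.columns]
    if len(scored) < 3:
        raise ValueError(f"need >= 3 scored reactions, got {len(scored)}")
    e = exp[scored].to_numpy(dtype=float)
    mat = samples.samples[scored].to_numpy(dtype=float)
    if not signed:
        mat = np.abs(mat)
    best_idx, best_r = -1, -np.inf
    for j in range(mat.shape[0]):
        x = mat[j]
        if np.std(x) == 0 or np.std(e) == 0:
            continue
        if method == "pearson":
            r = float(np.corrcoef(x, e)[0, 1])
        elif method == "spearman":
            from scipy.stats import spearmanr

            r = float(spearmanr(x, e).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        if np.isnan(r):
            continue
        if r > best_r:
            best_r, best_idx = r, j
    if best_idx < 0:
        raise ValueError("no sample yielded a defined correlation")
    return FluxState(
        fluxes=samples.samples.iloc[best_idx].copy(),
        correlation=best_r,
        sample_index=best_idx,
        seed=samples.seed,
    )


def flux_state(
    model: Model,
    exp: pd.Series,
    n_points: Optional[int] = None,
    seed: Optional[int] = None,
    **kwargs,
) -> FluxState:
    """Convenience: sample *model* and select the expression-optimal state."""
    return select_optimal_state(
        sample_fluxes(model, n_points=n_points, seed=seed), exp, **kwargs
    )


# ---------------------------------------------------------------------------
# FBA and functionality score
# ---------------------------------------------------------------------------

def fba_maximize(model: Model, reaction_id: str) -> float:
    """LP maximum of the named reaction's flux; unbounded reports +inf."""
    model = _configure(model.copy())
    model.objective = model.reactions.get_by_id(reaction_id)
    sol = model.optimize(objective_sense="maximize")
    if sol.status == "unbounded":
        return float("inf")
    if sol.status != "optimal":
        raise RuntimeError(f"FBA on {reaction_id} failed: status {sol.status}")
    return float(sol.objective_value)


def functionality_score(
    model: Model,
    sink_ids: Iterable[str],
    activity_tol: float = ACTIVITY_TOL,
) -> FunctionalityResult:
    """Count sink reactions whose FBA maximum exceeds the activity threshold."""
    net = LinearNetwork.from_model(model)
    mask = np.ones(net.n, dtype=bool)
    flux = {}
    for sid in sink_ids:
        if sid not in net.index:
            flux[sid] = 0.0
            continue
        val, _ = net.optimize(mask, net.index[sid], sense=-1)
        flux[sid] = 0.0 if np.isnan(val) else val
    per_sink = pd.Series(flux, name="max_flux")
    score = int((per_sink > activity_tol).sum())
    return FunctionalityResult(met_score=score, per_sink_flux=per_sink)


def empirical_p(random_scores: Sequence[int], met_score: int) -> float:
    """Randomisation p-value: fraction of random scores strictly above the
    observed score.  The strict inequality makes p = 0 attainable."""
    if not len(random_scores):
        raise ValueError("no random scores")
    return float(sum(s > met_score for s in random_scores)) / len(random_scores)


def _random_consistent_mask(
    net: LinearNetwork,
    target_size: int,
    rng: np.random.Generator,
    tol: float,
    size_slack: float = 0.02,
    max_rounds: int = 6,
) -> np.ndarray:
    """Random same-size flux-consistent submodel of the parent.

    Remove uniformly random reactions down to *target_size*, restore
    consistency, and greedily re-add removed reactions while the result is
    more than ``size_slack`` below target.  Returns the achieved mask even
    when the exact size is unreachable (caller logs the shortfall).
    """
    order = rng.permutation(net.n)
    keep = np.zeros(net.n, dtype=bool)
    keep[order[:target_size]] = True
    mask = net.consistent_mask(keep, tol)
    removed = [i for i in order[target_size:]]
    rounds = 0
    while mask.sum() < (1 - size_slack) * target_size and removed and rounds < max_rounds:
        rounds += 1
        n_add = min(len(removed), max(1, target_size - int(mask.sum())))
        add, removed = removed[:n_add], removed[n_add:]
        trial = mask.copy()
        trial[add] = True
        trial |= keep  # previously blocked picks may revive with new support
        mask = net.consistent_mask(trial, tol)
    return mask


def draw_random_context(
    parent: Model,
    target_size: int,
    seed: Optional[int] = None,
    activity_tol: float = ACTIVITY_TOL,
) -> set[str]:
    """Random flux-consistent submodel of *parent* with ~target_size reactions.

    Uses the same removal-and-restore procedure as the randomisation null of
    :func:`functionality_significance`, so contexts drawn this way are
    exchangeable with that null (useful for calibration checks).
    """
    net = LinearNetwork.from_model(parent)
    rng = np.random.default_rng(seed)
    mask = _random_consistent_mask(net, target_size, rng, activity_tol)
    return {net.rids[i] for i in np.flatnonzero(mask)}


def functionality_significance(
    parent: Model,
    context_reaction_ids: set[str],
    sink_ids: Sequence[str],
    iterations: int = 1000,
    seed: Optional[int] = None,
    activity_tol: float = ACTIVITY_TOL,
) -> FunctionalityResult:
    """Randomisation p-value for a context model's functionality score.

    Draws ``iterations`` random same-size flux-consistent submodels of
    *parent* (sink reactions always retained, so every random model is scored
    on the same functions) and reports
    ``p = #(random score > met_score) / iterations``.
    """
    net = LinearNetwork.from_model(parent)
    sink_idx = [net.index[s] for s in sink_ids if s in net.index]
    ctx_mask = np.zeros(net.n, dtype=bool)
    for r in context_reaction_ids:
        if r in net.index:
            ctx_mask[net.index[r]] = True
    # the sink set is part of every scored model, context and random alike
    ctx_mask[sink_idx] = True
    target = int(ctx_mask.sum())
    if target > net.n:
        raise ValueError("context larger than parent")

    def score_mask(mask: np.ndarray) -> int:
        s = 0
        for j in sink_idx:
            if not mask[j]:
                continue
            val, _ = net.optimize(mask, j, sense=-1)
            if not np.isnan(val) and val > activity_tol:
                s += 1
        return s

    met_score = score_mask(ctx_mask)
    rng = np.random.default_rng(seed)
    randoms: list[int] = []
    for _ in range(iterations):
        mask = _random_consistent_mask(net, target, rng, activity_tol)
        mask[sink_idx] = True  # always score the same sink set
        achieved = int(mask.sum())
        if achieved < (1 - 0.05) * target:
            logger.warning(
                "random model achieved size %d (target %d)", achieved, target
            )
        randoms.append(score_mask(mask))
    p = empirical_p(randoms, met_score)
    return FunctionalityResult(
        met_score=met_score,
        per_sink_flux=pd.Series(dtype=float),
        p_value=p,
        random_scores=randoms,
    )
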