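"""Loading, validation, and conditioning of genome-scale metabolic models.

A genome-scale metabolic model (GSMM) is a stoichiometric network ``S`` with
per-reaction flux bounds (mmol·gDW⁻¹·h⁻¹), gene-protein-reaction (GPR) boolean
rules, subsystem labels and metabolite formulas.  :class:`cobra.Model` is the
in-memory container throughout the package; this module provides

* :func:`load_model` / :func:`save_model` — SBML (L3+FBC) and BiGG-style JSON I/O
  with post-load structural validation,
* :func:`fix_carbon_bounds` — cap the uptake of every carbon-source exchange,
* :func:`add_sink_reactions` — irreversible drains used for the metabolic
  functionality score,
* :func:`flux_consistent_subnetwork` — the subnetwork of reactions able to carry
  flux at steady state (the input every extraction method requires).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional

import cobra
import numpy as np
from cobra import Metabolite, Model, Reaction
from cobra.flux_analysis import flux_variability_analysis

logger = logging.getLogger("fluxrevert")

#: global reaction-activity tolerance: a flux below this magnitude is "off"
ACTIVITY_TOL: float = 1e-6

#: default cap on carbon-source uptake, mmol·gDW⁻¹·h⁻¹
CARBON_UPTAKE_LIMIT: float = 10.0

#: large finite bound used when opening sink reactions
DEFAULT_BOUND: float = 1000.0

SOLVER = "glpk"


class ModelValidationError(ValueError):
    """A structural invariant of the metabolic network is violated."""


# ---------------------------------------------------------------------------
# model I/O
# ---------------------------------------------------------------------------

def _configure(model: Model) -> Model:
    model.solver = SOLVER
    return model


def load_model(path: str | Path, format: Optional[str] = None) -> Model:
    """Read a metabolic model from SBML or BiGG-style JSON.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"sbml"`` or ``"json"``; inferred from the suffix when *None*.

    Returns
    -------
    cobra.Model
        Validated model with GPR strings retained verbatim.

    Raises
    ------
    ModelValidationError
        If the file does not parse under the named standard or violates a
        structural invariant (undeclared metabolite, lb > ub, ...).
    ValueError
        For an unknown ``format``.
    """
    path = Path(path)
    if format is None:
        format = {".xml": "sbml", ".sbml": "sbml", ".json": "json"}.get(
            path.suffix.lower(), ""
        )
    if format not in {"sbml", "json"}:
        raise ValueError(f"unknown model format {format!r} for {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ModelValidationError(f"failed to parse {path} as {format}: {exc}") from exc
    validate_model(model)
    return _configure(model)


def save_model(model: Model, path: str | Path) -> None:
    """Write *model* in the BiGG-style JSON dialect."""
    cobra.io.save_json_model(model, str(path))


def validate_model(model: Model) -> None:
    """Check the structural invariants of a metabolic network.

    * every reaction references only declared metabolites,
    * ``lower_bound <= upper_bound`` for every reaction,
    * every gene mentioned by a GPR rule is in the model's gene list.
    """
    declared = set(model.metabolites)
    for rxn in model.reactions:
        for met in rxn.metabolites:
            if met not in declared:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met.id!r}"
                )
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id!r} has lower_bound {rxn.lower_bound} > "
                f"upper_bound {rxn.upper_bound}"
            )
    gene_ids = {g.id for g in model.genes}
    for rxn in model.reactions:
        for gid in rxn.gpr.genes:
            if gid not in gene_ids:
                raise ModelValidationError(
                    f"GPR of reaction {rxn.id!r} mentions unknown gene {gid!r}"
                )


def canonicalize(model: Model) -> Model:
    """Return a copy with reactions and metabolites sorted lexicographically.

    Matrices derived from a canonicalized model are reproducible across
    serialisation formats.
    """
    model = model.copy()
    model.reactions.sort(key=lambda r: r.id)
    model.metabolites.sort(key=lambda m: m.id)
    model.genes.sort(key=lambda g: g.id)
    return _configure(model)


# ---------------------------------------------------------------------------
# exchange identification and carbon bounds
# ---------------------------------------------------------------------------

def exchange_reactions(model: Model) -> list[Reaction]:
    """Boundary drains: reactions touching exactly one metabolite."""
    return [r for r in model.reactions if len(r.metabolites) == 1]


def _carbon_count(met: Metabolite) -> Optional[int]:
    """Number of carbon atoms in the metabolite formula, or None if unknown."""
    if not met.formula:
        return None
    try:
        return int(met.elements.get("C", 0))
    except Exception:  # unparseable formula
        return None


_EXCLUDED_IDS = ("co2", "hco3")
_EXCLUDED_FORMULAS = {"CO2", "CHO3", "HCO3"}


def _is_co2_or_bicarbonate(met: Metabolite) -> bool:
    # matched by id pattern and by formula, either suffices
    base = met.id.lower().split("[")[0]
    for pat in _EXCLUDED_IDS:
        if base == pat or base.startswith(pat + "_") or base.endswith("_" + pat):
            return True
    return (met.formula or "") in _EXCLUDED_FORMULAS


def fix_carbon_bounds(
    model: Model, uptake_limit: float = CARBON_UPTAKE_LIMIT
) -> Model:
    """Cap the uptake of every carbon-source exchange at *uptake_limit*.

    Every exchange reaction whose metabolite contains at least one carbon atom
    is a carbon source, except CO2 and bicarbonate.  Only the uptake direction
    is touched; secretion bounds and all non-exchange reactions keep their
    original bounds.  Metabolites without a parseable formula are treated as
    non-carbon (with a warning).  The operation is idempotent.
    """
    model = model.copy()
    for rxn in exchange_reactions(model):
        met, coef = next(iter(rxn.metabolites.items()))
        n_c = _carbon_count(met)
        if n_c is None:
            logger.warning(
                "exchange %s: metabolite %s has no parseable formula; "
                "treated as non-carbon",
                rxn.id,
                met.id,
            )
            continue
        if n_c < 1 or _is_co2_or_bicarbonate(met):
            continue
        # with stoichiometry -1 uptake is negative flux; +1 reverses the sense
        if coef < 0:
            if rxn.lower_bound < -uptake_limit:
                rxn.lower_bound = -uptake_limit
        else:
            if rxn.upper_bound > uptake_limit:
                rxn.upper_bound = uptake_limit
    return _configure(model)


# ---------------------------------------------------------------------------
# sink reactions
# ---------------------------------------------------------------------------

def remove_objective_reaction(model: Model) -> Model:
    """Drop the current objective (biomass) reaction, if any."""
    model = model.copy()
    obj = [r for r in model.reactions if r.objective_coefficient]
    if obj:
        model.remove_reactions(obj, remove_orphans=False)
    return _configure(model)


def add_sink_reactions(model: Model, metabolite_ids: Iterable[str]) -> Model:
    """Add one irreversible drain ``SK_<met>`` per listed metabolite.

    Duplicated ids yield a single sink (warning); unknown ids raise listing
    every miss.  Sinks consume the metabolite (stoichiometry −1) with bounds
    ``(0, DEFAULT_BOUND)``.
    """
    model = model.copy()
    missing = [m for m in metabolite_ids if m not in model.metabolites]
    if missing:
        raise KeyError(f"unknown metabolite ids for sink reactions: {missing}")
    seen: set[str] = set()
    for mid in metabolite_ids:
        if mid in seen:
            logger.warning("duplicate sink request for metabolite %s ignored", mid)
            continue
        seen.add(mid)
        sid = f"SK_{mid}"
        if sid in model.reactions:
            logger.warning("sink %s already present; left unchanged", sid)
            continue
        sink = Reaction(sid, lower_bound=0.0, upper_bound=DEFAULT_BOUND)
        sink.add_metabolites({model.metabolites.get_by_id(mid): -1.0})
        sink.subsystem = "Exchange/demand reaction"
        model.add_reactions([sink])
    return _configure(model)


def sink_ids(metabolite_ids: Iterable[str]) -> list[str]:
    return [f"SK_{m}" for m in metabolite_ids]


# ---------------------------------------------------------------------------
# flux consistency
# ---------------------------------------------------------------------------

def blocked_reactions(model: Model, tol: float = ACTIVITY_TOL) -> list[str]:
    """Reactions unable to carry ``|flux| >= tol`` in any feasible steady state."""
    if len(model.reactions) == 0:
        return []
    model = model.copy()
    _configure(model)
    model.objective = model.problem.Objective(0)
    fva = flux_variability_analysis(
        model, fraction_of_optimum=0.0, processes=1
    )
    out = []
    for rid, row in fva.iterrows():
        if max(row["maximum"], 0.0) < tol and min(row["minimum"], 0.0) > -tol:
            out.append(rid)
    return out


def flux_consistent_subnetwork(model: Model, tol: float = ACTIVITY_TOL) -> Model:
    """Largest subnetwork in which every reaction can carry ``|flux| >= tol``.

    Both directions are examined for reversible reactions.  Removal is
    transitively complete: blocked reactions are deleted (with orphaned
    metabolites) and the check repeats until a fixed point.  Raises if the
    network has no feasible steady state at its bounds.
    """
    if len(model.reactions) == 0:
        raise ValueError("empty network")
    model = model.copy()
    _configure(model)
    sol = model.optimize(objective_sense=None)
    if sol.status == "infeasible":
        raise ValueError("network admits no feasible steady state")
    while True:
        dead = blocked_reactions(model, tol=tol)
        if not dead:
            break
        model.remove_reactions(
            [model.reactions.get_by_id(r) for r in dead], remove_orphans=True
        )
        if len(model.reactions) == 0:
            break
    return _configure(model)


def is_flux_consistent(model: Model, tol: float = ACTIVITY_TOL) -> bool:
    """True if no reaction of *model* is blocked at tolerance *tol*."""
    if len(model.reactions) == 0:
        return True
    return not blocked_reactions(model, tol=tol)
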