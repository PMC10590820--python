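"""Context-specific model extraction: iMAT, FASTCORE and INIT.

All three methods are objective-free: they carve a subnetwork out of a parent
model so that reactions catalysed by highly expressed genes are preferentially
retained, without assuming a biomass objective.

Threshold schemes (two per method) are always recomputed from the supplied
reaction-expression array, never hard-coded:

===========  =====================================  ==================================
method       scheme Th1                             scheme Th2
===========  =====================================  ==================================
iMAT         lower = min(exp), upper = min(top10%)  lower/upper = mean(exp) ∓ std(exp)
FASTCORE     threshold = min(top 10% of exp)        threshold = min(exp)
INIT         threshold = min(top 10% of exp)        threshold = min(exp)
===========  =====================================  ==================================

where "min(top 10%)" is the smallest value among the highest decile of scored
reactions (ceiling count).  The integer programs are solved with HiGHS
(:func:`scipy.optimize.milp`), which is deterministic, and every returned
model is reduced to its flux-consistent subnetwork.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from cobra import Model
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import LinearConstraint, linprog, milp
from scipy.sparse import csr_matrix

from .network import ACTIVITY_TOL, flux_consistent_subnetwork

logger = logging.getLogger("fluxrevert")

#: minimum activation flux for iMAT/INIT (must exceed the 1e-6 activity scale)
DEFAULT_EPS: float = 1e-3


@dataclass(frozen=True)
class ThresholdScheme:
    """Expression thresholds for one extraction method and scheme."""

    method: str  # iMAT | FASTCORE | INIT
    scheme: str  # Th1 | Th2
    lower: float
    upper: Optional[float] = None  # iMAT only

    def __post_init__(self):
        if self.upper is not None and self.lower > self.upper:
            raise ValueError("lower threshold exceeds upper threshold")


@dataclass
class ContextModel:
    """A reaction subset of a parent model, with extraction provenance."""

    model: Model
    method: str
    scheme: str
    parent_id: str
    details: dict = field(default_factory=dict)

    @property
    def reaction_ids(self) -> set[str]:
        return {r.id for r in self.model.reactions}


def _top_decile_min(values: np.ndarray) -> float:
    """Smallest value among the highest decile (ceiling on the count)."""
    k = math.ceil(0.1 * values.size)
    return float(np.sort(values)[::-1][:k].min())


def compute_thresholds(
    exp: pd.Series, method: str, scheme: str
) -> ThresholdScheme:
    """Derive the threshold scheme from a reaction-expression array.

    Requires at least 10 scored reactions.  A constant array degenerates to
    lower == upper (warning).
    """
    method = method.upper() if method.upper() != "IMAT" else "iMAT"
    if method not in {"iMAT", "FASTCORE", "INIT"}:
        raise ValueError(f"unknown extraction method {method!r}")
    if scheme not in {"Th1", "Th2"}:
        raise ValueError(f"unknown threshold scheme {scheme!r}")
    vals = exp.dropna().to_numpy(dtype=float)
    if vals.size < 10:
        raise ValueError(
            f"need >= 10 scored reactions to set thresholds, got {vals.size}"
        )
    if np.ptp(vals) == 0:
        logger.warning("constant reaction-expression array; degenerate thresholds")
    if method == "iMAT":
        if scheme == "Th1":
            lower, upper = float(vals.min()), _top_decile_min(vals)
        else:
            m, s = float(vals.mean()), float(vals.std())
            lower, upper = m - s, m + s
        return ThresholdScheme(method, scheme, lower, upper)
    thr = _top_decile_min(vals) if scheme == "Th1" else float(vals.min())
    return ThresholdScheme(method, scheme, thr)


# ---------------------------------------------------------------------------
# shared matrix view
# ---------------------------------------------------------------------------

class _MatrixView:
    """Dense arrays (S, lb, ub, reaction ids) for the custom LP/MILP builds."""

    def __init__(self, model: Model):
        self.model = model
        self.S = create_stoichiometric_matrix(model)
        self.lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.rids = [r.id for r in model.reactions]
        self.index = {r: i for i, r in enumerate(self.rids)}
        self.n = len(self.rids)
        self.m = self.S.shape[0]


def _subnetwork(model: Model, keep: set[str], tol: float = ACTIVITY_TOL) -> Model:
    sub = model.copy()
    drop = [r for r in sub.reactions if r.id not in keep]
    sub.remove_reactions(drop, remove_orphans=True)
    if len(sub.reactions) == 0:
        return sub
    return flux_consistent_subnetwork(sub, tol=tol)


# ---------------------------------------------------------------------------
# iMAT
# ---------------------------------------------------------------------------

def imat_objective(
    model: Model, exp: pd.Series, lower: float, upper: float, eps: float = DEFAULT_EPS
) -> tuple[float, np.ndarray]:
    """Solve the iMAT MILP; return (optimal objective, witness flux vector).

    Maximises the number of high-expression reactions carrying ``|flux| >= eps``
    plus the number of low-expression reactions with zero flux, subject to
    steady state and bounds.
    """
    mv = _MatrixView(model)
    high = [mv.index[r] for r in mv.rids if not pd.isna(exp.get(r)) and exp[r] >= upper]
    low = [
        mv.index[r]
        for r in mv.rids
        if not pd.isna(exp.get(r)) and exp[r] <= lower and exp[r] < upper
    ]
    res = _imat_milp(mv, high, low, eps)
    if res.status != 0:
        raise RuntimeError(f"iMAT MILP failed: {res.message}")
    v = res.x[: mv.n]
    return float(round(-res.fun)), v


def _imat_milp(
    mv: _MatrixView,
    high: list[int],
    low: list[int],
    eps: float,
    extra_constraints: Optional[list[LinearConstraint]] = None,
    objective_override: Optional[np.ndarray] = None,
):
    """Assemble and solve the iMAT integer program.

    Variable layout: [v (n) | y+ (n_high) | y- (n_high) | y0 (n_low)].
    """
    n = mv.n
    nh, nl = len(high), len(low)
    nvar = n + 2 * nh + nl
    c = np.zeros(nvar)
    if objective_override is not None:
        c[:] = objective_override
    else:
        c[n:] = -1.0  # maximize count of satisfied indicators

    rows, cols, data, lo, hi = [], [], [], [], []
    r = 0

    def add_row(entries, lo_v, hi_v):
        nonlocal r
        for j, a in entries:
            rows.append(r)
            cols.append(j)
            data.append(a)
        lo.append(lo_v)
        hi.append(hi_v)
        r += 1

    # steady state
    for i in range(mv.m):
        entries = [(j, mv.S[i, j]) for j in range(n) if mv.S[i, j] != 0.0]
        add_row(entries, 0.0, 0.0)

    for k, j in enumerate(high):
        yp, ym = n + k, n + nh + k
        # y+ = 1 -> v_j >= eps :  v_j + y+ (lb_j - eps) >= lb_j
        add_row([(j, 1.0), (yp, mv.lb[j] - eps)], mv.lb[j], np.inf)
        # y- = 1 -> v_j <= -eps :  v_j + y- (ub_j + eps) <= ub_j
        add_row([(j, 1.0), (ym, mv.ub[j] + eps)], -np.inf, mv.ub[j])
        # at most one direction
        add_row([(yp, 1.0), (ym, 1.0)], -np.inf, 1.0)
    for k, j in enumerate(low):
        y0 = n + 2 * nh + k
        # y0 = 1 -> v_j = 0
        add_row([(j, 1.0), (y0, mv.ub[j])], -np.inf, mv.ub[j])
        add_row([(j, 1.0), (y0, mv.lb[j])], mv.lb[j], np.inf)

    A = csr_matrix((data, (rows, cols)), shape=(r, nvar))
    constraints = [LinearConstraint(A, lo, hi)]
    if extra_constraints:
        constraints.extend(extra_constraints)
    lb_var = np.concatenate([mv.lb, np.zeros(2 * nh + nl)])
    ub_var = np.concatenate([mv.ub, np.ones(2 * nh + nl)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * nh + nl)])
    from scipy.optimize import Bounds

    return milp(
        c,
        constraints=constraints,
        bounds=Bounds(lb_var, ub_var),
        integrality=integrality,
    )


def imat_extract(
    model: Model,
    exp: pd.Series,
    lower: float,
    upper: float,
    eps: float = DEFAULT_EPS,
    tol: float = ACTIVITY_TOL,
) -> ContextModel:
    """Extract an iMAT context model.

    Solves the iMAT MILP, then keeps every reaction that is active — or can be
    made active (``|flux| >= tol``) in some optimum-attaining solution — and
    reduces the result to its flux-consistent subnetwork.
    """
    mv = _MatrixView(model)
    high = [mv.index[r] for r in mv.rids if not pd.isna(exp.get(r)) and exp[r] >= upper]
    low = [
        mv.index[r]
        for r in mv.rids
        if not pd.isna(exp.get(r)) and exp[r] <= lower and exp[r] < upper
    ]
    base = _imat_milp(mv, high, low, eps)
    if base.status != 0:
        raise RuntimeError(f"iMAT MILP failed: {base.message}")
    opt = float(round(-base.fun))
    n = mv.n
    nvar = n + 2 * len(high) + len(low)
    # pin the indicator count at its optimum (indicators are integral)
    obj_row = np.zeros(nvar)
    obj_row[n:] = 1.0
    pin = LinearConstraint(csr_matrix(obj_row), opt - 0.5, np.inf)

    keep: set[str] = set()
    for j, rid in enumerate(mv.rids):
        c = np.zeros(nvar)
        c[j] = 1.0  # minimize v_j
        res_min = _imat_milp(mv, high, low, eps, [pin], c)
        if res_min.status == 0 and res_min.x[j] < -tol:
            keep.add(rid)
            continue
        c[j] = -1.0  # maximize v_j
        res_max = _imat_milp(mv, high, low, eps, [pin], c)
        if res_max.status == 0 and res_max.x[j] > tol:
            keep.add(rid)
    sub = _subnetwork(model, keep, tol)
    return ContextModel(
        sub,
        "iMAT",
        "",
        model.id or "",
        {"objective": opt, "lower": lower, "upper": upper, "eps": eps},
    )


# ---------------------------------------------------------------------------
# FASTCORE
# ---------------------------------------------------------------------------

def _lp7(mv: _MatrixView, J: list[int], eps: float) -> np.ndarray:
    """Maximise the number of reactions in J pushed to flux >= eps (LP relaxation)."""
    n = mv.n
    nj = len(J)
    c = np.zeros(n + nj)
    c[n:] = -1.0
    A_eq = np.hstack([mv.S, np.zeros((mv.m, nj))])
    # z_k <= v_{J_k}
    A_ub = np.zeros((nj, n + nj))
    for k, j in enumerate(J):
        A_ub[k, n + k] = 1.0
        A_ub[k, j] = -1.0
    bounds = [(mv.lb[i], mv.ub[i]) for i in range(n)] + [(0.0, eps)] * nj
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(nj),
        A_eq=A_eq,
        b_eq=np.zeros(mv.m),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP7 failed: {res.message}")
    return res.x[:n]


def _lp10(mv: _MatrixView, K: list[int], P: list[int], eps: float) -> np.ndarray:
    """Minimise the L1 flux through the penalty set P while forcing K active."""
    n = mv.n
    np_ = len(P)
    scale = 1e5
    c = np.zeros(n + np_)
    c[n:] = 1.0
    A_eq = np.hstack([mv.S, np.zeros((mv.m, np_))])
    # -z_k <= v_{P_k} <= z_k
    A_ub = np.zeros((2 * np_, n + np_))
    for k, j in enumerate(P):
        A_ub[2 * k, j] = 1.0
        A_ub[2 * k, n + k] = -1.0
        A_ub[2 * k + 1, j] = -1.0
        A_ub[2 * k + 1, n + k] = -1.0
    # bounds scaled so the forced core activation does not collide with the
    # parent bounds (classic 1e5 scaling of the LP10 step)
    bounds = []
    for i in range(n):
        if i in set(K):
            bounds.append((eps * scale, max(mv.ub[i] * scale, eps * scale)))
        else:
            bounds.append((mv.lb[i] * scale, mv.ub[i] * scale))
    bounds += [(0.0, None)] * np_
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(2 * np_),
        A_eq=A_eq,
        b_eq=np.zeros(mv.m),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP10 failed: {res.message}")
    return res.x[:n]


def _find_sparse_mode(
    mv: _MatrixView, J: list[int], P: list[int], singleton: bool, eps: float
) -> set[int]:
    if not J:
        return set()
    probe = [J[0]] if singleton else J
    v = _lp7(mv, probe, eps)
    K = [j for j in probe if v[j] >= 0.99 * eps]
    if not K:
        return set()
    v = _lp10(mv, K, P, eps)
    return {i for i in range(mv.n) if abs(v[i]) >= 0.99 * eps}


def fastcore_extract(
    model: Model,
    core: set[str],
    tol: float = ACTIVITY_TOL,
    eps: float = DEFAULT_EPS,
) -> ContextModel:
    """FASTCORE: smallest flux-consistent subnetwork containing every core reaction.

    *model* must be flux-consistent; *core* are the reaction ids whose
    expression exceeds the threshold (reactions without expression data are
    never core).  Implements the classic LP7/LP10 sequence with bound
    flipping for reversible core reactions.  Raises if a core reaction cannot
    carry flux in the consistent parent.
    """
    unknown = core - {r.id for r in model.reactions}
    if unknown:
        raise KeyError(f"core reactions absent from model: {sorted(unknown)}")
    if not core:
        sub = model.copy()
        sub.remove_reactions(list(sub.reactions), remove_orphans=True)
        return ContextModel(sub, "FASTCORE", "", model.id or "", {"core_size": 0})

    work = model.copy()
    mv = _MatrixView(work)
    C = sorted(mv.index[r] for r in core)
    irrev = {i for i in range(mv.n) if mv.lb[i] >= 0}
    A: set[int] = set()
    flipped = False
    singleton = False

    J = [i for i in C if i in irrev]
    P = [i for i in range(mv.n) if i not in set(C)]
    A |= _find_sparse_mode(mv, J, P, singleton, eps)
    missed_irrev = set(J) - A
    if missed_irrev:
        raise RuntimeError(
            "inconsistent irreversible core reactions: "
            f"{sorted(mv.rids[i] for i in missed_irrev)}"
        )
    J = [i for i in C if i not in A]
    guard = 0
    while J:
        guard += 1
        if guard > 4 * mv.n + 16:
            raise RuntimeError(
                f"FASTCORE failed to cover core reactions {sorted(mv.rids[i] for i in J)}"
            )
        P = [i for i in P if i not in A]
        supp = _find_sparse_mode(mv, J, P, singleton, eps)
        A |= supp
        if set(J) & A:
            J = [i for i in J if i not in A]
            flipped = False
            singleton = False
        else:
            j_rev = [i for i in ([J[0]] if singleton else J) if i not in irrev]
            if flipped or not j_rev:
                if singleton:
                    raise RuntimeError(
                        f"core reaction {mv.rids[J[0]]} cannot carry flux"
                    )
                flipped = False
                singleton = True
            else:
                for i in j_rev:
                    mv.lb[i], mv.ub[i] = -mv.ub[i], -mv.lb[i]
                    mv.S[:, i] *= -1.0
                flipped = True
    keep = {mv.rids[i] for i in A}
    sub = _subnetwork(model, keep, tol)
    assert core <= {r.id for r in sub.reactions}, "core lost during reduction"
    return ContextModel(
        sub, "FASTCORE", "", model.id or "", {"core_size": len(core)}
    )


# ---------------------------------------------------------------------------
# INIT
# ---------------------------------------------------------------------------

def init_weights(
    exp: pd.Series, threshold: float, missing_weight: float = -2.0
) -> pd.Series:
    """INIT reaction weights: ``5 * log2(expression / threshold)``.

    Reactions with no expression data receive ``missing_weight`` (−2).
    """
    if threshold <= 0:
        raise ValueError("INIT threshold must be positive")
    with np.errstate(divide="ignore"):
        w = 5.0 * np.log2(exp.astype(float) / threshold)
    w[exp.isna()] = missing_weight
    w[np.isneginf(w)] = missing_weight  # zero expression treated as unscored
    return w.rename("init_weight")


def init_extract(
    model: Model,
    weights: pd.Series,
    eps: float = DEFAULT_EPS,
    tol: float = ACTIVITY_TOL,
) -> ContextModel:
    """INIT: select the reaction subset maximising the summed weights.

    MILP over selection binaries y and direction binaries d: an excluded
    reaction carries zero flux; an included one must reach ``|v| >= eps`` in a
    single steady-state witness vector.  The selected set is reduced to its
    flux-consistent subnetwork.
    """
    mv = _MatrixView(model)
    w = np.array([float(weights.get(r, -2.0)) for r in mv.rids])
    w[np.isnan(w)] = -2.0
    n = mv.n
    # variables: [v | y | d | z (= y AND d) | t (= y AND NOT d)]
    nvar = n * 5
    iv = np.arange(n)
    iy = n + iv
    id_ = 2 * n + iv
    iz = 3 * n + iv
    it = 4 * n + iv

    c = np.zeros(nvar)
    c[iy] = -w  # maximize sum w_i y_i

    rows, cols, data, lo, hi = [], [], [], [], []
    r = 0

    def add(entries, lo_v, hi_v):
        nonlocal r
        for j, a in entries:
            rows.append(r)
            cols.append(j)
            data.append(a)
        lo.append(lo_v)
        hi.append(hi_v)
        r += 1

    for i in range(mv.m):
        add([(j, mv.S[i, j]) for j in range(n) if mv.S[i, j] != 0.0], 0.0, 0.0)
    for i in range(n):
        a_i, b_i = mv.lb[i], mv.ub[i]
        # y = 0 -> v = 0
        add([(iv[i], 1.0), (iy[i], -b_i)], -np.inf, 0.0)
        add([(iv[i], 1.0), (iy[i], -a_i)], 0.0, np.inf)
        # z = AND(y, d), t = AND(y, 1-d)
        add([(iz[i], 1.0), (iy[i], -1.0)], -np.inf, 0.0)
        add([(iz[i], 1.0), (id_[i], -1.0)], -np.inf, 0.0)
        add([(iz[i], 1.0), (iy[i], -1.0), (id_[i], -1.0)], -1.0, np.inf)
        add([(it[i], 1.0), (iy[i], -1.0)], -np.inf, 0.0)
        add([(it[i], 1.0), (id_[i], 1.0)], -np.inf, 1.0)
        add([(it[i], 1.0), (iy[i], -1.0), (id_[i], 1.0)], 0.0, np.inf)
        # z = 1 -> v >= eps ; t = 1 -> v <= -eps
        add([(iv[i], 1.0), (iz[i], a_i - eps)], a_i if np.isfinite(a_i) else -1e9, np.inf)
        add([(iv[i], 1.0), (it[i], b_i + eps)], -np.inf, b_i if np.isfinite(b_i) else 1e9)
        # y = 1 -> z + t = 1 (must be active in one direction)
        add([(iz[i], 1.0), (it[i], 1.0), (iy[i], -1.0)], 0.0, np.inf)

    A = csr_matrix((data, (rows, cols)), shape=(r, nvar))
    from scipy.optimize import Bounds

    lb_var = np.concatenate([mv.lb, np.zeros(4 * n)])
    ub_var = np.concatenate([mv.ub, np.ones(4 * n)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * n), np.zeros(2 * n)])
    res = milp(
        c,
        constraints=[LinearConstraint(A, lo, hi)],
        bounds=Bounds(lb_var, ub_var),
        integrality=integrality,
    )
    if res.status != 0:
        raise RuntimeError(f"INIT MILP failed: {res.message}")
    y = res.x[n : 2 * n]
    keep = {mv.rids[i] for i in range(n) if y[i] > 0.5}
    sub = _subnetwork(model, keep, tol)
    return ContextModel(
        sub,
        "INIT",
        "",
        model.id or "",
        {"objective": float(-res.fun), "eps": eps},
    )


def init_objective_of_set(weights: pd.Series, reaction_ids: set[str]) -> float:
    """Summed INIT weight of a candidate reaction set (for cross-checks)."""
    return float(sum(weights.get(r, -2.0) for r in reaction_ids))


# ---------------------------------------------------------------------------
# unified front-end
# ---------------------------------------------------------------------------

def extract_context_model(
    model: Model,
    exp: pd.Series,
    method: str,
    scheme: str = "Th1",
    eps: float = DEFAULT_EPS,
    tol: float = ACTIVITY_TOL,
) -> ContextModel:
    """Compute thresholds from *exp* and run the requested extraction method."""
    ts = compute_thresholds(exp, method, scheme)
    if ts.method == "iMAT":
        cm = imat_extract(model, exp, ts.lower, ts.upper, eps=eps, tol=tol)
    elif ts.method == "FASTCORE":
        core = {r for r in exp.index if not pd.isna(exp[r]) and exp[r] >= ts.lower}
        core &= {r.id for r in model.reactions}
        cm = fastcore_extract(model, core, tol=tol, eps=eps)
    else:
        w = init_weights(exp, ts.lower)
        cm = init_extract(model, w, eps=eps, tol=tol)
    cm.scheme = scheme
    return cm
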