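"""Thin scipy/HiGHS LP helpers over a fixed stoichiometric matrix.

Used in inner loops (consistency checks of thousands of random subnetworks,
per-sink flux maxima) where rebuilding a :class:`cobra.Model` per call would
dominate the runtime.  Subnetworks are boolean masks over the parent's
reaction columns; orphaned metabolite rows reduce to 0 = 0 and are harmless.
"""

from __future__ import annotations

import numpy as np
from cobra import Model
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog


class LinearNetwork:
    """Immutable (S, lb, ub) view of a model for masked LP queries."""

    def __init__(self, S: np.ndarray, lb: np.ndarray, ub: np.ndarray, rids: list[str]):
        self.S = S
        self.lb = lb
        self.ub = ub
        self.rids = rids
        self.index = {r: i for i, r in enumerate(rids)}
        self.n = len(rids)

    @classmethod
    def from_model(cls, model: Model) -> "LinearNetwork":
        S = create_stoichiometric_matrix(model)
        lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
        return cls(S, lb, ub, [r.id for r in model.reactions])

    def _solve(self, mask: np.ndarray, c_local: np.ndarray):
        cols = np.flatnonzero(mask)
        res = linprog(
            c_local,
            A_eq=self.S[:, cols],
            b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(self.lb[cols], self.ub[cols])),
            method="highs",
        )
        return res, cols

    def optimize(self, mask: np.ndarray, j: int, sense: int = -1):
        """Optimise flux of parent-index *j* over the masked subnetwork.

        ``sense=-1`` maximises.  Returns (optimal value, full-length flux
        vector) or (nan, None) on failure; unbounded gives ±inf.
        """
        cols = np.flatnonzero(mask)
        local = {g: k for k, g in enumerate(cols)}
        if j not in local:
            raise KeyError(f"reaction index {j} not in mask")
        c = np.zeros(cols.size)
        c[local[j]] = float(sense)
        res, cols = self._solve(mask, c)
        if res.status == 3:  # unbounded
            return (np.inf if sense == -1 else -np.inf), None
        if not res.success:
            return np.nan, None
        v = np.zeros(self.n)
        v[cols] = res.x
        return float(-res.fun if sense == -1 else res.fun), v

    def blocked(self, mask: np.ndarray, tol: float) -> np.ndarray:
        """Boolean array (parent indexing): True where the reaction cannot
        reach ``|flux| >= tol`` within the masked subnetwork."""
        mask = mask.astype(bool).copy()
        undecided = set(np.flatnonzero(mask))
        unblocked: set[int] = set()
        while undecided:
            j = min(undecided)
            vmax, v = self.optimize(mask, j, sense=-1)
            if v is not None:
                unblocked |= {int(i) for i in np.flatnonzero(np.abs(v) >= tol)}
            vmin, v = self.optimize(mask, j, sense=1)
            if v is not None:
                unblocked |= {int(i) for i in np.flatnonzero(np.abs(v) >= tol)}
            if j not in unblocked and (
                (not np.isnan(vmax) and vmax >= tol)
                or (not np.isnan(vmin) and vmin <= -tol)
            ):
                unblocked.add(j)
            undecided -= unblocked
            undecided.discard(j)
        out = np.zeros(self.n, dtype=bool)
        for j in np.flatnonzero(mask):
            out[j] = j not in unblocked
        return out

    def consistent_mask(self, mask: np.ndarray, tol: float) -> np.ndarray:
        """Largest flux-consistent sub-mask of *mask* (fixed point of removal)."""
        mask = mask.astype(bool).copy()
        while mask.any():
            dead = self.blocked(mask, tol)
            if not dead.any():
                break
            mask &= ~dead
        return mask
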