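"""Minimal LP interface over scipy's HiGHS backend.

Only objective values cross this boundary — flux vectors are deliberately
not exposed, because the steady-state LP admits multiple optima.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from babybiome.core import MetabolicModel

SOLVER_TOL = 1e-9

#: Coupling constraint: |v_rxn| <= factor * v_biomass.
Coupling = Tuple[str, str, float]


class InfeasibleError(RuntimeError):
    """The LP has no feasible point under the current constraints."""


class FluxSolver:
    """Steady-state LP over a model, reusable across objectives.

    The stoichiometric equality system and any coupling inequalities are
    assembled once; each :meth:`maximize` call solves one LP with a fresh
    objective and optional per-reaction bound overrides.
    """

    def __init__(
        self,
        model: MetabolicModel,
        couplings: Sequence[Coupling] = (),
    ):
        self.reaction_ids: List[str] = sorted(model.reactions)
        self.metabolite_ids: List[str] = sorted(model.metabolites)
        self._rxn_index = {r: i for i, r in enumerate(self.reaction_ids)}
        met_index = {m: i for i, m in enumerate(self.metabolite_ids)}

        rows, cols, vals = [], [], []
        for rid in self.reaction_ids:
            j = self._rxn_index[rid]
            for met_id, coeff in model.reactions[rid].stoichiometry.items():
                rows.append(met_index[met_id])
                cols.append(j)
                vals.append(float(coeff))
        n_rxn = len(self.reaction_ids)
        self._A_eq = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(self.metabolite_ids), n_rxn)
        )
        self._lb = np.array(
            [model.reactions[r].lower_bound for r in self.reaction_ids]
        )
        self._ub = np.array(
            [model.reactions[r].upper_bound for r in self.reaction_ids]
        )

        if couplings:
            c_rows, c_cols, c_vals = [], [], []
            row = 0
            for rxn_id, bio_id, factor in couplings:
                j = self._rxn_index[rxn_id]
                b = self._rxn_index[bio_id]
                # v_j - factor * v_bio <= 0
                c_rows += [row, row]
                c_cols += [j, b]
                c_vals += [1.0, -factor]
                row += 1
                # -v_j - factor * v_bio <= 0
                c_rows += [row, row]
                c_cols += [j, b]
                c_vals += [-1.0, -factor]
                row += 1
            self._A_ub = sparse.csr_matrix(
                (c_vals, (c_rows, c_cols)), shape=(row, n_rxn)
            )
            self._b_ub = np.zeros(row)
        else:
            self._A_ub = None
            self._b_ub = None

    def maximize(
        self,
        objective: Mapping[str, float],
        bound_overrides: Optional[Mapping[str, Tuple[float, float]]] = None,
    ) -> float:
        """Maximal value of ``sum(objective[r] * v_r)``; raises if infeasible."""
        c = np.zeros(len(self.reaction_ids))
        for rxn_id, coeff in objective.items():
            c[self._rxn_index[rxn_id]] = -float(coeff)  # linprog minimizes
        lb, ub = self._lb, self._ub
        if bound_overrides:
            lb = lb.copy()
            ub = ub.copy()
            for rxn_id, (lo, hi) in bound_overrides.items():
                j = self._rxn_index[rxn_id]
                lb[j], ub[j] = lo, hi
        result = linprog(
            c,
            A_eq=self._A_eq,
            b_eq=np.zeros(self._A_eq.shape[0]),
            A_ub=self._A_ub,
            b_ub=self._b_ub,
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options={"primal_feasibility_tolerance": SOLVER_TOL,
                     "dual_feasibility_tolerance": SOLVER_TOL},
        )
        if result.status == 2:
            raise InfeasibleError("LP infeasible")
        if not result.success:
            raise RuntimeError(f"LP solver failure: {result.message}")
        return -float(result.fun)

    def feasible(self) -> bool:
        try:
            self.maximize({})
        except InfeasibleError:
            return False
        return True


def max_flux(
    model: MetabolicModel,
    objective: Mapping[str, float],
    couplings: Sequence[Coupling] = (),
) -> float:
    """One-shot convenience wrapper around :class:`FluxSolver`."""
    return FluxSolver(model, couplings).maximize(objective)
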