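"""Flux balance analysis (LP) and minimization of metabolic adjustment (QP).

FBA maximizes an objective flux subject to steady-state mass balance
``S v = 0`` and flux bounds; it is solved with HiGHS through
``scipy.optimize.linprog``.  MOMA predicts a knockout mutant's flux state as
the point of the mutant's feasible space closest (Euclidean, over all
reactions) to a wild-type reference flux ``w``:

    min  sum_j (v_j - w_j)^2
    s.t. S v = 0,  lb <= v <= ub,  v_k = 0 for knocked-out reactions k

a convex QP solved with OSQP at tight tolerances plus solution polishing.

Because FBA optima are typically degenerate, :func:`reference_flux` fixes a
unique wild type by parsimonious tie-breaking: growth is pinned to its FBA
optimum and total absolute flux is minimized in a secondary LP.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog

from .model_io import MetabolicModel

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
SUBOPTIMAL = "suboptimal"
ERROR = "error"

#: feasibility tolerance for mass balance and bounds on reported optima
FEAS_TOL = 1e-6
#: OSQP primal/dual convergence target
QP_EPS = 1e-9


@dataclass
class FluxDistribution:
    """One flux value per reaction plus the solve outcome.

    ``objective_value`` is the optimized quantity (objective flux for FBA,
    squared distance to the reference for MOMA).  ``residual`` is the
    solution's worst constraint violation (inf-norm over mass balance and
    bounds); it doubles as the per-run solution-quality scalar used by the
    metrics module.
    """

    fluxes: np.ndarray | None
    objective_value: float
    status: str
    residual: float | None = None

    @property
    def optimal(self) -> bool:
        return self.status == OPTIMAL

    def flux(self, model: MetabolicModel, reaction_id: str) -> float:
        if self.fluxes is None:
            raise ValueError(f"no flux vector (status {self.status})")
        return float(self.fluxes[model.index(reaction_id)])

    def to_tsv(self, model: MetabolicModel, path: str | Path) -> None:
        lines = ["reaction_id\tflux"]
        if self.fluxes is not None:
            lines += [f"{r}\t{v:.10g}" for r, v in zip(model.reaction_ids, self.fluxes)]
        Path(path).write_text("\n".join(lines) + "\n")


def _max_violation(model: MetabolicModel, v: np.ndarray,
                   lb: np.ndarray | None = None,
                   ub: np.ndarray | None = None) -> float:
    lb = model.lower_bounds if lb is None else lb
    ub = model.upper_bounds if ub is None else ub
    mass = float(np.max(np.abs(model.stoichiometry @ v))) if model.n_metabolites else 0.0
    bound = float(np.max(np.maximum(lb - v, v - ub), initial=0.0))
    return max(mass, bound)


def solve_fba(model: MetabolicModel, objective_reaction: str | None = None,
              direction: str = "max") -> FluxDistribution:
    """LP: optimize one reaction's flux under mass balance and bounds.

    ``objective_reaction`` defaults to the biomass reaction.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    j = model.index(objective_reaction or model.biomass_reaction)
    c = np.zeros(model.n_reactions)
    c[j] = -1.0 if direction == "max" else 1.0
    res = linprog(
        c,
        A_eq=model.stoichiometry,
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([model.lower_bounds, model.upper_bounds]),
        method="highs",
    )
    if res.status == 2:
        return FluxDistribution(None, float("nan"), INFEASIBLE)
    if res.status != 0:
        return FluxDistribution(None, float("nan"), ERROR)
    v = res.x
    return FluxDistribution(v, float(v[j]), OPTIMAL, residual=_max_violation(model, v))


def max_theoretical_production(model: MetabolicModel, target_exchange: str) -> float:
    """FBA optimum of the target exchange flux, with no growth requirement.

    Upper-bounds the production of every mutant of the same model.
    """
    sol = solve_fba(model, target_exchange, "max")
    if not sol.optimal:
        raise RuntimeError(f"theoretical-maximum FBA ended with status {sol.status}")
    return sol.objective_value


def reference_flux(model: MetabolicModel) -> FluxDistribution:
    """Unique wild-type reference: FBA growth, then minimal total |flux|.

    The secondary LP (min sum_j |v_j| with growth fixed at its optimum)
    deterministically resolves FBA alternate optima, so repeated calls agree
    to solver tolerance.  ``objective_value`` is the growth rate.
    """
    fba = solve_fba(model)
    if not fba.optimal:
        return fba
    n, m = model.n_reactions, model.n_metabolites
    b = model.biomass_index
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    lb[b] = ub[b] = fba.objective_value
    # variables [v, t]; minimize sum t with -t <= v <= t
    eye = sp.eye(n, format="csc")
    A_eq = sp.hstack([model.stoichiometry, sp.csc_matrix((m, n))])
    A_ub = sp.vstack([sp.hstack([eye, -eye]), sp.hstack([-eye, -eye])])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(m),
        bounds=np.column_stack([
            np.concatenate([lb, np.zeros(n)]),
            np.concatenate([ub, np.full(n, np.inf)]),
        ]),
        method="highs",
    )
    if res.status != 0:
        return FluxDistribution(None, float("nan"), ERROR)
    v = res.x[:n]
    return FluxDistribution(v, float(v[b]), OPTIMAL, residual=_max_violation(model, v))


def solve_moma(model: MetabolicModel, reference: FluxDistribution | np.ndarray,
               disabled_reactions: Iterable[str] = ()) -> FluxDistribution:
    """QP: nearest mutant-feasible flux vector to the wild-type reference.

    Knocked-out reactions have both bounds pinned to zero.  Returns the
    minimizer with ``objective_value`` = the squared Euclidean distance; an
    infeasible knockout (no steady state left) yields status ``infeasible``,
    which callers treat as lethal.
    """
    w = reference.fluxes if isinstance(reference, FluxDistribution) else np.asarray(reference)
    if w is None or len(w) != model.n_reactions:
        raise ValueError("reference flux dimension does not match the model")
    lb = model.lower_bounds.copy()
    ub = model.upper_bounds.copy()
    for rid in disabled_reactions:
        k = model.index(rid)
        lb[k] = ub[k] = 0.0
    import osqp

    n, m = model.n_reactions, model.n_metabolites
    P = sp.eye(n, format="csc")
    q = -np.asarray(w, dtype=float)
    A = sp.vstack([model.stoichiometry, sp.eye(n)], format="csc")
    lo = np.concatenate([np.zeros(m), lb])
    hi = np.concatenate([np.zeros(m), ub])
    prob = osqp.OSQP()
    prob.setup(P, q, A, lo, hi, verbose=False, eps_abs=QP_EPS, eps_rel=QP_EPS,
               eps_prim_inf=1e-8, eps_dual_inf=1e-8, polishing=True,
               max_iter=50000)
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "infeasible" in status:
        return FluxDistribution(None, float("nan"), INFEASIBLE)
    if status not in ("solved", "solved inaccurate", "maximum iterations reached"):
        return FluxDistribution(None, float("nan"), ERROR)
    v = np.asarray(res.x, dtype=float)
    dist = float(np.sum((v - w) ** 2))
    violation = _max_violation(model, v, lb, ub)
    out_status = OPTIMAL if (status == "solved" and violation <= FEAS_TOL) else SUBOPTIMAL
    return FluxDistribution(v, dist, out_status, residual=violation)
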