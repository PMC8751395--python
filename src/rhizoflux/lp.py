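"""Optimization core: FBA, parsimonious FBA, flux variability analysis
(plain and loopless), MOMA, and single-gene deletion.

All linear programs are steady-state flux problems

    optimize  c . v   subject to   S v = 0,  lb <= v <= ub,

solved with the HiGHS backend of :func:`scipy.optimize.linprog`.  Parsimonious
FBA fixes the objective at a fraction of its optimum and then minimizes the
taxicab norm ``sum |v_i|`` via the standard non-negative flux splitting
``v = v+ - v-``, which drives thermodynamically infeasible loops to zero.
Loopless FVA enforces the loop law through a mixed-integer program on the
null space of the internal stoichiometry (solved with
:func:`scipy.optimize.milp`).  MOMA solves the quadratic program
``min ||v - v_wt||^2`` over the knockout polytope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, sparse

from .model import (
    FluxResult,
    MetabolicModel,
    evaluate_gpr,
    stoichiometric_matrix,
)

FEASIBILITY_TOL = 1e-9
ZERO_FLUX_TOL = 1e-6
ESSENTIALITY_THRESHOLD = 0.5


class InfeasibleError(RuntimeError):
    """Raised when a problem that must be feasible is not."""


@dataclass
class FvaRange:
    reaction_id: str
    minimum: float
    maximum: float
    objective_fraction: float


@dataclass
class DeletionResult:
    gene_id: str
    growth_rate: float
    wild_type_rate: float
    essential: bool
    method: str


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = optimize.linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs",
    )
    if res.status not in _STATUS:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res


def _flux_result(model: MetabolicModel, v: np.ndarray,
                 status: str = "optimal") -> FluxResult:
    c = model.objective_vector()
    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    return FluxResult(objective_value=float(c @ v), fluxes=fluxes,
                      status=status)


def fba(model: MetabolicModel) -> FluxResult:
    """Maximize the model objective ``c . v`` at steady state."""
    if not model.objective:
        raise ValueError("model has an empty objective")
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds()
    c = model.objective_vector()
    res = _solve(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                 bounds=list(zip(lb, ub)))
    if res.status != 0:
        return FluxResult(0.0, {}, _STATUS[res.status])
    return _flux_result(model, res.x)


def _split_bounds(lb: np.ndarray, ub: np.ndarray):
    """Bounds for the non-negative splitting v = p - m."""
    p_lo, p_hi = np.maximum(lb, 0.0), np.maximum(ub, 0.0)
    m_lo, m_hi = np.maximum(-ub, 0.0), np.maximum(-lb, 0.0)
    return list(zip(p_lo, p_hi)) + list(zip(m_lo, m_hi))


def minimize_weighted_flux(model: MetabolicModel, costs: np.ndarray,
                           objective_fraction: float,
                           optimum: float | None = None,
                           ) -> tuple[FluxResult, float]:
    """Minimize ``sum costs_i |v_i|`` with the objective held at a fraction
    of its optimum.  ``costs=1`` gives parsimonious (taxicab) FBA.

    Returns the flux result together with the attained weighted cost.
    """
    if not 0 < objective_fraction <= 1:
        raise ValueError("objective_fraction must be in (0, 1]")
    if optimum is None:
        wt = fba(model)
        if wt.status != "optimal":
            return FluxResult(0.0, {}, wt.status), float("nan")
        optimum = wt.objective_value
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    lb, ub = model.bounds()
    c = model.objective_vector()
    target = objective_fraction * optimum
    # relax the target by a hair so the LP stays feasible at fraction 1.0
    target -= FEASIBILITY_TOL * max(1.0, abs(optimum))
    A_eq = np.hstack([S, -S])
    A_ub = np.hstack([-c, c])[None, :]
    cost = np.concatenate([costs, costs])
    res = _solve(cost, A_ub=A_ub, b_ub=[-target], A_eq=A_eq,
                 b_eq=np.zeros(S.shape[0]), bounds=_split_bounds(lb, ub))
    if res.status != 0:
        return FluxResult(0.0, {}, _STATUS[res.status]), float("nan")
    v = res.x[:n] - res.x[n:]
    return _flux_result(model, v), float(res.fun)


def pfba(model: MetabolicModel, objective_fraction: float = 1.0) -> FluxResult:
    """Parsimonious FBA: minimize total flux at (near-)optimal objective."""
    n = len(model.reactions)
    result, _ = minimize_weighted_flux(model, np.ones(n), objective_fraction)
    return result


def fva(model: MetabolicModel, objective_fraction: float = 1.0,
        loopless: bool = False,
        reactions: list[str] | None = None) -> list[FvaRange]:
    """Per-reaction flux minima and maxima at an objective fraction.

    With ``loopless=True``, every extreme solution additionally satisfies
    the loop law (no flux around internal, thermodynamically infeasible
    cycles), via a MILP.
    """
    if not 0 < objective_fraction <= 1:
        raise ValueError("objective_fraction must be in (0, 1]")
    wt = fba(model)
    if wt.status != "optimal":
        raise InfeasibleError(
            f"FVA requires a feasible, bounded model (FBA status: {wt.status}"
            "); binding constraints: steady-state mass balance with current "
            "exchange bounds"
        )
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds()
    c = model.objective_vector()
    target = objective_fraction * wt.objective_value
    target -= FEASIBILITY_TOL * max(1.0, abs(wt.objective_value))
    wanted = [r.id for r in model.reactions] if reactions is None else reactions
    ridx = model.reaction_index()
    n = len(model.reactions)

    if loopless:
        mi = _LooplessProblem(model, S, lb, ub, c, target)
        solve_dir = mi.optimize
    else:
        A_ub = (-c)[None, :]

        def solve_dir(j: int, sense: float) -> float:
            obj = np.zeros(n)
            obj[j] = sense
            res = _solve(obj, A_ub=A_ub, b_ub=[-target], A_eq=S,
                         b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)))
            if res.status != 0:
                raise InfeasibleError(
                    f"FVA subproblem for reaction {model.reactions[j].id!r} "
                    f"returned {_STATUS[res.status]}; binding constraints: "
                    f"objective fraction {objective_fraction}"
                )
            return float(sense * res.fun)

    out = []
    for rid in wanted:
        j = ridx[rid]
        lo = solve_dir(j, 1.0)
        hi = solve_dir(j, -1.0)
        if lo > hi:  # solver noise on a fixed flux
            lo = hi = 0.5 * (lo + hi)
        out.append(FvaRange(rid, lo, hi, objective_fraction))
    return out


class _LooplessProblem:
    """Loop-law MILP: binary direction indicators on internal reactions and
    'potential' variables constrained orthogonal to every internal cycle."""

    M = 1000.0

    def __init__(self, model, S, lb, ub, c, target):
        self.n = len(model.reactions)
        self.internal = [j for j, r in enumerate(model.reactions)
                         if not r.is_boundary]
        k = len(self.internal)
        N = linalg.null_space(S[:, self.internal]) if k else np.zeros((0, 0))
        self.d = N.shape[1] if N.size else 0
        nv = self.n + 2 * k  # v, a, G
        rows = []

        eq = sparse.lil_matrix((S.shape[0], nv))
        eq[:, : self.n] = S
        rows.append(optimize.LinearConstraint(eq.tocsr(), 0.0, 0.0))
        rows.append(optimize.LinearConstraint(
            sparse.csr_matrix(np.concatenate([c, np.zeros(2 * k)])[None, :]),
            target, np.inf))
        if k:
            # v_j - M a_t in [-M, 0]  (a=1 -> v>=0 allowed; a=0 -> v<=0)
            A = sparse.lil_matrix((k, nv))
            for t, j in enumerate(self.internal):
                A[t, j] = 1.0
                A[t, self.n + t] = -self.M
            rows.append(optimize.LinearConstraint(A.tocsr(), -self.M, 0.0))
            # G_t + (M+1) a_t in [1, M]  (a=1 -> G<=-1; a=0 -> G>=1)
            A = sparse.lil_matrix((k, nv))
            for t in range(k):
                A[t, self.n + t] = self.M + 1.0
                A[t, self.n + k + t] = 1.0
            rows.append(optimize.LinearConstraint(A.tocsr(), 1.0, self.M))
            if self.d:
                A = sparse.lil_matrix((self.d, nv))
                A[:, self.n + k:] = N.T
                rows.append(optimize.LinearConstraint(A.tocsr(), 0.0, 0.0))
        self.constraints = rows
        self.k = k
        self.bounds = optimize.Bounds(
            np.concatenate([lb, np.zeros(k), -self.M * np.ones(k)]),
            np.concatenate([ub, np.ones(k), self.M * np.ones(k)]),
        )
        self.integrality = np.concatenate(
            [np.zeros(self.n), np.ones(k), np.zeros(k)]
        )

    def optimize(self, j: int, sense: float) -> float:
        obj = np.zeros(self.n + 2 * self.k)
        obj[j] = sense
        res = optimize.milp(obj, constraints=self.constraints,
                            integrality=self.integrality, bounds=self.bounds)
        if res.status != 0:
            raise InfeasibleError(
                f"loopless FVA MILP failed for reaction index {j}: "
                f"{res.message}"
            )
        return float(sense * res.fun)


def moma(model: MetabolicModel, wild_type_flux: FluxResult,
         disabled_reactions: set[str] | None = None,
         quadratic: bool = True) -> FluxResult:
    """Minimization of metabolic adjustment after a knockout.

    Finds the flux distribution of the mutant (reactions in
    ``disabled_reactions`` forced to zero) closest to the wild-type fluxes —
    Euclidean distance for the canonical quadratic form, taxicab distance
    when ``quadratic=False``.  An infeasible knockout yields status
    ``infeasible`` with growth 0.
    """
    disabled = disabled_reactions or set()
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds()
    ridx = model.reaction_index()
    for rid in disabled:
        j = ridx[rid]
        lb[j] = ub[j] = 0.0
    v_wt = wild_type_flux.flux_vector(model)
    n = len(model.reactions)

    feas = _solve(np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)))
    if feas.status != 0:
        return FluxResult(0.0, {}, "infeasible")

    # wild type still feasible -> zero adjustment is the exact optimum
    if (np.all(v_wt >= lb - FEASIBILITY_TOL)
            and np.all(v_wt <= ub + FEASIBILITY_TOL)
            and np.abs(S @ v_wt).max(initial=0.0) < 1e-6):
        return _flux_result(model, np.clip(v_wt, lb, ub))

    if not quadratic:
        # min sum |v - v_wt| via deviation splitting
        A_eq = np.block([
            [S, np.zeros((S.shape[0], 2 * n))],
            [np.eye(n), -np.eye(n), np.eye(n)],
        ])
        b_eq = np.concatenate([np.zeros(S.shape[0]), v_wt])
        cost = np.concatenate([np.zeros(n), np.ones(2 * n)])
        bnds = list(zip(lb, ub)) + [(0, None)] * (2 * n)
        res = _solve(cost, A_eq=A_eq, b_eq=b_eq, bounds=bnds)
        return _flux_result(model, res.x[:n])

    def fun(v):
        d = v - v_wt
        return float(d @ d)

    def jac(v):
        return 2.0 * (v - v_wt)

    hess = 2.0 * np.eye(n)
    res = optimize.minimize(
        fun, feas.x, jac=jac, hess=lambda v: hess, method="trust-constr",
        constraints=[optimize.LinearConstraint(S, 0.0, 0.0)],
        bounds=optimize.Bounds(lb, ub),
        options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 1000,
                 "verbose": 0},
    )
    v = np.clip(res.x, lb, ub)
    return _flux_result(model, v)


def single_gene_deletion(model: MetabolicModel,
                         genes: list[str] | None = None,
                         method: str = "fba",
                         threshold: float = ESSENTIALITY_THRESHOLD,
                         ) -> list[DeletionResult]:
    """Knock out each gene in turn and re-evaluate growth.

    A gene is essential when the mutant objective falls below
    ``threshold`` times the wild-type value (default 50%, matching the
    population-dynamics argument for pooled insertion-sequencing screens).
    """
    if method not in ("fba", "moma"):
        raise ValueError(f"unknown deletion method {method!r}")
    if genes is None:
        genes = list(model.genes)
    unknown = [g for g in genes if g not in set(model.genes)]
    if unknown:
        raise ValueError(f"genes absent from the model: {unknown}")
    wt = fba(model)
    if wt.status != "optimal":
        raise InfeasibleError("wild-type FBA is not optimal; cannot screen")
    wt_rate = wt.objective_value
    reference = pfba(model) if method == "moma" else wt

    results = []
    for gene in genes:
        disabled = {
            r.id for r in model.reactions
            if gene in r.genes and not evaluate_gpr(r.gpr, {gene})
        }
        if not disabled:
            growth = wt_rate
        elif method == "fba":
            mutant = model.copy()
            for r in mutant.reactions:
                if r.id in disabled:
                    r.lower_bound = r.upper_bound = 0.0
            sol = fba(mutant)
            growth = sol.objective_value if sol.status == "optimal" else 0.0
        else:
            sol = moma(model, reference, disabled)
            growth = sol.objective_value if sol.status == "optimal" else 0.0
        growth = max(growth, 0.0)
        results.append(DeletionResult(
            gene_id=gene, growth_rate=growth, wild_type_rate=wt_rate,
            essential=growth < threshold * wt_rate, method=method,
        ))
    return results
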