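"""Transcriptome-guided extraction of context-specific models.

The procedure mirrors expression-weighted parsimony ("reaction inclusion by
parsimony and transcript distribution"): transcript abundances are mapped
onto gene-associated reactions, overall flux is minimized with per-reaction
costs ``1 - w_r`` (highly expressed reactions are cheap), reactions that no
cost-optimal flux distribution uses are removed, and the remaining solution
space is sampled with an expression-biased sampler.  A sweep over objective
fractions ("max fit") picks the fraction whose sampled fluxes correlate best
(Spearman) with the transcriptome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .lp import (
    InfeasibleError,
    ZERO_FLUX_TOL,
    _solve,
    _split_bounds,
    fba,
    minimize_weighted_flux,
)
from .model import MetabolicModel, aggregate_gpr, stoichiometric_matrix
from .sampling import FluxSampleSet, sample_fluxes


@dataclass
class ExpressionProfile:
    """Gene abundances (RPKM) for one condition."""

    abundance: dict[str, float]
    condition: str = ""

    def __post_init__(self) -> None:
        bad = {g: a for g, a in self.abundance.items()
               if not np.isfinite(a) or a < 0}
        if bad:
            raise ValueError(f"non-finite or negative abundances: {bad}")


@dataclass
class TaskSet:
    """Reactions that contextualization must keep.

    ``protected_genes`` shields every reaction whose GPR mentions one of the
    genes (e.g. genes essential in the condition); ``forced_reactions`` puts
    positive lower bounds on reactions (e.g. demand reactions for polymers
    the cell is known to synthesize in that condition).
    """

    protected_genes: set[str] = field(default_factory=set)
    forced_reactions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r: v for r, v in self.forced_reactions.items() if v < 0}
        if bad:
            raise ValueError(f"forced minima must be >= 0: {bad}")

    def validate_against(self, model: MetabolicModel) -> None:
        stray = self.protected_genes - set(model.genes)
        if stray:
            warnings.warn(
                f"protected genes absent from model: {sorted(stray)}",
                stacklevel=2,
            )
        unknown = set(self.forced_reactions) - {r.id for r in model.reactions}
        if unknown:
            raise ValueError(f"forced reactions absent from model: "
                             f"{sorted(unknown)}")


@dataclass
class ContextualizationResult:
    pruned_model: MetabolicModel
    samples: FluxSampleSet
    objective_fraction: float
    rho: float
    rho_p: float
    removed_reactions: list[str]
    uptake_summary: pd.DataFrame
    fraction_scores: dict[float, float] = field(default_factory=dict)


def read_expression(path: str | Path, condition: str = "") -> ExpressionProfile:
    table = pd.read_csv(path, sep="\t")
    return ExpressionProfile(
        abundance=dict(zip(table["gene_id"].astype(str),
                           table["rpkm"].astype(float))),
        condition=condition or Path(path).stem,
    )


def read_tasks(gene_list_path: str | Path | None = None,
               forced_path: str | Path | None = None) -> TaskSet:
    """Task files: one protected gene per line; forced-reaction TSV with
    columns reaction_id, min_flux."""
    genes: set[str] = set()
    forced: dict[str, float] = {}
    if gene_list_path is not None:
        text = Path(gene_list_path).read_text()
        genes = {line.strip() for line in text.splitlines() if line.strip()}
    if forced_path is not None:
        table = pd.read_csv(forced_path, sep="\t")
        forced = dict(zip(table["reaction_id"].astype(str),
                          table["min_flux"].astype(float)))
    return TaskSet(protected_genes=genes, forced_reactions=forced)


def expression_to_reaction_weights(model: MetabolicModel,
                                   expr: ExpressionProfile,
                                   ) -> dict[str, float]:
    """Reaction weights in [0, 1]: GPR-aggregated abundance (OR -> max,
    AND -> min) normalized by the highest gene-associated abundance.
    Reactions without genes get the median gene-associated weight."""
    overlap = set(expr.abundance) & set(model.genes)
    if not overlap:
        raise ValueError(
            "no overlap between expression profile and model genes"
        )
    raw: dict[str, float] = {}
    for r in model.reactions:
        value = aggregate_gpr(r.gpr, expr.abundance)
        if value is not None:
            raw[r.id] = value
    top = max(raw.values(), default=0.0)
    if top <= 0:
        raise ValueError("all gene-associated abundances are zero")
    weights = {rid: a / top for rid, a in raw.items()}
    fallback = float(np.median(list(weights.values())))
    for r in model.reactions:
        weights.setdefault(r.id, fallback)
    return weights


def reaction_abundances(model: MetabolicModel, expr: ExpressionProfile,
                        ) -> dict[str, float]:
    """GPR-aggregated (un-normalized) abundance per gene-associated
    reaction."""
    out = {}
    for r in model.reactions:
        value = aggregate_gpr(r.gpr, expr.abundance)
        if value is not None:
            out[r.id] = value
    return out


def _protected_reaction_ids(model: MetabolicModel, tasks: TaskSet) -> set[str]:
    ids = set(tasks.forced_reactions) | set(model.objective)
    for r in model.reactions:
        if r.genes & tasks.protected_genes:
            ids.add(r.id)
    return ids


def _apply_tasks(model: MetabolicModel, tasks: TaskSet) -> MetabolicModel:
    out = model.copy()
    for rid, minimum in tasks.forced_reactions.items():
        r = out.get_reaction(rid)
        r.lower_bound = max(r.lower_bound, minimum)
        if r.upper_bound < r.lower_bound:
            r.upper_bound = r.lower_bound
    return out


def prune_model(model: MetabolicModel, weights: dict[str, float],
                tasks: TaskSet | None = None,
                objective_fraction: float = 0.8,
                ) -> tuple[MetabolicModel, list[str]]:
    """Remove reactions that no expression-parsimonious flux distribution
    uses.

    Minimizes ``sum (1 - w_r) |v_r|`` with the objective held at
    ``objective_fraction`` of its optimum and task minima applied.  A
    reaction is removed when it carries no flux in the minimizer *and* its
    flux range is zero over the optimal face of that weighted program, so
    alternative routes tied at the optimum survive for sampling.  Protected
    and forced reactions are never removed.
    """
    tasks = tasks or TaskSet()
    tasks.validate_against(model)
    work = _apply_tasks(model, tasks)
    wt = fba(work)
    if wt.status != "optimal":
        raise InfeasibleError(
            f"model infeasible with tasks applied (status {wt.status}); "
            f"conflicting constraints: forced minima "
            f"{sorted(tasks.forced_reactions)}"
        )
    costs = np.array([1.0 - weights.get(r.id, 0.5) for r in work.reactions])
    sol, min_cost = minimize_weighted_flux(
        work, costs, objective_fraction, optimum=wt.objective_value
    )
    if sol.status != "optimal":
        raise InfeasibleError(
            f"weighted parsimony infeasible at objective fraction "
            f"{objective_fraction}; conflicting constraints: objective "
            f"target with forced minima {sorted(tasks.forced_reactions)}"
        )

    protected = _protected_reaction_ids(work, tasks)
    candidates = [
        r.id for r in work.reactions
        if abs(sol.fluxes[r.id]) < ZERO_FLUX_TOL and r.id not in protected
    ]
    removable = _zero_on_optimal_face(
        work, costs, min_cost, objective_fraction, wt.objective_value,
        candidates,
    )

    pruned = work.copy()
    removed_set = set(removable)
    pruned.reactions = [r for r in pruned.reactions
                        if r.id not in removed_set]
    used_mets = set()
    for r in pruned.reactions:
        used_mets |= set(r.stoichiometry)
    pruned.metabolites = [m for m in pruned.metabolites if m.id in used_mets]
    used_genes = set()
    for r in pruned.reactions:
        used_genes |= r.genes
    pruned.genes = [g for g in pruned.genes if g in used_genes]
    _fix_objective_floor(pruned, objective_fraction, wt.objective_value)
    pruned.id = f"{model.id}_context"
    pruned.validate()
    return pruned, sorted(removed_set)


def _fix_objective_floor(model: MetabolicModel, fraction: float,
                         optimum: float) -> None:
    """Bake the objective-fraction constraint into the pruned model so that
    downstream sampling explores only near-objective flux states.  Only
    possible directly for a single-reaction objective."""
    if len(model.objective) != 1:
        return
    rid, weight = next(iter(model.objective.items()))
    if weight <= 0:
        return
    r = model.get_reaction(rid)
    floor = fraction * optimum / weight
    floor -= 1e-9 * max(1.0, abs(floor))
    r.lower_bound = max(r.lower_bound, floor)


def _zero_on_optimal_face(model, costs, min_cost, fraction, optimum,
                          candidates: list[str]) -> list[str]:
    """Candidates whose |flux| is zero across *all* cost-optimal solutions
    of the weighted parsimony program."""
    if not candidates:
        return []
    S = stoichiometric_matrix(model)
    n = len(model.reactions)
    lb, ub = model.bounds()
    c = model.objective_vector()
    target = fraction * optimum - 1e-9 * max(1.0, abs(optimum))
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    cost_row = np.concatenate([costs, costs])
    obj_row = np.concatenate([-c, c])
    A_ub = np.vstack([obj_row, cost_row])
    cost_cap = min_cost + 1e-9 * max(1.0, abs(min_cost))
    b_ub = np.array([-target, cost_cap])
    bounds = _split_bounds(lb, ub)
    ridx = model.reaction_index()

    removable = []
    for rid in candidates:
        j = ridx[rid]
        obj = np.zeros(2 * n)
        obj[j] = -1.0
        obj[n + j] = -1.0  # maximize p_j + m_j = |v_j|
        res = _solve(obj, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                     bounds=bounds)
        # threshold well above the parasitic flux the cost-cap slack can
        # admit, well below any genuinely usable alternative route
        if res.status != 0 or -res.fun < 1e-5:
            removable.append(rid)
    return removable


def correlate_flux_expression(samples: FluxSampleSet,
                              abundances: dict[str, float],
                              ) -> tuple[float, float]:
    """Spearman correlation of per-reaction median |flux| against
    GPR-aggregated transcript abundance.  Reactions absent from the sample
    set (pruned away) count as zero flux."""
    if len(abundances) < 3:
        raise ValueError("need at least 3 gene-associated reactions")
    med = samples.median_abs_flux()
    flux = [med.get(rid, 0.0) for rid in abundances]
    expr = list(abundances.values())
    rho, p = stats.spearmanr(flux, expr)
    return float(rho), float(p)


def summarize_uptake(result: ContextualizationResult,
                     objective_reaction: str) -> pd.DataFrame:
    """Biomass-normalized uptake per exchanged metabolite: median and IQR of
    |uptake flux| / objective flux over samples; zero-median rows dropped."""
    samples = result.samples
    model = result.pruned_model
    if objective_reaction not in samples.reaction_ids:
        raise ValueError(f"objective reaction {objective_reaction!r} not in "
                         "sample set")
    obj = samples.column(objective_reaction)
    if np.any(obj <= 0):
        raise ValueError(
            "objective flux must be positive in every sample to normalize "
            "uptake rates"
        )
    rows = []
    for r in model.reactions:
        if r.kind not in ("exchange", "sink"):
            continue
        flux = samples.column(r.id)
        uptake = np.clip(-flux, 0.0, None) / obj
        median = float(np.median(uptake))
        if median <= 0:
            continue
        q1, q3 = np.percentile(uptake, [25, 75])
        rows.append((next(iter(r.stoichiometry)), r.id, median,
                     float(q3 - q1)))
    return pd.DataFrame(
        rows, columns=["metabolite_id", "reaction_id", "median_uptake",
                       "iqr_uptake"],
    ).sort_values("median_uptake", ascending=False).reset_index(drop=True)


def _sampling_seed(seed: int, fraction: float) -> int:
    return (int(seed) * 1000 + int(round(fraction * 1000))) % (2**31 - 1)


def maxfit(model: MetabolicModel, expr: ExpressionProfile,
           tasks: TaskSet | None = None,
           fractions: list[float] | None = None,
           n_samples: int = 500, seed: int = 1,
           refine: bool = True) -> ContextualizationResult:
    """Sweep objective fractions, keep the context model whose sampled
    fluxes correlate best with the transcriptome.

    After the coarse grid, one refinement pass bisects the neighbourhood of
    the best fraction at half the grid step, which is how a best fraction
    can fall between grid points.
    """
    if fractions is None:
        fractions = [round(0.5 + 0.05 * i, 3) for i in range(10)]  # 0.50..0.95
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    tasks = tasks or TaskSet()
    weights = expression_to_reaction_weights(model, expr)
    abundances = reaction_abundances(model, expr)

    evaluated: dict[float, tuple] = {}

    def evaluate(f: float):
        if f in evaluated:
            return
        try:
            pruned, removed = prune_model(model, weights, tasks, f)
        except InfeasibleError:
            evaluated[f] = None
            return
        samples = sample_fluxes(pruned, n_samples,
                                seed=_sampling_seed(seed, f),
                                weights=weights)
        rho, p = correlate_flux_expression(samples, abundances)
        evaluated[f] = (rho, p, pruned, removed, samples)

    for f in sorted(fractions):
        evaluate(f)
    feasible = {f: r for f, r in evaluated.items() if r is not None}
    if not feasible:
        raise InfeasibleError("all objective fractions were infeasible")

    if refine and len(fractions) > 1:
        grid = sorted(fractions)
        step = min(b - a for a, b in zip(grid, grid[1:]))
        best = max(feasible, key=lambda f: (feasible[f][0], f))
        for f in (round(best - step / 2, 4), round(best + step / 2, 4)):
            if grid[0] <= f <= grid[-1]:
                evaluate(f)
        feasible = {f: r for f, r in evaluated.items() if r is not None}

    # ties in rho resolve to the largest fraction: the least relaxation
    # of the objective among equally well-supported models
    best = max(feasible, key=lambda f: (feasible[f][0], f))
    rho, p, pruned, removed, samples = feasible[best]
    result = ContextualizationResult(
        pruned_model=pruned, samples=samples, objective_fraction=best,
        rho=rho, rho_p=p, removed_reactions=removed,
        uptake_summary=pd.DataFrame(),
        fraction_scores={f: r[0] for f, r in feasible.items()},
    )
    if len(pruned.objective) == 1:
        obj_rid = next(iter(pruned.objective))
        try:
            result.uptake_summary = summarize_uptake(result, obj_rid)
        except ValueError:
            warnings.warn("uptake summary skipped: non-positive objective "
                          "flux in some samples", stacklevel=2)
    return result
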