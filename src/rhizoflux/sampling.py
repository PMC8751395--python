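"""Flux sampling of the steady-state polytope.

Plain mode is hit-and-run with fixed thinning inside
``{v : S v = 0, lb <= v <= ub}``, parametrized on the null space of S so
every step stays mass-balanced to machine precision.  Weighted mode mixes
hit-and-run steps with pulls toward the expression-parsimonious flux
distribution (the minimizer of ``sum (1 - w_r) |v_r|``), which biases the
chain so reactions with high weights tend to carry more flux.  This is a
contract about monotone bias, not a statement about the stationary
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .lp import InfeasibleError, _solve, _split_bounds
from .model import MetabolicModel, stoichiometric_matrix

_DIRECTION_TOL = 1e-11


@dataclass
class FluxSampleSet:
    samples: np.ndarray  # (n_samples, n_reactions)
    reaction_ids: list[str]
    seed: int
    sampler: str

    def column(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]

    def median_abs_flux(self) -> dict[str, float]:
        med = np.median(np.abs(self.samples), axis=0)
        return dict(zip(self.reaction_ids, med.tolist()))


def _warm_start(model, S, lb, ub) -> np.ndarray:
    """A well-centered interior point: the average of all per-reaction
    min/max LP solutions (a convex combination of polytope vertices)."""
    n = len(model.reactions)
    solutions = []
    for j in range(n):
        for sense in (1.0, -1.0):
            obj = np.zeros(n)
            obj[j] = sense
            res = _solve(obj, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         bounds=list(zip(lb, ub)))
            if res.status != 0:
                raise InfeasibleError(
                    "cannot sample: polytope is infeasible or unbounded "
                    f"(reaction {model.reactions[j].id!r}, status "
                    f"{res.status})"
                )
            solutions.append(res.x)
    return np.mean(solutions, axis=0)


def _weighted_pull_points(model, S, lb, ub, weights
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Two anchors for expression-biased sampling: the cost-minimal
    (expression-parsimonious) flux state and the state maximizing total
    weighted |flux| (with a small parsimony tie-break)."""
    n = len(model.reactions)
    w = np.array([weights.get(r.id, 0.5) for r in model.reactions])
    A_eq = np.hstack([S, -S])
    b_eq = np.zeros(S.shape[0])
    bounds = _split_bounds(lb, ub)
    points = []
    for cost in (1.0 - w, 0.01 - w):
        res = _solve(np.concatenate([cost, cost]), A_eq=A_eq, b_eq=b_eq,
                     bounds=bounds)
        if res.status != 0:
            raise InfeasibleError(
                f"weighted pull LP not optimal (status {res.status}); the "
                "flux polytope must be feasible and bounded"
            )
        points.append(res.x[:n] - res.x[n:])
    return points[0], points[1]


def sample_fluxes(model: MetabolicModel, n: int, seed: int,
                  weights: dict[str, float] | None = None,
                  thin: int = 20, burn_in: int = 100,
                  pull_probability: float = 0.25) -> FluxSampleSet:
    """Draw ``n`` feasible flux vectors; identical seeds give identical
    output.  ``weights`` switches on expression-biased sampling."""
    if n < 1:
        raise ValueError("n must be >= 1")
    S = stoichiometric_matrix(model)
    lb, ub = model.bounds()
    rng = np.random.default_rng(seed)

    v = _warm_start(model, S, lb, ub)
    N = linalg.null_space(S) if S.size else np.eye(len(model.reactions))
    ndim = N.shape[1] if N.size else 0
    pulls = (_weighted_pull_points(model, S, lb, ub, weights)
             if weights is not None else None)

    samples = np.empty((n, len(model.reactions)))
    collected = 0
    step = 0
    total_steps = burn_in + n * thin
    while collected < n:
        step += 1
        if pulls is not None and rng.random() < pull_probability:
            target = pulls[int(rng.random() < 0.5)]
            v = v + rng.random() * (target - v)
        elif ndim:
            direction = N @ rng.standard_normal(ndim)
            norm = np.linalg.norm(direction)
            if norm > _DIRECTION_TOL:
                direction /= norm
                t_lo, t_hi = -np.inf, np.inf
                active = np.abs(direction) > _DIRECTION_TOL
                if active.any():
                    with np.errstate(divide="ignore", invalid="ignore"):
                        low = (lb[active] - v[active]) / direction[active]
                        high = (ub[active] - v[active]) / direction[active]
                    t_lo = np.maximum(np.minimum(low, high), -1e9).max()
                    t_hi = np.minimum(np.maximum(low, high), 1e9).min()
                if t_hi > t_lo:
                    v = v + rng.uniform(t_lo, t_hi) * direction
        v = np.clip(v, lb, ub)
        if step > burn_in and (step - burn_in) % thin == 0:
            samples[collected] = v
            collected += 1
        if step > 10 * total_steps:  # safety, cannot normally trigger
            raise RuntimeError("sampler failed to collect samples")

    return FluxSampleSet(
        samples=samples,
        reaction_ids=[r.id for r in model.reactions],
        seed=seed,
        sampler="hit-and-run"
                + ("+weighted-pull" if pulls is not None else ""),
    )
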