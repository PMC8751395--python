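"""In-silico nutrient environments: media, root-exudate, and nodule-style
boundary conditions.

An :class:`Environment` lists metabolites available for uptake.  Applying it
to a model opens the matching extracellular exchange reactions to uptake
(lower bound ``-uptake_bound``); metabolites present only intracellularly
get a sink reaction (bounds ``(-uptake_bound, 0)``) so that compounds
present in the environment are not excluded merely because no transporter is
annotated.  All other exchange and sink reactions are closed to uptake but
left open to secretion.  Fixed uptake rates (e.g. a measured glucose uptake
of 1.710 mmol h^-1 gDW^-1) clamp the corresponding exchange lower bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lp import fba
from .model import MetabolicModel, Metabolite, Reaction

GROWTH_TOL = 1e-6


@dataclass
class Environment:
    name: str = "environment"
    available: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    uptake_bound: float = 1000.0
    fixed_uptakes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.available) & set(self.excluded)
        if overlap:
            raise ValueError(
                f"metabolites both available and excluded: {sorted(overlap)}"
            )
        if self.uptake_bound <= 0:
            raise ValueError("uptake_bound must be positive")
        for mid, rate in self.fixed_uptakes.items():
            if rate < 0:
                raise ValueError(f"fixed uptake for {mid!r} must be >= 0")

    def with_carbon_source(self, metabolite_id: str) -> "Environment":
        return Environment(
            name=f"{self.name}+{metabolite_id}",
            available=[*self.available, metabolite_id],
            excluded=list(self.excluded),
            uptake_bound=self.uptake_bound,
            fixed_uptakes=dict(self.fixed_uptakes),
        )


@dataclass
class GrowthCall:
    carbon_source: str
    predicted_growth: float
    grows: bool


def read_environment(path: str | Path, name: str | None = None,
                     uptake_bound: float = 1000.0) -> Environment:
    """Read a TSV with columns metabolite_id, role(available|excluded)
    and optional fixed_uptake."""
    table = pd.read_csv(path, sep="\t")
    available, excluded, fixed = [], [], {}
    for _, row in table.iterrows():
        role = str(row["role"]).strip().lower()
        mid = str(row["metabolite_id"]).strip()
        if role == "available":
            available.append(mid)
            if "fixed_uptake" in table.columns and pd.notna(row.get("fixed_uptake")):
                fixed[mid] = float(row["fixed_uptake"])
        elif role == "excluded":
            excluded.append(mid)
        else:
            raise ValueError(f"{path}: unknown role {role!r} for {mid!r}")
    return Environment(name=name or Path(path).stem, available=available,
                       excluded=excluded, uptake_bound=uptake_bound,
                       fixed_uptakes=fixed)


def _exchanges_by_metabolite(model: MetabolicModel) -> dict[str, Reaction]:
    out = {}
    for r in model.reactions:
        if r.kind == "exchange":
            out[next(iter(r.stoichiometry))] = r
    return out


def apply_environment(model: MetabolicModel, env: Environment,
                      ) -> tuple[MetabolicModel, dict[str, list[str]]]:
    """Return a copy of the model with the environment's boundary bounds.

    The report maps 'skipped' to environment metabolites absent from the
    model (also emitted as warnings), and 'sinks_added' to metabolites
    supplied through newly created sink reactions.
    """
    out = model.copy()
    report: dict[str, list[str]] = {"skipped": [], "sinks_added": []}
    exchanges = _exchanges_by_metabolite(out)

    def matching_metabolites(mid: str) -> list[Metabolite]:
        return [m for m in out.metabolites
                if m.id == mid or m.id.rsplit("[", 1)[0] == mid]

    # close every boundary uptake route first; secretion stays open
    for r in out.reactions:
        if r.kind in ("exchange", "sink") and r.lower_bound < 0:
            r.lower_bound = 0.0

    listed = set(env.available) | set(env.fixed_uptakes)
    for mid in sorted(listed):
        mets = matching_metabolites(mid)
        extracellular = [m for m in mets if m.id in exchanges]
        if extracellular:
            rxn = exchanges[extracellular[0].id]
            rate = env.fixed_uptakes.get(mid, env.uptake_bound)
            rxn.lower_bound = -rate
        elif mets:
            met = mets[0]
            sink_id = f"SK_{met.id}"
            if sink_id in {r.id for r in out.reactions}:
                rxn = out.get_reaction(sink_id)
            else:
                rxn = Reaction(
                    id=sink_id, name=f"{met.id} sink",
                    stoichiometry={met.id: -1.0}, lower_bound=0.0,
                    upper_bound=0.0, kind="sink",
                )
                out.reactions.append(rxn)
                report["sinks_added"].append(met.id)
            rxn.lower_bound = -env.fixed_uptakes.get(mid, env.uptake_bound)
            rxn.upper_bound = 0.0
        else:
            report["skipped"].append(mid)
            warnings.warn(
                f"environment metabolite {mid!r} absent from model "
                f"{model.id!r}; skipped", stacklevel=2,
            )
    out.validate()
    return out, report


def predict_growth(model: MetabolicModel, env: Environment) -> float:
    """FBA optimum of the model objective under the environment (h^-1 for a
    biomass objective); 0 when infeasible."""
    constrained, _ = apply_environment(model, env)
    sol = fba(constrained)
    if sol.status != "optimal":
        return 0.0
    return max(sol.objective_value, 0.0)


def carbon_source_screen(model: MetabolicModel, base_env: Environment,
                         candidates: list[str],
                         ) -> tuple[list[GrowthCall], list[str]]:
    """Growth call per candidate carbon source added individually to the
    base environment.  Candidates that are not metabolites of the model are
    returned separately rather than called."""
    present, absent = [], []
    base_ids = {m.id for m in model.metabolites}
    stem_ids = {m.id.rsplit("[", 1)[0] for m in model.metabolites}
    for mid in candidates:
        (present if mid in base_ids or mid in stem_ids else absent).append(mid)
    calls = []
    for mid in present:
        growth = predict_growth(model, base_env.with_carbon_source(mid))
        calls.append(GrowthCall(carbon_source=mid, predicted_growth=growth,
                                grows=growth > GROWTH_TOL))
    return calls, absent


def growth_calls_frame(calls: list[GrowthCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.carbon_source, c.predicted_growth, c.grows) for c in calls],
        columns=["carbon_source", "predicted_growth", "grows"],
    )
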