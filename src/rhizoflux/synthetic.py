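"""Generators for synthetic fixtures: mass-balanced toy models with
analytically known optima, planted expression contexts for generative
round-trip tests, brute-force essentiality labels, and simulated
differential-expression score sets.

Toy models are small (tens of reactions) by construction so that exhaustive
oracles — per-reaction LP enumeration, exhaustive gene deletion — run in
seconds.  Expression noise is lognormal, reflecting the right-skewed
heavy-tailed shape of RPKM distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .model import MetabolicModel, Metabolite, Reaction, evaluate_gpr
from .contextualize import ExpressionProfile
from .reporter import GeneScore, metabolite_neighbour_genes

#: Expression tiers (RPKM-like): planted-active genes, decoy genes, and
#: everything else.  Active vs decoy keeps the 10x separation the
#: contextualization signal relies on.
HIGH_MEAN = 100.0
LOW_MEAN = 10.0
MID_MEAN = 30.0

_GPR_PATTERNS = (
    lambda g: g[0],
    lambda g: f"{g[0]} and {g[1]}",
    lambda g: f"({g[0]} and {g[1]}) or {g[2]}",
    lambda g: f"{g[0]} or {g[1]}",
)


@dataclass
class ToySpec:
    n_linear_steps: int = 4
    n_decoy_branches: int = 1
    with_loop: bool = False
    carbon_sources: int = 1
    biomass_yield: float = 0.5
    uptake_bound: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_linear_steps, self.n_decoy_branches,
               self.carbon_sources) < 0:
            raise ValueError("counts must be >= 0")
        if self.biomass_yield <= 0:
            raise ValueError("biomass_yield must be positive")


@dataclass
class PlantedContext:
    active_reactions: set[str]
    decoy_reactions: set[str]
    true_fraction: float
    noise_sd: float
    seed: int
    #: flux carried by each active reaction in the planted ground-truth
    #: state; expression is generated proportional to it when present.
    reference_flux: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.active_reactions & self.decoy_reactions:
            raise ValueError("active and decoy reaction sets overlap")
        if not 0 < self.true_fraction <= 1:
            raise ValueError("true_fraction must be in (0, 1]")


def make_toy_model(spec: ToySpec) -> tuple[MetabolicModel, float]:
    """A mass-balanced toy model plus its closed-form FBA optimum.

    Carbon enters through exchanges (uptake bound per source), flows down a
    linear chain into biomass; optional decoy branches bypass the first
    chain step, an optional internal two-cycle tests loop handling, a
    sinked cofactor and a demand drain exercise every boundary kind.  The
    optimum is uptake-limited: ``carbon_sources * uptake_bound * yield``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_counter = 0

    def new_genes(n: int) -> list[str]:
        nonlocal gene_counter
        out = [f"g{gene_counter + i}" for i in range(n)]
        gene_counter += n
        return out

    def random_gpr() -> str:
        pattern = _GPR_PATTERNS[rng.integers(len(_GPR_PATTERNS))]
        return pattern(new_genes(3))

    mets = [Metabolite("V_c", compartment="c0"),
            Metabolite("W_c", compartment="c0")]
    rxns: list[Reaction] = []

    n_chain_mets = spec.n_linear_steps + 1
    for i in range(1, n_chain_mets + 1):
        mets.append(Metabolite(f"M{i}_c", compartment="c0"))

    for k in range(spec.carbon_sources):
        mets.append(Metabolite(f"C{k}_e", compartment="e0"))
        mets.append(Metabolite(f"C{k}_c", compartment="c0"))
        rxns.append(Reaction(
            id=f"EX_C{k}", stoichiometry={f"C{k}_e": -1.0},
            lower_bound=-spec.uptake_bound, upper_bound=1000.0,
            kind="exchange",
        ))
        rxns.append(Reaction(
            id=f"T_C{k}", stoichiometry={f"C{k}_e": -1.0, f"C{k}_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=random_gpr(),
            kind="transport",
        ))
        rxns.append(Reaction(
            id=f"ASSIM_C{k}", stoichiometry={f"C{k}_c": -1.0, "M1_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=random_gpr(),
        ))

    for i in range(1, spec.n_linear_steps + 1):
        rxns.append(Reaction(
            id=f"CHAIN_{i}",
            stoichiometry={f"M{i}_c": -1.0, f"M{i + 1}_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=random_gpr(),
        ))

    if spec.n_linear_steps >= 1:
        for d in range(spec.n_decoy_branches):
            mets.append(Metabolite(f"D{d}_c", compartment="c0"))
            rxns.append(Reaction(
                id=f"DECOY_{d}a",
                stoichiometry={"M1_c": -1.0, f"D{d}_c": 1.0},
                lower_bound=0.0, upper_bound=1000.0, gpr=random_gpr(),
            ))
            rxns.append(Reaction(
                id=f"DECOY_{d}b",
                stoichiometry={f"D{d}_c": -1.0, "M2_c": 1.0},
                lower_bound=0.0, upper_bound=1000.0, gpr=random_gpr(),
            ))

    if spec.with_loop:
        mets.append(Metabolite("X_c", compartment="c0"))
        last = f"M{n_chain_mets}_c"
        rxns.append(Reaction(
            id="LOOP_A", stoichiometry={last: -1.0, "X_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))
        rxns.append(Reaction(
            id="LOOP_B", stoichiometry={"X_c": -1.0, last: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))

    rxns.append(Reaction(
        id="SK_V_c", stoichiometry={"V_c": -1.0},
        lower_bound=-1000.0, upper_bound=0.0, kind="sink",
    ))
    rxns.append(Reaction(
        id="SIDE_W", stoichiometry={"M1_c": -1.0, "W_c": 1.0},
        lower_bound=0.0, upper_bound=1000.0, gpr=random_gpr(),
    ))
    rxns.append(Reaction(
        id="DM_W_c", stoichiometry={"W_c": -1.0},
        lower_bound=0.0, upper_bound=1000.0, kind="demand",
    ))
    rxns.append(Reaction(
        id="BIOMASS",
        stoichiometry={f"M{n_chain_mets}_c": -1.0 / spec.biomass_yield,
                       "V_c": -0.01},
        lower_bound=0.0, upper_bound=1000.0, kind="objective-support",
    ))

    model = MetabolicModel(
        id=f"toy_s{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        genes=[f"g{i}" for i in range(gene_counter)],
        objective={"BIOMASS": 1.0},
    )
    model.validate()
    optimum = spec.carbon_sources * spec.uptake_bound * spec.biomass_yield
    return model, optimum


def make_planted_model(true_fraction: float = 0.8,
                       uptake_bound: float = 10.0,
                       n_active_routes: int = 8,
                       n_overflow: int = 3,
                       n_side: int = 3,
                       n_pure_decoys: int = 2,
                       seed: int = 0,
                       noise_sd: float = 0.05,
                       ) -> tuple[MetabolicModel, PlantedContext]:
    """A capacity-tiered model whose expression-active subnetwork is the
    ground truth at ``true_fraction`` of the optimum.

    Many equal-capacity parallel routes feed biomass, sized so that exactly
    all of them are needed at ``true_fraction`` of the maximal growth.
    Those routes are planted as active (high expression); overflow routes
    and detours as decoys (low expression); idle side branches as
    intermediate.  Below the true fraction, fewer active routes are needed
    and pruning drops high-expression reactions; above it, low-expression
    overflow must carry flux — so the flux-expression rank correlation
    peaks at the true fraction.  This is the basis of the generative
    round-trip (max-fit parameter recovery) tests.
    """
    required = true_fraction * uptake_bound
    # staggered capacities: at the true fraction every route is forced to
    # its capacity, giving a distinct, expression-concordant flux ranking
    spread = np.linspace(1.25, 0.75, n_active_routes)
    active_caps = list(required * spread / spread.sum())
    spare = uptake_bound - required
    overflow_caps = [max(spare, 0.5)] * n_overflow

    mets = [
        Metabolite("C_e", compartment="e0"),
        Metabolite("C_c", compartment="c0"),
        Metabolite("P_c", compartment="c0"),
        Metabolite("V_c", compartment="c0"),
    ]
    rxns = [
        Reaction(id="EX_C", stoichiometry={"C_e": -1.0},
                 lower_bound=-uptake_bound, upper_bound=1000.0,
                 kind="exchange"),
        Reaction(id="T_C", stoichiometry={"C_e": -1.0, "C_c": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, gpr="gT",
                 kind="transport"),
        Reaction(id="SK_V_c", stoichiometry={"V_c": -1.0},
                 lower_bound=-1000.0, upper_bound=0.0, kind="sink"),
        Reaction(id="BIOMASS",
                 stoichiometry={"P_c": -1.0, "V_c": -0.01},
                 lower_bound=0.0, upper_bound=1000.0,
                 kind="objective-support"),
    ]
    genes = ["gT"]
    active = {"T_C"}
    decoys: set[str] = set()

    for i, cap in enumerate(active_caps, start=1):
        genes.append(f"gR{i}")
        rxns.append(Reaction(
            id=f"ROUTE_{i}", stoichiometry={"C_c": -1.0, "P_c": 1.0},
            lower_bound=0.0, upper_bound=cap, gpr=f"gR{i}",
        ))
        active.add(f"ROUTE_{i}")
    for i, cap in enumerate(overflow_caps, start=1):
        genes.append(f"gO{i}")
        rxns.append(Reaction(
            id=f"OVERFLOW_{i}", stoichiometry={"C_c": -1.0, "P_c": 1.0},
            lower_bound=0.0, upper_bound=cap, gpr=f"gO{i}",
        ))
        decoys.add(f"OVERFLOW_{i}")
    for d in range(n_pure_decoys):
        mets.append(Metabolite(f"D{d}_c", compartment="c0"))
        genes += [f"gD{d}a", f"gD{d}b"]
        rxns.append(Reaction(
            id=f"DECOY_{d}a", stoichiometry={"C_c": -1.0, f"D{d}_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=f"gD{d}a",
        ))
        rxns.append(Reaction(
            id=f"DECOY_{d}b", stoichiometry={f"D{d}_c": -1.0, "P_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=f"gD{d}b",
        ))
        decoys |= {f"DECOY_{d}a", f"DECOY_{d}b"}
    for s in range(n_side):
        mets.append(Metabolite(f"W{s}_c", compartment="c0"))
        genes.append(f"gS{s}")
        rxns.append(Reaction(
            id=f"SIDE_{s}", stoichiometry={"P_c": -1.0, f"W{s}_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0, gpr=f"gS{s}",
        ))
        rxns.append(Reaction(
            id=f"DM_W{s}_c", stoichiometry={f"W{s}_c": -1.0},
            lower_bound=0.0, upper_bound=1000.0, kind="demand",
        ))

    model = MetabolicModel(
        id=f"planted_s{seed}", metabolites=mets, reactions=rxns,
        genes=genes, objective={"BIOMASS": 1.0},
    )
    model.validate()
    reference = {"T_C": required}
    for i, cap in enumerate(active_caps, start=1):
        reference[f"ROUTE_{i}"] = cap
    ctx = PlantedContext(
        active_reactions=active, decoy_reactions=decoys,
        true_fraction=true_fraction, noise_sd=noise_sd, seed=seed,
        reference_flux=reference,
    )
    return model, ctx


def simulate_expression(model: MetabolicModel, ctx: PlantedContext,
                        condition: str = "planted") -> ExpressionProfile:
    """Expression profile with the planted structure: genes of active
    reactions high, decoy genes low (10x below), everything else
    intermediate; multiplicative lognormal noise, exact means at
    ``noise_sd = 0``.

    When the context carries a reference flux distribution, active-gene
    means scale with the flux their reaction carries in the ground-truth
    state (normalized to its median), emulating transcript abundance
    tracking pathway usage."""
    import warnings

    rxn_by_id = {r.id: r for r in model.reactions}
    for rid in ctx.active_reactions:
        if not rxn_by_id[rid].genes:
            warnings.warn(f"active reaction {rid!r} has no GPR; it cannot "
                          "carry an expression signal", stacklevel=2)
    ref = ctx.reference_flux
    ref_scale = (float(np.median([abs(v) for v in ref.values()]))
                 if ref else 1.0) or 1.0
    tier = {}
    for rid in ctx.decoy_reactions:
        for g in rxn_by_id[rid].genes:
            tier[g] = LOW_MEAN
    for rid in ctx.active_reactions:  # active wins over decoy membership
        factor = abs(ref[rid]) / ref_scale if rid in ref else 1.0
        for g in rxn_by_id[rid].genes:
            tier[g] = HIGH_MEAN * factor
    rng = np.random.default_rng(ctx.seed)
    abundance = {}
    for g in model.genes:
        mean = tier.get(g, MID_MEAN)
        abundance[g] = mean * float(np.exp(ctx.noise_sd *
                                           rng.standard_normal()))
    return ExpressionProfile(abundance=abundance, condition=condition)


def brute_force_essentiality(model: MetabolicModel,
                             threshold: float = 0.5) -> dict[str, bool]:
    """Exhaustive deletion oracle: per gene, disable GPR-false reactions and
    re-solve FBA with a directly assembled LP (independent of the engine in
    :mod:`rhizoflux.lp`)."""
    met_index = {m.id: i for i, m in enumerate(model.metabolites)}

    def solve(disabled: set[str]) -> float:
        n = len(model.reactions)
        A_eq = np.zeros((len(model.metabolites), n))
        c = np.zeros(n)
        bounds = []
        for j, r in enumerate(model.reactions):
            for mid, coeff in r.stoichiometry.items():
                A_eq[met_index[mid], j] = coeff
            if r.id in disabled:
                bounds.append((0.0, 0.0))
            else:
                bounds.append((r.lower_bound, r.upper_bound))
            c[j] = -model.objective.get(r.id, 0.0)
        res = optimize.linprog(c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]),
                               bounds=bounds, method="highs")
        return -res.fun if res.status == 0 else 0.0

    wild_type = solve(set())
    labels = {}
    for gene in model.genes:
        disabled = {
            r.id for r in model.reactions
            if gene in r.genes and not evaluate_gpr(r.gpr, {gene})
        }
        growth = solve(disabled) if disabled else wild_type
        labels[gene] = growth < threshold * wild_type
    return labels


def simulate_de_scores(model: MetabolicModel, perturbed_metabolite: str,
                       effect: float, seed: int = 1) -> list[GeneScore]:
    """Differential-expression scores with signal planted around one
    metabolite: its neighbour genes get p-values from ``u**(1 + effect)``
    (uniform at effect 0, sub-uniform otherwise), all other genes uniform
    with random direction."""
    neighbours = metabolite_neighbour_genes(model).get(perturbed_metabolite)
    if not neighbours:
        raise ValueError(
            f"metabolite {perturbed_metabolite!r} has no neighbour genes"
        )
    rng = np.random.default_rng(seed)
    scores = []
    for gene in model.genes:
        u = float(rng.random())
        if gene in neighbours:
            scores.append(GeneScore(gene, u ** (1.0 + effect), "up"))
        else:
            direction = "up" if rng.random() < 0.5 else "down"
            scores.append(GeneScore(gene, u, direction))
    return scores
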