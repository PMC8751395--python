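"""Core data structures for genome-scale metabolic models.

A :class:`MetabolicModel` holds the stoichiometric matrix ``S`` (implicitly,
as per-reaction stoichiometries), flux bounds ``lb``/``ub``, the linear
objective ``c`` and gene-protein-reaction (GPR) rules.  Steady-state flux
vectors ``v`` satisfy ``S @ v = 0`` with ``lb <= v <= ub``; the optimization
routines that operate on these structures live in :mod:`rhizoflux.lp`.

Boundary reactions follow the flux-balance convention: a negative flux on an
exchange or sink reaction is uptake into the system, a positive flux is
secretion.  Exchange, sink and demand reactions each touch exactly one
metabolite.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

DEFAULT_BOUND = 1000.0

REACTION_KINDS = (
    "metabolic",
    "transport",
    "exchange",
    "sink",
    "demand",
    "objective-support",
)

BOUNDARY_KINDS = ("exchange", "sink", "demand")


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class GPRSyntaxError(ValueError):
    """Raised when a gene-protein-reaction rule cannot be parsed."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c0"
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be non-empty"
            )


@dataclass
class Reaction:
    """A (possibly reversible) reaction with flux bounds and a GPR rule.

    ``stoichiometry`` maps metabolite ids to coefficients; negative
    coefficients are consumed, positive produced.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    kind: str = "metabolic"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(
                f"reaction {self.id!r}: unknown kind {self.kind!r}"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(
                f"reaction {self.id!r}: stoichiometry must be non-empty"
            )
        if self.kind in BOUNDARY_KINDS and len(self.stoichiometry) != 1:
            raise ModelValidationError(
                f"reaction {self.id!r}: {self.kind} reactions must touch "
                f"exactly one metabolite, got {len(self.stoichiometry)}"
            )

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    @property
    def is_boundary(self) -> bool:
        return self.kind in BOUNDARY_KINDS

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound


@dataclass
class MetabolicModel:
    """A stoichiometric model: metabolites x reactions, bounds, objective."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective: dict[str, float] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def get_metabolite(self, mid: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == mid:
                return m
        raise KeyError(mid)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        met_set = set(met_ids)
        gene_set = set(self.genes)
        for r in self.reactions:
            missing = set(r.stoichiometry) - met_set
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites: "
                    f"{sorted(missing)}"
                )
            orphan = r.genes - gene_set
            if orphan:
                raise ModelValidationError(
                    f"reaction {r.id!r} GPR uses genes absent from the gene "
                    f"list: {sorted(orphan)}"
                )
        unknown_obj = set(self.objective) - set(rxn_ids)
        if unknown_obj:
            raise ModelValidationError(
                f"objective references unknown reactions: {sorted(unknown_obj)}"
            )

    # -- numeric views -----------------------------------------------------
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        ridx = self.reaction_index()
        for rid, w in self.objective.items():
            c[ridx[rid]] = w
        return c

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[
                replace(r, stoichiometry=dict(r.stoichiometry))
                for r in self.reactions
            ],
            genes=list(self.genes),
            objective=dict(self.objective),
            notes=dict(self.notes),
        )


@dataclass
class FluxResult:
    """Outcome of a flux computation (FBA, pFBA, MOMA)."""

    objective_value: float
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    def flux_vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes.get(r.id, 0.0) for r in model.reactions])


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense stoichiometric matrix S (metabolites x reactions)."""
    midx = model.metabolite_index()
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            S[midx[mid], j] = coeff
    return S


# ---------------------------------------------------------------------------
# GPR rules: case-insensitive boolean expressions over gene ids with AND/OR
# and parentheses.  No NOT.  An empty rule means "no gene requirement".
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _GprNode:
    pass


@dataclass
class _Gene(_GprNode):
    gene: str


@dataclass
class _And(_GprNode):
    operands: list[_GprNode]


@dataclass
class _Or(_GprNode):
    operands: list[_GprNode]


def _tokenize(rule: str) -> list[str]:
    return _TOKEN_RE.findall(rule)


def parse_gpr(rule: str) -> _GprNode | None:
    """Parse a GPR rule into an expression tree; empty rule -> None."""
    tokens = _tokenize(rule)
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> _GprNode:
        operands = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            operands.append(parse_and())
        return operands[0] if len(operands) == 1 else _Or(operands)

    def parse_and() -> _GprNode:
        operands = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            operands.append(parse_atom())
        return operands[0] if len(operands) == 1 else _And(operands)

    def parse_atom() -> _GprNode:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of rule: {rule!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in rule {rule!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in rule {rule!r}")
        return _Gene(advance())

    node = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(
            f"trailing tokens {tokens[pos:]!r} in rule {rule!r}"
        )
    return node


def gpr_genes(rule: str) -> set[str]:
    """All gene ids referenced by a rule."""
    node = parse_gpr(rule)
    out: set[str] = set()

    def walk(n: _GprNode | None) -> None:
        if n is None:
            return
        if isinstance(n, _Gene):
            out.add(n.gene)
        else:
            for child in n.operands:  # type: ignore[union-attr]
                walk(child)

    walk(node)
    return out


def evaluate_gpr(rule: str, deleted_genes: Iterable[str] = ()) -> bool:
    """Whether a reaction remains catalysable after deleting ``deleted_genes``.

    Empty rule -> True (spontaneous / non-gene-associated reactions are
    unaffected by gene deletions).
    """
    deleted = set(deleted_genes)
    node = parse_gpr(rule)

    def ev(n: _GprNode | None) -> bool:
        if n is None:
            return True
        if isinstance(n, _Gene):
            return n.gene not in deleted
        if isinstance(n, _And):
            return all(ev(c) for c in n.operands)
        return any(ev(c) for c in n.operands)

    return ev(node)


def aggregate_gpr(rule: str, abundance: Mapping[str, float],
                  missing: float = 0.0) -> float | None:
    """Aggregate gene abundances over a GPR rule: OR -> max, AND -> min.

    Isoenzymes (OR) add capacity, so the most abundant operand wins; enzyme
    complexes (AND) are limited by the scarcest subunit.  Genes absent from
    ``abundance`` contribute ``missing``.  Empty rule -> None.
    """
    node = parse_gpr(rule)
    if node is None:
        return None

    def agg(n: _GprNode) -> float:
        if isinstance(n, _Gene):
            return float(abundance.get(n.gene, missing))
        if isinstance(n, _And):
            return min(agg(c) for c in n.operands)
        return max(agg(c) for c in n.operands)

    value = agg(node)
    if not math.isfinite(value):
        raise ValueError(f"non-finite aggregated abundance for rule {rule!r}")
    return value
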