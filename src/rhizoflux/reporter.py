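"""Reporter-metabolite analysis.

Gene-level differential-expression p-values are converted to z-scores
(``z_g = Phi^-1(1 - p)``) and aggregated over the metabolite neighbourhoods
defined by the model topology: the neighbours of a metabolite are the genes
appearing in the GPRs of the reactions that involve it.  The aggregate
``z_raw = sum(z_g) / sqrt(k)`` is corrected against the background of random
gene sets of the same size, and the corrected score is converted back to a
p-value.  Metabolites with small reporter p-values mark network
neighbourhoods of coordinated transcriptional change.

Currency metabolites (protons, water, ATP, redox cofactors, ...) neighbour
most genes and would swamp the ranking; they are excluded by a configurable
list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-16

#: Base ids (compartment suffix stripped) excluded from reporting by default.
DEFAULT_CURRENCY = frozenset({
    "h", "h2o", "atp", "adp", "amp", "pi", "ppi",
    "nad", "nadh", "nadp", "nadph", "co2", "o2",
})


@dataclass
class GeneScore:
    gene_id: str
    p_value: float
    direction: str = "both"  # up | down | both

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(
                f"gene {self.gene_id!r}: p-value {self.p_value} outside [0,1]"
            )
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")


def read_gene_scores(path: str | Path) -> list[GeneScore]:
    table = pd.read_csv(path, sep="\t")
    direction = (table["direction"].astype(str)
                 if "direction" in table.columns
                 else pd.Series(["both"] * len(table)))
    return [
        GeneScore(str(g), float(p), d)
        for g, p, d in zip(table["gene_id"], table["p_value"], direction)
    ]


def _one_sided_p(score: GeneScore, mode: str) -> float:
    """One-sided p for the requested regulation direction.

    Two-sided p-values with a known direction convert to one-sided as
    ``p/2`` (concordant) or ``1 - p/2`` (discordant); direction 'both'
    passes through.
    """
    if mode == "both" or score.direction == "both":
        return score.p_value
    if score.direction == mode:
        return score.p_value / 2.0
    return 1.0 - score.p_value / 2.0


def _strip_compartment(mid: str) -> str:
    base = mid.rsplit("[", 1)[0]
    for suffix in ("_c0", "_e0", "_c", "_e", "_p"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return base


def metabolite_neighbour_genes(model) -> dict[str, set[str]]:
    """Genes in the GPRs of the reactions containing each metabolite,
    deduplicated across duplicate reactions."""
    neighbours: dict[str, set[str]] = {m.id: set() for m in model.metabolites}
    for r in model.reactions:
        genes = r.genes
        if not genes:
            continue
        for mid in r.stoichiometry:
            neighbours[mid] |= genes
    return neighbours


def reporter_metabolites(model, scores: list[GeneScore],
                         n_background: int = 1000, seed: int = 1,
                         mode: str = "up",
                         currency: frozenset[str] = DEFAULT_CURRENCY,
                         ) -> pd.DataFrame:
    """Aggregate gene-level significance over metabolite neighbourhoods.

    ``mode`` selects the analysis of up-regulated ('up'), down-regulated
    ('down') or direction-agnostic ('both') transcriptional change.
    Returns a table with columns metabolite_id, k, z_raw, z_corrected,
    p_reporter and neg_log10_p.
    """
    if n_background < 100:
        warnings.warn(
            f"n_background={n_background} is small; background moments will "
            "be noisy", stacklevel=2,
        )
    z_by_gene = {}
    for s in scores:
        p = min(max(_one_sided_p(s, mode), P_FLOOR), 1.0 - P_FLOOR)
        z_by_gene[s.gene_id] = stats.norm.ppf(1.0 - p)
    scored_genes = set(z_by_gene)

    neighbours = metabolite_neighbour_genes(model)
    mapped = {
        mid: sorted(genes & scored_genes)
        for mid, genes in neighbours.items()
        if genes & scored_genes and _strip_compartment(mid) not in currency
    }
    if not mapped:
        raise ValueError("no scored gene maps into the model via GPRs")

    rng = np.random.default_rng(seed)
    pool = np.array([z_by_gene[g] for g in sorted(scored_genes)])
    sizes = sorted({len(g) for g in mapped.values()})
    background: dict[int, tuple[float, float]] = {}
    for k in sizes:
        if k >= len(pool):
            draws = np.full(n_background, pool.sum() / np.sqrt(len(pool)))
        else:
            idx = rng.random((n_background, len(pool))).argsort(axis=1)[:, :k]
            draws = pool[idx].sum(axis=1) / np.sqrt(k)
        mu, sd = float(draws.mean()), float(draws.std())
        background[k] = (mu, sd if sd > 0 else 1.0)

    rows = []
    for mid, genes in sorted(mapped.items()):
        k = len(genes)
        z_raw = sum(z_by_gene[g] for g in genes) / np.sqrt(k)
        mu, sd = background[k]
        z_corr = (z_raw - mu) / sd
        p_rep = float(np.clip(stats.norm.sf(z_corr), P_FLOOR, 1 - P_FLOOR))
        rows.append((mid, k, z_raw, z_corr, p_rep, -np.log10(p_rep)))
    return pd.DataFrame(
        rows, columns=["metabolite_id", "k", "z_raw", "z_corrected",
                       "p_reporter", "neg_log10_p"],
    ).sort_values("p_reporter").reset_index(drop=True)
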