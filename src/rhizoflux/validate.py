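"""Validation statistics: confusion metrics for growth/essentiality
screens, comparison of predicted fluxes with measured (e.g. 13C-derived)
fluxes against FVA envelopes, and amino-acid composition enrichment.

The recall denominator is the standard TP/(TP+FN); precision TP/(TP+FP);
accuracy (TP+TN)/total.  Metrics with a zero denominator are reported as
``None`` (undefined), never silently as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one call")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_metrics(cm: ConfusionMatrix,
                      ) -> tuple[float | None, float | None, float | None]:
    """(accuracy, precision, recall); undefined metrics are None."""
    accuracy = (cm.TP + cm.TN) / cm.total
    precision = cm.TP / (cm.TP + cm.FP) if cm.TP + cm.FP > 0 else None
    recall = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN > 0 else None
    return accuracy, precision, recall


def build_confusion(predicted: dict[str, bool],
                    observed: dict[str, bool]) -> ConfusionMatrix:
    """Counts over the intersection of ids (positives defined by the
    caller: growth, essentiality, ...)."""
    shared = sorted(set(predicted) & set(observed))
    if not shared:
        raise ValueError("predicted and observed share no ids")
    tp = sum(predicted[i] and observed[i] for i in shared)
    tn = sum(not predicted[i] and not observed[i] for i in shared)
    fp = sum(predicted[i] and not observed[i] for i in shared)
    fn = sum(not predicted[i] and observed[i] for i in shared)
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def compare_fluxes(predicted, ranges, measured: pd.DataFrame,
                   mapping: dict[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Check measured fluxes (columns reaction_id, mean, sd) against the FVA
    envelope and the FBA point prediction.

    ``mapping`` translates external reaction names to model ids; unmapped
    reactions are listed separately and excluded from the summary.
    Returns (table, unmapped).  The table's ``within_range`` flags whether
    the measured mean lies inside [fva_min, fva_max].
    """
    by_id = {r.reaction_id: r for r in ranges}
    rows, unmapped = [], []
    for _, row in measured.iterrows():
        name = str(row["reaction_id"])
        rid = (mapping or {}).get(name, name)
        if rid not in by_id:
            unmapped.append(name)
            continue
        rng = by_id[rid]
        mean = float(row["mean"])
        rows.append((
            rid, mean, float(row.get("sd", 0.0)),
            float(predicted.fluxes.get(rid, 0.0)),
            rng.minimum, rng.maximum,
            bool(rng.minimum <= mean <= rng.maximum),
        ))
    table = pd.DataFrame(
        rows, columns=["reaction_id", "measured_mean", "measured_sd",
                       "predicted", "fva_min", "fva_max", "within_range"],
    )
    return table, unmapped


def fraction_within_range(table: pd.DataFrame) -> float:
    if table.empty:
        raise ValueError("no mapped reactions to summarize")
    return float(table["within_range"].mean())


def _residue_counts(path: str | Path) -> tuple[Counter, Counter]:
    counts: Counter = Counter()
    other: Counter = Counter()
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        for aa in str(record.seq).upper():
            (counts if aa in AMINO_ACIDS else other)[aa] += 1
    if n_records == 0:
        raise ValueError(f"{path}: empty FASTA")
    return counts, other


def aa_enrichment(background_fasta: str | Path,
                  subset_fasta: str | Path) -> pd.DataFrame:
    """Hypergeometric over-representation of each residue in a protein
    subset relative to the full proteome, Benjamini-Hochberg adjusted.

    The draw is at residue level: from the pool of all background residues,
    the subset's residues are the sample; the upper tail of the
    hypergeometric gives the raw p per amino acid.
    """
    bg, _ = _residue_counts(background_fasta)
    sub, _ = _residue_counts(subset_fasta)
    excess = {aa: sub[aa] - bg[aa] for aa in sub if sub[aa] > bg[aa]}
    if excess:
        raise ValueError(
            f"subset residue counts exceed background counts: {excess}; the "
            "subset must be drawn from the background proteome"
        )
    M = sum(bg.values())
    N = sum(sub.values())
    rows = []
    for aa in AMINO_ACIDS:
        k, n = sub[aa], bg[aa]
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n > 0 else 1.0
        rows.append((aa, k, n, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["amino_acid", "count_subset",
                                        "count_background", "p_raw"])
    table["p_adjusted"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table
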