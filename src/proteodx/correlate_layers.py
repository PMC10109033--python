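"""Per-gene protein-mRNA Spearman correlation with strength binning."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .matrix_io import ExpressionMatrix, GeneAnnotation

STRENGTHS = ("strong", "moderate", "weak", "none")


@dataclass(frozen=True)
class CorrelationRecord:
    gene: str
    rho: float
    n_pairs: int
    strength: str
    cell_marker: str = "none"


def bin_strength(rho: float) -> str:
    """Bin |rho|: >=0.7 strong; [0.4, 0.7) moderate; [0.2, 0.4) weak; <0.2 none."""
    a = abs(rho)
    if a >= 0.7:
        return "strong"
    if a >= 0.4:
        return "moderate"
    if a >= 0.2:
        return "weak"
    return "none"


def spearman_per_gene(
    protein_m: ExpressionMatrix,
    rna_m: ExpressionMatrix,
    samples: list[str] | None = None,
    annot: GeneAnnotation | None = None,
) -> tuple[list[CorrelationRecord], list[tuple[str, str]]]:
    """Spearman rho between the two layers for every shared gene.

    Computed over the shared sample set with average ranks for ties.  Genes
    with zero variance on either layer have no defined rho and are returned
    in the second (excluded) list with a reason.
    """
    if samples is None:
        samples = [s for s in protein_m.samples if s in set(rna_m.samples)]
    if len(samples) < 5:
        raise InputError(f"spearman_per_gene requires >=5 shared samples, got {len(samples)}")
    shared_genes = [g for g in protein_m.genes if g in set(rna_m.genes)]
    markers = (
        annot.for_genes(shared_genes)["cell_marker"]
        if annot is not None
        else pd.Series("none", index=shared_genes)
    )
    prot = protein_m.values.loc[shared_genes, samples].to_numpy(dtype=float)
    rna = rna_m.values.loc[shared_genes, samples].to_numpy(dtype=float)

    records: list[CorrelationRecord] = []
    excluded: list[tuple[str, str]] = []
    for i, g in enumerate(shared_genes):
        x, y = prot[i], rna[i]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            excluded.append((g, "zero variance on one layer"))
            continue
        rho = float(stats.spearmanr(x, y).statistic)
        records.append(
            CorrelationRecord(
                gene=g,
                rho=rho,
                n_pairs=len(samples),
                strength=bin_strength(rho),
                cell_marker=str(markers.loc[g]),
            )
        )
    return records, excluded


def summarize_correlations(records: list[CorrelationRecord]) -> dict:
    """Median/IQR of rho, strength histogram, per-marker-group medians."""
    if not records:
        raise InputError("summarize_correlations requires >=1 record")
    rhos = np.array([r.rho for r in records], dtype=float)
    q1, med, q3 = np.percentile(rhos, [25, 50, 75])  # linear interpolation (type 7)
    hist = {s: 0 for s in STRENGTHS}
    for r in records:
        hist[r.strength] += 1
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.cell_marker, []).append(r.rho)
    group_medians = {k: float(np.median(v)) for k, v in sorted(groups.items())}
    return {
        "n": len(records),
        "median": float(med),
        "iqr": [float(q1), float(q3)],
        "strength_histogram": hist,
        "group_medians": group_medians,
    }


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "rho": r.rho,
                "n_pairs": r.n_pairs,
                "strength": r.strength,
                "cell_marker": r.cell_marker,
            }
            for r in records
        ]
    ).set_index("gene")
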