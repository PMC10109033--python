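"""Marker-based classification of B-/T-cell-deficient samples.

Marker selection (fewest missing values, then specificity), per-gene
z-normalization, k-means with k=2, elbow validation, and cross-layer
agreement reporting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._utils import log_stage
from .errors import InputError, ValidationError
from .matrix_io import ExpressionMatrix, GeneAnnotation


@dataclass
class MarkerPanel:
    cell_type: str
    candidates: pd.DataFrame  # index gene; columns mv_fraction, specificity
    selected: list[str]

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.candidates.index):
            raise ValidationError("selected markers must be a subset of candidates")


@dataclass
class ClusterResult:
    panel: MarkerPanel
    z_profile: pd.DataFrame  # panel genes x samples
    assignment: pd.Series  # sample -> "deficient" | "other"
    k: int
    inertia_by_k: dict[int, float] = field(default_factory=dict)
    elbow_k: int | None = None
    low_confidence_elbow: bool = False

    def deficient_samples(self) -> list[str]:
        return list(self.assignment.index[self.assignment == "deficient"])


def select_markers(
    m: ExpressionMatrix,
    annot: GeneAnnotation,
    cell_type: str,
    n_select: int = 3,
    specificity: Mapping[str, float] | None = None,
) -> MarkerPanel:
    """Pick marker genes for a cell type.

    Protein layer: candidates ranked by (MV fraction ascending, specificity
    descending, gene id) and the top ``n_select`` taken.  RNA layer: the
    panel is already target-enriched with no missing values, so every
    candidate passing the specificity criterion is used.
    """
    candidates = [g for g in annot.markers(cell_type) if g in set(m.genes)]
    if m.layer == "protein" and len(candidates) < n_select:
        raise InputError(
            f"need >= {n_select} {cell_type} markers in the matrix; available: {candidates}"
        )
    if not candidates:
        raise InputError(f"no {cell_type} marker genes present in the matrix")
    spec = {g: (specificity or {}).get(g, 1.0) for g in candidates}
    mv_frac = m.mask.loc[candidates].mean(axis=1)
    table = pd.DataFrame(
        {"mv_fraction": mv_frac, "specificity": pd.Series(spec)}
    ).loc[candidates]
    if m.layer == "rna":
        order = table.sort_values(
            by=["specificity"], ascending=False, kind="mergesort"
        ).index
        selected = list(order)
    else:
        ranked = table.assign(gene=table.index).sort_values(
            by=["mv_fraction", "specificity", "gene"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        selected = list(ranked.index[:n_select])
    return MarkerPanel(cell_type=cell_type, candidates=table, selected=selected)


def _marker_zscores(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Per-gene z rows restricted to the panel; constant genes are dropped."""
    sub = m.values.loc[genes]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g in genes if not keep.loc[g]]
    if dropped:
        log_stage("cluster", f"dropping constant panel genes: {dropped}")
    if not keep.any():
        raise InputError("every panel gene is constant across samples")
    z = sub.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z


def cluster_samples(
    m: ExpressionMatrix, panel: MarkerPanel, k: int = 2, seed: int = 0
) -> ClusterResult:
    """k-means over the z-scored marker profile; label the low-z cluster deficient."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    z = _marker_zscores(m, panel.selected)
    x = z.to_numpy(dtype=float).T  # samples x panel genes
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
    labels = km.fit_predict(x)
    mean_z = np.array([x[labels == c].mean() for c in range(k)])
    deficient_cluster = int(np.argmin(mean_z))
    assignment = pd.Series(
        ["deficient" if l == deficient_cluster else "other" for l in labels],
        index=m.samples,
    )
    log_stage(
        "cluster",
        f"{panel.cell_type}: {int((assignment == 'deficient').sum())} deficient "
        f"of {len(assignment)} samples (k={k})",
    )
    return ClusterResult(
        panel=panel, z_profile=z, assignment=assignment, k=k
    )


def elbow_curve(
    m: ExpressionMatrix,
    panel: MarkerPanel,
    k_range: range = range(1, 9),
    seed: int = 0,
) -> tuple[dict[int, float], int, bool]:
    """Within-cluster SS for each k and the elbow (max second difference).

    Returns ``(ss_by_k, elbow_k, low_confidence)``; the elbow is the k with
    the largest discrete curvature of the SS curve, ties going to smaller k.
    ``low_confidence`` is set when the curve is near-linear (max curvature
    below 10% of the total SS drop).
    """
    z = _marker_zscores(m, panel.selected)
    x = z.to_numpy(dtype=float).T
    ks = [k for k in k_range if 1 <= k < x.shape[0]]
    if not ks:
        raise InputError("k_range has no valid k below the sample count")
    ss: dict[int, float] = {}
    for k in ks:
        if k == 1:
            ss[k] = float(((x - x.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
            km.fit(x)
            ss[k] = float(km.inertia_)
    elbow_k, low_conf = _find_elbow(ss)
    return ss, elbow_k, low_conf


def _find_elbow(ss: dict[int, float]) -> tuple[int, bool]:
    ks = sorted(ss)
    if len(ks) < 3:
        return ks[-1], True
    vals = np.array([ss[k] for k in ks])
    curvature = vals[:-2] - 2 * vals[1:-1] + vals[2:]  # indexed by interior k
    best = int(np.argmax(curvature))  # argmax takes the first (smallest k) on ties
    elbow = ks[best + 1]
    total_drop = float(vals[0] - vals[-1])
    low_conf = total_drop <= 0 or float(curvature[best]) < 0.1 * total_drop
    return elbow, low_conf


def compare_layers(result_protein: ClusterResult, result_rna: ClusterResult) -> dict:
    """Agreement of the two layers' deficient clusters (Jaccard, containment)."""
    sp = set(result_protein.assignment.index)
    sr = set(result_rna.assignment.index)
    if sp != sr:
        raise ValidationError("compare_layers requires the same sample universe")
    p = set(result_protein.deficient_samples())
    r = set(result_rna.deficient_samples())
    inter, union = p & r, p | r
    return {
        "n_protein": len(p),
        "n_rna": len(r),
        "n_intersection": len(inter),
        "protein_only": sorted(p - r),
        "rna_only": sorted(r - p),
        "jaccard": (len(inter) / len(union)) if union else 1.0,
        "containment_protein_in_rna": (len(inter) / len(p)) if p else 1.0,
    }
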