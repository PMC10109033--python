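"""Sample eligibility, missingness diagnostics and gene filtering.

Implements the initial data funnel: PCA-based sample exclusion, the
regression of per-sample missing-value proportion on total observed
abundance, the abundance-density contrast between genes with and without
missing values, and the protein/RNA gene filters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import log_stage, percent
from .errors import InputError, PipelineError, ValidationError
from .matrix_io import ExpressionMatrix, GeneAnnotation

_MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


@dataclass
class FilterDecision:
    """Outcome of one funnel stage: kept ids, dropped ids with reasons."""

    stage: str
    kept: list[str]
    dropped: dict[str, str]  # id -> reason
    threshold: float | None = None

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise ValidationError(f"kept/dropped overlap: {sorted(overlap)[:5]}")

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.dropped)


@dataclass
class QcReport:
    """Per-sample QC metrics plus cohort-level missingness diagnostics."""

    mv_proportion: pd.Series
    total_abundance: pd.Series
    pc_coords: pd.DataFrame  # samples x [PC1, PC2]
    explained_variance: np.ndarray
    regression_all: dict
    regression_targeted: dict | None
    density: dict
    outliers: FilterDecision | None = None


def pca_samples(m: ExpressionMatrix, n_components: int = 2):
    """Project samples on principal components of the log2 matrix.

    Missing cells are filled with the per-gene observed *minimum* for this
    projection only (missingness is left-censored, so a missing cell sits at
    or below the gene's detection floor; a mean fill would instead pull
    high-dropout samples toward the centroid and hide them).  Genes missing
    in more than half the samples are excluded from the projection.  Returns
    (coords, explained_variance_ratio) with coordinates centered.
    """
    if m.shape[1] < 3:
        raise InputError(f"PCA requires >=3 samples, got {m.shape[1]}")
    logm = m.to_log2() if m.scale == "linear" else m
    x = logm.observed().to_numpy(dtype=float)
    frac_missing = np.mean(np.isnan(x), axis=1)
    keep = frac_missing <= 0.5
    if not keep.any():
        raise InputError("no gene has <=50% missing values; PCA impossible")
    x = x[keep]
    gene_floor = np.nanmin(x, axis=1)
    fill = np.where(np.isnan(x), gene_floor[:, None], x)
    # samples are observations: center each gene, eigendecompose sample cloud
    centered = (fill - fill.mean(axis=1, keepdims=True)).T  # samples x genes
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    # sign convention: largest-|loading| coordinate positive, for determinism
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    total_var = (s**2).sum()
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cdf = pd.DataFrame(
        coords, index=m.samples, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return cdf, evr


def _mad(x: np.ndarray) -> float:
    return _MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


def flag_outlier_samples(qc: QcReport, k_mad: float = 4.0) -> FilterDecision:
    """Flag ineligible samples by robust PC-space distance or MV proportion.

    A sample is flagged when its Euclidean distance from the coordinate-wise
    PC median exceeds ``median + k_mad * MAD`` robust deviations, or when its
    missing-value proportion does.  Both statistics are right-skewed, so the
    robust cut is applied on the log scale (which symmetrizes them and keeps
    the false-positive rate near nominal on null cohorts).  Refuses to
    continue if everything is flagged.
    """
    eps = 1e-9
    coords = qc.pc_coords.to_numpy(dtype=float)
    med = np.median(coords, axis=0)
    dist = np.sqrt(((coords - med) ** 2).sum(axis=1))
    log_dist = np.log(dist + eps)
    d_cut = np.median(log_dist) + k_mad * _mad(log_dist)
    mv = qc.mv_proportion.to_numpy(dtype=float)
    log_mv = np.log(mv + eps)
    mv_cut = np.median(log_mv) + k_mad * _mad(log_mv)

    kept, dropped = [], {}
    for i, s in enumerate(qc.pc_coords.index):
        reasons = []
        if _mad(log_dist) > 0 and log_dist[i] > d_cut:
            reasons.append(f"PC distance {dist[i]:.3g} > {np.exp(d_cut):.3g}")
        if _mad(log_mv) > 0 and log_mv[i] > mv_cut:
            reasons.append(f"MV proportion {mv[i]:.3g} > {np.exp(mv_cut):.3g}")
        if reasons:
            dropped[str(s)] = "; ".join(reasons)
        else:
            kept.append(str(s))
    if not kept:
        raise PipelineError("all samples flagged as outliers; refusing to continue")
    decision = FilterDecision("sample_outliers", kept, dropped, threshold=k_mad)
    log_stage("qc", f"samples kept {len(kept)} / dropped {len(dropped)}")
    return decision


def _mv_and_abundance(
    m: ExpressionMatrix, genes: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    sub = m if genes is None else m.subset(genes=genes)
    mask = sub.mask.to_numpy(dtype=bool)
    vals = sub.observed().to_numpy(dtype=float)
    mv_prop = mask.mean(axis=0)
    total = np.nansum(vals, axis=0)
    return mv_prop, total


def mv_regression(
    m: ExpressionMatrix, annot: GeneAnnotation | None = None, use_targeted_only: bool = False
) -> dict:
    """OLS of per-sample MV proportion on per-sample total observed abundance.

    With ``use_targeted_only`` the rbc/plasma (nontarget) proteins are
    excluded from both the proportion and the abundance before fitting.
    """
    if m.shape[1] < 3:
        raise InputError("mv_regression requires >=3 samples")
    if m.scale != "linear":
        raise ValidationError("mv_regression expects linear intensities")
    genes = None
    if use_targeted_only:
        if annot is None:
            raise ValidationError("use_targeted_only requires annotation")
        ann = annot.for_genes(m.genes)
        genes = list(ann.index[ann["nontarget_category"] == "none"])
    mv_prop, total = _mv_and_abundance(m, genes)
    if np.ptp(total) == 0:
        raise InputError("zero variance in total abundance; regression undefined")
    fit = stats.linregress(total, mv_prop)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "n_samples": int(len(total)),
        "targeted_only": bool(use_targeted_only),
    }


def mv_density_summary(m: ExpressionMatrix) -> dict:
    """Contrast per-gene mean observed log2 abundance for genes with vs without MVs."""
    logm = m.to_log2() if m.scale == "linear" else m
    vals = logm.observed().to_numpy(dtype=float)
    mask = logm.mask.to_numpy(dtype=bool)
    has_mv = mask.any(axis=1)
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        gene_means = np.where(n_obs > 0, np.nansum(np.where(obs, vals, 0.0), axis=1) / n_obs, np.nan)

    def _summ(sel: np.ndarray) -> dict:
        x = gene_means[sel]
        x = x[~np.isnan(x)]
        if x.size == 0:
            return {"n": 0, "mean": None, "median": None}
        return {"n": int(x.size), "mean": float(np.mean(x)), "median": float(np.median(x))}

    return {"with_mv": _summ(has_mv), "without_mv": _summ(~has_mv)}


def filter_proteins_by_mv(
    m: ExpressionMatrix, max_mv_fraction: float = 0.3
) -> FilterDecision:
    """Keep genes whose missing fraction is <= ``max_mv_fraction`` (inclusive)."""
    if not 0.0 <= max_mv_fraction <= 1.0:
        raise ValidationError("max_mv_fraction must lie in [0, 1]")
    frac = m.mask.mean(axis=1)
    kept, dropped = [], {}
    for g, f in frac.items():
        if f <= max_mv_fraction:
            kept.append(str(g))
        else:
            dropped[str(g)] = f"MV fraction {f:.3f} > {max_mv_fraction}"
    decision = FilterDecision("protein_mv_filter", kept, dropped, threshold=max_mv_fraction)
    log_stage("qc", f"protein MV filter: kept {len(kept)} / dropped {len(dropped)}")
    return decision


def filter_rna_by_total_count(
    m: ExpressionMatrix, min_total: int = 1000
) -> FilterDecision:
    """Keep RNA genes with total read count >= ``min_total`` (strict 'less than' dropped)."""
    if m.layer != "rna" or m.scale != "linear":
        raise ValidationError("filter_rna_by_total_count expects rna layer, linear counts")
    totals = m.values.sum(axis=1)
    kept, dropped = [], {}
    for g, t in totals.items():
        if t >= min_total:
            kept.append(str(g))
        else:
            dropped[str(g)] = f"total count {int(t)} < {min_total}"
    decision = FilterDecision("rna_count_filter", kept, dropped, threshold=float(min_total))
    log_stage("qc", f"RNA count filter: kept {len(kept)} / dropped {len(dropped)}")
    return decision


def overlap_genes(
    protein_kept: list[str] | set[str],
    rna_kept: list[str] | set[str],
    annot: GeneAnnotation | None = None,
) -> dict:
    """Coverage of the (coding) RNA panel by the protein gene set.

    Noncoding genes are removed from the RNA side before intersecting;
    percentage = 100 * |intersection| / |RNA side|, rounded half-up.
    """
    protein_set = set(protein_kept)
    rna_set = set(rna_kept)
    noncoding: set[str] = set()
    if annot is not None:
        ann = annot.for_genes(sorted(rna_set))
        noncoding = set(ann.index[~ann["coding"].astype(bool)])
    rna_coding = rna_set - noncoding
    inter = protein_set & rna_coding
    pct = percent(len(inter), len(rna_coding)) if rna_coding else 0
    return {
        "n_protein": len(protein_set),
        "n_rna_coding": len(rna_coding),
        "n_noncoding_removed": len(noncoding),
        "n_overlap": len(inter),
        "percent_of_rna": pct,
        "overlap": sorted(inter),
    }


def build_qc_report(
    m: ExpressionMatrix, annot: GeneAnnotation | None = None
) -> QcReport:
    """Assemble the full QC report (PCA, MV regression x2, density contrast)."""
    coords, evr = pca_samples(m)
    mv_prop, total = _mv_and_abundance(m)
    reg_all = mv_regression(m, annot, use_targeted_only=False)
    reg_t = None
    if annot is not None and len(annot.for_genes(m.genes).query("nontarget_category != 'none'")):
        reg_t = mv_regression(m, annot, use_targeted_only=True)
    return QcReport(
        mv_proportion=pd.Series(mv_prop, index=m.samples),
        total_abundance=pd.Series(total, index=m.samples),
        pc_coords=coords,
        explained_variance=evr,
        regression_all=reg_all,
        regression_targeted=reg_t,
        density=mv_density_summary(m),
    )
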