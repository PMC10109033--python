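"""Single-case disease-gene calling.

Cohort z-scores on both layers, archetype classification (concordant loss vs
protein-only loss etc.), and patient-vs-healthy-control log fold changes for
MA-style reporting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .matrix_io import CohortMeta, ExpressionMatrix

ARCHETYPES = (
    "concordant_down",
    "protein_only_down",
    "mrna_only_down",
    "concordant_up",
    "none",
)


@dataclass(frozen=True)
class DiagnosticThresholds:
    z_cut: float = 2.0  # |z| >= z_cut is a significant change (inclusive)
    lfc_cut: float = -5.0  # lfc < lfc_cut is extreme (strict)

    def __post_init__(self) -> None:
        if self.z_cut <= 0:
            raise ValidationError("z_cut must be > 0")
        if self.lfc_cut >= 0:
            raise ValidationError("lfc_cut must be < 0")


def cohort_zscores(m: ExpressionMatrix, leave_one_out: bool = False) -> pd.DataFrame:
    """Per-gene z-scores across all (non-excluded) samples.

    ``z = (x - mean) / sd`` with the sample sd (n-1 denominator) over every
    sample including the case itself; a zero-variance gene yields NaN (an
    undefined z, never 0).  With ``leave_one_out`` each sample is scored
    against the distribution of the remaining samples.
    """
    if m.shape[1] < 3:
        raise InputError("cohort_zscores requires >=3 samples")
    x = m.values.to_numpy(dtype=float)
    n = x.shape[1]
    if not leave_one_out:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (x - mu) / sd, np.nan)
    else:
        z = np.empty_like(x)
        for j in range(n):
            rest = np.delete(x, j, axis=1)
            mu = rest.mean(axis=1)
            sd = rest.std(axis=1, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                z[:, j] = np.where(sd > 0, (x[:, j] - mu) / sd, np.nan)
    return pd.DataFrame(z, index=m.genes, columns=m.samples)


def classify_archetype(
    z_protein: float,
    z_rna: float | None,
    thr: DiagnosticThresholds = DiagnosticThresholds(),
) -> str:
    """Classify a (gene, sample) pair from its z-scores on the two layers.

    ``z_rna is None`` means the gene is absent from the RNA panel — treated
    as "no mRNA evidence", not as z = 0.  Boundaries are inclusive
    (|z| >= z_cut is significant).
    """
    if z_protein is None or not np.isfinite(z_protein):
        raise ValidationError("z_protein must be defined")
    zc = thr.z_cut
    p_down = z_protein <= -zc
    p_up = z_protein >= zc
    if z_rna is None or not np.isfinite(z_rna):
        return "protein_only_down" if p_down else "none"
    r_down = z_rna <= -zc
    r_up = z_rna >= zc
    if p_down and r_down:
        return "concordant_down"
    if p_down and not r_down:
        return "protein_only_down"
    if r_down and not p_down:
        return "mrna_only_down"
    if p_up and r_up:
        return "concordant_up"
    return "none"


def case_vs_hc(
    m: ExpressionMatrix,
    meta: CohortMeta,
    case_sample: str,
    thr: DiagnosticThresholds = DiagnosticThresholds(),
    raw_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change and mean expression of a case vs healthy controls.

    ``lfc = case_log2 - mean(HC log2)``; ``mean_expr`` is the mean log2 value
    over the case and the HCs.  Genes missing in the case before imputation
    (per ``raw_mask`` or the matrix's own mask) are reported with
    ``case_missing=True`` — on an MA plot they form the floor line.  Genes
    missing in every HC are excluded with a reason.
    """
    hcs = [s for s in meta.controls() if s != case_sample]
    if len(hcs) < 2:
        raise InputError("case_vs_hc requires >=2 healthy controls")
    if case_sample not in m.samples:
        raise InputError(f"case sample {case_sample!r} not in matrix")
    if case_sample in meta.controls():
        raise ValidationError("case sample must not be in the HC set")
    mask = (raw_mask if raw_mask is not None else m.mask).astype(bool)

    hc_vals = m.values[hcs].to_numpy(dtype=float)
    case_vals = m.values[case_sample].to_numpy(dtype=float)
    hc_all_missing = mask[hcs].to_numpy(dtype=bool).all(axis=1)
    case_missing = mask[case_sample].to_numpy(dtype=bool)

    hc_mean = hc_vals.mean(axis=1)
    lfc = case_vals - hc_mean
    mean_expr = (case_vals + hc_vals.sum(axis=1)) / (len(hcs) + 1)

    keep = ~hc_all_missing
    out = pd.DataFrame(
        {
            "lfc_vs_hc": lfc[keep],
            "mean_expr": mean_expr[keep],
            "case_missing": case_missing[keep],
            "lfc_extreme": lfc[keep] < thr.lfc_cut,
        },
        index=m.genes[keep],
    )
    out.index.name = "gene"
    out.attrs["excluded"] = [
        (g, "missing in all HCs") for g in m.genes[hc_all_missing]
    ]
    return out


def diagnostic_calls(
    z_protein: pd.DataFrame,
    z_rna: pd.DataFrame | None,
    case_sample: str,
    ma_table: pd.DataFrame | None = None,
    thr: DiagnosticThresholds = DiagnosticThresholds(),
) -> pd.DataFrame:
    """Assemble per-gene diagnostic calls for one case sample."""
    zp = z_protein[case_sample]
    defined = np.isfinite(zp.to_numpy(dtype=float))
    genes = z_protein.index[defined]
    zp = zp.loc[genes]

    zr = pd.Series(np.nan, index=genes)
    if z_rna is not None:
        shared = genes.intersection(z_rna.index)
        zr.loc[shared] = z_rna.loc[shared, case_sample]

    zc = thr.z_cut
    zpv, zrv = zp.to_numpy(dtype=float), zr.to_numpy(dtype=float)
    rna_absent = ~np.isfinite(zrv)
    p_down, p_up = zpv <= -zc, zpv >= zc
    with np.errstate(invalid="ignore"):
        r_down, r_up = zrv <= -zc, zrv >= zc
    arch = np.full(len(genes), "none", dtype=object)
    arch[p_down] = "protein_only_down"  # default when mRNA absent or not down
    arch[p_down & r_down] = "concordant_down"
    arch[~p_down & r_down & ~rna_absent] = "mrna_only_down"
    arch[p_up & r_up & ~rna_absent] = "concordant_up"

    out = pd.DataFrame(
        {
            "sample": case_sample,
            "z_protein": zpv,
            "z_rna": zrv,
            "archetype": arch,
            "z_significant": np.abs(zpv) >= zc,
        },
        index=genes,
    )
    if ma_table is not None:
        out = out.join(ma_table[["lfc_vs_hc", "mean_expr", "lfc_extreme"]], how="left")
    out.index.name = "gene"
    return out


def rank_candidates(
    calls: pd.DataFrame,
    targeted_only: bool = False,
    targeted_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Order candidate genes by ascending protein z (ties broken by gene id).

    Returns an empty frame with ``attrs['status'] == 'no candidate'`` when no
    gene passes the significance flag.
    """
    df = calls.copy()
    if targeted_only:
        if targeted_genes is None:
            raise ValidationError("targeted_only requires targeted_genes")
        df = df[df.index.isin(targeted_genes)]
    df = df[df["z_significant"]]
    if len(df):
        order = np.lexsort((df.index.to_numpy(), df["z_protein"].to_numpy()))
        df = df.iloc[order]
    df.attrs["status"] = "ok" if len(df) else "no candidate"
    return df
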