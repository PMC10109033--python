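"""Left-censored imputation and normalization of both layers.

Two imputation strategies for protein missing values (hard floor for the
diagnostic arm, per-sample low quantile for the exploratory arm), quantile
and robust-linear-regression normalization, a size-factor log transform for
RNA counts, and a small normalization-assessment metric used to choose
between methods.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import log_stage
from .errors import ConfigError, InputError, ValidationError
from .matrix_io import ExpressionMatrix


@dataclass(frozen=True)
class PreprocessConfig:
    impute_method: str = "min_det"  # "zero" | "min_det"
    min_det_quantile: float = 0.01
    protein_norm: str = "quantile"  # "quantile" | "rlr"
    rna_transform: str = "vst_log"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.impute_method not in ("zero", "min_det"):
            raise ConfigError(f"unknown impute_method {self.impute_method!r}")
        if not 0.0 < self.min_det_quantile < 0.5:
            raise ConfigError("min_det_quantile must lie in (0, 0.5)")
        if self.protein_norm not in ("quantile", "rlr"):
            raise ConfigError(f"unknown protein_norm {self.protein_norm!r}")
        if self.pseudocount <= 0:
            raise ConfigError("pseudocount must be > 0")


def impute(m: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Fill missing cells on the log2 matrix; the mask is kept as provenance.

    ``zero``: a hard detection floor — if the observed minimum is <= 0 the
    whole matrix is shifted so it becomes positive, then missing cells get 0
    (the floor of the shifted scale).  ``min_det``: each missing cell gets
    the ``min_det_quantile`` quantile of its *sample's* observed values.
    """
    if m.layer != "protein":
        raise ValidationError("impute operates on the protein layer")
    if m.scale != "log2":
        raise ValidationError("impute expects a log2-scale matrix")
    vals = m.observed().to_numpy(dtype=float)
    mask = m.mask.to_numpy(dtype=bool)
    n_obs = (~mask).sum(axis=0)
    for j, n in enumerate(n_obs):
        if n == 0:
            raise InputError(f"sample {m.samples[j]!r} has zero observed values")

    out = vals.copy()
    if cfg.impute_method == "zero":
        obs_min = np.nanmin(vals)
        shift = 0.0
        if obs_min <= 0:
            shift = 1.0 - obs_min  # move the observed minimum to exactly 1
            out = out + shift
        out[mask] = 0.0
        log_stage("impute", f"zero-floor imputation (scale shift {shift:+.4g})")
    else:
        for j in range(out.shape[1]):
            col = vals[:, j]
            q = float(np.nanquantile(col, cfg.min_det_quantile))
            out[np.isnan(out[:, j]), j] = q
        log_stage("impute", f"min_det imputation at q={cfg.min_det_quantile}")
    df = pd.DataFrame(out, index=m.genes, columns=m.samples)
    return ExpressionMatrix(df, m.mask.copy(), m.layer, "log2")


def _check_complete(m: ExpressionMatrix, op: str) -> np.ndarray:
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError(f"{op} requires a complete (imputed) matrix")
    return vals


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic rank-mean quantile normalization.

    Each sample's sorted values are replaced by the across-sample means of
    sorted values; ties within a sample receive the mean of their tied
    positions, so every per-sample distribution is identical afterwards.
    """
    vals = _check_complete(m, "quantile_normalize")
    n_g, n_s = vals.shape
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    row_means = sorted_vals.mean(axis=1)

    out = np.empty_like(vals)
    for j in range(n_s):
        col_order = order[:, j]
        sorted_col = sorted_vals[:, j]
        i = 0
        while i < n_g:  # runs of equal values share the mean of their positions
            k = i
            while k + 1 < n_g and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            out[col_order[i : k + 1], j] = row_means[i : k + 1].mean()
            i = k + 1
    df = pd.DataFrame(out, index=m.genes, columns=m.samples)
    return ExpressionMatrix(df, m.mask.copy(), m.layer, "normalized")


def rlr_normalize(m: ExpressionMatrix, max_iter: int = 50, tol: float = 1e-8) -> ExpressionMatrix:
    """Robust linear-regression normalization against the median pseudo-sample.

    Each sample is regressed on the per-gene median reference with Huber
    weights (c = 1.345) and corrected by inverting the fitted line; on
    non-convergence the fit falls back to OLS with a warning.
    """
    vals = _check_complete(m, "rlr_normalize")
    ref = np.median(vals, axis=1)
    exog = sm.add_constant(ref)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        y = vals[:, j]
        try:
            with warnings.catch_warnings():
                # a perfect fit (e.g. pure affine shift) is fine, not a failure
                warnings.simplefilter("ignore")
                fit = sm.RLM(y, exog, M=sm.robust.norms.HuberT(t=1.345)).fit(
                    maxiter=max_iter, tol=tol
                )
            intercept, slope = fit.params
            if not np.isfinite([intercept, slope]).all() or slope == 0:
                raise ValueError("degenerate robust fit")
        except Exception:
            warnings.warn(
                f"RLM failed to converge for sample {m.samples[j]!r}; using OLS",
                RuntimeWarning,
                stacklevel=2,
            )
            intercept, slope = np.polyfit(ref, y, 1)[::-1]
        out[:, j] = (y - intercept) / slope
    df = pd.DataFrame(out, index=m.genes, columns=m.samples)
    return ExpressionMatrix(df, m.mask.copy(), m.layer, "normalized")


def vst_rna(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Variance-stabilizing log transform of counts with median-of-ratios size factors.

    Size factor per sample = median over genes of count / geometric-mean
    count, computed on genes with no zero in any sample.  The geometric mean
    for sample ``j`` is taken over the *other* samples, so rescaling one
    sample's counts rescales its own size factor by exactly the same factor
    and leaves its transformed values unchanged.  If no zero-free gene
    exists, total-count ratios are used instead (logged).  Transformed value
    = log2(count / size_factor + pseudocount).
    """
    if m.layer != "rna" or m.scale != "linear":
        raise ValidationError("vst_rna expects rna layer with linear counts")
    counts = m.values.to_numpy(dtype=float)
    n_s = counts.shape[1]
    all_pos = (counts > 0).all(axis=1)
    if all_pos.any() and n_s >= 2:
        logc = np.log(counts[all_pos])
        # leave-one-out geometric mean per (gene, sample)
        loo_geo = (logc.sum(axis=1, keepdims=True) - logc) / (n_s - 1)
        sf = np.median(np.exp(logc - loo_geo), axis=0)
    else:
        totals = counts.sum(axis=0)
        loo_log_geo = (np.sum(np.log(totals)) - np.log(totals)) / max(n_s - 1, 1)
        sf = totals / np.exp(loo_log_geo)
        log_stage("vst", "no zero-free gene; falling back to total-count size factors")
    out = np.log2(counts / sf[None, :] + pseudocount)
    df = pd.DataFrame(out, index=m.genes, columns=m.samples)
    res = ExpressionMatrix(df, m.mask.copy(), m.layer, "vst")
    res.size_factors = pd.Series(sf, index=m.samples)  # provenance attribute
    return res


def assess_normalization(before: ExpressionMatrix, after: ExpressionMatrix) -> dict:
    """Compare matrices on two spread metrics (lower is better).

    Reports the pooled per-gene coefficient of variation (sd/mean of linear
    intensities, median over genes) and the median absolute deviation of
    per-sample medians on the log2 scale.
    """
    if before.shape != after.shape:
        raise ValidationError("assess_normalization needs matched matrices")

    def metrics(m: ExpressionMatrix) -> dict:
        vals = m.values.to_numpy(dtype=float)
        lin = np.power(2.0, vals)
        mu = lin.mean(axis=1)
        sd = lin.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mu > 0, sd / mu, np.nan)
        med = np.median(vals, axis=0)
        return {
            "pooled_cv": float(np.nanmedian(cv)),
            "sample_median_mad": float(np.median(np.abs(med - np.median(med)))),
        }

    return {"before": metrics(before), "after": metrics(after)}
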