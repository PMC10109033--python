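"""Moderated two-group differential expression and gene-set enrichment.

The moderated t-statistic shrinks per-gene variances toward a prior
estimated by method-of-moments on the distribution of log sample variances
(the standard empirical-Bayes construction); enrichment is a hypergeometric
upper-tail test with Benjamini-Hochberg adjustment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import InputError, ValidationError
from .matrix_io import ExpressionMatrix, GeneSetCollection


def _trigamma_inverse(y: float, max_iter: int = 75) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        tet = float(special.polygamma(2, x))
        step = (tri - y) / tet
        x -= step
        if abs(step) < 1e-10 * x:
            break
    return x


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of (prior_df d0, prior_var s0^2) from sample variances."""
    pos = s2[s2 > 0]
    if pos.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    return d0, s0_2


def moderated_dea(
    m: ExpressionMatrix,
    groups: pd.Series,
    deficient_label: str = "deficient",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of deficient-vs-other log2 values.

    ``lfc`` is the mean difference (deficient minus other).  The prior
    degrees of freedom d0 and prior variance s0^2 come from a
    method-of-moments fit on the log sample variances; a degenerate
    (infinite) d0 is capped at 10x the residual df.  ``prior_df`` overrides
    the fitted d0 (``0`` recovers the ordinary two-sample t-test).
    """
    groups = groups.reindex(m.samples)
    if groups.isna().any():
        raise ValidationError("groups must label every sample in the matrix")
    in_g = groups == deficient_label
    s1 = list(m.samples[in_g])
    s2_samples = list(m.samples[~in_g])
    if len(s1) < 2 or len(s2_samples) < 2:
        raise InputError("both groups need >=2 samples")
    x1 = m.values[s1].to_numpy(dtype=float)
    x2 = m.values[s2_samples].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2

    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d

    if prior_df is None:
        d0, s0_2 = _fit_variance_prior(s2, d)
        if not np.isfinite(d0):
            d0 = 10.0 * d
    else:
        d0 = float(prior_df)
        s0_2 = float(np.mean(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    if d0 > 0:
        s2_tilde = (d0 * s0_2 + d * s2) / (d0 + d)
    else:
        s2_tilde = s2
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, lfc / se, np.nan)
    df_total = d0 + d if np.isfinite(d0) else 10.0 * d + d
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    adj = bh_adjust(np.nan_to_num(p, nan=1.0))
    out = pd.DataFrame(
        {
            "lfc": lfc,
            "t_moderated": t,
            "p": p,
            "adj_p": adj,
            "significant_down": (p < 0.05) & (lfc < -1.5),
        },
        index=m.genes,
    )
    out.attrs["prior_df"] = float(d0)
    out.attrs["prior_var"] = float(s0_2)
    out.attrs["residual_df"] = float(d)
    return out


def significant_down(
    results: pd.DataFrame, p_cut: float = 0.05, lfc_cut: float = -1.5
) -> list[str]:
    """Genes with p < p_cut AND lfc < lfc_cut (both strict), ordered by (p, gene)."""
    sel = results[(results["p"] < p_cut) & (results["lfc"] < lfc_cut)]
    order = np.lexsort((sel.index.to_numpy(), sel["p"].to_numpy()))
    return [str(g) for g in sel.index.to_numpy()[order]]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def enrich(
    gene_list: list[str],
    gene_sets: GeneSetCollection,
    universe: list[str] | set[str],
    top_n: int = 10,
    adj_p_cut: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of ``gene_list`` in each set.

    The universe is the full set of tested genes; every gene set is
    intersected with it before testing.  BH adjustment runs across all
    tested sets; the returned frame is sorted by (adj_p, p, set id) and
    flags the top-``top_n``.
    """
    uni = set(universe)
    draw = set(gene_list) & uni
    if not set(gene_list) <= uni:
        stray = sorted(set(gene_list) - uni)
        raise ValidationError(f"gene list contains genes outside the universe: {stray[:5]}")
    restricted = gene_sets.restrict(uni)
    if not draw or not restricted.sets:
        return pd.DataFrame(
            columns=[
                "set_id", "name", "overlap", "set_size", "universe_size",
                "draw_size", "p", "adj_p", "significant", "top",
            ]
        ).set_index("set_id")
    M, N = len(uni), len(draw)
    rows = []
    for sid in sorted(restricted.sets):
        members = restricted.sets[sid]
        K = len(members)
        k = len(members & draw)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append(
            {
                "set_id": sid,
                "name": restricted.names.get(sid, sid),
                "overlap": k,
                "set_size": K,
                "universe_size": M,
                "draw_size": N,
                "p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("set_id")
    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["adj_p"] < adj_p_cut
    order = np.lexsort((df.index.to_numpy(), df["p"].to_numpy(), df["adj_p"].to_numpy()))
    df = df.iloc[order]
    df["top"] = False
    df.iloc[: min(top_n, len(df)), df.columns.get_loc("top")] = True
    return df
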