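"""Per-gene differential expression between stress groups.

Fits, gene by gene, an ordinary least-squares model on the normalized
log2-scale values

    expr_g ~ intercept + stress_group + covariates,

so the group coefficient is directly a log2 fold change (high vs low
stress; positive = up in high stress). Two-sided t p-values are corrected
across genes with Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from noarewire.iotypes import ExpressionMatrix, SampleMeta


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2fc: float
    p_value: float
    q_value: float


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_adjust")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(
    expr: ExpressionMatrix,
    grouping,
    meta: SampleMeta | None = None,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """High-vs-low-stress DE table (gene, log2fc, p, q).

    Unassigned samples are excluded. ``covariate_names`` adds adjustment
    columns from ``meta`` to the design. Returns a DataFrame indexed by
    gene id with columns log2fc, p_value, q_value.
    """
    if expr.value_kind == "raw":
        raise ValueError("differential_expression expects normalized or residual values")
    covariate_names = covariate_names or []
    low = [s for s in grouping.low_samples if s in expr.values.columns]
    high = [s for s in grouping.high_samples if s in expr.values.columns]
    if len(low) < 2 or len(high) < 2:
        raise ValueError(f"need >= 2 samples per group, got {len(low)} low / {len(high)} high")
    samples = low + high
    group = np.array([0.0] * len(low) + [1.0] * len(high))
    cols = [np.ones(len(samples)), group]
    if covariate_names:
        if meta is None:
            raise ValueError("covariates requested but no sample metadata given")
        design = meta.covariate_matrix(covariate_names).reindex(samples)
        if design.isna().any().any():
            raise ValueError("covariates missing for some grouped samples")
        cols.extend(design.to_numpy(float).T)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design in differential expression")
    df_resid = len(samples) - X.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    Y = expr.values[samples].to_numpy(float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    lfc = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, lfc / se, np.inf * np.sign(lfc))
    tstat = np.where((se == 0) & (lfc == 0), 0.0, tstat)
    p = 2 * stats.t.sf(np.abs(tstat), df=df_resid)
    q = bh_adjust(p)
    return pd.DataFrame(
        {"log2fc": lfc, "p_value": p, "q_value": q},
        index=pd.Index(expr.gene_ids, name="gene"),
    )


def select_upregulated(results: pd.DataFrame, fc_min: float, q_max: float) -> set[str]:
    """Genes with log2fc >= fc_min (inclusive) and q < q_max (strict)."""
    if results.empty:
        return set()
    mask = (results["log2fc"] >= fc_min) & (results["q_value"] < q_max)
    return set(results.index[mask])
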