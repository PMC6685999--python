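"""Expression preprocessing: gene filters, normalization, covariate
correction, and exclusion of CNA-correlated genes.

The intent of the CNA-correlation filter is to discard genes whose
expression change merely tracks their own copy number — those are
dosage effects, not the stress-induced rewiring the pipeline looks for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from noarewire.de import bh_adjust
from noarewire.iotypes import ExpressionMatrix, SampleMeta

logger = logging.getLogger(__name__)

LOW_COUNT_THRESHOLD = 10
LOW_COUNT_SAMPLE_FRACTION = 0.9
PSEUDOCOUNT = 0.5


@dataclass
class GeneFilterReport:
    """Partition of the input genes by filtering outcome."""

    kept: list[str]
    dropped_zero_variance: list[str] = field(default_factory=list)
    dropped_low_count: list[str] = field(default_factory=list)
    dropped_cna_correlated: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["r", "q"])
    )

    def summary(self) -> dict[str, int]:
        return {
            "kept": len(self.kept),
            "dropped_zero_variance": len(self.dropped_zero_variance),
            "dropped_low_count": len(self.dropped_low_count),
            "dropped_cna_correlated": len(self.dropped_cna_correlated),
        }


def filter_genes(counts: ExpressionMatrix) -> GeneFilterReport:
    """Drop zero-variance genes and genes with count < 10 in more than 90%
    of samples (strict: exactly 90% low is kept)."""
    if counts.value_kind != "raw":
        raise ValueError("filter_genes expects raw counts")
    v = counts.values
    if v.shape[1] == 0:
        raise ValueError("expression matrix has zero samples")
    arr = v.to_numpy(float)
    zero_var = arr.var(axis=1) == 0
    low_frac = (arr < LOW_COUNT_THRESHOLD).mean(axis=1)
    low_count = (low_frac > LOW_COUNT_SAMPLE_FRACTION) & ~zero_var
    keep = ~zero_var & ~low_count
    report = GeneFilterReport(
        kept=list(v.index[keep]),
        dropped_zero_variance=list(v.index[zero_var]),
        dropped_low_count=list(v.index[low_count]),
    )
    logger.info("gene filter: %s", report.summary())
    return report


def normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size normalization plus a variance-stabilizing log transform.

    Size factors are median-of-ratios against the geometric-mean reference
    sample (the DESeq convention); when fewer than 100 genes are positive
    in every sample the factors fall back to upper-quartile scaling.
    Output values are log2(count / size_factor + 0.5).
    """
    if counts.value_kind != "raw":
        raise ValueError("normalize expects raw counts")
    arr = counts.values.to_numpy(float)
    if (arr.sum(axis=0) == 0).any():
        bad = counts.values.columns[arr.sum(axis=0) == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    all_pos = (arr > 0).all(axis=1)
    if all_pos.sum() >= min(100, arr.shape[0]):
        log_ref = np.log(arr[all_pos]).mean(axis=1, keepdims=True)
        size = np.exp(np.median(np.log(arr[all_pos]) - log_ref, axis=0))
    else:
        logger.warning("too few all-positive genes; falling back to upper-quartile size factors")
        uq = np.array([np.percentile(col[col > 0], 75) for col in arr.T])
        size = uq / np.exp(np.mean(np.log(uq)))
    size = size / np.exp(np.mean(np.log(size)))  # geometric mean 1
    norm = np.log2(arr / size + PSEUDOCOUNT)
    out = pd.DataFrame(norm, index=counts.values.index, columns=counts.values.columns)
    return ExpressionMatrix(values=out, value_kind="normalized")


def correct_covariates(
    norm: ExpressionMatrix, meta: SampleMeta, covariate_names: list[str]
) -> ExpressionMatrix:
    """Residualize each gene on intercept + covariates by least squares.

    The result has zero mean per gene and zero sample correlation with
    every continuous covariate. Rank-deficient designs raise, naming the
    collinear columns.
    """
    if norm.value_kind == "raw":
        raise ValueError("correct_covariates expects normalized values")
    samples = norm.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to residualize")
    design = meta.covariate_matrix(covariate_names).reindex(samples)
    if design.isna().any().any():
        missing = design.index[design.isna().any(axis=1)][0]
        raise ValueError(f"covariates missing for sample {missing!r}")
    X = np.column_stack([np.ones(len(samples)), design.to_numpy(float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear covariates among {list(design.columns)}"
        )
    if len(samples) <= X.shape[1]:
        raise ValueError("no residual degrees of freedom")
    Y = norm.values.to_numpy(float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    out = pd.DataFrame(resid, index=norm.values.index, columns=norm.values.columns)
    return ExpressionMatrix(values=out, value_kind="residual")


def filter_cna_correlated(
    norm: ExpressionMatrix,
    gene_cna_values: pd.DataFrame,
    q_threshold: float = 0.05,
) -> GeneFilterReport:
    """Remove genes whose expression significantly tracks their own CNA.

    ``gene_cna_values`` is genes x samples of log2 copy ratios aggregated
    over each gene's locus. Per gene: Pearson r against normalized
    expression, two-sided p via the t transform, BH q across tested genes;
    genes with q <= ``q_threshold`` are removed (kept set is q > threshold).
    Genes with fewer than 3 paired samples are skipped with a warning.
    """
    shared_samples = [s for s in norm.sample_ids if s in gene_cna_values.columns]
    results: dict[str, tuple[float, float]] = {}
    skipped: list[str] = []
    for gene in norm.gene_ids:
        if gene not in gene_cna_values.index:
            skipped.append(gene)
            continue
        x = gene_cna_values.loc[gene, shared_samples].to_numpy(float)
        y = norm.values.loc[gene, shared_samples].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            skipped.append(gene)
            continue
        xo, yo = x[ok], y[ok]
        if xo.std() == 0 or yo.std() == 0:
            results[gene] = (0.0, 1.0)
            continue
        r = float(np.corrcoef(xo, yo)[0, 1])
        n = int(ok.sum())
        r_cl = min(max(r, -1.0), 1.0)
        if abs(r_cl) == 1.0:
            p = 0.0
        else:
            t = r_cl * np.sqrt((n - 2) / (1 - r_cl**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        results[gene] = (r, p)
    if skipped:
        logger.warning("CNA filter: %d gene(s) skipped (insufficient paired data)", len(skipped))
    genes = list(results)
    if genes:
        pvals = np.array([results[g][1] for g in genes])
        qvals = bh_adjust(pvals)
    else:
        qvals = np.array([])
    removed_mask = qvals <= q_threshold if len(genes) else np.array([], bool)
    removed = pd.DataFrame(
        {"r": [results[g][0] for g, m in zip(genes, removed_mask) if m],
         "q": [q for q, m in zip(qvals, removed_mask) if m]},
        index=[g for g, m in zip(genes, removed_mask) if m],
    )
    kept = [g for g, m in zip(genes, removed_mask) if not m] + skipped
    # preserve input gene order
    order = {g: i for i, g in enumerate(norm.gene_ids)}
    kept.sort(key=order.__getitem__)
    report = GeneFilterReport(kept=kept, dropped_cna_correlated=removed)
    logger.info("CNA-correlation filter: %s", report.summary())
    return report


def gene_cna_from_segments(
    profiles, gene_loci: pd.DataFrame, default: float = 0.0
) -> pd.DataFrame:
    """Length-weighted mean seg_mean over each gene's locus, per sample.

    ``gene_loci`` is indexed by gene id with columns (chromosome, start,
    end). Genes with no overlapping segment get ``default`` (copy-neutral).
    """
    out = pd.DataFrame(
        default, index=gene_loci.index, columns=[p.sample_id for p in profiles], dtype=float
    )
    for p in profiles:
        seg = p.segments
        for gene, locus in gene_loci.iterrows():
            on_chr = seg[seg["chromosome"] == locus["chromosome"]]
            if on_chr.empty:
                continue
            ov_start = np.maximum(on_chr["start"].to_numpy(), locus["start"])
            ov_end = np.minimum(on_chr["end"].to_numpy(), locus["end"])
            ov_len = np.maximum(ov_end - ov_start + 1, 0)
            if ov_len.sum() == 0:
                continue
            out.loc[gene, p.sample_id] = float(
                np.average(on_chr["seg_mean"].to_numpy(), weights=ov_len)
            )
    return out
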