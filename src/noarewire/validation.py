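"""Stability, overlap-significance and gene-dependency validation.

Three independent checks on the pipeline's output:

* subsampling stability — re-run module detection on 90%/70% subsamples
  of each stress group and measure how much of the full-run gene set is
  recovered;
* hypergeometric overlap — upper-tail probability that two gene sets
  drawn from a common universe share at least the observed overlap;
* dependency permutation — whether a gene set's mean CRISPR dependency
  score is lower (stronger dependency) than random same-size sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from noarewire.diffcoex import DiffCoExParams, adjacency_change, condition_correlations, \
    detect_modules, pick_soft_threshold, topological_overlap
from noarewire.iotypes import DependencyMatrix
from noarewire.stress import StressGrouping

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    fraction: float
    fold: int
    overlap_percent: float
    hypergeom_p: float
    n_subsampled_genes: int


def hypergeometric_overlap_test(k_overlap: int, n1: int, n2: int, n_universe: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, n1, n2)."""
    if not (0 <= k_overlap <= min(n1, n2) <= n_universe) or max(n1, n2) > n_universe:
        raise ValueError(
            f"inconsistent counts: k={k_overlap}, n1={n1}, n2={n2}, N={n_universe}"
        )
    return float(stats.hypergeom.sf(k_overlap - 1, n_universe, n1, n2))


def _module_gene_union(expr, grouping, params: DiffCoExParams) -> set[str]:
    corr = condition_correlations(expr, grouping)
    beta = params.beta if params.beta is not None else pick_soft_threshold(
        corr, params.soft_threshold_candidates, params.scale_free_r2_target
    )
    d = adjacency_change(corr, beta)
    tom = topological_overlap(d)
    modules = detect_modules(1.0 - tom, corr.gene_order, params)
    return set(modules.index[modules > 0])


def subsample_stability(
    expr,
    grouping: StressGrouping,
    params: DiffCoExParams | None = None,
    fractions: tuple[float, ...] = (0.9, 0.7),
    k: int = 5,
    seed: int = 0,
    min_group: int = 3,
) -> list[StabilityReport]:
    """Module gene-set stability under repeated group subsampling.

    For each fraction and each of ``k`` repeats both stress groups are
    independently subsampled without replacement, module detection is
    re-run, and the union of module genes is compared with the full run's
    union: overlap_percent = 100 * |intersection| / |full-run set|, with
    hypergeometric significance against the tested-gene universe.
    """
    params = params or DiffCoExParams()
    full_set = _module_gene_union(expr, grouping, params)
    if not full_set:
        raise ValueError("full run produced no module genes; stability undefined")
    universe = len(expr.gene_ids)
    rng = np.random.default_rng(seed)
    low = np.array(grouping.low_samples)
    high = np.array(grouping.high_samples)
    reports: list[StabilityReport] = []
    for fraction in fractions:
        for fold in range(k):
            n_low = int(round(fraction * len(low)))
            n_high = int(round(fraction * len(high)))
            if n_low < min_group or n_high < min_group:
                logger.warning(
                    "fraction %.2f fold %d: subsampled group below %d samples; skipped",
                    fraction, fold, min_group,
                )
                continue
            sub_low = rng.choice(low, size=n_low, replace=False)
            sub_high = rng.choice(high, size=n_high, replace=False)
            labels = pd.Series("unassigned", index=grouping.labels.index, dtype=object)
            labels[sub_low] = "low"
            labels[sub_high] = "high"
            sub_grouping = StressGrouping(
                labels=labels, thresholds=grouping.thresholds, min_group=0
            )
            sub_set = _module_gene_union(expr, sub_grouping, params)
            overlap = len(full_set & sub_set)
            pct = 100.0 * overlap / len(full_set)
            p = hypergeometric_overlap_test(
                overlap, len(full_set), len(sub_set), universe
            ) if sub_set else 1.0
            reports.append(
                StabilityReport(
                    fraction=fraction, fold=fold, overlap_percent=pct,
                    hypergeom_p=p, n_subsampled_genes=len(sub_set),
                )
            )
    return reports


def dependency_permutation_test(
    dependency: DependencyMatrix,
    gene_set,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Is the gene set's mean dependency score lower than chance?

    The observed statistic is the mean per-gene dependency (averaged over
    cell lines) of the set; the null draws ``n_perm`` random same-size
    gene subsets. p_perm is one-sided lower-tail with the +1 correction
    (lower score = stronger dependency). A two-sided rank-sum test of the
    set vs non-set per-gene means is reported alongside.
    """
    means = dependency.gene_means()
    in_set = [g for g in set(gene_set) if g in means.index]
    if len(in_set) < 2:
        raise ValueError(
            f"gene set intersects only {len(in_set)} gene(s) of the dependency matrix"
        )
    if len(in_set) < len(set(gene_set)):
        logger.info(
            "dependency test: %d of %d set genes present in the matrix",
            len(in_set), len(set(gene_set)),
        )
    arr = means.to_numpy(float)
    set_mask = means.index.isin(in_set)
    observed = float(arr[set_mask].mean())
    background = float(arr.mean())
    rng = np.random.default_rng(seed)
    n, size = len(arr), len(in_set)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        null[i] = arr[idx].mean()
    p_perm = (1 + int((null <= observed).sum())) / (n_perm + 1)
    others = arr[~set_mask]
    if len(others):
        rank = stats.mannwhitneyu(
            arr[set_mask], others, alternative="two-sided", method="asymptotic"
        )
        rank_p = float(rank.pvalue)
    else:
        rank_p = 1.0
    return {
        "p_perm": p_perm,
        "rank_test_p": rank_p,
        "set_mean": observed,
        "background_mean": background,
        "n_set_genes": size,
        "n_perm": n_perm,
    }
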