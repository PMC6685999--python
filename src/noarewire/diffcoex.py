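"""Two-condition differential coexpression module detection.

The change in coexpression between the low- and high-stress condition is
encoded in a change adjacency

    d_ij = ( 1/2 * | sign(c1_ij) c1_ij^2 - sign(c2_ij) c2_ij^2 | )^(beta/2),

where c1 and c2 are per-condition Pearson correlation matrices and beta is
a soft-threshold exponent chosen for approximate scale-free topology. The
change adjacency is converted to a topological overlap matrix (TOM), whose
dissimilarity 1 - TOM feeds average-linkage hierarchical clustering with a
tree cut; modules smaller than ``min_module_size`` are left unassigned.
Module significance comes from a dispersion statistic — the RMS
correlation change within the module — tested against a sample-label
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class DiffCoExParams:
    beta: int | None = None  # None = pick automatically
    min_module_size: int = 30
    n_perm: int = 1000
    seed: int = 0
    cut_height_quantile: float = 0.99
    soft_threshold_candidates: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.85
    gap_factor: float = 10.0
    coherence_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class CorrelationMatrices:
    gene_order: list[str]
    c1: np.ndarray  # low-stress condition
    c2: np.ndarray  # high-stress condition

    def __post_init__(self) -> None:
        n = len(self.gene_order)
        for name, c in (("c1", self.c1), ("c2", self.c2)):
            if c.shape != (n, n):
                raise ValueError(f"{name} shape {c.shape} != ({n},{n})")
            if not np.allclose(c, c.T):
                raise ValueError(f"{name} is not symmetric")
            if (np.abs(c) > 1 + 1e-9).any():
                raise ValueError(f"{name} has entries outside [-1, 1]")


@dataclass
class ModuleTestResult:
    module: int
    size: int
    dispersion: float
    p_value: float


def _pearson(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with zero-variance rows mapped to 0."""
    x = np.asarray(x, float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance gene(s) in a condition; correlations set to 0", flat.sum())
    xs = x.copy()
    xs[flat] = np.random.default_rng(0).normal(size=(flat.sum(), x.shape[1]))  # placeholder rows
    c = np.corrcoef(xs)
    c[flat, :] = 0.0
    c[:, flat] = 0.0
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def condition_correlations(expr, grouping) -> CorrelationMatrices:
    """Pearson correlation matrices per stress condition."""
    low = [s for s in grouping.low_samples if s in expr.values.columns]
    high = [s for s in grouping.high_samples if s in expr.values.columns]
    if len(low) < 3 or len(high) < 3:
        raise ValueError("need >= 3 samples per condition for correlations")
    c1 = _pearson(expr.values[low].to_numpy(float))
    c2 = _pearson(expr.values[high].to_numpy(float))
    return CorrelationMatrices(gene_order=expr.gene_ids, c1=c1, c2=c2)


def _change_matrix(c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """Unthresholded change score: 1/2 |sign(c1) c1^2 - sign(c2) c2^2|."""
    return 0.5 * np.abs(np.sign(c1) * c1**2 - np.sign(c2) * c2**2)


def adjacency_change(c: CorrelationMatrices, beta: int) -> np.ndarray:
    """Soft-thresholded change adjacency d = (change score)^(beta/2)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    d = _change_matrix(c.c1, c.c2) ** (beta / 2.0)
    np.fill_diagonal(d, 0.0)
    return d


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Positive when the fitted slope is negative (scale-free decay); the
    sign convention penalizes increasing degree distributions.
    """
    k = k[k > 0]
    if len(k) < 10:
        return -1.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(logk, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = logk[which == b]
        if len(members) == 0:
            continue
        xs.append(np.log10(np.mean(10**members)))
        ys.append(np.log10(len(members) / len(logk)))
    if len(xs) < 3:
        return -1.0
    xs, ys = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * xs + intercept
    ss_res = ((ys - fitted) ** 2).sum()
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    c: CorrelationMatrices,
    candidates: tuple[int, ...] = tuple(range(1, 21)),
    r2_target: float = 0.85,
) -> int:
    """Smallest beta whose change-adjacency connectivity is scale-free.

    For each candidate the connectivity k_i = sum_j d_ij(beta) is binned on
    a log scale and log-frequency is regressed on log-mean-degree; the
    smallest beta with signed fit R^2 >= ``r2_target`` wins. If none
    reaches the target the beta maximizing R^2 is returned with a warning.
    """
    if not candidates:
        raise ValueError("no soft-threshold candidates given")
    if len(candidates) == 1:
        return candidates[0]
    if len(c.gene_order) < 50:
        logger.warning("fewer than 50 genes; scale-free fit is unreliable")
    base = _change_matrix(c.c1, c.c2)
    np.fill_diagonal(base, 0.0)
    best_beta, best_r2 = candidates[0], -np.inf
    for beta in sorted(candidates):
        k = (base ** (beta / 2.0)).sum(axis=1)
        r2 = _scale_free_r2(k)
        if r2 >= r2_target:
            return beta
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    logger.warning(
        "no candidate beta reached scale-free R^2 %.2f; using beta=%d (R^2=%.3f)",
        r2_target, best_beta, best_r2,
    )
    return best_beta


def topological_overlap(d: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a weighted adjacency in [0, 1].

    TOM_ij = (sum_u d_iu d_uj + d_ij) / (min(k_i, k_j) + 1 - d_ij) with
    k_i = sum_u d_iu, unit diagonal. Shared-neighbour weight rescues
    gene pairs whose direct change score is weak but whose neighbourhoods
    change together.
    """
    d = np.asarray(d, float)
    if ((d < 0) | (d > 1)).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = d.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    numer = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = numer / np.maximum(denom, 1e-12)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _choose_cut_height(
    heights: np.ndarray, quantile: float, gap_factor: float, min_size: int
) -> float:
    """Cut height for the dendrogram: the largest gap between consecutive
    merge heights (below the ``quantile`` ceiling), if it is decisive.

    Tight differential modules finish merging well below the heights at
    which unrelated genes join, leaving a wide empty band in the merge
    height distribution; cutting inside that band isolates the modules.
    A gap only counts as decisive when it exceeds ``gap_factor`` times
    the median inter-merge gap — otherwise (no clear multi-scale
    structure) the cut falls back to the ``quantile`` of merge heights.
    """
    ceiling = float(np.quantile(heights, quantile))
    h = np.sort(heights)
    gaps = np.diff(h)
    # a cluster of m leaves needs m - 1 merges below the cut, so gaps in
    # the first min_size - 2 ranks cannot sit above a complete module
    eligible = (np.arange(1, len(h)) >= min_size - 1) & (h[1:] <= ceiling)
    if not eligible.any() or len(h) < 3:
        return ceiling
    idx = np.flatnonzero(eligible)
    best = idx[np.argmax(gaps[idx])]
    median_gap = float(np.median(gaps[gaps > 0])) if (gaps > 0).any() else 0.0
    if median_gap == 0 or gaps[best] < gap_factor * median_gap:
        return ceiling
    return float((h[best] + h[best + 1]) / 2.0)


def _coherent_clusters(
    dmat: np.ndarray, idx: np.ndarray, params: DiffCoExParams,
) -> list[np.ndarray]:
    """One round of cut-and-screen on the genes in ``idx``.

    Clusters the submatrix, cuts at the most decisive merge-height gap
    (falling back to the ``cut_height_quantile`` static cut), and returns
    the clusters that are both module-sized and coherent: mean
    within-cluster TOM similarity at least ``coherence_ratio`` times the
    mean similarity to the other genes of this round. The coherence
    screen is what keeps selection on sampling noise from minting
    spurious modules.
    """
    sub = dmat[np.ix_(idx, idx)]
    sim = 1.0 - sub
    condensed = squareform(np.maximum(sub, 0.0), checks=False)
    link = hierarchy.linkage(condensed, method="average")
    cut_height = _choose_cut_height(
        link[:, 2], params.cut_height_quantile, params.gap_factor,
        params.min_module_size,
    )
    raw = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    n = len(idx)
    found = []
    for m in np.unique(raw):
        members = np.flatnonzero(raw == m)
        if len(members) < params.min_module_size:
            continue
        outside = np.setdiff1d(np.arange(n), members)
        if len(outside) == 0:
            logger.warning("cluster spans every gene; no contrast to call it a module")
            continue
        iu = np.triu_indices(len(members), k=1)
        within = float(sim[np.ix_(members, members)][iu].mean())
        between = float(sim[np.ix_(members, outside)].mean())
        if within < params.coherence_ratio * max(between, 1e-12):
            logger.info(
                "cluster of %d genes rejected: within/between TOM ratio %.2f < %.2f",
                len(members), within / max(between, 1e-12), params.coherence_ratio,
            )
            continue
        found.append(idx[members])
    return found


def detect_modules(
    dissimilarity: np.ndarray,
    gene_order: list[str],
    params: DiffCoExParams,
) -> pd.Series:
    """Average-linkage clustering of the TOM dissimilarity with a tree cut.

    Modules are extracted by iterated peeling: each round clusters the
    not-yet-assigned genes, cuts the dendrogram at the most decisive gap
    in its merge-height distribution (see :func:`_choose_cut_height`;
    without such a gap the cut falls back to the ``cut_height_quantile``
    of merge heights), keeps the clusters that are module-sized and pass
    the TOM-coherence screen, removes their genes, and repeats until a
    round yields nothing. Peeling makes detection multi-scale: a weakly
    separated module hidden above the first cut is found once the
    stronger modules no longer dominate the height distribution. Genes
    never assigned are labeled 0; modules are numbered 1, 2, ... in
    decreasing size order (ties broken by smallest member gene id, so the
    labeling is invariant to gene order).
    """
    n = len(gene_order)
    if n < params.min_module_size:
        logger.warning("fewer genes (%d) than min module size; all unassigned", n)
        return pd.Series(0, index=pd.Index(gene_order, name="gene"))
    dmat = np.asarray(dissimilarity, float)
    remaining = np.arange(n)
    modules: list[np.ndarray] = []
    while len(remaining) >= params.min_module_size + 2:
        found = _coherent_clusters(dmat, remaining, params)
        if not found:
            break
        modules.extend(found)
        assigned = np.concatenate(found)
        remaining = np.setdiff1d(remaining, assigned)
    labels = np.zeros(n, dtype=int)
    modules.sort(key=lambda c: (-len(c), int(c.min())))
    for new, members in enumerate(modules, start=1):
        labels[members] = new
    out = pd.Series(labels, index=pd.Index(gene_order, name="gene"))
    logger.info("detected %d module(s) of size >= %d", len(modules), params.min_module_size)
    return out


def module_dispersion(c1: np.ndarray, c2: np.ndarray, idx: np.ndarray) -> float:
    """RMS correlation change over unordered gene pairs of a module:
    sqrt(mean_{i<j} (c1_ij - c2_ij)^2 / 2)."""
    if len(idx) < 2:
        raise ValueError("module must have >= 2 genes")
    sub = (c1[np.ix_(idx, idx)] - c2[np.ix_(idx, idx)]) ** 2
    iu = np.triu_indices(len(idx), k=1)
    return float(np.sqrt(sub[iu].mean() / 2.0))


def module_dispersion_test(
    expr,
    grouping,
    modules: pd.Series,
    params: DiffCoExParams,
) -> list[ModuleTestResult]:
    """Permutation significance of each module's dispersion statistic.

    Sample labels are shuffled between the two conditions (group sizes
    preserved; unassigned samples never enter); one shuffle set is shared
    by all modules. p = (1 + #{perm >= obs}) / (n_perm + 1), ties counting
    against significance.
    """
    low = [s for s in grouping.low_samples if s in expr.values.columns]
    high = [s for s in grouping.high_samples if s in expr.values.columns]
    if len(low) < 3 or len(high) < 3:
        raise ValueError("need >= 3 samples per condition")
    labels = modules[modules > 0]
    module_ids = sorted(labels.unique())
    results: list[ModuleTestResult] = []
    if not module_ids:
        return results
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    module_idx = {}
    for m in module_ids:
        genes = [g for g in labels.index[labels == m]]
        idx = np.array([gene_pos[g] for g in genes])
        if len(idx) < 2:
            logger.warning("module %s has < 2 genes; skipped", m)
            continue
        module_idx[m] = idx
    union = np.unique(np.concatenate(list(module_idx.values())))
    remap = {orig: i for i, orig in enumerate(union)}
    data = expr.values[low + high].to_numpy(float)[union]
    n_low = len(low)

    def cond_corr(cols_low: np.ndarray, cols_high: np.ndarray):
        return _pearson(data[:, cols_low]), _pearson(data[:, cols_high])

    obs_c1, obs_c2 = cond_corr(np.arange(n_low), np.arange(n_low, data.shape[1]))
    observed = {
        m: module_dispersion(obs_c1, obs_c2, np.array([remap[i] for i in idx]))
        for m, idx in module_idx.items()
    }
    rng = np.random.default_rng(params.seed)
    exceed = {m: 0 for m in module_idx}
    n_samples = data.shape[1]
    for _ in range(params.n_perm):
        perm = rng.permutation(n_samples)
        p1, p2 = cond_corr(perm[:n_low], perm[n_low:])
        for m, idx in module_idx.items():
            local = np.array([remap[i] for i in idx])
            if module_dispersion(p1, p2, local) >= observed[m]:
                exceed[m] += 1
    for m, idx in module_idx.items():
        results.append(
            ModuleTestResult(
                module=int(m),
                size=len(idx),
                dispersion=observed[m],
                p_value=(1 + exceed[m]) / (params.n_perm + 1),
            )
        )
    return results


def run_diffcoex(expr, grouping, params: DiffCoExParams | None = None):
    """Full differential-coexpression pass: correlations, soft threshold,
    TOM, modules, dispersion test. Returns (modules, test results, beta)."""
    params = params or DiffCoExParams()
    corr = condition_correlations(expr, grouping)
    beta = params.beta if params.beta is not None else pick_soft_threshold(
        corr, params.soft_threshold_candidates, params.scale_free_r2_target
    )
    d = adjacency_change(corr, beta)
    tom = topological_overlap(d)
    modules = detect_modules(1.0 - tom, corr.gene_order, params)
    tests = module_dispersion_test(expr, grouping, modules, params)
    return modules, tests, beta
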