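"""Interactome mapping, rewiring-hub identification and overlap statistics.

Differential coexpression modules are mapped onto the scored physical
interactome; a gene qualifies as a NOA rewiring hub when it is itself
significantly upregulated (q < 0.05, log2FC >= 0.5) and has at least three
physically interacting neighbours that are significantly differentially
expressed in either direction (the rewiring degree). Overlap of hub or
neighbour sets across cohorts is quantified with the Jaccard index and
tested against a within-degree node-label permutation null that preserves
the interactome's degree sequence exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from noarewire.iotypes import InteractomeGraph

logger = logging.getLogger(__name__)

HUB_FC_MIN = 0.5
HUB_Q_MAX = 0.05
MIN_REWIRING = 3
MIN_CONNECTED = 5


@dataclass
class ModuleSubgraph:
    """Induced interactome subgraph of one module's member genes."""

    module: int
    subgraph: nx.Graph

    @property
    def member_genes(self) -> set[str]:
        return set(self.subgraph.nodes)

    @property
    def connected_member_count(self) -> int:
        return sum(1 for n in self.subgraph.nodes if self.subgraph.degree(n) >= 1)


@dataclass
class HubRecord:
    gene_id: str
    run: str
    module: int
    log2fc: float
    q_value: float
    rewiring_degree: int
    neighbor_genes: frozenset[str]

    def __post_init__(self) -> None:
        assert self.log2fc >= HUB_FC_MIN
        assert self.q_value < HUB_Q_MAX
        assert self.rewiring_degree >= MIN_REWIRING


@dataclass
class OverlapResult:
    matrix: pd.DataFrame  # Jaccard off-diagonal; set sizes on the diagonal
    average_offdiag: float
    permutation_p: float | None = None
    null_values: np.ndarray | None = field(default=None, repr=False)


def map_module_to_interactome(
    module_genes, interactome: InteractomeGraph,
    module: int = 0, min_connected: int = MIN_CONNECTED,
) -> ModuleSubgraph | None:
    """Induce the module on the interactome; keep it only if at least
    ``min_connected`` members carry an induced edge."""
    present = set(module_genes) & set(interactome.graph.nodes)
    sub = interactome.graph.subgraph(present).copy()
    ms = ModuleSubgraph(module=module, subgraph=sub)
    if ms.connected_member_count < min_connected:
        return None
    return ms


def rewiring_degree(
    gene: str, subgraph: nx.Graph, de_results: pd.DataFrame, de_q: float = 0.05
) -> tuple[int, list[str]]:
    """Count the gene's neighbours that are significantly differentially
    expressed (q strictly below ``de_q``, either direction)."""
    if gene not in de_results.index:
        raise KeyError(f"gene {gene!r} absent from DE results")
    neighbors = []
    for nb in subgraph.neighbors(gene):
        if nb in de_results.index and de_results.loc[nb, "q_value"] < de_q:
            neighbors.append(nb)
    return len(neighbors), sorted(neighbors)


def identify_noa_hubs(
    subgraphs: list[ModuleSubgraph],
    de_results: pd.DataFrame,
    run: str = "run",
    fc_min: float = HUB_FC_MIN,
    q_max: float = HUB_Q_MAX,
    min_rewiring: int = MIN_REWIRING,
) -> list[HubRecord]:
    """Hub rule: upregulated (log2fc >= fc_min, q < q_max) with rewiring
    degree >= min_rewiring, counted within the gene's module subgraph."""
    hubs: list[HubRecord] = []
    for ms in subgraphs:
        for gene in sorted(ms.member_genes):
            if gene not in de_results.index:
                continue
            lfc = float(de_results.loc[gene, "log2fc"])
            q = float(de_results.loc[gene, "q_value"])
            if lfc < fc_min or q >= q_max:
                continue
            deg, nbrs = rewiring_degree(gene, ms.subgraph, de_results, q_max)
            if deg >= min_rewiring:
                hubs.append(
                    HubRecord(
                        gene_id=gene, run=run, module=ms.module,
                        log2fc=lfc, q_value=q,
                        rewiring_degree=deg, neighbor_genes=frozenset(nbrs),
                    )
                )
    return hubs


def rank_modules_by_activation(
    modules: pd.Series,
    subgraphs: list[ModuleSubgraph],
    de_results: pd.DataFrame,
    fc_min: float = HUB_FC_MIN,
    q_max: float = HUB_Q_MAX,
) -> pd.DataFrame:
    """Rank modules by the fraction of members that are significantly
    upregulated AND carry at least one induced interactome edge.

    Descending by fraction; ties broken by module size (larger first) then
    module label.
    """
    sub_by_module = {ms.module: ms for ms in subgraphs}
    rows = []
    for m in sorted(set(modules[modules > 0])):
        genes = list(modules.index[modules == m])
        ms = sub_by_module.get(m)
        count = 0
        if ms is not None:
            for g in genes:
                if g not in ms.subgraph or ms.subgraph.degree(g) < 1:
                    continue
                if g in de_results.index and (
                    de_results.loc[g, "log2fc"] >= fc_min
                    and de_results.loc[g, "q_value"] < q_max
                ):
                    count += 1
        rows.append({"module": int(m), "size": len(genes),
                     "activated": count, "fraction": count / len(genes)})
    df = pd.DataFrame(rows, columns=["module", "size", "activated", "fraction"])
    return df.sort_values(
        ["fraction", "size", "module"], ascending=[False, False, True]
    ).reset_index(drop=True)


def jaccard_index(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; 0 for two empty sets (logged)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        logger.info("jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def pairwise_overlap_matrix(named_sets: dict[str, set]) -> OverlapResult:
    """Symmetric Jaccard matrix over named gene sets.

    The diagonal carries the set sizes (the off-diagonal entries are
    Jaccard indices); ``average_offdiag`` is the mean over unordered
    distinct pairs.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 named sets")
    mat = pd.DataFrame(0.0, index=names, columns=names)
    vals = []
    for i, a in enumerate(names):
        mat.loc[a, a] = float(len(named_sets[a]))
        for b in names[i + 1:]:
            j = jaccard_index(named_sets[a], named_sets[b])
            mat.loc[a, b] = mat.loc[b, a] = j
            vals.append(j)
    return OverlapResult(matrix=mat, average_offdiag=float(np.mean(vals)))


def degree_preserving_permutation(
    graph: nx.Graph, rng, degree_binning: str = "exact"
) -> dict:
    """Uniform node-label shuffle within each degree class.

    Returns the relabeling map old -> new. Edge structure is untouched;
    with the default exact-degree classes every label keeps its degree
    exactly. ``degree_binning="log2"`` pools degrees into powers-of-two
    bins instead — useful for small graphs whose high-degree classes are
    singletons and would otherwise pin hub labels in place; the degree
    sequence is then only preserved up to bin resolution. Warns when every
    class is a singleton (the permutation is then the identity).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if degree_binning not in ("exact", "log2"):
        raise ValueError(f"unknown degree_binning {degree_binning!r}")
    by_degree: dict[int, list] = {}
    for node, deg in graph.degree():
        key = deg if degree_binning == "exact" else (deg.bit_length() if deg > 0 else 0)
        by_degree.setdefault(key, []).append(node)
    mapping = {}
    nontrivial = False
    for deg, nodes in sorted(by_degree.items()):
        nodes = sorted(nodes)
        if len(nodes) > 1:
            nontrivial = True
        shuffled = list(rng.permutation(nodes))
        mapping.update(dict(zip(nodes, shuffled)))
    if not nontrivial:
        logger.warning("all degree classes are singletons; permutation is the identity")
    return mapping


def neighbor_overlap_null_test(
    hub_sets: dict[str, set],
    interactome: InteractomeGraph,
    de_genes_per_run: dict[str, set],
    n_networks: int = 1000,
    seed: int = 0,
    degree_binning: str = "exact",
) -> OverlapResult:
    """Test whether hubs of different cohorts share rewired neighbourhoods.

    Observed statistic: average off-diagonal Jaccard of the pooled
    DE-neighbour sets of each run's hubs. Null: ``n_networks``
    within-degree node-label permutations of the interactome, hubs and DE
    status held fixed, statistic recomputed on each relabelled graph.
    p = (1 + #{null >= observed}) / (n_networks + 1).
    """
    if all(len(h) == 0 for h in hub_sets.values()):
        raise ValueError("all hub sets are empty")
    g = interactome.graph
    adjacency = {n: set(g.neighbors(n)) for n in g.nodes}
    observed_sets = {
        run: set().union(
            *(adjacency.get(h, set()) & de_genes_per_run[run] for h in hubs)
        ) if hubs else set()
        for run, hubs in hub_sets.items()
    }
    observed = pairwise_overlap_matrix(observed_sets)
    rng = np.random.default_rng(seed)
    null_vals = np.empty(n_networks)
    for i in range(n_networks):
        mapping = degree_preserving_permutation(g, rng, degree_binning)
        inverse = {v: k for k, v in mapping.items()}
        # neighbours of hub h in the relabelled graph = images of the
        # neighbours of h's pre-image
        null_sets = {}
        for run, hubs in hub_sets.items():
            de = de_genes_per_run[run]
            acc: set = set()
            for h in hubs:
                pre = inverse.get(h)
                if pre is None:
                    continue
                acc |= {mapping[nb] for nb in adjacency[pre]} & de
            null_sets[run] = acc
        null_vals[i] = pairwise_overlap_matrix(null_sets).average_offdiag
    p = (1 + int((null_vals >= observed.average_offdiag).sum())) / (n_networks + 1)
    return OverlapResult(
        matrix=observed.matrix,
        average_offdiag=observed.average_offdiag,
        permutation_p=p,
        null_values=null_vals,
    )


def cross_run_gene_summary(
    module_genes_per_run: dict[str, set],
    de_per_run: dict[str, pd.DataFrame],
    fc_min: float = HUB_FC_MIN,
    min_runs: int = 6,
) -> pd.DataFrame:
    """Per-gene participation across cohorts.

    run_count = number of runs whose differential modules contain the
    gene; median log2FC over the runs where the gene was tested; flagged
    when median >= ``fc_min`` and run_count > ``min_runs`` (strict)."""
    all_genes = sorted(set().union(*module_genes_per_run.values())) if module_genes_per_run else []
    rows = []
    for gene in all_genes:
        run_count = sum(1 for genes in module_genes_per_run.values() if gene in genes)
        lfcs = [
            float(de.loc[gene, "log2fc"])
            for de in de_per_run.values()
            if gene in de.index
        ]
        med = float(np.median(lfcs)) if lfcs else np.nan
        rows.append({
            "gene": gene,
            "run_count": run_count,
            "median_log2fc": med,
            "flagged": bool(run_count > min_runs and med >= fc_min),
        })
    return pd.DataFrame(rows, columns=["gene", "run_count", "median_log2fc", "flagged"]).set_index("gene")


def hub_table(hubs: list[HubRecord]) -> pd.DataFrame:
    rows = [
        {"gene": h.gene_id, "run": h.run, "module": h.module,
         "log2fc": h.log2fc, "q_value": h.q_value,
         "rewiring_degree": h.rewiring_degree,
         "neighbors": ";".join(sorted(h.neighbor_genes))}
        for h in hubs
    ]
    return pd.DataFrame(
        rows, columns=["gene", "run", "module", "log2fc", "q_value",
                       "rewiring_degree", "neighbors"],
    )
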