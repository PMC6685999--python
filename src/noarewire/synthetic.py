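"""Synthetic-data generators with known ground truth.

Every pipeline input kind can be generated offline: copy-number segment
profiles with controllable burden, negative-binomial count matrices with
planted condition-specific coexpression modules and hub fold changes, a
scale-free scored interactome with planted hub neighbourhoods, and
dependency-score matrices with a planted depleted gene set. Each
generator is a pure function of (parameters, seed); per-generator
sub-seeds are derived deterministically from one root seed.

Planted coexpression uses a shared latent factor per module per
condition. The factor loading is chosen so that the *observable*
correlation of log-scale expression — after the negative-binomial
sampling noise dilutes the latent signal — matches the requested target;
when the counting noise alone exceeds what the target permits, the
loading saturates and a warning reports the achievable ceiling.
"""

from __future__ import annotations

import logging
import zlib
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from noarewire import io_formats
from noarewire.iotypes import (
    DependencyMatrix,
    ExpressionMatrix,
    GenomeModel,
    InteractomeGraph,
    SampleMeta,
    SegmentProfile,
    SyntheticTruth,
)

logger = logging.getLogger(__name__)

LN2_SQ = np.log(2.0) ** 2


def gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def subseed(root_seed: int, name: str) -> int:
    """Stable sub-seed for a named generator, below 2**31."""
    return (int(root_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


def simulate_segment_profiles(
    n_samples: int,
    target_burdens,
    genome: GenomeModel,
    seed: int = 0,
    tolerance: float = 0.01,
) -> tuple[list[SegmentProfile], list[float]]:
    """Segment profiles whose CNA burden hits the requested targets.

    Per chromosome one altered segment (|seg_mean| >= 0.2, drawn in
    +/-[0.3, 1.5]) covers the target fraction of the chromosome at a
    random offset; the flanks are emitted as copy-neutral segments with
    seg_mean in (-0.2, 0.2). The realized burden therefore matches the
    target up to base-pair rounding; an error is raised if rounding alone
    exceeds ``tolerance`` (genome too small).
    """
    targets = np.broadcast_to(np.asarray(target_burdens, float), (n_samples,))
    if (targets < 0).any() or (targets >= 1).any():
        raise ValueError("target burdens must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    profiles: list[SegmentProfile] = []
    realized: list[float] = []
    for i, target in enumerate(targets):
        rows = []
        altered_total = 0
        for chrom, length in genome.lengths.items():
            alt_len = int(round(target * length))
            if alt_len == 0:
                rows.append((chrom, 1, length, float(rng.uniform(-0.19, 0.19))))
                continue
            start = int(rng.integers(1, length - alt_len + 2))
            end = start + alt_len - 1
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mean = float(sign * rng.uniform(0.3, 1.5))
            if start > 1:
                rows.append((chrom, 1, start - 1, float(rng.uniform(-0.19, 0.19))))
            rows.append((chrom, start, end, mean))
            if end < length:
                rows.append((chrom, end + 1, length, float(rng.uniform(-0.19, 0.19))))
            altered_total += alt_len
        burden = altered_total / genome.n_autosome
        if abs(burden - target) > tolerance:
            raise ValueError(
                f"genome too small to reach target burden {target:.3f} "
                f"within {tolerance} (got {burden:.3f})"
            )
        seg = pd.DataFrame(rows, columns=["chromosome", "start", "end", "seg_mean"])
        profiles.append(SegmentProfile(sample_id=f"s{i + 1:04d}", segments=seg))
        realized.append(burden)
    return profiles, realized


def simulate_expression(
    n_genes: int,
    groups: dict[str, str],
    truth: SyntheticTruth,
    nb_dispersion: float = 0.1,
    covariate_effects: dict[str, float] | None = None,
    seed: int = 0,
    latent_sd: float = 1.0,
    base_log2_mean: tuple[float, float] = (6.0, 9.0),
) -> tuple[ExpressionMatrix, SampleMeta]:
    """Negative-binomial counts with planted modules and fold changes.

    ``groups`` maps sample id -> {low, high}. Counts are NB with variance
    mu + alpha * mu^2 (alpha = ``nb_dispersion``) around a log2-scale
    latent signal of per-gene sd ``latent_sd``. Within a planted module
    the latent signals share a condition-specific factor tuned so that
    the observable pairwise correlation of log2 counts approximates the
    (r_low, r_high) targets. Planted hub and neighbour genes gain the
    target log2FC in the high group. Optional covariate effects
    (``age_slope`` per year, ``sex_offset`` for males) act on the latent
    scale and are recorded in the returned metadata.
    """
    if nb_dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    genes = gene_names(n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, (members, _, _) in truth.planted_modules.items():
        missing = members - set(genes)
        if missing:
            raise ValueError(f"planted module {name!r} references unknown genes {sorted(missing)[:3]}")
    samples = list(groups)
    if min(
        sum(1 for g in groups.values() if g == "low"),
        sum(1 for g in groups.values() if g == "high"),
    ) < 2:
        raise ValueError("each group needs >= 2 samples")
    high_mask = np.array([groups[s] == "high" for s in samples])
    rng = np.random.default_rng(seed)
    n_samples = len(samples)

    base = rng.uniform(*base_log2_mean, size=n_genes)
    # observable log2-scale counting-noise variance per gene (delta method)
    v_nb = (1.0 / 2.0**base + nb_dispersion) / LN2_SQ
    total_var = latent_sd**2 + v_nb

    latent = base[:, None] + rng.normal(0.0, latent_sd, size=(n_genes, n_samples))
    for name, (members, r_low, r_high) in truth.planted_modules.items():
        idx = np.array(sorted(gene_pos[g] for g in members))
        for cond_mask, r in ((~high_mask, r_low), (high_mask, r_high)):
            if r == 0 or not cond_mask.any():
                continue
            shared_var = r * total_var[idx]
            indep_var = (1 - r) * latent_sd**2 - r * v_nb[idx]
            if (indep_var < 0).any():
                logger.warning(
                    "module %s: target correlation %.2f exceeds the NB noise "
                    "ceiling for %d gene(s); loading saturated",
                    name, r, int((indep_var < 0).sum()),
                )
                shared_var = np.minimum(shared_var, latent_sd**2)
                indep_var = np.maximum(indep_var, 0.0)
            factor = rng.normal(size=cond_mask.sum())
            # center the factor so the planted coexpression cannot leak a
            # coherent module-wide offset into the planted fold changes
            factor -= factor.mean()
            noise = rng.normal(size=(len(idx), cond_mask.sum()))
            block = (
                np.sqrt(shared_var)[:, None] * factor[None, :]
                + np.sqrt(indep_var)[:, None] * noise
            )
            latent[np.ix_(idx, np.where(cond_mask)[0])] = base[idx][:, None] + block

    for hub, (lfc, neighbors) in truth.planted_hubs.items():
        shifted = {hub} | set(neighbors)
        missing = shifted - set(genes)
        if missing:
            raise ValueError(f"planted hub genes absent from gene set: {sorted(missing)[:3]}")
        idx = np.array(sorted(gene_pos[g] for g in shifted))
        latent[np.ix_(idx, np.where(high_mask)[0])] += lfc

    age = rng.uniform(30.0, 80.0, size=n_samples)
    sex = rng.choice(["F", "M"], size=n_samples)
    effects = covariate_effects or {}
    if "age_slope" in effects:
        latent += effects["age_slope"] * (age - age.mean())[None, :]
    if "sex_offset" in effects:
        latent += effects["sex_offset"] * (sex == "M").astype(float)[None, :]

    mu = 2.0**latent
    if nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / nb_dispersion
        counts = rng.negative_binomial(shape, shape / (shape + mu))
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples),
        value_kind="raw",
    )
    meta = SampleMeta(
        table=pd.DataFrame(
            {"age": age, "sex": sex, "stress_label": [groups[s] for s in samples]},
            index=pd.Index(samples, name="sample"),
        )
    )
    return expr, meta


def simulate_interactome(
    n_nodes: int,
    degree_exponent: float = 2.5,
    truth: SyntheticTruth | None = None,
    seed: int = 0,
    score_cutoff: float = 0.156,
) -> InteractomeGraph:
    """Approximately scale-free scored PPI graph with planted hub wiring.

    Background topology comes from a configuration model on a power-law
    degree sequence (self-loops and multi-edges rejected); every planted
    hub is additionally wired to all of its designated neighbours with
    scores above the cutoff, so planted edges survive load-time filtering.
    Background edge scores are uniform on [0, 1] and filtered at the
    cutoff like real data.
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    truth = truth or SyntheticTruth()
    nodes = gene_names(n_nodes)
    node_set = set(nodes)
    for hub, (_, neighbors) in truth.planted_hubs.items():
        missing = ({hub} | set(neighbors)) - node_set
        if missing:
            raise ValueError(f"planted interactome genes absent from node set: {sorted(missing)[:3]}")
    rng = np.random.default_rng(seed)
    # discrete power-law degrees, minimum 1, capped at sqrt(n)
    u = rng.random(n_nodes)
    degrees = np.floor(u ** (-1.0 / (degree_exponent - 1.0))).astype(int)
    degrees = np.clip(degrees, 1, max(2, int(np.sqrt(n_nodes) * 2)))
    if degrees.sum() % 2:
        degrees[int(rng.integers(n_nodes))] += 1
    g_cfg = nx.configuration_model(degrees, seed=int(rng.integers(2**31 - 1)))
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b in g_cfg.edges():
        if a == b:
            continue
        u_node, v_node = nodes[a], nodes[b]
        if not g.has_edge(u_node, v_node):
            g.add_edge(u_node, v_node, score=float(rng.uniform(0.0, 1.0)))
    for hub, (_, neighbors) in truth.planted_hubs.items():
        for nb in sorted(neighbors):
            score = float(rng.uniform(score_cutoff + 1e-6, 1.0))
            if g.has_edge(hub, nb):
                g[hub][nb]["score"] = max(g[hub][nb]["score"], score)
            else:
                g.add_edge(hub, nb, score=score)
    drop = [(a, b) for a, b, d in g.edges(data=True) if d["score"] <= score_cutoff]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    return InteractomeGraph(graph=g, score_cutoff=score_cutoff)


def simulate_dependency_scores(
    n_genes: int,
    n_cell_lines: int,
    planted_set,
    shift: float,
    seed: int = 0,
) -> DependencyMatrix:
    """Standard-normal dependency scores with a mean shift on a planted
    gene set (negative shift = stronger dependency)."""
    if n_cell_lines < 2:
        raise ValueError("need at least 2 cell lines")
    planted = sorted(set(planted_set))
    genes = gene_names(n_genes)
    unknown = set(planted) - set(genes)
    if unknown:
        raise ValueError(f"planted genes outside the gene set: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n_genes, n_cell_lines))
    pos = {g: i for i, g in enumerate(genes)}
    idx = [pos[g] for g in planted]
    scores[idx] += shift
    cells = [f"cl{i:03d}" for i in range(1, n_cell_lines + 1)]
    return DependencyMatrix(
        scores=pd.DataFrame(scores, index=pd.Index(genes, name="gene"), columns=cells)
    )


def default_truth(
    n_genes: int = 500,
    n_modules: int = 3,
    module_size: int = 40,
    r_low: float = 0.7,
    r_high: float = 0.0,
    n_hubs: int = 2,
    hub_log2fc: float = 1.0,
    n_neighbors: int = 5,
    dependency_shift: float = -0.5,
    root_seed: int = 0,
) -> SyntheticTruth:
    """Standard planted configuration used by the bundled fixture.

    The first ``n_hubs`` modules each contribute one hub (their first
    member) with ``n_neighbors`` designated neighbours drawn from the same
    module; hub and neighbours share the planted log2FC. The planted
    dependency set is the union of hubs and neighbours.
    """
    genes = gene_names(n_genes)
    if n_modules * module_size > n_genes:
        raise ValueError("planted modules exceed the gene set")
    modules: dict[str, tuple[frozenset[str], float, float]] = {}
    hubs: dict[str, tuple[float, frozenset[str]]] = {}
    for m in range(n_modules):
        members = genes[m * module_size:(m + 1) * module_size]
        modules[f"M{m + 1}"] = (frozenset(members), r_low, r_high)
        if m < n_hubs:
            hub, neighbors = members[0], frozenset(members[1:1 + n_neighbors])
            hubs[hub] = (hub_log2fc, neighbors)
    dep_genes = frozenset().union(
        *({h} | set(nbrs) for h, (_, nbrs) in hubs.items())
    ) if hubs else frozenset()
    return SyntheticTruth(
        planted_modules=modules,
        planted_hubs=hubs,
        planted_dependency_set=(dep_genes, dependency_shift),
        seeds={"root": int(root_seed)},
    )


def simulate_fixture(
    out_dir: str | Path | None = None,
    n_genes: int = 500,
    n_low: int = 60,
    n_high: int = 60,
    n_cell_lines: int = 50,
    nb_dispersion: float = 0.05,
    seed: int = 0,
    genome: GenomeModel | None = None,
    truth: SyntheticTruth | None = None,
) -> dict:
    """One coherent fixture covering every pipeline input.

    Low-stress samples receive CNA burdens in [0.01, 0.06] and high-stress
    samples in [0.25, 0.60], so the published threshold pair (0.070,
    0.192) reproduces the planted grouping exactly. If ``out_dir`` is
    given, all tables plus ``truth.json`` are written there.
    """
    genome = genome or GenomeModel.toy(n_chromosomes=4, chromosome_length=50_000_000)
    if truth is None:
        module_size = max(6, min(40, n_genes // 4))
        truth = default_truth(n_genes=n_genes, module_size=module_size, root_seed=seed)
    truth.seeds.update({
        name: subseed(seed, name)
        for name in ("segments", "expression", "interactome", "dependency")
    })
    rng = np.random.default_rng(subseed(seed, "burden-targets"))
    burdens = np.concatenate([
        rng.uniform(0.01, 0.06, size=n_low),
        rng.uniform(0.25, 0.60, size=n_high),
    ])
    profiles, realized = simulate_segment_profiles(
        n_low + n_high, burdens, genome, seed=truth.seeds["segments"]
    )
    groups = {
        p.sample_id: ("low" if i < n_low else "high")
        for i, p in enumerate(profiles)
    }
    expr, meta = simulate_expression(
        n_genes, groups, truth,
        nb_dispersion=nb_dispersion,
        covariate_effects={"age_slope": 0.005, "sex_offset": 0.2},
        seed=truth.seeds["expression"],
    )
    interactome = simulate_interactome(
        n_genes, truth=truth, seed=truth.seeds["interactome"]
    )
    dependency = simulate_dependency_scores(
        n_genes, n_cell_lines,
        truth.planted_dependency_set[0], truth.planted_dependency_set[1],
        seed=truth.seeds["dependency"],
    )
    bundle = {
        "genome": genome,
        "truth": truth,
        "profiles": profiles,
        "realized_burdens": realized,
        "expression": expr,
        "meta": meta,
        "interactome": interactome,
        "dependency": dependency,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io_formats.write_segment_table(profiles, out / "segments.tsv")
        io_formats.write_expression_matrix(expr, out / "counts.tsv")
        io_formats.write_sample_meta(meta, out / "meta.tsv")
        io_formats.write_interactome(interactome, out / "ppi.tsv")
        io_formats.write_dependency_matrix(dependency, out / "dependency.tsv")
        io_formats.write_truth(truth, out / "truth.json")
    return bundle
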