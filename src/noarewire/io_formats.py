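"""Readers and writers for the tabular formats the pipeline touches.

All files are UTF-8 TSV; gzip is handled transparently by extension
(pandas infers compression from ``.gz``). Validation is strict: malformed
rows raise with line context rather than being silently coerced.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from noarewire.iotypes import (
    SEGMENT_COLUMNS,
    DependencyMatrix,
    ExpressionMatrix,
    GenomeModel,
    InteractomeGraph,
    SampleMeta,
    SegmentProfile,
    SyntheticTruth,
)

logger = logging.getLogger(__name__)

_SEG_HEADER = ["sample", "chromosome", "start", "end", "seg_mean"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def read_segment_table(path: str | Path, genome: GenomeModel) -> list[SegmentProfile]:
    """Read a SEG-like TSV into one :class:`SegmentProfile` per sample.

    Columns: sample, chromosome, start, end, seg_mean. Segments on
    chromosomes outside the autosome model (e.g. chrX) are dropped with a
    logged count. Row order is preserved within each sample.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty segment file") from exc
    missing = [c for c in _SEG_HEADER if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("start", "end", "seg_mean"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            line = int(df.index[numeric.isna()][0]) + 2  # header is line 1
            raise FormatError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = numeric
    known = set(genome.chromosome_names)
    off = ~df["chromosome"].isin(known)
    if off.any():
        logger.warning(
            "%s: dropped %d segment(s) on non-autosome chromosomes (%s)",
            path, int(off.sum()), sorted(df.loc[off, "chromosome"].unique()),
        )
        df = df.loc[~off]
    profiles = []
    for sample_id, sub in df.groupby("sample", sort=False):
        seg = sub[list(SEGMENT_COLUMNS)].astype(
            {"start": int, "end": int, "seg_mean": float}
        )
        profiles.append(SegmentProfile(sample_id=str(sample_id), segments=seg))
    return profiles


def write_segment_table(profiles: list[SegmentProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        seg = p.segments.copy()
        seg.insert(0, "sample", p.sample_id)
        frames.append(seg)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_SEG_HEADER)
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV of raw counts (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample column {dup!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if (arr < 0).any():
        raise FormatError(f"{path}: negative counts present")
    if not np.allclose(np.asarray(arr, float) % 1, 0):
        raise FormatError(f"{path}: fractional counts present")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df, value_kind="raw")


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_matrix(path: str | Path, value_kind: str = "normalized") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), value_kind=value_kind)  # type: ignore[arg-type]


def read_sample_meta(path: str | Path) -> SampleMeta:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMeta(table=df)


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample")


def read_interactome(path: str | Path, score_cutoff: float = 0.156) -> InteractomeGraph:
    """Read a scored edge list TSV (geneA, geneB, score) into a simple graph.

    Edges with score strictly greater than ``score_cutoff`` are retained;
    self-loops are dropped; duplicate pairs keep the maximum score.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns (geneA, geneB, score)")
    df = df.iloc[:, :3]
    df.columns = ["gene_a", "gene_b", "score"]
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        line = int(df.index[score.isna()][0]) + 2
        raise FormatError(f"{path}: malformed score at line {line}")
    if ((score < 0) | (score > 1)).any():
        line = int(df.index[(score < 0) | (score > 1)][0]) + 2
        raise FormatError(f"{path}: score outside [0, 1] at line {line}")
    g = nx.Graph()
    n_loops = 0
    for a, b, s in zip(df["gene_a"].astype(str), df["gene_b"].astype(str), score):
        if a == b:
            n_loops += 1
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(s))
        else:
            g.add_edge(a, b, score=float(s))
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    drop = [(u, v) for u, v, d in g.edges(data=True) if d["score"] <= score_cutoff]
    g.remove_edges_from(drop)
    g.remove_nodes_from(list(nx.isolates(g)))
    if g.number_of_edges() == 0:
        logger.warning("%s: no edges above score cutoff %s", path, score_cutoff)
    return InteractomeGraph(graph=g, score_cutoff=score_cutoff)


def write_interactome(interactome: InteractomeGraph, path: str | Path) -> None:
    rows = [
        {"gene_a": u, "gene_b": v, "score": d["score"]}
        for u, v, d in sorted(interactome.graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(path, sep="\t", index=False)


def read_dependency_matrix(path: str | Path) -> DependencyMatrix:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return DependencyMatrix(scores=df.astype(float))


def write_dependency_matrix(dep: DependencyMatrix, path: str | Path) -> None:
    sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    dep.scores.to_csv(path, sep=sep, index_label="gene")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "planted_modules": {
            name: {"genes": sorted(genes), "r_low": r_low, "r_high": r_high}
            for name, (genes, r_low, r_high) in truth.planted_modules.items()
        },
        "planted_hubs": {
            hub: {"log2fc": lfc, "neighbors": sorted(nbrs)}
            for hub, (lfc, nbrs) in truth.planted_hubs.items()
        },
        "planted_dependency_set": {
            "genes": sorted(truth.planted_dependency_set[0]),
            "shift": truth.planted_dependency_set[1],
        },
        "seeds": truth.seeds,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        planted_modules={
            name: (frozenset(m["genes"]), m["r_low"], m["r_high"])
            for name, m in payload["planted_modules"].items()
        },
        planted_hubs={
            hub: (h["log2fc"], frozenset(h["neighbors"]))
            for hub, h in payload["planted_hubs"].items()
        },
        planted_dependency_set=(
            frozenset(payload["planted_dependency_set"]["genes"]),
            payload["planted_dependency_set"]["shift"],
        ),
        seeds={k: int(v) for k, v in payload["seeds"].items()},
    )
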