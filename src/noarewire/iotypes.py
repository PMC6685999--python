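"""Core domain containers shared across the pipeline.

All containers are lightweight dataclasses around numpy/pandas/networkx
objects; they validate their invariants at construction time so that
downstream stages can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

SEGMENT_COLUMNS = ("chromosome", "start", "end", "seg_mean")


@dataclass(frozen=True)
class GenomeModel:
    """Autosome reference: ordered chromosome labels and lengths in bp.

    ``n_autosome`` (the total autosomal length) is the denominator of the
    CNA-burden fraction.
    """

    chromosome_names: tuple[str, ...]
    chromosome_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chromosome_names) == 0:
            raise ValueError("genome must contain at least one chromosome")
        if len(self.chromosome_names) != len(self.chromosome_lengths):
            raise ValueError("chromosome names and lengths differ in length")
        if len(set(self.chromosome_names)) != len(self.chromosome_names):
            raise ValueError("duplicate chromosome labels")
        if any(ln <= 0 for ln in self.chromosome_lengths):
            raise ValueError("all chromosome lengths must be positive")
        for name in self.chromosome_names:
            if name.lstrip("chr").upper() in {"X", "Y"}:
                raise ValueError(f"sex chromosome {name!r} not allowed in autosome model")

    @property
    def n_autosome(self) -> int:
        return int(sum(self.chromosome_lengths))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chromosome_names, self.chromosome_lengths))

    @classmethod
    def toy(cls, n_chromosomes: int = 2, chromosome_length: int = 1_000_000) -> "GenomeModel":
        """Small synthetic genome for tests and simulations."""
        names = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
        return cls(names, (chromosome_length,) * n_chromosomes)


@dataclass
class SegmentProfile:
    """Per-sample copy-number segments.

    ``segments`` is a DataFrame with columns (chromosome, start, end,
    seg_mean); seg_mean is the log2 tumour/normal copy ratio. Coordinates
    are 1-based inclusive, so segment length = end - start + 1.
    """

    sample_id: str
    segments: pd.DataFrame

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")
        self.segments = seg = seg.loc[:, list(SEGMENT_COLUMNS)].reset_index(drop=True)
        if len(seg) and (seg["start"] > seg["end"]).any():
            bad = seg.index[seg["start"] > seg["end"]][0]
            raise ValueError(f"segment {bad} of sample {self.sample_id}: start > end")
        if len(seg) and not np.isfinite(seg["seg_mean"].to_numpy(float)).all():
            raise ValueError(f"non-finite seg_mean in sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``value_kind`` tracks the processing state: ``raw`` (non-negative
    integer counts), ``normalized`` (log-scale finite reals) or
    ``residual`` (covariate-corrected normalized values).
    """

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    value_kind: Literal["raw", "normalized", "residual"] = "raw"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy()
        if self.value_kind == "raw":
            if arr.size and (np.asarray(arr, dtype=float) < 0).any():
                raise ValueError("raw counts must be non-negative")
            if arr.size and not np.allclose(np.asarray(arr, dtype=float) % 1, 0):
                raise ValueError("raw counts must be integer-valued")
        else:
            if arr.size and not np.isfinite(np.asarray(arr, dtype=float)).all():
                raise ValueError("normalized values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleMeta:
    """Per-sample covariates and stress labels.

    ``table`` is indexed by sample id; ``stress_label`` column (if present)
    takes values in {low, high, unassigned}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r} in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def covariate_matrix(self, names: list[str]) -> pd.DataFrame:
        """Numeric design columns for the requested covariates.

        Categorical covariates are expanded into treatment-coded dummy
        columns; missing values raise.
        """
        cols = []
        for name in names:
            if name not in self.table.columns:
                raise KeyError(f"covariate {name!r} not in sample metadata")
            col = self.table[name]
            if col.isna().any():
                bad = col.index[col.isna()][0]
                raise ValueError(f"covariate {name!r} missing for sample {bad!r}")
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.astype(float).rename(name))
            else:
                dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
                cols.extend(dummies[c] for c in dummies.columns)
        if not cols:
            return pd.DataFrame(index=self.table.index)
        return pd.concat(cols, axis=1)


@dataclass
class InteractomeGraph:
    """Scored undirected protein-protein interaction network.

    Simple graph (no self-loops, no parallel edges); every retained edge
    has ``score`` strictly greater than ``score_cutoff``.
    """

    graph: nx.Graph
    score_cutoff: float = 0.156

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")
        for u, v, data in self.graph.edges(data=True):
            s = data.get("score")
            if s is None or not (self.score_cutoff < s <= 1.0):
                raise ValueError(
                    f"edge ({u},{v}) score {s} not in ({self.score_cutoff}, 1]"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DependencyMatrix:
    """Gene x cell-line dependency scores; lower = stronger dependency."""

    scores: pd.DataFrame  # index = gene ids, columns = cell-line ids

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate gene ids in dependency matrix")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate cell-line ids in dependency matrix")
        if self.scores.isna().all(axis=1).any():
            bad = self.scores.index[self.scores.isna().all(axis=1)][0]
            raise ValueError(f"gene {bad!r} has no non-missing dependency score")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    def gene_means(self) -> pd.Series:
        return self.scores.mean(axis=1, skipna=True)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic-data generators.

    ``planted_modules`` maps a module name to (gene set, r_low, r_high),
    the target within-module log-scale correlations per stress condition.
    ``planted_hubs`` maps hub gene -> (target log2FC, neighbor gene set).
    ``planted_dependency_set`` carries a mean dependency-score shift.
    """

    planted_modules: dict[str, tuple[frozenset[str], float, float]] = field(default_factory=dict)
    planted_hubs: dict[str, tuple[float, frozenset[str]]] = field(default_factory=dict)
    planted_dependency_set: tuple[frozenset[str], float] = (frozenset(), 0.0)
    seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.planted_modules)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if self.planted_modules[a][0] & self.planted_modules[b][0]:
                    raise ValueError(f"planted modules {a!r} and {b!r} overlap")
        for hub in self.planted_hubs:
            homes = [m for m, (genes, _, _) in self.planted_modules.items() if hub in genes]
            if len(homes) != 1:
                raise ValueError(f"hub {hub!r} must belong to exactly one planted module")

    def module_of(self, gene: str) -> str | None:
        for name, (genes, _, _) in self.planted_modules.items():
            if gene in genes:
                return name
        return None
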