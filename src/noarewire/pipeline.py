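"""Configuration and end-to-end orchestration.

``run_pipeline`` chains stratification -> preprocessing -> differential
expression -> differential coexpression -> interactome mapping -> hub
identification, writes every result table as TSV plus a JSON run
manifest, and is deterministic for fixed (inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from noarewire import __version__, de as de_mod, diffcoex, io_formats, preprocess, rewiring
from noarewire.iotypes import ExpressionMatrix, GenomeModel
from noarewire.stress import (
    StressThresholds,
    assign_stress_groups,
    burden_table,
    derive_stress_thresholds,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated pipeline configuration with every tunable threshold."""

    segments: str
    counts: str
    meta: str
    ppi: str
    out_dir: str
    run_label: str = "run"
    dependency: str | None = None
    genome_chromosomes: dict[str, int] = field(default_factory=dict)
    burden_window: tuple[float, float] = (-0.2, 0.2)
    stress_thresholds: tuple[float, float] | str = "derive"
    min_group: int = 20
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    edge_score_cutoff: float = 0.156
    hub_fc_min: float = 0.5
    hub_q_max: float = 0.05
    min_rewiring: int = 3
    min_module_size: int = 30
    min_connected: int = 5
    module_p_max: float = 0.05
    n_perm: int = 1000
    beta: int | None = 2
    cut_height_quantile: float = 0.99
    seed: int = 0


_REQUIRED = ("segments", "counts", "meta", "ppi", "out_dir")

_DOMAINS = {
    "min_group": lambda v: v >= 0,
    "edge_score_cutoff": lambda v: 0 <= v <= 1,
    "hub_fc_min": lambda v: v >= 0,
    "hub_q_max": lambda v: 0 < v <= 1,
    "min_rewiring": lambda v: v >= 0,
    "min_module_size": lambda v: v >= 2,
    "min_connected": lambda v: v >= 1,
    "module_p_max": lambda v: 0 < v <= 1,
    "n_perm": lambda v: v >= 1,
    "cut_height_quantile": lambda v: 0 < v <= 1,
}


def validate_config(raw: dict) -> RunConfig:
    """Normalize a raw config mapping: fill defaults, reject unknown keys,
    check every threshold against its documented domain."""
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    missing = [k for k in _REQUIRED if not raw.get(k)]
    if missing:
        raise ConfigError(f"missing required key(s): {missing}")
    cfg = RunConfig(**raw)
    for key, ok in _DOMAINS.items():
        val = getattr(cfg, key)
        if not ok(val):
            raise ConfigError(f"config value {key}={val!r} outside its valid domain")
    lo, hi = cfg.burden_window
    if not (lo < 0 < hi):
        raise ConfigError(f"burden_window must straddle 0, got {cfg.burden_window}")
    if cfg.stress_thresholds != "derive":
        low_cut, high_cut = cfg.stress_thresholds
        if not (0 <= low_cut <= high_cut):
            raise ConfigError(f"stress_thresholds out of order: {cfg.stress_thresholds}")
        cfg.stress_thresholds = (float(low_cut), float(high_cut))
    if cfg.beta is not None and cfg.beta < 1:
        raise ConfigError("beta must be >= 1")
    return cfg


def _genome_from_config(cfg: RunConfig) -> GenomeModel:
    if cfg.genome_chromosomes:
        names = tuple(cfg.genome_chromosomes)
        lengths = tuple(int(v) for v in cfg.genome_chromosomes.values())
        return GenomeModel(names, lengths)
    return GenomeModel.toy(n_chromosomes=4, chromosome_length=50_000_000)


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write all result tables.

    Returns a bundle with the in-memory results; writes burden, DE,
    module, module-test, hub and ranking tables plus ``manifest.json``
    under ``cfg.out_dir``. Raises :class:`StageError` naming the failing
    stage; a ``FAILED_STAGE`` marker file flags partial results.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED_STAGE"
    stage = "setup"
    try:
        genome = _genome_from_config(cfg)
        stage = "stratification"
        profiles = io_formats.read_segment_table(cfg.segments, genome)
        burdens = burden_table(profiles, genome, cfg.burden_window)
        if cfg.stress_thresholds == "derive":
            thresholds = derive_stress_thresholds(burdens["burden"])
        else:
            thresholds = StressThresholds(*cfg.stress_thresholds)
        grouping = assign_stress_groups(
            burdens["burden"], thresholds, min_group=cfg.min_group
        )
        burdens["label"] = grouping.labels
        burdens.to_csv(out / "burden.tsv", sep="\t")
        if not grouping.included:
            raise StageError(
                "stratification",
                f"cohort excluded: {len(grouping.low_samples)} low / "
                f"{len(grouping.high_samples)} high samples (min {cfg.min_group})",
            )

        stage = "preprocessing"
        counts = io_formats.read_count_matrix(cfg.counts)
        meta = io_formats.read_sample_meta(cfg.meta)
        report = preprocess.filter_genes(counts)
        kept = counts.values.loc[report.kept]
        counts_f = ExpressionMatrix(values=kept, value_kind="raw")
        norm = preprocess.normalize(counts_f)
        expr = (
            preprocess.correct_covariates(norm, meta, cfg.covariates)
            if cfg.covariates else norm
        )
        io_formats.write_expression_matrix(norm, out / "normalized.tsv")

        stage = "differential_expression"
        de_results = de_mod.differential_expression(
            expr, grouping, meta, covariate_names=[]
        )
        de_results.to_csv(out / "de.tsv", sep="\t")

        stage = "diffcoex"
        params = diffcoex.DiffCoExParams(
            beta=cfg.beta,
            min_module_size=cfg.min_module_size,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            cut_height_quantile=cfg.cut_height_quantile,
        )
        modules, tests, beta = diffcoex.run_diffcoex(expr, grouping, params)
        modules.rename("module").to_frame().assign(run=cfg.run_label).to_csv(
            out / "modules.tsv", sep="\t"
        )
        test_df = pd.DataFrame(
            [{"module": t.module, "size": t.size,
              "dispersion": t.dispersion, "p_value": t.p_value} for t in tests]
        )
        test_df.to_csv(out / "module_tests.tsv", sep="\t", index=False)

        stage = "rewiring"
        interactome = io_formats.read_interactome(cfg.ppi, cfg.edge_score_cutoff)
        significant = {t.module for t in tests if t.p_value < cfg.module_p_max}
        subgraphs = []
        for m in sorted(significant):
            genes = set(modules.index[modules == m])
            ms = rewiring.map_module_to_interactome(
                genes, interactome, module=m, min_connected=cfg.min_connected
            )
            if ms is not None:
                subgraphs.append(ms)
        hubs = rewiring.identify_noa_hubs(
            subgraphs, de_results, run=cfg.run_label,
            fc_min=cfg.hub_fc_min, q_max=cfg.hub_q_max,
            min_rewiring=cfg.min_rewiring,
        )
        rewiring.hub_table(hubs).to_csv(out / "hubs.tsv", sep="\t", index=False)
        ranking = rewiring.rank_modules_by_activation(
            modules, subgraphs, de_results, cfg.hub_fc_min, cfg.hub_q_max
        )
        ranking.to_csv(out / "module_ranking.tsv", sep="\t", index=False)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": {k: v for k, v in asdict(cfg).items()},
            "thresholds": {"low_cut": thresholds.low_cut, "high_cut": thresholds.high_cut},
            "beta": int(beta),
            "counts": {
                "samples_low": len(grouping.low_samples),
                "samples_high": len(grouping.high_samples),
                "genes_kept": len(report.kept),
                "modules_found": int((modules.max())) if len(modules) else 0,
                "modules_significant": len(significant),
                "modules_mapped": len(subgraphs),
                "hubs_found": len(hubs),
            },
            "input_checksums": {
                key: _checksum(getattr(cfg, key))
                for key in ("segments", "counts", "meta", "ppi")
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        if marker.exists():
            marker.unlink()
        return {
            "burdens": burdens,
            "thresholds": thresholds,
            "grouping": grouping,
            "filter_report": report,
            "expression": expr,
            "de": de_results,
            "modules": modules,
            "module_tests": tests,
            "beta": beta,
            "subgraphs": subgraphs,
            "hubs": hubs,
            "ranking": ranking,
            "manifest": manifest,
        }
    except StageError:
        marker.write_text(stage)
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        marker.write_text(stage)
        raise StageError(stage, str(exc)) from exc
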