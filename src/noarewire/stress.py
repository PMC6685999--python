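"""CNA-burden statistic and genomic-stress group assignment.

The burden of a sample is the fraction of the autosomal genome covered by
copy-number-altered segments,

    burden = (n_gain + n_loss) / n_autosome,

where a segment counts as altered when its segment mean (log2 tumour /
normal copy ratio) lies outside the open neutral window (-0.2, 0.2):
seg_mean >= 0.2 counts its length into n_gain, seg_mean <= -0.2 into
n_loss. Samples are stratified into low stress (burden <= first-quartile
cut) and high stress (burden > median cut); intermediate samples stay
unassigned, and a cohort enters the comparative analysis only when both
groups hold at least ``min_group`` samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from noarewire.iotypes import GenomeModel, SegmentProfile

logger = logging.getLogger(__name__)

NEUTRAL_WINDOW = (-0.2, 0.2)


@dataclass(frozen=True)
class BurdenResult:
    sample_id: str
    n_gain: int  # base pairs in gain segments
    n_loss: int  # base pairs in loss segments
    burden: float

    def __post_init__(self) -> None:
        if self.burden < 0:
            raise ValueError("burden cannot be negative")


@dataclass(frozen=True)
class StressThresholds:
    """Burden cuts: low <= low_cut < burden <= high_cut is unassigned."""

    low_cut: float
    high_cut: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_cut <= self.high_cut):
            raise ValueError(f"need 0 <= low_cut <= high_cut, got {self}")


@dataclass
class StressGrouping:
    """Per-sample stress labels plus the cohort inclusion flag."""

    labels: pd.Series  # sample id -> {low, high, unassigned}
    thresholds: StressThresholds
    min_group: int = 20

    @property
    def low_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "low"])

    @property
    def high_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == "high"])

    @property
    def included(self) -> bool:
        return (
            len(self.low_samples) >= self.min_group
            and len(self.high_samples) >= self.min_group
        )


def compute_cna_burden(
    profile: SegmentProfile,
    genome: GenomeModel,
    window: tuple[float, float] = NEUTRAL_WINDOW,
) -> BurdenResult:
    """Fraction of the autosomal genome covered by altered segments.

    Segments with ``window[0] < seg_mean < window[1]`` are copy-neutral and
    ignored; the boundary values themselves count as altered. Overlapping
    altered segments are summed as given (no merging); a diagnostic warns
    if the summed altered length exceeds the genome size.
    """
    if genome.n_autosome <= 0:
        raise ValueError("empty genome")
    known = set(genome.chromosome_names)
    seg = profile.segments
    if len(seg) == 0:
        logger.warning("sample %s has zero segments; burden set to 0", profile.sample_id)
        return BurdenResult(profile.sample_id, 0, 0, 0.0)
    unknown = set(seg["chromosome"]) - known
    if unknown:
        raise ValueError(f"sample {profile.sample_id}: non-autosomal segments on {sorted(unknown)}")
    sm = seg["seg_mean"].to_numpy(float)
    length = (seg["end"] - seg["start"] + 1).to_numpy(np.int64)
    gain = sm >= window[1]
    loss = sm <= window[0]
    n_gain = int(length[gain].sum())
    n_loss = int(length[loss].sum())
    if n_gain + n_loss > genome.n_autosome:
        logger.warning(
            "sample %s: summed altered length %d exceeds autosome length %d "
            "(overlapping segments?)",
            profile.sample_id, n_gain + n_loss, genome.n_autosome,
        )
    burden = (n_gain + n_loss) / genome.n_autosome
    return BurdenResult(profile.sample_id, n_gain, n_loss, burden)


def burden_table(
    profiles: list[SegmentProfile], genome: GenomeModel,
    window: tuple[float, float] = NEUTRAL_WINDOW,
) -> pd.DataFrame:
    """Burden per sample as a DataFrame indexed by sample id."""
    rows = [compute_cna_burden(p, genome, window) for p in profiles]
    return pd.DataFrame(
        {"n_gain": [r.n_gain for r in rows],
         "n_loss": [r.n_loss for r in rows],
         "burden": [r.burden for r in rows]},
        index=pd.Index([r.sample_id for r in rows], name="sample"),
    )


def derive_stress_thresholds(burdens) -> StressThresholds:
    """Low/high cuts at the first quartile and median of pooled burdens.

    Percentiles use linear interpolation between order statistics so the
    thresholds are exactly reproducible.
    """
    arr = np.asarray(list(burdens), dtype=float)
    if len(np.unique(arr)) < 4:
        raise ValueError("need at least 4 distinct burden values to derive thresholds")
    low_cut = float(np.percentile(arr, 25, method="linear"))
    high_cut = float(np.percentile(arr, 50, method="linear"))
    if low_cut == high_cut:
        raise ValueError(
            f"degenerate burden distribution: Q1 == median == {low_cut}; "
            "groups would collapse"
        )
    return StressThresholds(low_cut=low_cut, high_cut=high_cut)


def assign_stress_groups(
    burdens: pd.Series | dict,
    thresholds: StressThresholds,
    min_group: int = 20,
) -> StressGrouping:
    """Label samples low / high / unassigned against fixed thresholds.

    low: burden <= low_cut; high: burden > high_cut; otherwise unassigned.
    """
    s = pd.Series(burdens, dtype=float)
    labels = pd.Series("unassigned", index=s.index, dtype=object)
    labels[s <= thresholds.low_cut] = "low"
    labels[s > thresholds.high_cut] = "high"
    grouping = StressGrouping(labels=labels, thresholds=thresholds, min_group=min_group)
    if not grouping.included:
        logger.warning(
            "cohort excluded: %d low / %d high samples (min %d per group)",
            len(grouping.low_samples), len(grouping.high_samples), min_group,
        )
    return grouping
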