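"""Allelic-status calling from tumor variant-allele fractions.

The decision rule is the >10% imbalance criterion: with delta =
tumor_vaf - reference_vaf, a tumor is called LOSS_WT when delta exceeds
the threshold (variant allele enriched, wild-type lost), LOSS_VARIANT when
delta falls below minus the threshold, and BALANCE otherwise. The
inequality is strict, so a delta of exactly 0.10 is balance.

Pyrosequencing samples are aggregated as the mean of replicates; a
two-sample t-test against non-carrier control replicates is available as
QC metadata but never overrides the threshold rule.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy import stats

from .types import (
    AllelicStatusCall,
    Method,
    QCFlag,
    ReplicateComparison,
    SecondHitEvent,
    TumorSample,
)

DEFAULT_THRESHOLD = 0.10
DEFAULT_MIN_DEPTH = 50
DEFAULT_LOW_CELLULARITY_CUTOFF = 0.30


def aggregate_replicates(replicate_vafs: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation of replicate VAFs (sd=0 for n=1)."""
    if len(replicate_vafs) == 0:
        raise ValueError("at least one replicate is required")
    arr = np.asarray(replicate_vafs, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def replicate_t_test(
    sample_vafs: Sequence[float], control_vafs: Sequence[float]
) -> ReplicateComparison:
    """Two-sample t-test of carrier-tumor replicates vs a non-carrier control."""
    if len(sample_vafs) < 2 or len(control_vafs) < 2:
        raise ValueError("t-test needs at least two replicates per group")
    mean, sd = aggregate_replicates(sample_vafs)
    t, p = stats.ttest_ind(sample_vafs, control_vafs)
    return ReplicateComparison(
        mean_vaf=mean,
        sd_vaf=sd,
        t_statistic=float(t),
        p_value=float(p),
        n_sample=len(sample_vafs),
        n_control=len(control_vafs),
    )


def call_allelic_status(
    tumor_vaf: float,
    reference_vaf: float = 0.5,
    threshold: float = DEFAULT_THRESHOLD,
    sample_id: str = "",
    qc_flags: set[QCFlag] | None = None,
) -> AllelicStatusCall:
    """Apply the strict >threshold imbalance rule to an aggregated VAF."""
    for name, v in (("tumor_vaf", tumor_vaf), ("reference_vaf", reference_vaf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    if not 0.0 < threshold < 0.5:
        raise ValueError(f"threshold={threshold} outside (0, 0.5)")
    delta = tumor_vaf - reference_vaf
    if delta > threshold:
        status = SecondHitEvent.LOSS_WT
    elif delta < -threshold:
        status = SecondHitEvent.LOSS_VARIANT
    else:
        status = SecondHitEvent.BALANCE
    return AllelicStatusCall(
        sample_id=sample_id,
        status=status,
        tumor_vaf=tumor_vaf,
        reference_vaf=reference_vaf,
        delta=delta,
        qc_flags=set(qc_flags or ()),
    )


def call_from_reads(
    alt_depth: int,
    total_depth: int,
    reference_vaf: float = 0.5,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    sample_id: str = "",
    qc_flags: set[QCFlag] | None = None,
) -> AllelicStatusCall:
    """Call from NGS allele depths; flags LOW_DEPTH below ``min_depth``."""
    if total_depth <= 0:
        raise ValueError("total_depth must be >= 1")
    if not 0 <= alt_depth <= total_depth:
        raise ValueError("alt_depth must be in [0, total_depth]")
    flags = set(qc_flags or ())
    if total_depth < min_depth:
        flags.add(QCFlag.LOW_DEPTH)
    return call_allelic_status(
        alt_depth / total_depth, reference_vaf, threshold, sample_id, flags
    )


def call_sample(
    sample: TumorSample,
    threshold: float = DEFAULT_THRESHOLD,
    min_depth: int = DEFAULT_MIN_DEPTH,
    low_cellularity_cutoff: float = DEFAULT_LOW_CELLULARITY_CUTOFF,
) -> AllelicStatusCall:
    """Route a sample through the appropriate measurement path and call it.

    The reference is the sample's germline VAF when present, else the
    heterozygous expectation 0.5 with a NO_GERMLINE_REFERENCE flag. Tumors
    with cellularity below the cutoff are flagged LOW_CELLULARITY: dilution
    by normal cells can mask a real imbalance there.
    """
    flags: set[QCFlag] = set()
    if sample.germline_vaf is not None:
        reference = sample.germline_vaf
    else:
        reference = 0.5
        flags.add(QCFlag.NO_GERMLINE_REFERENCE)
    if sample.cellularity is not None and sample.cellularity < low_cellularity_cutoff:
        flags.add(QCFlag.LOW_CELLULARITY)
    if sample.method is Method.PYRO:
        mean, _ = aggregate_replicates(sample.replicate_vafs)
        return call_allelic_status(mean, reference, threshold, sample.sample_id, flags)
    return call_from_reads(
        sample.alt_depth,
        sample.total_depth,
        reference,
        threshold,
        min_depth,
        sample.sample_id,
        flags,
    )


def call_cohort(cohort, **kwargs) -> list[AllelicStatusCall]:
    """Call every sample in a cohort (keyword arguments as in call_sample)."""
    return [call_sample(s, **kwargs) for s in cohort.samples]
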