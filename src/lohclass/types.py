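"""Domain types for tumor LOH analysis of germline BRCA1 variant carriers.

The central objects are a germline variant with its (prior) classification,
a tumor sample measured either by pyrosequencing (replicate variant-allele
fractions) or by amplicon NGS (alt/total read depths), and the per-tumor
allelic-status call: allelic balance, loss of the wild-type allele (the
classic second hit), or loss of the variant allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class SecondHitEvent(str, enum.Enum):
    """Latent somatic event at the locus in a carrier's tumor."""

    BALANCE = "BALANCE"
    LOSS_WT = "LOSS_WT"
    LOSS_VARIANT = "LOSS_VARIANT"


class CopyModel(str, enum.Enum):
    """Copy-number state of an LOH event.

    DELETION: the lost allele's copy is physically absent in tumor cells
    (one copy total). CN_LOH: the retained allele is duplicated, so total
    copy number stays at two (copy-neutral LOH).
    """

    DELETION = "DELETION"
    CN_LOH = "CN_LOH"


class VariantClass(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"


#: Classes pooled as the "benign group" in cohort summaries (B + LB).
BENIGN_GROUP = frozenset({VariantClass.BENIGN, VariantClass.LIKELY_BENIGN})
#: Classes pooled as the "pathogenic group".
PATHOGENIC_GROUP = frozenset({VariantClass.PATHOGENIC, VariantClass.LIKELY_PATHOGENIC})


class Effect(str, enum.Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    SYNONYMOUS = "SYNONYMOUS"
    SPLICE = "SPLICE"
    DUPLICATION = "DUPLICATION"


#: Protein effects grouped as "truncating" when contrasting with missense.
TRUNCATING_EFFECTS = frozenset(
    {Effect.NONSENSE, Effect.FRAMESHIFT, Effect.DUPLICATION, Effect.SPLICE}
)


class Tissue(str, enum.Enum):
    BREAST = "BREAST"
    OVARY = "OVARY"


class Method(str, enum.Enum):
    PYRO = "PYRO"
    NGS = "NGS"


class QCFlag(str, enum.Enum):
    LOW_CELLULARITY = "LOW_CELLULARITY"
    NO_GERMLINE_REFERENCE = "NO_GERMLINE_REFERENCE"
    LOW_DEPTH = "LOW_DEPTH"


@dataclass(frozen=True)
class GermlineVariant:
    variant_id: str
    classification: VariantClass
    effect: Effect
    hgvs_c: str = ""
    hgvs_p: str = ""


@dataclass
class TumorSample:
    """One tumor's measurement of the germline variant's allele fraction.

    Exactly one measurement channel must be present: ``replicate_vafs``
    (pyrosequencing) or ``alt_depth``/``total_depth`` (NGS).
    """

    sample_id: str
    variant_id: str
    tissue: Tissue
    method: Method
    replicate_vafs: list[float] | None = None
    alt_depth: int | None = None
    total_depth: int | None = None
    cellularity: float | None = None
    germline_vaf: float | None = None
    truth_event: SecondHitEvent | None = None

    def __post_init__(self) -> None:
        has_pyro = self.replicate_vafs is not None
        has_ngs = self.alt_depth is not None and self.total_depth is not None
        if has_pyro == has_ngs:
            raise ValueError(
                f"sample {self.sample_id!r}: exactly one of replicate_vafs "
                "or (alt_depth, total_depth) must be provided"
            )
        if has_pyro:
            if not self.replicate_vafs:
                raise ValueError(f"sample {self.sample_id!r}: empty replicate list")
            bad = [v for v in self.replicate_vafs if not 0.0 <= v <= 1.0]
            if bad:
                raise ValueError(f"sample {self.sample_id!r}: VAFs outside [0,1]: {bad}")
        else:
            if self.total_depth <= 0:
                raise ValueError(f"sample {self.sample_id!r}: total_depth must be >= 1")
            if not 0 <= self.alt_depth <= self.total_depth:
                raise ValueError(f"sample {self.sample_id!r}: alt_depth > total_depth")
        for name in ("cellularity", "germline_vaf"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"sample {self.sample_id!r}: {name}={v} outside [0,1]")

    @property
    def vaf(self) -> float:
        """Point estimate of the tumor VAF (replicate mean or alt/total)."""
        if self.replicate_vafs is not None:
            return float(sum(self.replicate_vafs) / len(self.replicate_vafs))
        return self.alt_depth / self.total_depth


@dataclass
class VariantCohort:
    """All tumor samples grouped by the germline variant they carry."""

    variants: list[GermlineVariant]
    samples: list[TumorSample]

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_id in cohort")
        self._by_id = {v.variant_id: v for v in self.variants}
        missing = {s.variant_id for s in self.samples} - set(ids)
        if missing:
            raise ValueError(f"samples reference unknown variants: {sorted(missing)}")

    def variant(self, variant_id: str) -> GermlineVariant:
        return self._by_id[variant_id]

    def samples_for(self, variant_id: str) -> list[TumorSample]:
        return [s for s in self.samples if s.variant_id == variant_id]

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class AllelicStatusCall:
    """Per-tumor allelic-status call from the >threshold imbalance rule.

    ``delta`` is the signed imbalance tumor_vaf - reference_vaf: positive
    delta (variant enriched) means the wild-type allele was lost.
    """

    sample_id: str
    status: SecondHitEvent
    tumor_vaf: float
    reference_vaf: float
    delta: float
    qc_flags: set[QCFlag] = field(default_factory=set)


@dataclass(frozen=True)
class ReplicateComparison:
    """Two-sample t-test of replicate VAFs against a non-carrier control."""

    mean_vaf: float
    sd_vaf: float
    t_statistic: float
    p_value: float
    n_sample: int
    n_control: int
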