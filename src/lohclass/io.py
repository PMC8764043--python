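"""Readers and writers for the tabular sample/call formats.

The sample table is tab-separated with a single header row; lines starting
with ``#`` are comments. Required columns: sample_id, variant_id,
variant_class, effect, tissue, method. Pyrosequencing rows carry rep1..repN
fraction columns; NGS rows carry integer alt_depth/total_depth. Optional:
cellularity, germline_vaf, truth_event, hgvs_c, hgvs_p.

Fraction-valued cells greater than 1 and at most 100 are interpreted as
percentages and divided by 100 (logged), since published VAF and
cellularity tables conventionally print percent.
"""

from __future__ import annotations

import logging
import math
import re

import pandas as pd

from .types import (
    AllelicStatusCall,
    Effect,
    GermlineVariant,
    Method,
    SecondHitEvent,
    Tissue,
    TumorSample,
    VariantCohort,
    VariantClass,
)

logger = logging.getLogger("lohclass")

REQUIRED_COLUMNS = ["sample_id", "variant_id", "variant_class", "effect", "tissue", "method"]
_REP_RE = re.compile(r"^rep(\d+)$")


class SampleTableError(ValueError):
    """Malformed sample table: names the offending row and column."""


def _as_fraction(value: float, row: int, column: str) -> float:
    """Coerce to [0,1]; values in (1, 100] are treated as percent."""
    if 0.0 <= value <= 1.0:
        return float(value)
    if 1.0 < value <= 100.0:
        logger.info("row %d, column %s: interpreting %g as a percentage", row, column, value)
        return float(value) / 100.0
    raise SampleTableError(f"row {row}, column {column}: value {value} outside [0,1] (or percent)")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def read_sample_table(path) -> VariantCohort:
    """Read a tab-separated sample table into a typed cohort."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "variant_id": str})
    if df.empty:
        raise SampleTableError(f"{path}: no data rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SampleTableError(f"{path}: missing required columns {missing}")
    rep_cols = sorted(
        (c for c in df.columns if _REP_RE.match(c)),
        key=lambda c: int(_REP_RE.match(c).group(1)),
    )
    variants: dict[str, GermlineVariant] = {}
    samples: list[TumorSample] = []
    for idx, rec in df.iterrows():
        row = idx + 2  # 1-based, after header
        try:
            method = Method(rec["method"])
            tissue = Tissue(rec["tissue"])
            classification = VariantClass(rec["variant_class"])
            effect = Effect(rec["effect"])
        except ValueError as exc:
            raise SampleTableError(f"row {row}: {exc}") from exc
        vid = rec["variant_id"]
        variant = GermlineVariant(
            variant_id=vid,
            classification=classification,
            effect=effect,
            hgvs_c=str(rec.get("hgvs_c") or ""),
            hgvs_p=str(rec.get("hgvs_p", "") or ""),
        )
        if vid in variants and variants[vid] != variant:
            raise SampleTableError(f"row {row}: conflicting annotation for variant {vid!r}")
        variants.setdefault(vid, variant)

        kwargs: dict = {}
        if method is Method.PYRO:
            reps = []
            for c in rep_cols:
                v = rec.get(c)
                if not _is_missing(v):
                    reps.append(_as_fraction(float(v), row, c))
            if not reps:
                raise SampleTableError(f"row {row}: PYRO sample without rep1..repN values")
            kwargs["replicate_vafs"] = reps
        else:
            for c in ("alt_depth", "total_depth"):
                if c not in df.columns or _is_missing(rec.get(c)):
                    raise SampleTableError(f"row {row}, column {c}: required for NGS samples")
            kwargs["alt_depth"] = int(rec["alt_depth"])
            kwargs["total_depth"] = int(rec["total_depth"])
        for c in ("cellularity", "germline_vaf"):
            v = rec.get(c)
            if not _is_missing(v):
                kwargs[c] = _as_fraction(float(v), row, c)
        te = rec.get("truth_event")
        if not _is_missing(te):
            kwargs["truth_event"] = SecondHitEvent(te)
        try:
            samples.append(
                TumorSample(
                    sample_id=str(rec["sample_id"]),
                    variant_id=vid,
                    tissue=tissue,
                    method=method,
                    **kwargs,
                )
            )
        except ValueError as exc:
            raise SampleTableError(f"row {row}: {exc}") from exc
    return VariantCohort(variants=list(variants.values()), samples=samples)


def cohort_to_frame(cohort: VariantCohort) -> pd.DataFrame:
    """Flatten a cohort to the sample-table layout (one row per sample)."""
    n_rep = max((len(s.replicate_vafs) for s in cohort.samples if s.replicate_vafs), default=0)
    rows = []
    for s in cohort.samples:
        v = cohort.variant(s.variant_id)
        rec = {
            "sample_id": s.sample_id,
            "variant_id": s.variant_id,
            "variant_class": v.classification.value,
            "effect": v.effect.value,
            "tissue": s.tissue.value,
            "method": s.method.value,
            "cellularity": s.cellularity,
            "germline_vaf": s.germline_vaf,
            "truth_event": s.truth_event.value if s.truth_event else None,
        }
        for i in range(n_rep):
            rec[f"rep{i + 1}"] = (
                s.replicate_vafs[i] if s.replicate_vafs and i < len(s.replicate_vafs) else None
            )
        rec["alt_depth"] = s.alt_depth
        rec["total_depth"] = s.total_depth
        rows.append(rec)
    return pd.DataFrame(rows)


def write_sample_table(cohort: VariantCohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: list[AllelicStatusCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "status": [c.status.value for c in calls],
            "tumor_vaf": [c.tumor_vaf for c in calls],
            "reference_vaf": [c.reference_vaf for c in calls],
            "delta": [c.delta for c in calls],
            "qc_flags": [",".join(sorted(f.value for f in c.qc_flags)) for c in calls],
        }
    )


class VCFExtractionError(ValueError):
    pass


def extract_vaf_from_vcf(
    path, sample_name: str, chrom: str, pos: int, ref: str, alt: str
) -> tuple[int, int]:
    """Extract (alt_depth, total_depth) for one sample at one variant locus.

    Uses the per-sample AD (allelic depths) FORMAT field; multi-allelic
    records are resolved to the requested alternate allele. total_depth is
    the sum of the reference and requested-alternate depths.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_name not in vcf.samples:
        raise VCFExtractionError(f"sample {sample_name!r} not in {path}")
    sample_idx = vcf.samples.index(sample_name)
    try:
        # linear scan: plain-text VCFs carry no index for region queries
        for rec in vcf:
            if rec.CHROM != chrom or rec.POS != pos or rec.REF != ref:
                continue
            if alt not in rec.ALT:
                continue
            ad = rec.format("AD")
            if ad is None:
                raise VCFExtractionError(f"{chrom}:{pos}: no AD field for sample depths")
            depths = ad[sample_idx]
            alt_idx = rec.ALT.index(alt) + 1  # AD[0] is the reference depth
            ref_depth = int(depths[0])
            alt_depth = int(depths[alt_idx])
            if ref_depth < 0 or alt_depth < 0:
                raise VCFExtractionError(f"{chrom}:{pos}: missing AD values")
            return alt_depth, ref_depth + alt_depth
    finally:
        vcf.close()
    raise VCFExtractionError(f"variant {chrom}:{pos} {ref}>{alt} not found in {path}")
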