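"""Cohort-level aggregation of allelic-status calls.

Summaries mirror the layout of published LOH cohort tables: one row per
variant with counts of balance / loss-of-variant / loss-of-WT calls, the
percentage of imbalanced tumors, and the percentage of imbalanced tumors
in which the wild-type allele was the one lost. Class totals pool
pathogenic vs benign+likely-benign vs VUS variants. Treating a loss-of-WT
call as a positive prediction of pathogenicity yields a per-tumor
sensitivity/specificity, and a 2x2 chi-squared test measures the
class association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .types import (
    AllelicStatusCall,
    BENIGN_GROUP,
    Effect,
    GermlineVariant,
    PATHOGENIC_GROUP,
    SecondHitEvent,
    Tissue,
    TRUNCATING_EFFECTS,
    VariantClass,
)


def render_pct_int(pct: float | None) -> str:
    """Integer percent rendering, rounding half away from zero ('-' if undefined)."""
    if pct is None:
        return "-"
    return str(int(math.floor(pct + 0.5)))


def render_pct_trunc1(pct: float | None) -> str:
    """One-decimal percent rendering by truncation (65.45 -> '65.4')."""
    if pct is None:
        return "-"
    return f"{math.floor(pct * 10) / 10:.1f}"


@dataclass
class VariantSummaryRow:
    variant_id: str
    classification: VariantClass
    effect: Effect
    n_balance: int
    n_loss_variant: int
    n_loss_wt: int

    @property
    def n_total(self) -> int:
        return self.n_balance + self.n_loss_variant + self.n_loss_wt

    @property
    def n_imbalanced(self) -> int:
        return self.n_loss_variant + self.n_loss_wt

    @property
    def pct_imbalance(self) -> float | None:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_imbalanced / self.n_total

    @property
    def pct_loss_wt_of_imbalanced(self) -> float | None:
        if self.n_imbalanced == 0:
            return None
        return 100.0 * self.n_loss_wt / self.n_imbalanced


@dataclass(frozen=True)
class PredictorPerformance:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


def summarize_by_variant(
    calls: list[AllelicStatusCall],
    variants: list[GermlineVariant],
    sample_variant_ids: dict[str, str],
    sample_tissues: dict[str, Tissue] | None = None,
    tissue: Tissue | None = None,
) -> list[VariantSummaryRow]:
    """One summary row per variant from per-sample calls.

    ``sample_variant_ids`` maps sample_id -> variant_id;
    ``sample_tissues`` (needed only when filtering) maps sample_id -> tissue.
    """
    by_id = {v.variant_id: v for v in variants}
    counts: dict[str, dict[SecondHitEvent, int]] = {
        v.variant_id: {e: 0 for e in SecondHitEvent} for v in variants
    }
    for call in calls:
        vid = sample_variant_ids.get(call.sample_id)
        if vid is None or vid not in by_id:
            raise ValueError(f"call for unknown sample/variant: {call.sample_id!r}")
        if tissue is not None:
            if sample_tissues is None:
                raise ValueError("tissue filter requires sample_tissues")
            if sample_tissues[call.sample_id] is not tissue:
                continue
        counts[vid][call.status] += 1
    rows = []
    for v in variants:
        c = counts[v.variant_id]
        rows.append(
            VariantSummaryRow(
                variant_id=v.variant_id,
                classification=v.classification,
                effect=v.effect,
                n_balance=c[SecondHitEvent.BALANCE],
                n_loss_variant=c[SecondHitEvent.LOSS_VARIANT],
                n_loss_wt=c[SecondHitEvent.LOSS_WT],
            )
        )
    return rows


def rows_from_counts(df: pd.DataFrame, tissue: Tissue | None = None) -> list[VariantSummaryRow]:
    """Summary rows from a per-variant counts table (e.g. the packaged cohort)."""
    sub = df if tissue is None else df[df["tissue"] == tissue.value]
    grouped = sub.groupby(["variant_id", "classification", "effect"], sort=False)[
        ["n_balance", "n_loss_variant", "n_loss_wt"]
    ].sum()
    return [
        VariantSummaryRow(
            variant_id=vid,
            classification=VariantClass(cls),
            effect=Effect(eff),
            n_balance=int(rec["n_balance"]),
            n_loss_variant=int(rec["n_loss_variant"]),
            n_loss_wt=int(rec["n_loss_wt"]),
        )
        for (vid, cls, eff), rec in grouped.iterrows()
    ]


DEFAULT_CLASS_GROUPING: dict[str, frozenset[VariantClass]] = {
    "pathogenic": frozenset({VariantClass.PATHOGENIC, VariantClass.LIKELY_PATHOGENIC}),
    "benign": BENIGN_GROUP,
    "vus": frozenset({VariantClass.VUS}),
}


def summarize_by_class(
    rows: list[VariantSummaryRow],
    class_grouping: dict[str, frozenset[VariantClass]] | None = None,
) -> dict[str, VariantSummaryRow]:
    """Pool variant rows into class-group totals (counts summed, percents recomputed)."""
    if not rows:
        raise ValueError("no rows to summarize")
    grouping = class_grouping or DEFAULT_CLASS_GROUPING
    out: dict[str, VariantSummaryRow] = {}
    for label, classes in grouping.items():
        members = [r for r in rows if r.classification in classes]
        out[label] = VariantSummaryRow(
            variant_id=f"total_{label}",
            classification=sorted(classes, key=lambda c: c.value)[0],
            effect=Effect.MISSENSE,
            n_balance=sum(r.n_balance for r in members),
            n_loss_variant=sum(r.n_loss_variant for r in members),
            n_loss_wt=sum(r.n_loss_wt for r in members),
        )
    return out


def predictor_performance(
    status_class_pairs: list[tuple[SecondHitEvent, VariantClass]],
) -> PredictorPerformance:
    """Loss-of-WT as a per-tumor predictor of variant pathogenicity.

    Each tumor is one trial; VUS samples are excluded. A LOSS_WT call on a
    pathogenic-group tumor is a true positive; on a benign-group tumor a
    false positive.
    """
    tp = fn = tn = fp = 0
    for status, cls in status_class_pairs:
        if cls is VariantClass.VUS:
            continue
        positive = status is SecondHitEvent.LOSS_WT
        if cls in PATHOGENIC_GROUP:
            tp += positive
            fn += not positive
        elif cls in BENIGN_GROUP:
            fp += positive
            tn += not positive
        else:  # pragma: no cover - enum is exhaustive
            raise ValueError(f"unclassifiable sample class {cls}")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("need at least one pathogenic and one benign-group sample")
    return PredictorPerformance(tp=tp, fn=fn, tn=tn, fp=fp)


def performance_from_counts(
    df: pd.DataFrame, tissue: Tissue | None = None
) -> PredictorPerformance:
    """Predictor performance straight from a per-variant counts table."""
    pairs: list[tuple[SecondHitEvent, VariantClass]] = []
    sub = df if tissue is None else df[df["tissue"] == tissue.value]
    for _, rec in sub.iterrows():
        cls = VariantClass(rec["classification"])
        pairs.extend([(SecondHitEvent.LOSS_WT, cls)] * int(rec["n_loss_wt"]))
        pairs.extend([(SecondHitEvent.BALANCE, cls)] * int(rec["n_balance"]))
        pairs.extend([(SecondHitEvent.LOSS_VARIANT, cls)] * int(rec["n_loss_variant"]))
    return predictor_performance(pairs)


def class_association_test(
    pathogenic_counts: tuple[int, int],
    benign_counts: tuple[int, int],
    correction: bool = False,
) -> tuple[float, float]:
    """2x2 chi-squared test of loss-of-WT enrichment between classes.

    Rows are (loss_wt, other) counts; Yates continuity correction is off by
    default. Returns (chi2, p).
    """
    table = [list(pathogenic_counts), list(benign_counts)]
    if any(c < 0 for row in table for c in row):
        raise ValueError("counts must be non-negative")
    if any(sum(row) == 0 for row in table) or any(
        table[0][j] + table[1][j] == 0 for j in range(2)
    ):
        raise ValueError("chi-squared undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def effect_stratified_summary(
    rows: list[VariantSummaryRow],
    truncating_effects: frozenset[Effect] = TRUNCATING_EFFECTS,
    classes: frozenset[VariantClass] = frozenset({VariantClass.PATHOGENIC}),
) -> dict:
    """Loss-of-WT rates among pathogenic tumors, missense vs truncating.

    The truncating group is a parameter because published per-effect splits
    can pool effects in more than one defensible way. Returns the two
    percentages (None when a group is empty) and, when both groups are
    populated, the 2x2 chi-squared comparison.
    """
    missense = [r for r in rows if r.classification in classes and r.effect is Effect.MISSENSE]
    truncating = [
        r for r in rows if r.classification in classes and r.effect in truncating_effects
    ]

    def _rate(group):
        k = sum(r.n_loss_wt for r in group)
        n = sum(r.n_total for r in group)
        return (k, n, 100.0 * k / n if n else None)

    k_ms, n_ms, pct_ms = _rate(missense)
    k_tr, n_tr, pct_tr = _rate(truncating)
    result = {
        "missense": {"n_loss_wt": k_ms, "n_total": n_ms, "pct_loss_wt": pct_ms},
        "truncating": {"n_loss_wt": k_tr, "n_total": n_tr, "pct_loss_wt": pct_tr},
        "chi2": None,
        "p_value": None,
    }
    if n_ms and n_tr and 0 < k_ms + k_tr < n_ms + n_tr:
        chi2, p = class_association_test((k_tr, n_tr - k_tr), (k_ms, n_ms - k_ms))
        result["chi2"], result["p_value"] = chi2, p
    return result


def summary_to_frame(rows: list[VariantSummaryRow]) -> pd.DataFrame:
    """Tabular rendering with both full-precision and integer percent columns."""
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in rows],
            "classification": [r.classification.value for r in rows],
            "effect": [r.effect.value for r in rows],
            "n_balance": [r.n_balance for r in rows],
            "n_loss_variant": [r.n_loss_variant for r in rows],
            "n_loss_wt": [r.n_loss_wt for r in rows],
            "n_total": [r.n_total for r in rows],
            "pct_imbalance": [r.pct_imbalance for r in rows],
            "pct_loss_wt_of_imbalanced": [r.pct_loss_wt_of_imbalanced for r in rows],
            "pct_imbalance_int": [render_pct_int(r.pct_imbalance) for r in rows],
            "pct_loss_wt_int": [render_pct_int(r.pct_loss_wt_of_imbalanced) for r in rows],
        }
    )
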