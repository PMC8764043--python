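"""Binomial evidence from repeated loss-of-WT observations.

Across independent tumors carrying the same germline variant, the number
of tumors with loss of the wild-type allele is modeled as X ~ B(n, p),
where p is the class-conditional per-tumor loss-of-WT rate. Two one-sided
tails quantify the evidence:

* P(X >= k | p_benign): how surprising the observed recurrence would be
  for a benign variant (small -> exclude neutrality);
* P(X <= k | p_pathogenic): how surprising so few losses would be for a
  pathogenic variant (small -> exclude pathogenicity).

Tails are exact sums of the pmf, accumulated in log space so they remain
stable for n well beyond cohort sizes. This framework is deliberately not
a hypothesis test: it prioritizes variants for further evidence
collection, and never by itself assigns a class.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

# Default per-tumor loss-of-WT rates observed in the reference cohort.
# Combined breast+ovary: benign group 6/27, pathogenic 36/55. Breast-only
# alternatives are provided because published summaries quote both scopes.
P_BENIGN_COMBINED = 6 / 27
P_PATHOGENIC_COMBINED = 36 / 55
P_BENIGN_BREAST = 5 / 26
P_PATHOGENIC_BREAST = 32 / 51


def _validate(k: int, n: int, p: float) -> None:
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0,1]")


def _log_pmf_range(ks: np.ndarray, n: int, p: float) -> np.ndarray:
    if p == 0.0:
        return np.where(ks == 0, 0.0, -np.inf)
    if p == 1.0:
        return np.where(ks == n, 0.0, -np.inf)
    return (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * math.log(p)
        + (n - ks) * math.log1p(-p)
    )


def binomial_pmf(k: int, n: int, p: float) -> float:
    """P(X = k) for X ~ B(n, p): C(n,k) p^k (1-p)^(n-k), log-space stable."""
    _validate(k, n, p)
    return float(np.exp(_log_pmf_range(np.array([k]), n, p)[0]))


def tail_ge(k: int, n: int, p: float) -> float:
    """P(X >= k): exact upper-tail sum of the pmf."""
    _validate(k, n, p)
    if k == 0:
        return 1.0
    ks = np.arange(k, n + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf_range(ks, n, p)))))


def tail_le(k: int, n: int, p: float) -> float:
    """P(X <= k): exact lower-tail sum of the pmf."""
    _validate(k, n, p)
    if k == n:
        return 1.0
    ks = np.arange(0, k + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf_range(ks, n, p)))))


@dataclass(frozen=True)
class BinomialEvidence:
    """Two-scenario tail evidence for k loss-of-WT calls among n tumors."""

    n: int
    k: int
    p_benign: float
    p_pathogenic: float
    prob_ge_k_given_benign: float
    prob_le_k_given_pathogenic: float


def evidence(
    k: int,
    n: int,
    p_benign: float = P_BENIGN_COMBINED,
    p_pathogenic: float = P_PATHOGENIC_COMBINED,
) -> BinomialEvidence:
    """Evaluate both scenario tails for an observed (k of n) recurrence."""
    _validate(k, n, p_benign)
    _validate(k, n, p_pathogenic)
    return BinomialEvidence(
        n=n,
        k=k,
        p_benign=p_benign,
        p_pathogenic=p_pathogenic,
        prob_ge_k_given_benign=tail_ge(k, n, p_benign),
        prob_le_k_given_pathogenic=tail_le(k, n, p_pathogenic),
    )


@dataclass(frozen=True)
class DecisionThresholds:
    """Risk/power settings for the minimum-sample decision framework.

    alpha_benign_strict (0.05%) is the accepted risk for a class-2-grade
    exclusion of neutrality; alpha_benign (5%) the exploratory level;
    power_pathogenic the probability a true pathogenic variant reaches the
    deciding k; alpha_pathogenic the accepted miss rate when excluding
    pathogenicity.
    """

    alpha_benign: float = 0.05
    alpha_benign_strict: float = 0.0005
    power_pathogenic: float = 0.90
    alpha_pathogenic: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha_benign", "alpha_benign_strict", "power_pathogenic", "alpha_pathogenic"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0,1)")


@dataclass(frozen=True)
class BinomialDecisionRow:
    """Decision-table row for n analyzed tumors.

    k_min_exclude_neutrality: smallest k whose benign upper tail is below
    alpha (None when even k = n is too likely under p_benign);
    power_at_k_min: probability a pathogenic variant reaches that k;
    k_max_exclude_pathogenicity: largest k whose pathogenic lower tail is
    below alpha_pathogenic (None when even k = 0 is too likely);
    miss_rate: that lower tail.
    """

    n: int
    k_min_exclude_neutrality: int | None
    risk_at_k_min: float | None
    power_at_k_min: float | None
    k_max_exclude_pathogenicity: int | None
    miss_rate: float | None


def decision_table(
    p_benign: float = P_BENIGN_COMBINED,
    p_pathogenic: float = P_PATHOGENIC_COMBINED,
    n_max: int = 20,
    thresholds: DecisionThresholds = DecisionThresholds(),
    alpha: float | None = None,
) -> list[BinomialDecisionRow]:
    """Minimum-sample decision table for n = 1..n_max.

    ``alpha`` (default thresholds.alpha_benign) is the accepted risk for
    excluding neutrality; pass thresholds.alpha_benign_strict for the
    class-2-grade table.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    a = thresholds.alpha_benign if alpha is None else alpha
    if not 0.0 < a <= 1.0:
        raise ValueError(f"alpha={a} outside (0,1]")
    rows = []
    for n in range(1, n_max + 1):
        k_min = risk = power = None
        for k in range(0, n + 1):
            r = tail_ge(k, n, p_benign)
            # alpha = 1 is the degenerate accept-everything threshold
            if r < a or a == 1.0:
                k_min, risk = k, r
                power = tail_ge(k, n, p_pathogenic)
                break
        k_max = miss = None
        for k in range(n, -1, -1):
            m = tail_le(k, n, p_pathogenic)
            if m < thresholds.alpha_pathogenic:
                k_max, miss = k, m
                break
        rows.append(
            BinomialDecisionRow(
                n=n,
                k_min_exclude_neutrality=k_min,
                risk_at_k_min=risk,
                power_at_k_min=power,
                k_max_exclude_pathogenicity=k_max,
                miss_rate=miss,
            )
        )
    return rows


def minimum_informative_n(
    p_benign: float = P_BENIGN_BREAST,
    alpha: float = 0.0005,
    n_max: int = 100,
) -> int | None:
    """Smallest n at which *some* k can exclude neutrality at level alpha.

    With the breast benign-group rate and the strict 0.05% risk this is
    n = 5 (all five tumors must show loss of WT).
    """
    for n in range(1, n_max + 1):
        if tail_ge(n, n, p_benign) < alpha:
            return n
    return None


class LohSuggestion(str, enum.Enum):
    EXCLUDE_NEUTRALITY_STRONG = "EXCLUDE_NEUTRALITY_STRONG"
    EXCLUDE_NEUTRALITY_MODERATE = "EXCLUDE_NEUTRALITY_MODERATE"
    EXCLUDE_PATHOGENICITY = "EXCLUDE_PATHOGENICITY"
    INCONCLUSIVE = "INCONCLUSIVE"


#: Benign-tail boundary for "moderate" evidence against neutrality (~1%).
MODERATE_EVIDENCE_ALPHA = 0.01


def classify_by_loh(
    k: int,
    n: int,
    p_benign: float = P_BENIGN_COMBINED,
    p_pathogenic: float = P_PATHOGENIC_COMBINED,
    thresholds: DecisionThresholds = DecisionThresholds(),
) -> LohSuggestion:
    """Prioritization suggestion from an observed (k of n) LOH recurrence.

    STRONG when the benign tail falls below the strict 0.05% risk,
    MODERATE below the ~1% zone, EXCLUDE_PATHOGENICITY when the pathogenic
    lower tail falls below alpha_pathogenic; otherwise INCONCLUSIVE. Never
    a definitive class on its own.
    """
    if n == 0:
        return LohSuggestion.INCONCLUSIVE
    ev = evidence(k, n, p_benign, p_pathogenic)
    if ev.prob_ge_k_given_benign < thresholds.alpha_benign_strict:
        return LohSuggestion.EXCLUDE_NEUTRALITY_STRONG
    if ev.prob_ge_k_given_benign < MODERATE_EVIDENCE_ALPHA:
        return LohSuggestion.EXCLUDE_NEUTRALITY_MODERATE
    if ev.prob_le_k_given_pathogenic < thresholds.alpha_pathogenic:
        return LohSuggestion.EXCLUDE_PATHOGENICITY
    return LohSuggestion.INCONCLUSIVE


def decision_table_to_frame(rows: list[BinomialDecisionRow]):
    import pandas as pd

    return pd.DataFrame(
        {
            "n": [r.n for r in rows],
            "k_min_exclude_neutrality": [r.k_min_exclude_neutrality for r in rows],
            "risk_at_k_min": [r.risk_at_k_min for r in rows],
            "power_at_k_min": [r.power_at_k_min for r in rows],
            "k_max_exclude_pathogenicity": [r.k_max_exclude_pathogenicity for r in rows],
            "miss_rate": [r.miss_rate for r in rows],
        }
    )
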