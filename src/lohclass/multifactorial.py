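"""Multifactorial (Bayesian) combination of variant-classification evidence.

Independent likelihood-ratio components (co-segregation, tumor pathology,
family history, co-occurrence, optionally an LOH term) multiply into an
overall odds for causality; combined with a prior probability of
pathogenicity this yields the posterior

    posterior = prior * odds / (prior * odds + 1 - prior)

which maps onto the standard 5-tier classes by posterior-probability
bands: class 5 (pathogenic) > 0.99, class 4 in [0.95, 0.99], class 3 in
[0.05, 0.95), class 2 in [0.001, 0.05), class 1 < 0.001. The LR product
is accumulated in log space: co-segregation LRs from large pedigrees can
exceed floating-point range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Component names conventionally recognized; others are accepted too.
KNOWN_COMPONENTS = ("cosegregation", "pathology", "family_history", "cooccurrence", "loh")

DEFAULT_PRIOR = 0.03


def combine_log_odds(lr_components: dict[str, float]) -> float:
    """Natural-log of the product of component LRs (0 for an empty map)."""
    logs = []
    for name, lr in lr_components.items():
        if not lr > 0.0:
            raise ValueError(f"likelihood ratio {name!r} must be > 0, got {lr}")
        logs.append(math.log(lr))
    return math.fsum(logs)


def combine_odds(lr_components: dict[str, float]) -> float:
    """Product of component likelihood ratios; missing components count as 1."""
    return math.exp(combine_log_odds(lr_components))


def posterior_from_log_odds(prior: float, log_odds: float) -> float:
    """Posterior from prior and log combined odds, stable for |log_odds| ~ 700+."""
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior={prior} must be in (0,1)")
    # posterior = 1 / (1 + exp(log((1-prior)/prior) - log_odds))
    z = math.log1p(-prior) - math.log(prior) - log_odds
    if z > 0:
        return math.exp(-z) / (1.0 + math.exp(-z))
    return 1.0 / (1.0 + math.exp(z))


def posterior_probability(prior: float, odds: float) -> float:
    """prior*odds / (prior*odds + 1 - prior)."""
    if not odds > 0.0:
        raise ValueError(f"odds={odds} must be > 0")
    return posterior_from_log_odds(prior, math.log(odds))


def tier(posterior: float) -> int:
    """5-tier class from the posterior probability of pathogenicity.

    Band edges: >0.99 -> 5; [0.95, 0.99] -> 4; [0.05, 0.95) -> 3;
    [0.001, 0.05) -> 2; <0.001 -> 1.
    """
    if not 0.0 <= posterior <= 1.0:
        raise ValueError(f"posterior={posterior} outside [0,1]")
    if posterior > 0.99:
        return 5
    if posterior >= 0.95:
        return 4
    if posterior >= 0.05:
        return 3
    if posterior >= 0.001:
        return 2
    return 1


@dataclass(frozen=True)
class MultifactorialResult:
    variant_id: str
    prior: float
    lr_components: dict[str, float]
    combined_odds: float
    log_combined_odds: float
    posterior: float
    tier: int

    def render_posterior(self, decimals: int = 5) -> str:
        return f"{self.posterior:.{decimals}f}"


def classify_variant(
    variant_id: str,
    prior: float = DEFAULT_PRIOR,
    lr_components: dict[str, float] | None = None,
    loh_lr: float | None = None,
) -> MultifactorialResult:
    """Combine a prior with named LR components into a posterior and tier.

    ``loh_lr`` optionally adds an LOH-recurrence likelihood ratio as an
    extra component. This weighting is experimental: no published
    calibration of LOH recurrence into the LR scale exists yet, so the
    term is opt-in and clearly separated.
    """
    components = dict(lr_components or {})
    if loh_lr is not None:
        components["loh"] = loh_lr
    log_odds = combine_log_odds(components)
    posterior = posterior_from_log_odds(prior, log_odds)
    return MultifactorialResult(
        variant_id=variant_id,
        prior=prior,
        lr_components=components,
        combined_odds=math.exp(log_odds) if log_odds < 700 else math.inf,
        log_combined_odds=log_odds,
        posterior=posterior,
        tier=tier(posterior),
    )
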