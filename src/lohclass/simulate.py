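"""Synthetic carrier cohorts with a latent somatic second hit.

Each simulated tumor from a germline-variant carrier draws one latent event
(allelic balance, loss of the wild-type allele, or loss of the variant
allele) with class-conditional probabilities, and is then observed through
a purity-diluted variant-allele fraction with measurement noise: binomial
read counts for NGS, Gaussian replicate noise for pyrosequencing.

The expected VAF is obtained by allele-copy counting in a mixture of tumor
cells (effective fraction rho = purity x subclonal_fraction) and diploid
heterozygous normal cells. Under DELETION the lost copy is absent; under
copy-neutral LOH (CN_LOH) the retained allele is duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .types import (
    CopyModel,
    Effect,
    GermlineVariant,
    Method,
    SecondHitEvent,
    Tissue,
    TumorSample,
    VariantCohort,
    VariantClass,
)

# Class-conditional second-hit rates observed in the 97-tumor reference
# cohort (loss-of-WT / loss-of-variant out of informative carrier tumors).
DEFAULT_P_LOSS_WT: dict[VariantClass, float] = {
    VariantClass.PATHOGENIC: 36 / 55,
    VariantClass.BENIGN: 6 / 27,
    VariantClass.VUS: 10 / 15,
}
DEFAULT_P_LOSS_VARIANT: dict[VariantClass, float] = {
    VariantClass.PATHOGENIC: 3 / 55,
    VariantClass.BENIGN: 4 / 27,
    VariantClass.VUS: 1 / 15,
}

_EFFECT_MIX: dict[VariantClass, list[tuple[Effect, float]]] = {
    # pathogenic set: 4 missense, 6 truncating of 10 variants
    VariantClass.PATHOGENIC: [
        (Effect.MISSENSE, 0.4),
        (Effect.FRAMESHIFT, 0.4),
        (Effect.NONSENSE, 0.2),
    ],
    VariantClass.BENIGN: [(Effect.MISSENSE, 7 / 8), (Effect.SYNONYMOUS, 1 / 8)],
    VariantClass.VUS: [(Effect.MISSENSE, 1.0)],
}


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic carrier cohort.

    Defaults reproduce the reference study's conditions: ~100 tumors over
    a few dozen variants, class-conditional loss rates taken from the
    observed cohort, pathologist-estimated purity spanning 30-90%,
    triplicate pyrosequencing with replicate sd 0.02 for most samples and
    deep amplicon NGS for a small minority, breast tumors dominating.
    """

    n_variants_per_class: int = 8
    samples_per_variant: int = 4
    p_loss_wt_by_class: dict[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_P_LOSS_WT)
    )
    p_loss_variant_by_class: dict[VariantClass, float] = field(
        default_factory=lambda: dict(DEFAULT_P_LOSS_VARIANT)
    )
    purity_range: tuple[float, float] = (0.3, 0.9)
    read_depth: int = 1000
    pyro_sd: float = 0.02
    replicates: int = 3
    copy_model: CopyModel = CopyModel.DELETION
    subclonal_fraction_range: tuple[float, float] = (1.0, 1.0)
    p_ngs: float = 6 / 97
    p_ovary: float = 7 / 97
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_variants_per_class < 1 or self.samples_per_variant < 1:
            raise ValueError("counts must be >= 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.pyro_sd < 0:
            raise ValueError("pyro_sd must be >= 0")
        for rng_name in ("purity_range", "subclonal_fraction_range"):
            lo, hi = getattr(self, rng_name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{rng_name}=({lo}, {hi}) must satisfy 0 <= lo <= hi <= 1")
        for p_name in ("p_ngs", "p_ovary"):
            if not 0.0 <= getattr(self, p_name) <= 1.0:
                raise ValueError(f"{p_name} must be in [0,1]")
        if set(self.p_loss_wt_by_class) != set(self.p_loss_variant_by_class):
            raise ValueError("loss-rate maps must cover the same classes")
        for cls in self.p_loss_wt_by_class:
            pw = self.p_loss_wt_by_class[cls]
            pv = self.p_loss_variant_by_class[cls]
            if pw < 0 or pv < 0 or pw + pv > 1.0 + 1e-12:
                raise ValueError(
                    f"{cls.value}: p_loss_wt + p_loss_variant must be in [0,1]"
                )

    @property
    def classes(self) -> list[VariantClass]:
        return sorted(self.p_loss_wt_by_class, key=lambda c: c.value)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        for key in ("p_loss_wt_by_class", "p_loss_variant_by_class"):
            if key in kwargs:
                kwargs[key] = {
                    VariantClass(k): float(v) for k, v in kwargs[key].items()
                }
        if "copy_model" in kwargs:
            kwargs["copy_model"] = CopyModel(kwargs["copy_model"])
        for key in ("purity_range", "subclonal_fraction_range"):
            if key in kwargs:
                kwargs[key] = tuple(float(x) for x in kwargs[key])
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def expected_vaf(
    event: SecondHitEvent,
    purity: float,
    copy_model: CopyModel = CopyModel.DELETION,
    subclonal_fraction: float = 1.0,
) -> float:
    """Expected tumor VAF for a latent event at given effective purity.

    With rho = purity * subclonal_fraction, allele-copy counting over the
    tumor/normal mixture gives:

    ========== ============= ==============
    event       DELETION      CN_LOH
    ========== ============= ==============
    BALANCE     1/2           1/2
    LOSS_WT     1/(2 - rho)   (1 + rho)/2
    LOSS_VAR    (1-rho)/(2-rho)  (1 - rho)/2
    ========== ============= ==============
    """
    for name, v in (("purity", purity), ("subclonal_fraction", subclonal_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0,1]")
    rho = purity * subclonal_fraction
    if event is SecondHitEvent.BALANCE:
        return 0.5
    if copy_model is CopyModel.DELETION:
        if event is SecondHitEvent.LOSS_WT:
            return 1.0 / (2.0 - rho)
        return (1.0 - rho) / (2.0 - rho)
    # copy-neutral: total copy number stays 2 in tumor cells
    if event is SecondHitEvent.LOSS_WT:
        return (1.0 + rho) / 2.0
    return (1.0 - rho) / 2.0


def simulate_pyrosequencing(
    true_vaf: float,
    sd: float,
    replicates: int,
    rng: np.random.Generator,
) -> list[float]:
    """Replicate pyrosequencing reads of a true VAF: Gaussian noise, clipped."""
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError("true_vaf outside [0,1]")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    values = rng.normal(true_vaf, sd, size=replicates)
    return [float(v) for v in np.clip(values, 0.0, 1.0)]


def _draw_event(
    classification: VariantClass, config: SimulationConfig, rng: np.random.Generator
) -> SecondHitEvent:
    p_wt = config.p_loss_wt_by_class[classification]
    p_var = config.p_loss_variant_by_class[classification]
    u = rng.random()
    if u < p_wt:
        return SecondHitEvent.LOSS_WT
    if u < p_wt + p_var:
        return SecondHitEvent.LOSS_VARIANT
    return SecondHitEvent.BALANCE


def simulate_sample(
    variant: GermlineVariant,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "S1",
) -> TumorSample:
    """Draw one tumor sample for a carrier of ``variant``.

    Draw order (fixed for reproducibility): event kind, purity, subclonal
    fraction, tissue, measurement method, then measurement noise.
    """
    if variant.classification not in config.p_loss_wt_by_class:
        raise ValueError(f"no loss rates configured for {variant.classification.value}")
    event = _draw_event(variant.classification, config, rng)
    lo, hi = config.purity_range
    purity = float(rng.uniform(lo, hi))
    slo, shi = config.subclonal_fraction_range
    subclonal = float(rng.uniform(slo, shi))
    tissue = Tissue.OVARY if rng.random() < config.p_ovary else Tissue.BREAST
    method = Method.NGS if rng.random() < config.p_ngs else Method.PYRO
    mu = expected_vaf(event, purity, config.copy_model, subclonal)
    if method is Method.NGS:
        alt = int(rng.binomial(config.read_depth, mu))
        return TumorSample(
            sample_id=sample_id,
            variant_id=variant.variant_id,
            tissue=tissue,
            method=method,
            alt_depth=alt,
            total_depth=config.read_depth,
            cellularity=purity,
            germline_vaf=0.5,
            truth_event=event,
        )
    reps = simulate_pyrosequencing(mu, config.pyro_sd, config.replicates, rng)
    return TumorSample(
        sample_id=sample_id,
        variant_id=variant.variant_id,
        tissue=tissue,
        method=method,
        replicate_vafs=reps,
        cellularity=purity,
        germline_vaf=0.5,
        truth_event=event,
    )


def simulate_cohort(config: SimulationConfig) -> VariantCohort:
    """Simulate a full carrier cohort; reproducible from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    variants: list[GermlineVariant] = []
    for cls in config.classes:
        mix = _EFFECT_MIX.get(cls, [(Effect.MISSENSE, 1.0)])
        effects = [e for e, _ in mix]
        weights = np.array([w for _, w in mix], dtype=float)
        weights /= weights.sum()
        for i in range(config.n_variants_per_class):
            effect = effects[int(rng.choice(len(effects), p=weights))]
            variants.append(
                GermlineVariant(
                    variant_id=f"{cls.value[:4]}_{i + 1:03d}",
                    classification=cls,
                    effect=effect,
                )
            )
    samples = [
        simulate_sample(v, config, rng, sample_id=f"{v.variant_id}-T{j + 1}")
        for v in variants
        for j in range(config.samples_per_variant)
    ]
    return VariantCohort(variants=variants, samples=samples)
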