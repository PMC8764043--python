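"""Synthetic-cohort generator: expected-VAF model, noise, reproducibility."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lohclass.simulate import (
    SimulationConfig,
    expected_vaf,
    simulate_cohort,
    simulate_pyrosequencing,
    simulate_sample,
)
from lohclass.types import CopyModel, GermlineVariant, Effect, Method, SecondHitEvent, VariantClass


class TestExpectedVaf:
    @pytest.mark.parametrize(
        "event,purity,model,sub,expected",
        [
            (SecondHitEvent.LOSS_WT, 1.0, CopyModel.DELETION, 1.0, 1.0),
            (SecondHitEvent.LOSS_WT, 0.0, CopyModel.DELETION, 1.0, 0.5),
            (SecondHitEvent.BALANCE, 0.0, CopyModel.CN_LOH, 1.0, 0.5),
            (SecondHitEvent.LOSS_VARIANT, 0.0, CopyModel.CN_LOH, 1.0, 0.5),
            # rho=0.5 deletion: tumor contributes 1 variant / 0 WT copies,
            # normal 1/1, so VAF = (0.5+0.5)/(0.5+1.0) = 2/3
            (SecondHitEvent.LOSS_WT, 0.5, CopyModel.DELETION, 1.0, 1 / 1.5),
            (SecondHitEvent.LOSS_WT, 0.5, CopyModel.CN_LOH, 1.0, 0.75),
            (SecondHitEvent.LOSS_VARIANT, 0.5, CopyModel.DELETION, 1.0, 0.5 / 1.5),
            (SecondHitEvent.LOSS_VARIANT, 1.0, CopyModel.CN_LOH, 1.0, 0.0),
            # subclonality multiplies purity: 0.8 * 0.5 -> rho 0.4
            (SecondHitEvent.LOSS_WT, 0.8, CopyModel.DELETION, 0.5, 1 / 1.6),
        ],
    )
    def test_copy_counting_values(self, event, purity, model, sub, expected):
        assert expected_vaf(event, purity, model, sub) == pytest.approx(expected)

    @given(
        rho1=st.floats(0, 1),
        rho2=st.floats(0, 1),
        model=st.sampled_from(list(CopyModel)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_monotone_in_purity(self, rho1, rho2, model):
        lo, hi = sorted((rho1, rho2))
        assert expected_vaf(SecondHitEvent.LOSS_WT, hi, model) >= expected_vaf(
            SecondHitEvent.LOSS_WT, lo, model
        )
        assert expected_vaf(SecondHitEvent.LOSS_VARIANT, hi, model) <= expected_vaf(
            SecondHitEvent.LOSS_VARIANT, lo, model
        )

    @given(
        purity=st.floats(0, 1),
        sub=st.floats(0, 1),
        event=st.sampled_from(list(SecondHitEvent)),
        model=st.sampled_from(list(CopyModel)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_result_in_unit_interval(self, purity, sub, event, model):
        assert 0.0 <= expected_vaf(event, purity, model, sub) <= 1.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            expected_vaf(SecondHitEvent.LOSS_WT, 1.2)

    def test_detectability_boundaries(self):
        """The 0.10 imbalance rule detects deletion LOH iff purity > 1/3 and
        copy-neutral LOH iff purity > 0.2."""
        eps = 1e-6
        for model, boundary in [(CopyModel.DELETION, 1 / 3), (CopyModel.CN_LOH, 0.2)]:
            below = expected_vaf(SecondHitEvent.LOSS_WT, boundary - eps, model) - 0.5
            at = expected_vaf(SecondHitEvent.LOSS_WT, boundary, model) - 0.5
            above = expected_vaf(SecondHitEvent.LOSS_WT, boundary + eps, model) - 0.5
            assert below < 0.10
            assert at == pytest.approx(0.10, abs=1e-9)
            assert above > 0.10


class TestPyrosequencingNoise:
    def test_zero_sd_returns_truth(self, rng):
        assert simulate_pyrosequencing(0.37, 0.0, 3, rng) == [0.37] * 3

    def test_replicate_count(self, rng):
        assert len(simulate_pyrosequencing(0.5, 0.02, 7, rng)) == 7

    def test_mean_converges(self, rng):
        reps = simulate_pyrosequencing(0.5, 0.02, 10_000, rng)
        assert abs(np.mean(reps) - 0.5) < 0.001

    def test_clipped_to_unit_interval(self, rng):
        reps = simulate_pyrosequencing(0.99, 0.1, 1000, rng)
        assert all(0.0 <= v <= 1.0 for v in reps)

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_pyrosequencing(0.5, -0.01, 3, rng)


PV = GermlineVariant("v1", VariantClass.PATHOGENIC, Effect.FRAMESHIFT)


class TestSimulateSample:
    def test_pure_tumor_full_loss_limit(self):
        cfg = SimulationConfig(
            p_loss_wt_by_class={VariantClass.PATHOGENIC: 1.0},
            p_loss_variant_by_class={VariantClass.PATHOGENIC: 0.0},
            purity_range=(1.0, 1.0),
            read_depth=10**6,
            p_ngs=1.0,
            seed=0,
        )
        s = simulate_sample(PV, cfg, np.random.default_rng(0))
        assert s.truth_event is SecondHitEvent.LOSS_WT
        assert s.alt_depth / s.total_depth == pytest.approx(1.0, abs=1e-3)

    def test_deterministic_given_seeded_rng(self):
        cfg = SimulationConfig(seed=3)
        s1 = simulate_sample(PV, cfg, np.random.default_rng(42))
        s2 = simulate_sample(PV, cfg, np.random.default_rng(42))
        assert s1 == s2

    def test_event_rate_matches_generative_probability(self):
        cfg = SimulationConfig(
            p_loss_wt_by_class={VariantClass.PATHOGENIC: 0.654},
            p_loss_variant_by_class={VariantClass.PATHOGENIC: 0.0},
            seed=0,
        )
        rng = np.random.default_rng(11)
        n = 10_000
        hits = sum(
            simulate_sample(PV, cfg, rng).truth_event is SecondHitEvent.LOSS_WT
            for _ in range(n)
        )
        se = math.sqrt(0.654 * 0.346 / n)
        assert abs(hits / n - 0.654) < 3 * se

    def test_unconfigured_class_rejected(self):
        cfg = SimulationConfig(
            p_loss_wt_by_class={VariantClass.PATHOGENIC: 0.5},
            p_loss_variant_by_class={VariantClass.PATHOGENIC: 0.1},
        )
        benign = GermlineVariant("b1", VariantClass.BENIGN, Effect.MISSENSE)
        with pytest.raises(ValueError):
            simulate_sample(benign, cfg, np.random.default_rng(0))


class TestSimulateCohort:
    def test_cohort_size(self):
        cfg = SimulationConfig(
            n_variants_per_class=3,
            samples_per_variant=5,
            p_loss_wt_by_class={VariantClass.PATHOGENIC: 0.9, VariantClass.BENIGN: 0.1},
            p_loss_variant_by_class={VariantClass.PATHOGENIC: 0.0, VariantClass.BENIGN: 0.1},
        )
        cohort = simulate_cohort(cfg)
        assert len(cohort.variants) == 6
        assert cohort.n_samples == 30

    def test_same_seed_same_cohort(self):
        a = simulate_cohort(SimulationConfig(seed=9))
        b = simulate_cohort(SimulationConfig(seed=9))
        assert a.variants == b.variants
        assert a.samples == b.samples

    def test_different_seed_differs(self):
        a = simulate_cohort(SimulationConfig(seed=1))
        b = simulate_cohort(SimulationConfig(seed=2))
        assert a.samples != b.samples

    def test_truth_events_recorded(self):
        cohort = simulate_cohort(SimulationConfig(seed=5))
        assert all(s.truth_event is not None for s in cohort.samples)

    def test_samples_methods_mixed(self):
        cohort = simulate_cohort(SimulationConfig(seed=5, samples_per_variant=20))
        methods = {s.method for s in cohort.samples}
        assert methods == {Method.PYRO, Method.NGS}


class TestConfigValidation:
    def test_loss_probabilities_must_fit_in_unit_interval(self):
        with pytest.raises(ValueError):
            SimulationConfig(
                p_loss_wt_by_class={VariantClass.PATHOGENIC: 0.8},
                p_loss_variant_by_class={VariantClass.PATHOGENIC: 0.3},
            )

    def test_purity_range_checked(self):
        with pytest.raises(ValueError):
            SimulationConfig(purity_range=(0.9, 0.3))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_variants_per_class: 2\n"
            "samples_per_variant: 3\n"
            "p_loss_wt_by_class: {PATHOGENIC: 0.9, BENIGN: 0.1}\n"
            "p_loss_variant_by_class: {PATHOGENIC: 0.0, BENIGN: 0.2}\n"
            "purity_range: [0.5, 0.9]\n"
            "copy_model: CN_LOH\n"
            "seed: 4\n"
        )
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.copy_model is CopyModel.CN_LOH
        assert cfg.p_loss_wt_by_class[VariantClass.BENIGN] == 0.1
        assert cfg.purity_range == (0.5, 0.9)
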