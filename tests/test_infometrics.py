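"""AUROC, gamma-mixture fitting and the structural-information metric."""

import math

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from fourbase.infometrics import (
    ESIResult,
    GammaMixture,
    StructureModels,
    auroc,
    expected_structural_information,
    fit_gamma_mixture,
    posterior_paired,
    structural_information,
)
from fourbase.reactivity import ReactivityProfile


def unit_mixture(mean=0.5, zero_mass=0.0):
    """A simple fitted-looking mixture with the given continuous mean."""
    w = 1.0 - zero_mass
    return GammaMixture(
        weights=np.array([0.6 * w, 0.4 * w]),
        shapes=np.array([2.0, 6.0]),
        scales=np.array([mean / 2.0, mean / 6.0]),
        zero_mass=zero_mass,
    )


def point_mass_at_zero():
    """All likelihood on r <= 0: disjoint support from any continuous mixture."""
    return GammaMixture(
        weights=np.array([0.0, 0.0]),
        shapes=np.array([1.0, 1.0]),
        scales=np.array([1.0, 1.0]),
        zero_mass=1.0,
    )


class TestAuroc:
    def test_perfect_separation(self):
        vals = np.array([0.9, 0.8, 0.1, 0.2])
        unpaired = np.array([True, True, False, False])
        assert auroc(vals, unpaired) == 1.0

    def test_all_tied_scores_give_half(self):
        vals = np.full(10, 0.3)
        unpaired = np.arange(10) < 4
        assert auroc(vals, unpaired) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        assert math.isnan(auroc(np.array([0.1, 0.2]), np.array([True, True])))

    def test_matches_pairwise_comparison_oracle(self, rng):
        """AUROC equals U/(n1*n0) counted by brute-force pair enumeration,
        and agrees with scikit-learn's independent implementation."""
        for _ in range(100):
            n = int(rng.integers(8, 40))
            vals = np.round(rng.normal(size=n), 1)  # rounding forces ties
            unpaired = rng.random(n) < 0.5
            if unpaired.all() or not unpaired.any():
                continue
            pos, neg = vals[unpaired], vals[~unpaired]
            u = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos
                for q in neg
            )
            expected = u / (len(pos) * len(neg))
            assert auroc(vals, unpaired) == pytest.approx(expected)
            assert auroc(vals, unpaired) == pytest.approx(
                roc_auc_score(unpaired, vals)
            )

    def test_invariant_under_monotone_transform(self, rng):
        vals = rng.gamma(1.0, 1.0, size=60)
        unpaired = rng.random(60) < 0.4
        if unpaired.all() or not unpaired.any():
            unpaired[:5] = True
            unpaired[5:] = False
        base = auroc(vals, unpaired)
        assert auroc(np.log1p(vals) * 7 + 2, unpaired) == pytest.approx(base)

    def test_mask_is_applied(self):
        vals = np.array([0.9, 0.8, 0.1, 5.0])
        unpaired = np.array([True, True, False, False])
        mask = np.array([True, True, True, False])
        assert auroc(vals, unpaired, mask) == 1.0


class TestFitGammaMixture:
    def test_parameter_recovery(self, rng):
        true = GammaMixture(
            weights=np.array([0.54, 0.36]),
            shapes=np.array([0.6, 3.0]),
            scales=np.array([0.12, 0.5]),
            zero_mass=0.10,
        )
        fit = fit_gamma_mixture(true.sample(5000, rng), seed=0)
        for name in ("weights", "shapes", "scales"):
            rel = np.abs(getattr(fit, name) - getattr(true, name)) / getattr(true, name)
            assert (rel < 0.15).all(), f"{name}: {rel}"
        assert fit.zero_mass == pytest.approx(0.10, abs=0.02)

    def test_single_gamma_collapses_to_one_component(self, rng):
        fit = fit_gamma_mixture(rng.gamma(2.0, 0.3, size=3000), seed=0)
        assert fit.weights.max() >= 0.9

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gamma_mixture(np.full(100, 0.2))

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_gamma_mixture(np.arange(30) / 30)
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_mixture(np.concatenate([np.zeros(90), np.ones(10)]))

    def test_density_integrates_to_continuous_mass(self, rng):
        fit = fit_gamma_mixture(rng.gamma(1.0, 0.4, size=2000) - 0.02, seed=0)
        grid = np.linspace(1e-6, 50, 200_000)
        integral = np.trapezoid(fit.pdf(grid), grid)
        assert integral == pytest.approx(1.0 - fit.zero_mass, abs=1e-3)


class TestStructuralInformation:
    def test_equal_likelihoods_give_zero_bits(self):
        m = unit_mixture()
        assert structural_information(0.37, m, m) == pytest.approx(0.0, abs=1e-12)
        assert posterior_paired(0.37, m, m) == pytest.approx(0.5)

    def test_disjoint_likelihoods_give_one_bit(self):
        paired = point_mass_at_zero()
        unpaired = unit_mixture(0.8)
        assert structural_information(0.8, paired, unpaired) == 1.0
        assert structural_information(0.0, paired, unpaired) == 1.0

    def test_quarter_posterior_entropy(self):
        """p(b|r) = 0.25 gives SI = 1 - H(0.25) = 0.18872 (binary entropy
        evaluated directly at high precision)."""
        # evaluate at r <= 0 where the zero masses set a 1:3 likelihood ratio
        paired_scaled = GammaMixture(np.array([0.75, 0.0]), np.ones(2), np.ones(2), 0.25)
        unpaired_scaled = GammaMixture(np.array([0.25, 0.0]), np.ones(2), np.ones(2), 0.75)
        pb = posterior_paired(-1.0, paired_scaled, unpaired_scaled)
        assert pb == pytest.approx(0.25)
        h = -(0.25 * math.log2(0.25) + 0.75 * math.log2(0.75))
        si = structural_information(-1.0, paired_scaled, unpaired_scaled)
        assert si == pytest.approx(1.0 - h)
        assert si == pytest.approx(0.18872, abs=1e-5)

    def test_scale_invariance_of_si(self, rng):
        """SI depends only on the likelihood ratio, so doubling both class
        zero-masses (r <= 0 branch) leaves it unchanged."""
        a = GammaMixture(np.array([0.9, 0.0]), np.ones(2), np.ones(2), 0.10)
        b = GammaMixture(np.array([0.6, 0.0]), np.ones(2), np.ones(2), 0.40)
        a2 = GammaMixture(np.array([0.8, 0.0]), np.ones(2), np.ones(2), 0.20)
        b2 = GammaMixture(np.array([0.2, 0.0]), np.ones(2), np.ones(2), 0.80)
        assert structural_information(-0.5, a, b) == pytest.approx(
            structural_information(-0.5, a2, b2)
        )

    def test_si_bounds_on_random_inputs(self, rng):
        paired, unpaired = unit_mixture(0.1, 0.3), unit_mixture(0.9, 0.05)
        r = np.concatenate([rng.normal(0.3, 0.5, 200), [-1, 0, 10]])
        si = structural_information(r, paired, unpaired)
        assert ((si >= 0) & (si <= 1)).all()


def make_profile(seq, reactivity, mask=None):
    n = len(seq)
    return ReactivityProfile(
        seq,
        modified_rate=np.zeros(n),
        reactivity=np.asarray(reactivity, dtype=float),
        mask=mask,
    )


def models_for(bases, paired, unpaired):
    return StructureModels({b: (paired, unpaired) for b in bases})


class TestExpectedStructuralInformation:
    def test_identical_models_give_zero(self, rng):
        m = unit_mixture()
        profile = make_profile("ACGU" * 25, rng.gamma(1.0, 0.5, 100))
        result = expected_structural_information(profile, models_for("ACGU", m, m))
        assert result.esi == 0.0
        assert result.n_used == 100

    def test_disjoint_models_give_one(self, rng):
        paired, unpaired = point_mass_at_zero(), unit_mixture(0.8)
        react = np.where(rng.random(100) < 0.5, 0.0, rng.gamma(2.0, 0.3, 100))
        profile = make_profile("ACGU" * 25, react)
        result = expected_structural_information(
            profile, models_for("ACGU", paired, unpaired)
        )
        assert result.esi == 1.0

    def test_two_base_mode_keeps_gu_in_denominator(self, rng):
        """Perfect A/C models on an exactly 50% A+C sequence give ESI 0.5:
        G and U contribute SI = 0 but stay in the average."""
        seq = "ACGU" * 25
        paired, unpaired = point_mass_at_zero(), unit_mixture(0.8)
        react = np.where(rng.random(100) < 0.5, 0.0, rng.gamma(2.0, 0.3, 100))
        profile = make_profile(seq, react)
        result = expected_structural_information(
            profile, models_for("AC", paired, unpaired), bases="AC"
        )
        assert result.esi == pytest.approx(0.5)
        assert result.n_used == 100

    def test_four_base_esi_dominates_two_base(self, rng):
        paired, unpaired = unit_mixture(0.1, 0.3), unit_mixture(0.8, 0.05)
        react = rng.gamma(1.0, 0.4, 100)
        profile = make_profile("ACGU" * 25, react)
        models = models_for("ACGU", paired, unpaired)
        four = expected_structural_information(profile, models).esi
        two = expected_structural_information(profile, models, bases="AC").esi
        assert four >= two

    def test_esi_monotone_in_separation(self, rng):
        """Pushing the unpaired mixture mean away from the paired one
        never decreases ESI on a fixed profile."""
        react = rng.gamma(1.0, 0.3, 120)
        profile = make_profile("ACGU" * 30, react)
        paired = unit_mixture(0.1)
        last = -1.0
        for mean in (0.15, 0.3, 0.6, 1.2, 2.4):
            models = models_for("ACGU", paired, unit_mixture(mean))
            esi = expected_structural_information(profile, models).esi
            assert esi >= last - 1e-12
            last = esi

    def test_masked_positions_excluded(self, rng):
        m, u = unit_mixture(0.1), unit_mixture(0.9)
        mask = np.ones(100, dtype=bool)
        mask[:50] = False
        profile = make_profile("ACGU" * 25, rng.gamma(1.0, 0.4, 100), mask)
        result = expected_structural_information(profile, models_for("ACGU", m, u))
        assert result.n_used == 50
        assert np.isnan(result.si[:50]).all()

    def test_no_unmasked_positions_is_an_error(self):
        profile = make_profile("ACGU", [0.1] * 4, np.zeros(4, dtype=bool))
        m = unit_mixture()
        with pytest.raises(ValueError, match="no unmasked"):
            expected_structural_information(profile, models_for("ACGU", m, m))


def test_models_json_roundtrip():
    models = models_for("ACGU", unit_mixture(0.1, 0.2), unit_mixture(0.9))
    again = StructureModels.from_json(models.to_json())
    for b in "ACGU":
        for orig, back in zip(models.models[b], again.models[b]):
            assert np.allclose(orig.weights, back.weights)
            assert np.allclose(orig.shapes, back.shapes)
            assert np.allclose(orig.scales, back.scales)
            assert orig.zero_mass == back.zero_mass
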