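"""Unit and property tests for the genotype/weight/trait simulators."""

import numpy as np
import pytest
from scipy import stats

import twasvc as tv
from twasvc.synthetic_data import simulate_alternative_study


class TestLdSpec:
    def test_identity_spec_is_identity(self):
        ld = tv.LdSpec.identity(5)
        assert ld.is_identity
        assert np.array_equal(ld.correlation_matrix(), np.eye(5))

    def test_block_sizes_must_sum(self):
        with pytest.raises(ValueError, match="sum"):
            tv.LdSpec(5, (2, 2), (0.1, 0.1))

    def test_non_psd_block_rejected_naming_block(self):
        bad = np.array([[1.0, 0.8, -0.8], [0.8, 1.0, 0.8], [-0.8, 0.8, 1.0]])
        with pytest.raises(ValueError, match="block 1"):
            tv.LdSpec(4, (1, 3), (0.0, bad))

    def test_exchangeable_correlation_range(self):
        with pytest.raises(ValueError, match=r"\[0, 1\)"):
            tv.LdSpec(2, (2,), (1.0,))


class TestSimulateGenotypes:
    def test_identity_columns_nearly_uncorrelated(self):
        G = tv.simulate_genotypes(1000, tv.LdSpec.identity(999),
                                  maf_range=(0.5, 0.5), seed=3)
        assert G.dosages.shape == (1000, 999)
        C = np.corrcoef(G.dosages.T)
        off = C[np.triu_indices(999, k=1)]
        assert abs(off.mean()) < 0.01

    def test_block_ld_realized_correlation(self):
        # latent-threshold construction, calibrated: requested dosage
        # correlation 0.9 should be approximately realized at large n
        ld = tv.LdSpec(2, (2,), (0.9,))
        G = tv.simulate_genotypes(10000, ld, maf_range=(0.5, 0.5), seed=7)
        r = np.corrcoef(G.dosages.T)[0, 1]
        assert 0.75 <= r <= 0.95

    def test_maf_precondition(self):
        with pytest.raises(ValueError, match="maf_range"):
            tv.simulate_genotypes(100, tv.LdSpec.identity(5),
                                  maf_range=(0.6, 0.7), seed=0)

    def test_standardization_invariant(self):
        G = tv.simulate_genotypes(200, tv.LdSpec.identity(20), seed=5,
                                  standardize=True)
        assert np.all(np.abs(G.dosages.mean(axis=0)) < 1e-8)
        assert np.all(np.abs(G.dosages.var(axis=0) - 1.0) < 1e-8)

    def test_dosages_in_range(self):
        ld = tv.LdSpec(6, (3, 3), (0.5, 0.0))
        G = tv.simulate_genotypes(300, ld, seed=11)
        assert set(np.unique(G.dosages)) <= {0.0, 1.0, 2.0}


class TestMediatorWeights:
    def test_sparsity_is_exact(self):
        w = tv.simulate_mediator_weights(10, 1, seed=1)
        assert w.n_model_variants == 1
        assert len(w.variant_ids) == 1
        assert np.all(w.weights != 0)

    def test_dense_weights(self):
        w = tv.simulate_mediator_weights(999, 999, seed=2)
        assert len(w.weights) == 999
        assert np.count_nonzero(w.weights) == 999

    def test_zero_nonzero_rejected(self):
        with pytest.raises(ValueError, match="n_nonzero"):
            tv.simulate_mediator_weights(10, 0, seed=0)

    def test_student_t_weights_heavier_tailed(self):
        # pooled kurtosis over 1000 redraws of 100 weights: t(4) has
        # heavier tails than normal (its population excess kurtosis diverges)
        t_draws = np.concatenate([
            tv.simulate_mediator_weights(100, 100, dist="student_t", df=4,
                                         seed=s).weights for s in range(1000)])
        n_draws = np.concatenate([
            tv.simulate_mediator_weights(100, 100, dist="normal",
                                         seed=s).weights for s in range(1000)])
        assert stats.kurtosis(t_draws) > stats.kurtosis(n_draws)


class TestNullTrait:
    def test_unit_variance(self):
        t = tv.simulate_null_trait(1000, seed=4)
        assert abs(np.var(t.values) - 1.0) < 4 * np.sqrt(2.0 / 999)
        assert t.kind == "null_nonpolygenic" and t.h2 == 0.0

    def test_student_t_null_unit_variance(self):
        t = tv.simulate_null_trait(5000, dist="student_t", df=5, seed=4)
        assert abs(np.var(t.values) - 1.0) < 0.15

    def test_needs_two_individuals(self):
        with pytest.raises(ValueError):
            tv.simulate_null_trait(1, seed=0)


class TestPolygenicTrait:
    def test_h2_zero_has_no_genetic_component(self, small_panel):
        t = tv.simulate_polygenic_trait(small_panel, 0.0, seed=9)
        assert t.kind == "null_nonpolygenic"
        assert abs(np.var(t.values) - 1.0) < 0.2

    def test_exact_scale_pins_genetic_variance(self):
        # with h2 = 1 (noise-free, explicitly allowed) the trait IS the
        # genetic component, so exact rescaling must give variance 1 exactly
        G = tv.simulate_genotypes(50, tv.LdSpec.identity(10), seed=6,
                                  standardize=True)
        t = tv.simulate_polygenic_trait(G, 1.0, seed=6, allow_noise_free=True)
        assert abs(np.var(t.values) - 1.0) < 1e-12

    def test_noise_free_requires_flag(self, small_panel):
        with pytest.raises(ValueError, match="noise-free"):
            tv.simulate_polygenic_trait(small_panel, 1.0, seed=0)

    def test_total_variance_near_one(self, small_panel):
        t = tv.simulate_polygenic_trait(small_panel, 0.5, seed=10)
        assert abs(np.var(t.values) - 1.0) < 0.25

    def test_student_t_effects_keep_variance_contract(self, small_panel):
        t = tv.simulate_polygenic_trait(small_panel, 0.5, effect_dist="student_t",
                                        df=4, seed=12)
        assert abs(np.var(t.values) - 1.0) < 0.25


class TestAlternative:
    def test_denominator_positivity_enforced(self):
        with pytest.raises(ValueError, match="positive"):
            tv.AlternativeSpec(beta=2.0, tau2=1.0, sigma_T2=1.0, sigma_Y2=1.0)

    def test_tau2_one_prediction_equals_true_mediator(self, small_panel,
                                                      dense_weights):
        spec = tv.AlternativeSpec(beta=0.3, tau2=1.0, h2_delta=0.1)
        d = simulate_alternative_study(small_panel, dense_weights, spec, seed=3)
        assert np.allclose(d.prediction, d.true_mediator)

    def test_tau2_controls_prediction_variance(self, small_panel, dense_weights):
        spec = tv.AlternativeSpec(beta=0.1, tau2=0.5, h2_delta=0.2)
        d = simulate_alternative_study(small_panel, dense_weights, spec, seed=3)
        assert abs(np.var(d.prediction) - 1.0 / 0.5) < 1e-8
        assert abs(np.var(d.true_mediator) - 1.0) < 1e-8

    def test_beta_zero_trait_unrelated_to_mediator(self, small_panel,
                                                   dense_weights):
        spec = tv.AlternativeSpec(beta=0.0, tau2=0.8, h2_delta=0.0)
        rs = []
        for s in range(200):
            d = simulate_alternative_study(small_panel, dense_weights, spec,
                                           seed=s)
            rs.append(np.corrcoef(d.trait.values, d.true_mediator)[0, 1])
        assert abs(np.mean(rs)) < 3.0 / np.sqrt(200 * small_panel.n_individuals)

    def test_requires_true_weights(self, small_panel, dense_weights):
        w = tv.WeightSet("g", dense_weights.variant_ids,
                         dense_weights.weights.copy())
        w.true_weights = None
        with pytest.raises(ValueError, match="true_weights"):
            tv.simulate_alternative_trait(small_panel, w,
                                          tv.AlternativeSpec(0.1, 0.9), seed=0)


@pytest.mark.parametrize("make", [
    lambda s: tv.simulate_genotypes(50, tv.LdSpec(4, (2, 2), (0.4, 0.0)),
                                    seed=s).dosages,
    lambda s: tv.simulate_mediator_weights(20, 5, seed=s).weights,
    lambda s: tv.simulate_null_trait(30, seed=s).values,
], ids=["genotypes", "weights", "null_trait"])
def test_seeded_simulators_are_bit_deterministic(make):
    assert np.array_equal(make(99), make(99))
    assert not np.array_equal(make(99), make(100))


def test_null_traits_independent_of_predicted_mediator(small_panel,
                                                       dense_weights):
    # over many seeds, corr(null trait, predicted mediator) averages to zero
    t = tv.predict_mediator(small_panel, dense_weights)
    n = small_panel.n_individuals
    rs = [np.corrcoef(t, tv.simulate_null_trait(n, seed=s).values)[0, 1]
          for s in range(1000)]
    assert abs(np.mean(rs)) < 3.0 / np.sqrt(1000 * n)
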