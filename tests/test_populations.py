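"""Population parameters: metric conversion, defaults, non-invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ordsem.populations import (
    FOCAL,
    REFERENT,
    DesignError,
    InvalidLoadingError,
    ItemParams,
    LinearItemParams,
    MeasurementSpec,
    apply_noninvariance,
    default_target_measurement,
    linear_to_theta,
    population_structural,
    sample_auxiliary_measurement,
    theta_to_linear,
)


class TestMetricConversion:
    @pytest.mark.parametrize(
        "lam, tau, a, b",
        [
            (0.6, (-1.7, -0.5), 0.75, (-2.125, -0.625)),
            (0.0, (-1.0, 1.0), 0.0, (-1.0, 1.0)),
            (0.8, (0.3,), 4.0 / 3.0, (0.5,)),
        ],
    )
    def test_linear_to_theta_closed_form(self, lam, tau, a, b):
        item = linear_to_theta(LinearItemParams(lam, tau))
        assert item.discrimination == pytest.approx(a, abs=1e-12)
        assert np.allclose(item.thresholds, b, atol=1e-12)

    def test_theta_to_linear_closed_form(self):
        lin = theta_to_linear(ItemParams(0.75, (-2.125, -0.625)))
        assert lin.loading == pytest.approx(0.6, abs=1e-12)
        assert np.allclose(lin.thresholds, (-1.7, -0.5), atol=1e-12)

    def test_zero_discrimination_identity(self):
        lin = theta_to_linear(ItemParams(0.0, (-1.0, 1.0)))
        assert lin.loading == 0.0
        assert lin.thresholds == (-1.0, 1.0)

    def test_invalid_loading_raises(self):
        with pytest.raises(InvalidLoadingError):
            LinearItemParams(1.0, (0.0,))

    @settings(max_examples=100, deadline=None)
    @given(
        lam=st.floats(-0.99, 0.99),
        t0=st.floats(-2.5, 0.0),
        gap=st.floats(0.1, 2.0),
    )
    def test_round_trip_identity(self, lam, t0, gap):
        item = LinearItemParams(lam, (t0, t0 + gap))
        back = theta_to_linear(linear_to_theta(item))
        assert back.loading == pytest.approx(item.loading, abs=1e-10)
        assert np.allclose(back.thresholds, item.thresholds, atol=1e-10)

    def test_error_variance_identity(self):
        item = LinearItemParams(0.7, (-0.5,))
        assert item.error_variance == pytest.approx(1 - 0.49, abs=1e-15)


class TestDefaultTarget:
    def test_shape_and_validity(self):
        spec = default_target_measurement()
        assert spec.n_items == 6
        assert spec.n_categories == 3
        for it in spec.items:
            assert len(it.thresholds) == 2
            assert it.thresholds[0] < it.thresholds[1]
            assert abs(theta_to_linear(it).loading) < 1

    def test_pure_function(self):
        assert default_target_measurement() == default_target_measurement()


class TestAuxiliarySampling:
    def test_determinism(self):
        a = sample_auxiliary_measurement(np.random.default_rng(5))
        b = sample_auxiliary_measurement(np.random.default_rng(5))
        assert a == b

    def test_shape(self, rng):
        spec = sample_auxiliary_measurement(rng)
        assert spec.n_items == 4
        assert spec.n_categories == 5

    def test_threshold_steps_exact(self, rng):
        spec = sample_auxiliary_measurement(rng)
        for it in spec.items:
            lin = theta_to_linear(it)
            offsets = np.array(lin.thresholds) - lin.thresholds[0]
            assert np.allclose(offsets, [0.0, 1.2, 2.4, 3.6], atol=1e-9)

    def test_loading_distribution(self, rng):
        # sampled loadings follow N(0.6, 0.1) truncated to [0.05, 0.95];
        # compare against that distribution's analytic moments
        from scipy.stats import truncnorm

        sd = np.sqrt(0.1)
        a, b = (0.05 - 0.6) / sd, (0.95 - 0.6) / sd
        m_exp, v_exp = truncnorm.stats(a, b, loc=0.6, scale=sd, moments="mv")
        specs = [
            sample_auxiliary_measurement(rng, n_items=20) for _ in range(500)
        ]
        lams = np.array(
            [theta_to_linear(it).loading for s in specs for it in s.items]
        )
        assert lams.mean() == pytest.approx(float(m_exp), abs=0.01)
        assert lams.var() == pytest.approx(float(v_exp), abs=0.005)

    def test_loading_bounds_respected(self, rng):
        for _ in range(50):
            spec = sample_auxiliary_measurement(rng)
            for it in spec.items:
                lam = theta_to_linear(it).loading
                assert 0.05 <= lam <= 0.95


class TestNoninvariance:
    def test_level_zero_identity(self):
        target = default_target_measurement()
        ref, foc = apply_noninvariance(target, "both", 0)
        assert ref.items == foc.items

    def test_loading_halving(self):
        target = default_target_measurement()
        ref, foc = apply_noninvariance(target, "loadings", 2)
        for j in (1, 3):
            assert foc.items[j].discrimination == pytest.approx(
                0.5 * ref.items[j].discrimination
            )
            assert foc.items[j].thresholds == ref.items[j].thresholds
        for j in (0, 2, 4, 5):
            assert foc.items[j] == ref.items[j]

    def test_threshold_shifts(self):
        target = default_target_measurement()
        ref, foc = apply_noninvariance(target, "thresholds", 3)
        for j, shift in zip((1, 3, 5), (0.8, 1.0, 1.2)):
            assert foc.items[j].thresholds[0] == pytest.approx(
                ref.items[j].thresholds[0] - shift
            )
            assert foc.items[j].thresholds[1] == ref.items[j].thresholds[1]
            assert foc.items[j].discrimination == ref.items[j].discrimination

    @pytest.mark.parametrize("typ", ["thresholds", "loadings", "both"])
    @pytest.mark.parametrize("level", [0, 1, 2, 3])
    def test_ordering_preserved_and_count(self, typ, level):
        target = default_target_measurement()
        ref, foc = apply_noninvariance(target, typ, level)
        changed = sum(r != f for r, f in zip(ref.items, foc.items))
        assert changed == level
        for it in foc.items:
            assert it.thresholds[0] < it.thresholds[1]

    def test_level_out_of_range(self):
        with pytest.raises(DesignError):
            apply_noninvariance(default_target_measurement(), "both", 4)

    def test_wrong_item_count(self):
        target = default_target_measurement()
        small = MeasurementSpec(items=target.items[:4], n_categories=3)
        with pytest.raises(DesignError):
            apply_noninvariance(small, "both", 1)


class TestStructural:
    def test_simple_values(self):
        s = population_structural("simple", "predictor")
        assert s.paths(REFERENT)[("X", "Y")] == 0.22
        assert s.residual_variance("Y", REFERENT) == pytest.approx(1 - 0.0484)

    def test_moderation_group_slopes(self):
        s = population_structural("moderation", "criterion")
        assert s.paths(REFERENT)[("X", "Y")] == 0.47
        assert s.paths(FOCAL)[("X", "Y")] == 0.18
        assert s.residual_variance("Y", REFERENT) == pytest.approx(1 - 0.47**2)
        assert s.residual_variance("Y", FOCAL) == pytest.approx(1 - 0.18**2)

    def test_mediation_path_tracing(self):
        s = population_structural("mediation", "mediator")
        cov = s.latent_covariance(REFERENT)
        i, j = s.latent_names.index("X"), s.latent_names.index("Y")
        assert cov[i, j] == pytest.approx(0.22 * -0.22, abs=1e-12)

    def test_partial_residual_two_orthogonal_predictors(self):
        s = population_structural("partial", "criterion")
        assert s.residual_variance("Y", FOCAL) == pytest.approx(
            1 - (0.22**2 + 0.37**2)
        )

    @pytest.mark.parametrize(
        "model, position",
        [
            ("simple", "predictor"),
            ("simple", "criterion"),
            ("partial", "predictor"),
            ("partial", "criterion"),
            ("mediation", "predictor"),
            ("mediation", "mediator"),
            ("mediation", "criterion"),
            ("moderation", "predictor"),
            ("moderation", "criterion"),
        ],
    )
    def test_unit_latent_variances(self, model, position):
        s = population_structural(model, position)
        for g in (REFERENT, FOCAL):
            cov = s.latent_covariance(g)
            assert np.allclose(np.diag(cov), 1.0, atol=1e-12)

    def test_invalid_pairing(self):
        with pytest.raises(DesignError):
            population_structural("simple", "mediator")
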