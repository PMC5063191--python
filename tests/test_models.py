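"""Likelihood, prior and random-effects densities for the six parameterizations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from armnma.data import ArmRecord, NmaDataset
from armnma.models import (
    FIXED_EFFECT_PARAMETERIZATIONS,
    PARAMETERIZATIONS,
    RANDOM_EFFECT_PARAMETERIZATIONS,
    ModelSpec,
    ParameterState,
    contrast_re_trial_logpdf,
    inverse_logit,
    linear_predictor,
    log_likelihood,
    log_posterior,
    log_prior,
    log_random_effects_density,
    nonbase_arm_positions,
)


def _state_for(data, spec, mu=0.0, d=None, delta=None, sigma=1.0):
    """Build a dimensionally correct state, defaulting deltas to their means."""
    mu_vec = np.full(data.n_trials, mu, dtype=float)
    d_vec = np.zeros(data.n_treatments) if d is None else np.asarray(d, float)
    if spec.parameterization in ("arm_re", "arm_re_tx"):
        dl = d_vec[data.treatment_index] if delta is None else np.asarray(delta)
    elif spec.parameterization == "contrast_re":
        nb = nonbase_arm_positions(data)
        dl = (
            d_vec[data.treatment_index[nb]] - d_vec[data.arm_base_treatment[nb]]
            if delta is None
            else np.asarray(delta)
        )
    else:
        dl = np.empty(0)
    sig = np.full(spec.n_sigma(data), sigma)
    return ParameterState(mu=mu_vec, d=d_vec, delta=dl, sigma=sig)


@pytest.fixture(scope="module")
def three_arm_trial():
    return NmaDataset.from_arms(
        [
            ArmRecord("s1", "A", 5, 50),
            ArmRecord("s1", "B", 9, 50),
            ArmRecord("s1", "C", 12, 50),
        ],
        reference_treatment="A",
    )


class TestInverseLogit:
    def test_symmetry_point(self):
        assert inverse_logit(0.0) == 0.5

    def test_closed_form(self):
        assert inverse_logit(math.log(3.0)) == pytest.approx(0.75, abs=1e-12)

    def test_no_underflow_in_likelihood_path(self, one_trial_dataset):
        spec = ModelSpec("arm_fe")
        state = _state_for(one_trial_dataset, spec, mu=-40.0)
        assert inverse_logit(-40.0) > 0.0
        assert np.isfinite(log_likelihood(state, one_trial_dataset, spec))

    @given(st.floats(-30, 30))
    def test_monotone_and_bounded(self, eta):
        p = inverse_logit(eta)
        assert 0.0 < p < 1.0
        assert inverse_logit(eta + 0.5) > p


class TestLinearPredictor:
    def test_contrast_fe_three_arm_hand_expansion(self, three_arm_trial):
        # consistency relation: d_bk = d_1k - d_1b with b the base arm
        spec = ModelSpec("contrast_fe")
        state = _state_for(three_arm_trial, spec, mu=-1.0, d=[0.0, 0.5, 1.0])
        np.testing.assert_allclose(
            linear_predictor(state, three_arm_trial, spec), [-1.0, -0.5, 0.0]
        )

    def test_arm_fe_reference_arm_is_baseline(self, one_trial_dataset):
        spec = ModelSpec("arm_fe")
        state = _state_for(one_trial_dataset, spec, mu=0.7, d=[0.0, 1.1])
        eta = linear_predictor(state, one_trial_dataset, spec)
        assert eta[0] == pytest.approx(0.7)
        assert eta[1] == pytest.approx(1.8)

    def test_baseshift_reparameterization_identity(self, small_mixed_dataset):
        # mu' = mu + d_b gives identical linear predictors
        data = small_mixed_dataset
        d = np.array([0.0, 0.3, 0.6, 0.9])
        plain = _state_for(data, ModelSpec("arm_fe"), mu=-1.0, d=d)
        shifted_mu = plain.mu + d[data.trial_base_treatment]
        shifted = ParameterState(mu=shifted_mu, d=d.copy())
        np.testing.assert_allclose(
            linear_predictor(plain, data, ModelSpec("arm_fe")),
            linear_predictor(shifted, data, ModelSpec("arm_fe_baseshift")),
            atol=1e-12,
        )

    def test_dimension_mismatch_raises(self, three_arm_trial):
        spec = ModelSpec("arm_fe")
        state = _state_for(three_arm_trial, spec)
        state.mu = np.zeros(5)
        with pytest.raises(ValueError, match="mu has shape"):
            linear_predictor(state, three_arm_trial, spec)

    @pytest.mark.parametrize("para", PARAMETERIZATIONS)
    def test_consistency_closure_at_random_effect_means(
        self, small_mixed_dataset, para
    ):
        """With random effects at their means, any within-trial contrast of
        linear predictors equals d_1k - d_1k'."""
        data = small_mixed_dataset
        spec = ModelSpec(para)
        d = np.array([0.0, 0.4, 0.9, 1.3])
        state = _state_for(data, spec, mu=-0.8, d=d)
        eta = linear_predictor(state, data, spec)
        for j in range(data.n_trials):
            arms = data.trial_arms(j)
            for a in arms:
                for b in arms:
                    implied = eta[a] - eta[b]
                    expected = (
                        d[data.treatment_index[a]] - d[data.treatment_index[b]]
                    )
                    assert implied == pytest.approx(expected, abs=1e-10)


class TestLogLikelihood:
    def test_closed_form_single_binomial(self):
        data = NmaDataset.from_arms(
            [ArmRecord("s", "A", 1, 2), ArmRecord("s", "B", 1, 2)],
            reference_treatment="A",
        )
        spec = ModelSpec("arm_fe")
        state = _state_for(data, spec)  # eta = 0 -> p = 1/2 for both arms
        assert log_likelihood(state, data, spec) == pytest.approx(
            2.0 * math.log(0.5), abs=1e-12
        )

    def test_degenerate_limit_zero_events(self):
        data = NmaDataset.from_arms(
            [ArmRecord("s", "A", 0, 10), ArmRecord("s", "B", 0, 10)],
            reference_treatment="A",
        )
        spec = ModelSpec("arm_fe")
        state = _state_for(data, spec, mu=-35.0)
        assert log_likelihood(state, data, spec) == pytest.approx(0.0, abs=1e-9)

    def test_additivity_under_dataset_doubling(self, smoking_reduced):
        spec = ModelSpec("arm_fe")
        state = _state_for(smoking_reduced, spec, mu=-1.0, d=[0.0, 0.2, 0.5, 0.8])
        doubled_arms = [
            ArmRecord(f"{a.study} ({copy})", a.treatment, a.events, a.size)
            for copy in ("a", "b")
            for a in smoking_reduced.arms
        ]
        doubled = NmaDataset.from_arms(
            doubled_arms,
            "no_contact",
            treatment_order=smoking_reduced.coding.labels,
        )
        state2 = _state_for(doubled, spec, mu=-1.0, d=[0.0, 0.2, 0.5, 0.8])
        assert log_likelihood(state2, doubled, spec) == pytest.approx(
            2.0 * log_likelihood(state, smoking_reduced, spec), rel=1e-12
        )


class TestRandomEffectsDensity:
    def test_two_arm_trial_reduces_to_plain_normal(self):
        # first conditional: variance sigma^2 * 2/2 = sigma^2
        val = contrast_re_trial_logpdf(np.array([0.3]), np.array([0.5]), 0.8)
        assert val == pytest.approx(
            stats.norm.logpdf(0.3, 0.5, 0.8), abs=1e-12
        )

    @pytest.mark.parametrize("n_contrasts", [1, 2, 3])
    def test_conditional_factorization_matches_mvn_oracle(self, n_contrasts):
        """Conditional-univariate construction equals the joint multivariate
        normal with variance sigma^2 and covariance sigma^2/2 (trials of
        2, 3 and 4 arms)."""
        rng = np.random.default_rng(7)
        sigma = 0.73
        for _ in range(5):
            deltas = rng.normal(size=n_contrasts)
            means = rng.normal(size=n_contrasts)
            cov = np.full((n_contrasts, n_contrasts), sigma**2 / 2.0)
            np.fill_diagonal(cov, sigma**2)
            oracle = stats.multivariate_normal.logpdf(deltas, means, cov)
            ours = contrast_re_trial_logpdf(deltas, means, sigma)
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_arm_re_density_at_mode(self, one_trial_dataset):
        # each arm effect at its mean contributes log N(0 | 0, 1/2)
        spec = ModelSpec("arm_re")
        state = _state_for(one_trial_dataset, spec, d=[0.0, 0.4], sigma=1.0)
        expected = one_trial_dataset.n_arms * math.log(
            1.0 / math.sqrt(2.0 * math.pi * 0.5)
        )
        assert log_random_effects_density(
            state, one_trial_dataset, spec
        ) == pytest.approx(expected, abs=1e-12)

    def test_arm_re_tx_with_equal_sigmas_reduces_to_arm_re(
        self, small_mixed_dataset
    ):
        data = small_mixed_dataset
        rng = np.random.default_rng(3)
        d = np.array([0.0, 0.3, 0.6, 0.9])
        delta = rng.normal(size=data.n_arms)
        common = ParameterState(
            mu=np.zeros(data.n_trials), d=d, delta=delta, sigma=[0.62]
        )
        per_treatment = ParameterState(
            mu=np.zeros(data.n_trials),
            d=d,
            delta=delta,
            sigma=np.full(4, 0.62),
        )
        assert log_random_effects_density(
            per_treatment, data, ModelSpec("arm_re_tx")
        ) == pytest.approx(
            log_random_effects_density(common, data, ModelSpec("arm_re")),
            abs=1e-12,
        )

    def test_contrast_re_matches_scipy_on_network(self, small_mixed_dataset):
        data = small_mixed_dataset
        spec = ModelSpec("contrast_re")
        rng = np.random.default_rng(11)
        d = np.array([0.0, 0.2, 0.6, 1.1])
        delta = rng.normal(size=spec.n_delta(data))
        state = _state_for(data, spec, d=d, delta=delta, sigma=0.9)
        nb = nonbase_arm_positions(data)
        expected = 0.0
        pos = {int(i): idx for idx, i in enumerate(nb)}
        for j in range(data.n_trials):
            arms = [int(i) for i in data.trial_arms(j) if int(i) in pos]
            L = len(arms)
            means = (
                d[data.treatment_index[arms]] - d[data.trial_base_treatment[j]]
            )
            cov = np.full((L, L), 0.9**2 / 2)
            np.fill_diagonal(cov, 0.9**2)
            expected += stats.multivariate_normal.logpdf(
                delta[[pos[i] for i in arms]], means, cov
            )
        assert log_random_effects_density(state, data, spec) == pytest.approx(
            expected, abs=1e-10
        )

    def test_fixed_effects_spec_refuses(self, one_trial_dataset):
        spec = ModelSpec("arm_fe")
        state = _state_for(one_trial_dataset, spec)
        with pytest.raises(ValueError, match="fixed-effects"):
            log_random_effects_density(state, one_trial_dataset, spec)


class TestPriorAndPosterior:
    def test_sigma_outside_support_is_minus_inf(self, one_trial_dataset):
        spec = ModelSpec("arm_re", prior_sigma_upper=5.0)
        state = _state_for(one_trial_dataset, spec, sigma=5.1)
        assert log_prior(state, spec) == -math.inf
        assert log_posterior(state, one_trial_dataset, spec) == -math.inf

    def test_prior_closed_form_at_zero(self, one_trial_dataset):
        spec = ModelSpec("arm_re")
        state = _state_for(one_trial_dataset, spec, sigma=1.0)
        # J mu terms + 1 free d term + uniform sigma term
        expected = (one_trial_dataset.n_trials + 1) * stats.norm.logpdf(
            0.0, 0.0, 100.0
        ) - math.log(5.0)
        assert log_prior(state, spec) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("para", FIXED_EFFECT_PARAMETERIZATIONS)
    def test_fe_posterior_is_likelihood_plus_prior(self, small_mixed_dataset, para):
        spec = ModelSpec(para)
        state = _state_for(small_mixed_dataset, spec, mu=-0.5, d=[0, 0.1, 0.2, 0.3])
        assert log_posterior(state, small_mixed_dataset, spec) == pytest.approx(
            log_likelihood(state, small_mixed_dataset, spec)
            + log_prior(state, spec),
            rel=1e-12,
        )

    def test_baseshift_corresponding_states_differ_only_in_mu_prior(
        self, small_mixed_dataset
    ):
        data = small_mixed_dataset
        d = np.array([0.0, 0.3, 0.6, 0.9])
        plain = _state_for(data, ModelSpec("arm_fe"), mu=-1.0, d=d)
        shifted = ParameterState(
            mu=plain.mu + d[data.trial_base_treatment], d=d.copy()
        )
        lp_plain = log_posterior(plain, data, ModelSpec("arm_fe"))
        lp_shift = log_posterior(shifted, data, ModelSpec("arm_fe_baseshift"))
        prior_gap = log_prior(plain, ModelSpec("arm_fe")) - log_prior(
            shifted, ModelSpec("arm_fe_baseshift")
        )
        assert lp_plain - lp_shift == pytest.approx(prior_gap, abs=1e-9)

    def test_prior_invariant_to_trial_permutation(self, smoking_reduced):
        spec = ModelSpec("contrast_fe")
        rng = np.random.default_rng(5)
        mu = rng.normal(size=smoking_reduced.n_trials)
        d = np.array([0.0, 0.2, 0.5, 0.9])
        a = ParameterState(mu=mu, d=d)
        b = ParameterState(mu=mu[rng.permutation(len(mu))], d=d)
        assert log_prior(a, spec) == pytest.approx(log_prior(b, spec), rel=1e-12)


class TestModelSpec:
    def test_unknown_parameterization_rejected(self):
        with pytest.raises(ValueError, match="unknown parameterization"):
            ModelSpec("arm_gibberish")

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            ModelSpec("arm_fe", prior_sd_mu=0.0)

    def test_dict_round_trip(self):
        spec = ModelSpec("arm_re_tx", prior_sigma_upper=2.5)
        assert ModelSpec.from_dict(spec.to_dict()) == spec

    @pytest.mark.parametrize(
        "para,expected_re", [(p, p in RANDOM_EFFECT_PARAMETERIZATIONS) for p in PARAMETERIZATIONS]
    )
    def test_random_effects_flag(self, para, expected_re):
        assert ModelSpec(para).is_random_effects is expected_re
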