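import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr
from scipy.stats import truncnorm

from phenocal.misclassification import ErrorRates
from phenocal.threshold import (
    LiabilityRecord,
    ThresholdConfig,
    gibbs_threshold,
    heritability_summary,
    record_likelihood,
    sample_delta_and_liability,
    threshold_from_incidence,
)


class TestThresholdFromIncidence:
    def test_median_incidence_gives_zero(self):
        assert threshold_from_incidence(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_normal_quantile_oracle(self):
        from scipy.stats import norm

        assert threshold_from_incidence(0.2006) == pytest.approx(norm.ppf(1 - 0.2006))
        assert threshold_from_incidence(0.2006) == pytest.approx(0.8395, abs=5e-4)

    def test_monotone_decreasing_in_incidence(self):
        qs = np.linspace(0.05, 0.95, 19)
        taus = [threshold_from_incidence(q) for q in qs]
        assert all(a > b for a, b in zip(taus, taus[1:]))

    @pytest.mark.parametrize("q", [0.0, 1.0])
    def test_degenerate_incidence_rejected(self, q):
        with pytest.raises(ValueError):
            threshold_from_incidence(q)


class TestRecordLikelihood:
    def test_perfect_rates_reduce_to_standard_threshold_likelihood(self):
        rec = LiabilityRecord(observed_status=1, linear_predictor=0.3)
        p = record_likelihood(rec, tau=0.84, rates=ErrorRates(1, 1))
        assert p == pytest.approx(float(ndtr(0.3 - 0.84)))

    def test_balanced_record_arithmetic(self):
        # tau = linear predictor, fn 0.1 / fp 0.2: p(y*=1) = 0.9*0.5 + 0.2*0.5
        rec = LiabilityRecord(observed_status=1, linear_predictor=0.0)
        p = record_likelihood(rec, tau=0.0, rates=ErrorRates(0.9, 0.8))
        assert p == pytest.approx(0.55)

    def test_observed_classes_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            m, tau = rng.normal(size=2) * 2
            rates = ErrorRates(rng.uniform(0.5, 1), rng.uniform(0.5, 1))
            p1 = record_likelihood(LiabilityRecord(1, m), tau, rates)
            p0 = record_likelihood(LiabilityRecord(0, m), tau, rates)
            assert p1 + p0 == pytest.approx(1.0, abs=1e-12)

    def test_equal_rates_match_single_parameter_form(self):
        """With fp = fn = pi the likelihood collapses to the common-pi model."""
        rng = np.random.default_rng(1)
        pi = 0.15
        rates = ErrorRates(sensitivity=1 - pi, specificity=1 - pi)
        for _ in range(100):
            m, tau = rng.normal(size=2)
            p1_model = record_likelihood(LiabilityRecord(1, m), tau, rates)
            p1_single = (1 - pi) * ndtr(m - tau) + pi * ndtr(tau - m)
            assert p1_model == pytest.approx(float(p1_single), abs=1e-12)


class TestSampleDeltaAndLiability:
    def test_perfect_rates_force_observed_side(self):
        rng = np.random.default_rng(0)
        for status in (0, 1):
            rec = LiabilityRecord(observed_status=status, linear_predictor=0.2)
            for _ in range(50):
                delta, eta = sample_delta_and_liability(rec, 0.84, ErrorRates(1, 1), rng)
                assert delta == 0
                assert (eta > 0.84) == bool(status)

    def test_delta_rate_matches_two_state_enumeration(self):
        """Marginal P(delta=1 | y*=1) against the exact two-state posterior."""
        tau, rates = 0.84, ErrorRates(0.9, 0.8)
        rec = LiabilityRecord(observed_status=1, linear_predictor=0.0)
        p1 = float(ndtr(0.0 - tau))
        w_true1 = rates.sensitivity * p1
        w_true0 = rates.false_positive * (1 - p1)
        expected = w_true0 / (w_true0 + w_true1)  # true negative => delta
        rng = np.random.default_rng(42)
        n = 100_000
        deltas = sum(
            sample_delta_and_liability(rec, tau, rates, rng)[0] for _ in range(n)
        )
        assert deltas / n == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / n))

    def test_truncated_draws_match_truncnorm_moments(self):
        rng = np.random.default_rng(7)
        rec = LiabilityRecord(observed_status=1, linear_predictor=-0.5)
        draws = np.array(
            [sample_delta_and_liability(rec, 0.84, ErrorRates(1, 1), rng)[1] for _ in range(40_000)]
        )
        ref = truncnorm(0.84 - (-0.5), np.inf, loc=-0.5)
        assert draws.mean() == pytest.approx(ref.mean(), abs=0.02)
        assert draws.std() == pytest.approx(ref.std(), rel=0.05)

    def test_fixed_seed_reproducible(self):
        rec = LiabilityRecord(observed_status=1, linear_predictor=0.1)
        a = sample_delta_and_liability(rec, 0.8, ErrorRates(0.9, 0.8), np.random.default_rng(5))
        b = sample_delta_and_liability(rec, 0.8, ErrorRates(0.9, 0.8), np.random.default_rng(5))
        assert a == b


class TestGibbsThreshold:
    def test_same_seed_bit_identical_chains(self, study_trait, study_design):
        mm, A, Ainv = study_design
        cfg = ThresholdConfig(iterations=400, burn_in=100, thin=5, seed=3)
        y = study_trait.y_true.astype(int)
        a = gibbs_threshold(y, mm, Ainv, cfg)
        b = gibbs_threshold(y, mm, Ainv, cfg)
        pd.testing.assert_frame_equal(a.chain, b.chain)
        assert np.array_equal(a.effects["u_mean"], b.effects["u_mean"])

    def test_single_class_rejected(self, study_design):
        mm, A, Ainv = study_design
        with pytest.raises(ValueError, match="each observed class"):
            gibbs_threshold(np.ones(mm.n_records, dtype=int), mm, Ainv, ThresholdConfig())

    def test_posterior_delta_rate_tracks_injected_misclassification(
        self, study_trait, study_design
    ):
        """Known unequal rates: posterior misclassification fraction near the
        injected expectation 0.2*(1-q) + 0.1*q ~= 0.18."""
        from phenocal.simulate import inject_misclassification

        mm, A, Ainv = study_design
        rng = np.random.default_rng(99)
        y_obs = inject_misclassification(study_trait.y_true, (0.2, 0.1), rng).astype(int)
        cfg = ThresholdConfig(
            iterations=4000, burn_in=1000, seed=12, error_rates=ErrorRates(0.9, 0.8)
        )
        out = gibbs_threshold(y_obs, mm, Ainv, cfg)
        q = study_trait.incidence
        expected = 0.2 * (1 - q) + 0.1 * q
        assert out.mean("prop_delta") == pytest.approx(expected, abs=0.05)

    def test_perfect_rates_posterior_matches_standard_threshold_model(
        self, study_trait, study_design
    ):
        """rates=(1,1) must reproduce the no-misclassification sampler exactly:
        with the same seed the delta indicators are degenerate at 0 and the
        chain is the standard threshold chain."""
        mm, A, Ainv = study_design
        y = study_trait.y_true.astype(int)
        cfg = ThresholdConfig(iterations=2000, burn_in=500, seed=8)
        out = gibbs_threshold(y, mm, Ainv, cfg)
        assert float(out.chain["prop_delta"].max()) == 0.0
        assert out.chain["incidence"].nunique() == 1

    def test_rate_estimation_stays_identified(self, study_trait, study_design):
        from phenocal.simulate import inject_misclassification

        mm, A, Ainv = study_design
        rng = np.random.default_rng(5)
        y_obs = inject_misclassification(study_trait.y_true, (0.2, 0.1), rng).astype(int)
        cfg = ThresholdConfig(
            iterations=3000, burn_in=1000, seed=4, estimate_rates=True,
            incidence=float(study_trait.incidence),
        )
        out = gibbs_threshold(y_obs, mm, Ainv, cfg)
        assert (out.chain["pi11"] + out.chain["pi00"]).min() > 1.0
        assert 0.5 < out.mean("pi00") <= 1.0


class TestHeritabilitySummary:
    def test_constant_chain(self):
        chain = pd.DataFrame({"sigma_u2": [2 / 3] * 10})
        s = heritability_summary(chain)
        assert s.loc["h2_liability", "mean"] == pytest.approx(0.4)
        assert s.loc["h2_liability", "sd"] == 0.0

    def test_two_value_chain_arithmetic(self):
        chain = pd.DataFrame({"sigma_u2": [0.25, 0.75]})
        s = heritability_summary(chain)
        assert s.loc["h2_liability", "mean"] == pytest.approx((0.2 + 0.75 / 1.75) / 2)

    def test_invariant_under_trivial_thinning(self):
        chain = pd.DataFrame({"sigma_u2": np.linspace(0.1, 1.0, 50)})
        a = heritability_summary(chain)
        b = heritability_summary(chain.iloc[::1])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            heritability_summary(pd.DataFrame({"sigma_u2": []}))
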