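"""Information-theoretic estimators: KSG/Ross MI, entropy, Blahut-Arimoto,
the capacity heuristic, and the likelihood-based error rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nfkbcap as nc
from nfkbcap.exceptions import DegenerateInputError, InvalidDistributionError
from nfkbcap.info_metrics import blahut_arimoto, discrete_entropy

from conftest import gaussian_toy_channel


def gaussian_mi_bits(rho):
    return -0.5 * np.log2(1.0 - rho ** 2)


class TestDiscreteEntropy:
    @pytest.mark.parametrize("p, expected", [
        ((0.5, 0.5), 1.0),
        ((0.25, 0.25, 0.25, 0.25), 2.0),
        ((1.0, 0.0), 0.0),
    ])
    def test_closed_forms(self, p, expected):
        assert discrete_entropy(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(-0.1, 1.1), (0.4, 0.4)])
    def test_invalid_distributions_rejected(self, bad):
        with pytest.raises(InvalidDistributionError):
            discrete_entropy(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=8))
    def test_bounds_and_permutation_invariance(self, weights):
        p = np.array(weights) / np.sum(weights)
        h = discrete_entropy(p)
        assert -1e-9 <= h <= np.log2(len(p)) + 1e-9
        assert discrete_entropy(p[::-1]) == pytest.approx(h, abs=1e-12)


class TestKnnMutualInformation:
    def test_independent_samples_near_zero(self):
        rng = np.random.default_rng(0)
        est = nc.knn_mutual_information(rng.normal(size=2000), rng.normal(size=2000))
        assert abs(est.raw_value) < 0.05

    def test_bivariate_gaussian_closed_form(self):
        rho, n = 0.9, 5000
        rng = np.random.default_rng(1)
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        est = nc.knn_mutual_information(x, y)
        assert est.value == pytest.approx(gaussian_mi_bits(rho), abs=0.05)

    def test_agreement_with_reference_implementation(self):
        sklearn = pytest.importorskip("sklearn.feature_selection")
        rng = np.random.default_rng(2)
        x = rng.normal(size=1500)
        y = 0.8 * x + 0.6 * rng.normal(size=1500)
        ours = nc.knn_mutual_information(x, y).value
        ref = sklearn.mutual_info_regression(
            x.reshape(-1, 1), y, n_neighbors=3, random_state=0)[0] / np.log(2)
        assert ours == pytest.approx(ref, abs=0.02)

    def test_discrete_continuous_near_noiseless_channel(self):
        rng = np.random.default_rng(3)
        labels = np.arange(2000) % 2
        y = labels + rng.normal(0.0, 1e-6, size=2000)
        est = nc.knn_mutual_information(labels, y, variant="discrete-continuous")
        assert est.value == pytest.approx(1.0, abs=0.03)

    def test_discrete_continuous_matches_reference(self):
        sklearn = pytest.importorskip("sklearn.feature_selection")
        rng = np.random.default_rng(4)
        labels = np.arange(1200) % 3
        y = labels + rng.normal(0.0, 0.7, size=1200)
        ours = nc.knn_mutual_information(labels, y, variant="discrete-continuous").value
        ref = sklearn.mutual_info_classif(
            y.reshape(-1, 1), labels, n_neighbors=3, random_state=0)[0] / np.log(2)
        assert ours == pytest.approx(ref, abs=0.02)

    def test_symmetry_of_continuous_variant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = x + rng.normal(size=500)
        assert (nc.knn_mutual_information(x, y).value
                == pytest.approx(nc.knn_mutual_information(y, x).value, abs=1e-12))

    def test_invariance_under_monotone_transforms(self):
        """Underwrites comparing absolute vs fold-change responses: strictly
        monotone rescalings of either margin leave the estimate unchanged
        within sampling error."""
        rho, n = 0.8, 2000
        rng = np.random.default_rng(6)
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
        base = nc.knn_mutual_information(x, y).value
        assert nc.knn_mutual_information(np.exp(x), y).value == pytest.approx(base, abs=0.05)
        assert nc.knn_mutual_information(x, 2 * y + 1).value == pytest.approx(base, abs=0.05)

    def test_estimator_bias_shrinks_with_sample_size(self):
        rho = 0.6
        errors = []
        for n in (500, 5000):
            rng = np.random.default_rng(7)
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            errors.append(abs(nc.knn_mutual_information(x, y).value - gaussian_mi_bits(rho)))
        assert errors[1] < errors[0]

    def test_degenerate_margin_rejected(self):
        x = np.ones(100)
        y = np.arange(100.0)
        with pytest.raises(DegenerateInputError):
            nc.knn_mutual_information(x, y)

    def test_tied_responses_handled_in_discrete_variant(self):
        # half the population sits exactly at a shared resting level
        rng = np.random.default_rng(8)
        labels = np.arange(400) % 2
        y = np.where(labels == 0, 0.5, 1.0 + rng.normal(0, 0.01, 400))
        est = nc.knn_mutual_information(labels, y, variant="discrete-continuous")
        assert est.value == pytest.approx(1.0, abs=0.05)


class TestBlahutArimoto:
    def test_noiseless_binary_channel(self):
        assert blahut_arimoto(np.eye(2)) == pytest.approx(1.0, abs=1e-9)

    def test_useless_channel(self):
        assert blahut_arimoto([[0.5, 0.5], [0.5, 0.5]]) == pytest.approx(0.0, abs=1e-9)

    def test_binary_symmetric_channel_closed_form(self):
        f = 0.11
        h2 = -(f * np.log2(f) + (1 - f) * np.log2(1 - f))
        cap = blahut_arimoto([[1 - f, f], [f, 1 - f]])
        assert cap == pytest.approx(1.0 - h2, abs=1e-6)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(InvalidDistributionError):
            blahut_arimoto([[0.5, 0.6], [0.5, 0.5]])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_capacity_bounded_by_alphabet_entropy(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.dirichlet(np.ones(4), size=3)
        cap = blahut_arimoto(P)
        assert -1e-9 <= cap <= np.log2(3) + 1e-9


def discretized_capacity(sigma, n_in=64, n_out=64, lo=-0.5, hi=1.5):
    """Independent oracle: Blahut-Arimoto on a discretized version of the
    additive-Gaussian activation channel."""
    from scipy.stats import norm

    inputs = np.linspace(0.0, 1.0, n_in)
    edges = np.linspace(lo, hi, n_out + 1)
    P = np.array([np.diff(norm.cdf(edges, loc=m, scale=sigma)) for m in inputs])
    P /= P.sum(axis=1, keepdims=True)
    return blahut_arimoto(P)


class TestCapacityHeuristic:
    def test_uninformative_channel_stops_early(self, synthetic_curve):
        def channel(probe, n_per_level, rng):
            labels = np.repeat(np.arange(probe.n_levels), n_per_level)
            return labels, rng.normal(size=len(labels))

        est = nc.estimate_channel_capacity(channel, synthetic_curve,
                                           {"n_per_level": 400, "seed": 0})
        assert est.capacity <= 0.1
        assert est.n_at_max in (2, 3)
        assert est.stopping_reason == "plateau"

    def test_perfectly_resolvable_four_levels(self, synthetic_curve):
        est = nc.estimate_channel_capacity(
            gaussian_toy_channel(1e-4), synthetic_curve,
            {"n_per_level": 400, "max_n": 4, "seed": 1})
        assert est.capacity == pytest.approx(2.0, abs=0.05)
        assert est.stopping_reason == "max_n"

    @pytest.mark.parametrize("sigma", [0.01, 0.05, 0.1, 0.25])
    def test_agreement_with_blahut_arimoto_oracle(self, synthetic_curve, sigma):
        est = nc.estimate_channel_capacity(
            gaussian_toy_channel(sigma), synthetic_curve,
            {"n_per_level": 600, "seed": 2})
        oracle = discretized_capacity(sigma)
        assert est.capacity == pytest.approx(oracle, abs=0.15)

    def test_mutual_information_bounded_by_prior_entropy(self, synthetic_curve):
        est = nc.estimate_channel_capacity(
            gaussian_toy_channel(0.05), synthetic_curve,
            {"n_per_level": 300, "seed": 3})
        for n, mi in est.mi_by_n.items():
            assert mi.value <= np.log2(n) + 0.05
        assert est.capacity == max(m.value for m in est.mi_by_n.values())

    def test_saturation_diagnostic_licenses_increments(self, synthetic_curve):
        est = nc.estimate_channel_capacity(
            gaussian_toy_channel(0.01), synthetic_curve,
            {"n_per_level": 300, "max_n": 4, "seed": 4})
        # a near-noiseless channel resolves every probed alphabet
        assert est.saturated[2] and est.saturated[3]


class TestDiscriminationErrorRates:
    def test_disjoint_supports_are_error_free(self):
        rng = np.random.default_rng(0)
        er = nc.discrimination_error_rates(
            rng.normal(0, 1, 500), rng.normal(100, 1, 500))
        assert er.false_positive_pct == 0.0
        assert er.false_negative_pct == 0.0

    def test_identical_distributions_split_all_mass(self):
        """When both classes share one distribution the task is hopeless:
        essentially every sample is a coin flip, so the two error rates sum
        to ~100%.  (The split between them fluctuates more than binomially
        because kernel-density decisions are correlated through the shared
        density surfaces.)"""
        rng = np.random.default_rng(1)
        er = nc.discrimination_error_rates(
            rng.normal(size=2000), rng.normal(size=2000), seed=0)
        total = er.false_positive_pct + er.false_negative_pct
        # slightly above 100 on average: the own-class density is fit
        # leave-one-out (n-1 points) while the cross density uses all n
        assert 90.0 < total < 115.0
        assert 25.0 < er.false_positive_pct < 80.0
        assert 25.0 < er.false_negative_pct < 80.0

    def test_unit_shifted_gaussians_match_phi_oracle(self):
        # misclassification beyond the midpoint of N(0,1) vs N(2,1)
        rng = np.random.default_rng(2)
        er = nc.discrimination_error_rates(
            rng.normal(0, 1, 5000), rng.normal(2, 1, 5000), seed=0)
        expected = 15.87  # 100 * Phi(-1)
        assert er.false_positive_pct == pytest.approx(expected, abs=1.5)
        assert er.false_negative_pct == pytest.approx(expected, abs=1.5)

    def test_zero_variance_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            nc.discrimination_error_rates(np.ones(200), np.arange(200.0))

    def test_log_scale_variant(self):
        rng = np.random.default_rng(3)
        low = np.exp(rng.normal(0.0, 0.3, 1000))
        high = np.exp(rng.normal(2.0, 0.3, 1000))
        er = nc.discrimination_error_rates(low, high, bandwidth_rule="silverman-log")
        assert er.false_positive_pct < 1.0 and er.false_negative_pct < 1.0
        with pytest.raises(ValueError):
            nc.discrimination_error_rates(-low, high, bandwidth_rule="silverman-log")

    def test_appreciable_errors_imply_low_capacity(self, synthetic_curve):
        """Two-anchor confusion appears together with capacity near or
        below one bit on the same channel family."""
        for sigma in (0.02, 0.4):
            rng = np.random.default_rng(4)
            low = rng.normal(0.0, sigma, 1000)
            high = rng.normal(1.0, sigma, 1000)
            er = nc.discrimination_error_rates(low, high, seed=0)
            est = nc.estimate_channel_capacity(
                gaussian_toy_channel(sigma), synthetic_curve,
                {"n_per_level": 400, "seed": 5})
            total_error = er.false_positive_pct + er.false_negative_pct
            if total_error > 5.0:
                assert est.capacity < 1.05
            else:
                assert est.capacity > 1.05
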