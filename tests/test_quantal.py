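import numpy as np
import pytest
from scipy import stats

from svquant import (
    BetaDecayModel,
    QuantalMixtureModel,
    compare_distributions,
    fit_beta_decay,
    fit_noise_gaussian,
    fit_quantal_mixture,
    multivesicular_fraction,
)


def mixture_sample(rng, n, weights, means, sds):
    counts = rng.multinomial(n, weights)
    return np.concatenate(
        [rng.normal(m, s, c) for m, s, c in zip(means, sds, counts)]
    )


def calibration_sample(rng, mean=623.0, sd=122.0, n=1178):
    """Single-vesicle calibration: fit of the 1q Gaussian on its own sample."""
    s = rng.normal(mean, sd, n)
    return float(s.mean()), float(s.std(ddof=1))


class TestNoiseGaussian:
    def test_recovers_zero_centered_noise(self):
        rng = np.random.default_rng(0)
        mean, sd, chi2 = fit_noise_gaussian(rng.normal(0.0, 212.0, 10_000))
        assert abs(mean) < 10
        assert abs(sd - 212.0) < 10
        assert chi2 > 0

    def test_symmetrized_input_centers_at_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100.0, 50.0, 3000)
        mean, _, _ = fit_noise_gaussian(np.concatenate([x, -x]))
        assert abs(mean) < 5

    def test_recovers_quantal_peak(self):
        rng = np.random.default_rng(2)
        mean, sd, _ = fit_noise_gaussian(rng.normal(623.0, 122.0, 5000))
        assert abs(mean - 623) / 623 < 0.05
        assert abs(sd - 122) / 122 < 0.05

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="identical"):
            fit_noise_gaussian(np.full(100, 5.0))


class TestQuantalMixture:
    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(3)
        res = fit_quantal_mixture(rng.normal(623.0, 122.0, 1200), q_init=600.0)
        assert res.n_components == 1
        assert abs(res.q - 623) / 623 < 0.03

    def test_two_component_weight_recovery(self):
        rng = np.random.default_rng(4)
        x = mixture_sample(rng, 1200, (0.83, 0.17), (623, 834), (122, 111))
        res = fit_quantal_mixture(x, calibration=calibration_sample(rng))
        assert res.n_components == 2
        assert res.multivesicular_fraction() == pytest.approx(0.17, abs=0.06)
        assert 1.1 <= res.c <= 1.6

    def test_three_component_third_mean_is_exactly_2q(self):
        rng = np.random.default_rng(5)
        x = mixture_sample(
            rng, 1100, (0.30, 0.35, 0.35), (623, 834, 1246), (91, 111, 182)
        )
        res = fit_quantal_mixture(
            x, calibration=calibration_sample(rng, sd=91.0)
        )
        assert res.n_components == 3
        assert res.means[-1] == 2 * res.q  # hard constraint, exact arithmetic
        assert res.multivesicular_fraction() == pytest.approx(0.70, abs=0.07)

    def test_weights_on_simplex_and_mean_ratios(self):
        rng = np.random.default_rng(6)
        x = mixture_sample(rng, 1100, (0.3, 0.35, 0.35), (623, 834, 1246), (91, 111, 182))
        res = QuantalMixtureModel(x, calibration=(623.0, 91.0)).fit()
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.weights >= 0)
        np.testing.assert_allclose(
            res.means / res.q, (1.0, res.c, 2.0)[: res.n_components]
        )

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        x = mixture_sample(rng, 1200, (0.83, 0.17), (623, 834), (122, 111))
        r1 = fit_quantal_mixture(x, calibration=(623.0, 122.0))
        r2 = fit_quantal_mixture(rng.permutation(x), calibration=(623.0, 122.0))
        np.testing.assert_allclose(r1.weights, r2.weights, atol=1e-6)

    def test_multivesicular_fraction_helper(self):
        rng = np.random.default_rng(8)
        res = fit_quantal_mixture(rng.normal(623.0, 122.0, 1200))
        assert multivesicular_fraction(res) == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 100"):
            fit_quantal_mixture(np.random.default_rng(0).normal(0, 1, 50))

    def test_component_count_selection_rate(self):
        # selected component count matches the generative truth in >= 80%
        # of replicate datasets per scenario
        scenarios = {
            1: ((1.0,), (623,), (122,)),
            2: ((0.83, 0.17), (623, 834), (122, 111)),
            3: ((0.30, 0.35, 0.35), (623, 834, 1246), (91, 111, 182)),
        }
        n_rep = 50
        for true_k, (w, m, s) in scenarios.items():
            correct = 0
            for rep in range(n_rep):
                rng = np.random.default_rng(1000 * true_k + rep)
                x = mixture_sample(rng, 1200 if true_k < 3 else 1100, w, m, s)
                cal = calibration_sample(rng, sd=s[0])
                res = fit_quantal_mixture(x, calibration=cal)
                correct += res.n_components == true_k
            assert correct / n_rep >= 0.80, f"{true_k}-component scenario"


class TestBetaDecay:
    def test_uniform_is_beta_1_1(self):
        rng = np.random.default_rng(9)
        res = fit_beta_decay(rng.uniform(1e-6, 1.0, 2000), scale=1.0)
        assert res.alpha == pytest.approx(1.0, abs=0.15)
        assert res.beta_ == pytest.approx(1.0, abs=0.15)

    def test_recovers_beta_2_5(self):
        rng = np.random.default_rng(10)
        x = 2.0 * rng.beta(2.0, 5.0, 1000)
        res = fit_beta_decay(x, scale=2.0)
        assert res.alpha == pytest.approx(2.0, rel=0.15)
        assert res.beta_ == pytest.approx(5.0, rel=0.15)

    def test_mean_identity(self):
        rng = np.random.default_rng(11)
        res = fit_beta_decay(rng.beta(2.0, 3.0, 500), scale=1.0)
        assert res.mean == res.loc + res.scale * res.alpha / (res.alpha + res.beta_)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_beta_decay(np.linspace(-0.1, 1.0, 100))

    def test_explicit_support(self):
        rng = np.random.default_rng(12)
        x = 0.1 + 0.9 * rng.beta(2.0, 2.0, 500)
        res = BetaDecayModel(x, support=(0.05, 1.05)).fit()
        assert res.loc == pytest.approx(0.05)
        assert 0.05 <= res.median <= 1.05

    def test_order_invariance(self):
        rng = np.random.default_rng(13)
        x = rng.beta(2.0, 4.0, 300)
        r1 = fit_beta_decay(x, scale=1.1)
        r2 = fit_beta_decay(x[::-1], scale=1.1)
        assert r1.alpha == pytest.approx(r2.alpha, rel=1e-9)


class TestCompareDistributions:
    def test_identical_samples(self):
        x = np.arange(50, dtype=float)
        res = compare_distributions(x, x.copy(), "ks")
        assert res.ks_stat == 0.0
        assert res.p == pytest.approx(1.0)

    def test_separated_normals(self):
        rng = np.random.default_rng(14)
        res = compare_distributions(
            rng.normal(0, 1, 500), rng.normal(3, 1, 500), "ks"
        )
        assert res.p < 1e-6

    def test_dmax_location_matches_brute_force(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 200), rng.normal(1, 2, 300)
        res = compare_distributions(a, b, "ks")
        # brute-force CDF scan over all observed values
        grid = np.sort(np.concatenate([a, b]))
        gaps = np.abs(
            np.searchsorted(np.sort(a), grid, side="right") / a.size
            - np.searchsorted(np.sort(b), grid, side="right") / b.size
        )
        assert res.ks_stat == pytest.approx(gaps.max())
        assert res.dmax_location == pytest.approx(grid[np.argmax(gaps)])
        assert res.ks_stat == pytest.approx(res.statistic)

    @pytest.mark.parametrize("test", ["chi2_gof", "dagostino_pearson", "t_test"])
    def test_other_tests_run(self, test):
        rng = np.random.default_rng(16)
        res = compare_distributions(
            rng.normal(0, 1, 200), rng.normal(0, 1, 200), test
        )
        assert 0 <= res.p <= 1

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError, match="unknown test"):
            compare_distributions(np.ones(10), np.ones(10), "anova")


def test_results_plot_returns_axis():
    import matplotlib

    matplotlib.use("Agg")
    rng = np.random.default_rng(21)
    x = rng.normal(623.0, 122.0, 1200)
    res = fit_quantal_mixture(x)
    ax = res.plot(amplitudes=x)
    assert ax.get_xlabel() == "amplitude (a.u.)"
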