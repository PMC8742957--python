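"""Mixture EM, bootstrap LRT, model-based ROC, prevalence and KS tests."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import norm

from celsignal.errors import (
    InfeasibleCutoffError,
    ValidationError,
)
from celsignal.population_mixture import (
    MixtureModel,
    _ks_stat,
    fit_mixture_em,
    ks_two_sample,
    lrt_num_components,
    mixture_log_likelihood,
    prevalence,
    roc_from_mixture,
    select_cutoff,
)
from celsignal.synthetic_data import MixtureSpec, generate_cohort_scores

PUBLISHED_MODEL = MixtureModel(
    3, (0.33, 0.19, 0.48), (40.0, 130.0, 446.0), (35.0, 55.0, 195.0),
    -1.0, 79, True, 1)


class TestEM:
    def test_k1_equals_closed_form_mle(self, rng):
        x = rng.normal(10.0, 3.0, size=200)
        fit = fit_mixture_em(x, 1)
        assert fit.means[0] == pytest.approx(np.mean(x), abs=1e-10)
        assert fit.sds[0] == pytest.approx(np.std(x), abs=1e-10)
        assert fit.weights == (1.0,)

    def test_log_likelihood_monotone(self, rng):
        for _ in range(5):
            x = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 2, 80)])
            fit = fit_mixture_em(x, 2, seed=0)
            hist = np.asarray(fit.ll_history)
            assert np.all(np.diff(hist) >= -1e-7 * (np.abs(hist[:-1]) + 1))

    def test_components_sorted_by_mean(self, rng):
        x = np.concatenate([rng.normal(50, 5, 100), rng.normal(-10, 5, 100)])
        fit = fit_mixture_em(x, 2, seed=1)
        assert fit.means[0] < fit.means[1]
        assert sum(fit.weights) == pytest.approx(1.0, abs=1e-12)

    def test_more_components_never_lower_likelihood(self, rng):
        x = rng.normal(0, 1, size=150)
        ll1 = fit_mixture_em(x, 1).log_likelihood
        ll2 = fit_mixture_em(x, 2, seed=3).log_likelihood
        assert ll2 >= ll1 - 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_mixture_em([1.0, 2.0, 3.0], 2)

    def test_parameter_recovery_matches_sklearn_oracle(self, rng):
        """Cross-check the EM fit against an independent implementation."""
        from sklearn.mixture import GaussianMixture

        spec = MixtureSpec((0.3, 0.7), (0.0, 8.0), (1.0, 2.0))
        df, _ = generate_cohort_scores(spec, 2000, seed=17)
        x = df["score"].to_numpy()
        ours = fit_mixture_em(x, 2, seed=5)
        gm = GaussianMixture(2, covariance_type="spherical", n_init=5,
                             random_state=0, tol=1e-8).fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(ours.means,
                                   gm.means_.ravel()[order], atol=0.05)
        np.testing.assert_allclose(ours.weights,
                                   gm.weights_[order], atol=0.01)
        np.testing.assert_allclose(
            ours.sds, np.sqrt(gm.covariances_[order]), atol=0.05)

    def test_seed_averaged_recovery_with_overlapping_components(self):
        """With a heavily overlapping middle component the per-seed MLE is
        noisy, but the seed-averaged top-component estimates are unbiased."""
        spec = MixtureSpec((0.33, 0.19, 0.48), (50.0, 250.0, 446.0),
                           (40.0, 60.0, 195.0))
        mus, ws = [], []
        for seed in range(15):
            df, _ = generate_cohort_scores(spec, 2000, seed=seed)
            fit = fit_mixture_em(df["score"].to_numpy(), 3, seed=seed,
                                 n_restarts=5)
            mus.append(fit.means[2])
            ws.append(fit.weights[2])
        assert abs(np.mean(mus) - 446.0) <= 15.0
        assert abs(np.mean(ws) - 0.48) <= 0.03

    def test_recovery_at_small_cohort_size_is_characterized(self):
        """Median |error| of the top-component mean at n=79 stays bounded."""
        errors = []
        for seed in range(100):
            df, _ = generate_cohort_scores(
                MixtureSpec((0.33, 0.19, 0.48), (40., 130., 446.),
                            (35., 55., 195.)), 79, seed=seed)
            fit = fit_mixture_em(df["score"].to_numpy(), 3, seed=seed,
                                 n_restarts=5)
            errors.append(abs(fit.means[2] - 446.0))
        med = float(np.median(errors))
        assert np.isfinite(med) and med < 60.0


class TestLRT:
    def test_identical_fits_give_zero_statistic(self, rng):
        x = rng.normal(0, 1, 100)
        res = lrt_num_components(x, 1, 2, n_bootstrap=19, seed=0)
        # on pure-noise data the K=2 gain is small and p is large
        assert res.statistic >= 0.0
        assert 0.0 < res.p_value <= 1.0

    def test_power_on_well_separated_components(self):
        spec = MixtureSpec((0.3, 0.3, 0.4), (0.0, 20.0, 45.0), (2.0, 2.5, 3.0))
        df, _ = generate_cohort_scores(spec, 400, seed=2)
        res = lrt_num_components(df["score"].to_numpy(), 2, 3,
                                 n_bootstrap=99, seed=3, n_restarts=5)
        assert res.p_value <= 0.05

    def test_k1_not_less_than_k0_rejected(self, rng):
        with pytest.raises(ValidationError):
            lrt_num_components(rng.normal(size=50), 2, 2)


class TestROC:
    def test_published_component_sensitivity_at_cutoff(self):
        r = roc_from_mixture(PUBLISHED_MODEL, cutoffs=[250.0])[0]
        assert r.sensitivity == pytest.approx(
            norm.cdf((446 - 250) / 195), abs=1e-12)
        assert round(100 * r.sensitivity) == 84
        assert r.false_positive_rate < 0.01

    def test_degenerate_cutoff_gives_unit_rates(self):
        r = roc_from_mixture(PUBLISHED_MODEL, cutoffs=[-1e9])[0]
        assert r.sensitivity == pytest.approx(1.0)
        assert r.false_positive_rate == pytest.approx(1.0)

    def test_curves_non_increasing_in_cutoff(self):
        roc = roc_from_mixture(PUBLISHED_MODEL,
                               cutoffs=np.linspace(-200, 1200, 100))
        sens = [r.sensitivity for r in roc]
        fp = [r.false_positive_rate for r in roc]
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(fp) <= 1e-12)
        assert all(0 <= v <= 1 for v in fp)

    def test_positive_component_out_of_range(self):
        with pytest.raises(ValidationError):
            roc_from_mixture(PUBLISHED_MODEL, positive_component=3)

    def test_single_component_model_rejected(self, rng):
        m = fit_mixture_em(rng.normal(size=50), 1)
        with pytest.raises(ValidationError):
            roc_from_mixture(m)


class TestSelectCutoff:
    grid = np.linspace(-200, 1200, 400)

    def test_constraint_satisfied(self):
        roc = roc_from_mixture(PUBLISHED_MODEL, cutoffs=self.grid)
        chosen = select_cutoff(roc, max_fp=0.01)
        assert chosen.false_positive_rate <= 0.01

    def test_trivial_bound_returns_smallest_cutoff(self):
        roc = roc_from_mixture(PUBLISHED_MODEL, cutoffs=self.grid)
        chosen = select_cutoff(roc, max_fp=1.0)
        assert chosen.cutoff == pytest.approx(self.grid[0])

    def test_matches_exhaustive_scan(self):
        roc = roc_from_mixture(PUBLISHED_MODEL, cutoffs=self.grid)
        chosen = select_cutoff(roc, max_fp=0.05)
        brute = min((r for r in roc if r.false_positive_rate <= 0.05),
                    key=lambda r: (r.cutoff,))
        assert chosen.cutoff == brute.cutoff

    def test_infeasible_bound(self):
        roc = roc_from_mixture(PUBLISHED_MODEL, cutoffs=[0.0])
        with pytest.raises(InfeasibleCutoffError):
            select_cutoff(roc, max_fp=1e-6)


class TestPrevalence:
    def test_published_cohort_point_estimate(self):
        est = prevalence(19, 79)
        assert round(100 * est.proportion, 1) == 24.1

    def test_zero_positives(self):
        est = prevalence(0, 50)
        assert est.proportion == 0.0 and est.ci_lower == 0.0

    def test_wilson_coverage(self):
        p_true, n = 0.24, 79
        rng = np.random.default_rng(12)
        covered = 0
        reps = 10_000
        counts = rng.binomial(n, p_true, size=reps)
        # cache: prevalence depends on the count only
        cis = {k: prevalence(int(k), n) for k in np.unique(counts)}
        for k in counts:
            est = cis[int(k)]
            covered += est.ci_lower <= p_true <= est.ci_upper
        assert covered / reps >= 0.93

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            prevalence(5, 4)


class TestKS:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = ks_two_sample(x, x.copy(), mode="asymptotic")
        assert res.statistic == 0.0
        assert res.p_value > 0.99

    def test_disjoint_supports(self):
        res = ks_two_sample([1.0, 2.0], [3.0, 4.0], mode="asymptotic")
        assert res.statistic == 1.0

    def test_permutation_matches_enumeration(self, rng):
        """For small n the implementation must equal a direct enumeration."""
        for _ in range(5):
            x = rng.normal(0, 1, size=4)
            y = rng.normal(0.8, 1, size=4)
            res = ks_two_sample(x, y, mode="permutation")
            assert res.exact
            # independent enumeration oracle
            pooled = np.concatenate([x, y])
            n1 = len(x)
            d_obs = _oracle_d(x, y)
            count, total = 0, 0
            for comb in itertools.combinations(range(len(pooled)), n1):
                sel = np.zeros(len(pooled), bool)
                sel[list(comb)] = True
                if _oracle_d(pooled[sel], pooled[~sel]) >= d_obs - 1e-12:
                    count += 1
                total += 1
            assert total == math.comb(8, 4)
            assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_asymptotic_and_permutation_agree_in_rank(self, rng):
        ps_a, ps_p = [], []
        for shift in (0.0, 1.5, 3.0):
            x = rng.normal(0, 1, size=8)
            y = rng.normal(shift, 1, size=8)
            ps_a.append(ks_two_sample(x, y, "asymptotic").p_value)
            ps_p.append(ks_two_sample(x, y, "permutation").p_value)
        assert np.argsort(ps_a).tolist() == np.argsort(ps_p).tolist()

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([1.0], [2.0, 3.0])


def _oracle_d(x, y):
    """Brute-force sup |Fx - Fy| over a fine grid of pooled values."""
    grid = np.unique(np.concatenate([x, y]))
    best = 0.0
    for g in grid:
        fx = np.mean(x <= g)
        fy = np.mean(y <= g)
        best = max(best, abs(fx - fy))
    return best


class TestLikelihoodHelper:
    def test_matches_fit_value(self, rng):
        x = rng.normal(0, 1, 120)
        fit = fit_mixture_em(x, 2, seed=0)
        assert mixture_log_likelihood(fit, x) == pytest.approx(
            fit.log_likelihood, rel=1e-9)
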