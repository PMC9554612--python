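"""EM correctness against closed forms and a grid-search ML oracle."""


import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from metaqtl.mixture import (
    HeteroscedasticGaussianMixture,
    fit_mixture,
    information_criteria,
    select_model,
)


def mixture_loglik(x, s2, mu, pi):
    """Direct evaluation of the observed-data log-likelihood."""
    comp = np.stack(
        [np.log(p) + norm.logpdf(x, m, np.sqrt(s2)) for m, p in zip(mu, pi)]
    )
    return float(logsumexp(comp, axis=0).sum())


def grid_oracle_k2(x, s2, step=0.05):
    """Brute-force ML for K=2: grid over ordered mean pairs; for each pair
    the weight is optimized by fixed-mean EM (concave in the weights).
    Vectorized over all pairs."""
    lo, hi = x.min() - 1.0, x.max() + 1.0
    grid = np.arange(lo, hi + step, step)
    logpdf = norm.logpdf(x[None, :], grid[:, None], np.sqrt(s2)[None, :])
    ia, ib = np.triu_indices(len(grid), k=1)
    p1, p2 = logpdf[ia], logpdf[ib]          # (n_pairs, n)
    pi = np.full(len(ia), 0.5)
    for _ in range(100):
        l1 = np.log(pi)[:, None] + p1
        l2 = np.log1p(-pi)[:, None] + p2
        m = np.maximum(l1, l2)
        r1 = np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))
        pi = np.clip(r1.mean(axis=1), 1e-12, 1 - 1e-12)
    l1 = np.log(pi)[:, None] + p1
    l2 = np.log1p(-pi)[:, None] + p2
    ll = logsumexp(np.stack([l1, l2]), axis=0).sum(axis=1)
    return float(ll.max())


class TestClosedForms:
    def test_k1_equal_variances_is_plain_mean(self):
        fit = fit_mixture([10.0, 20.0], [1.0, 1.0], 1)
        assert fit.means_[0] == pytest.approx(15.0, abs=1e-9)

    def test_k1_is_inverse_variance_weighted_mean(self):
        fit = fit_mixture([10.0, 20.0], [1.0, 4.0], 1)
        assert fit.means_[0] == pytest.approx(12.0, abs=1e-9)

    def test_k1_matches_closed_form_on_random_data(self, rng):
        x = rng.normal(50, 5, 20)
        s2 = rng.uniform(0.5, 4.0, 20)
        fit = fit_mixture(x, s2, 1)
        w = 1.0 / s2
        assert fit.means_[0] == pytest.approx((w * x).sum() / w.sum(), abs=1e-9)

    def test_two_tight_pairs_recovered_with_k2(self):
        x = np.array([0.0, 0.1, 50.0, 50.1])
        fit = fit_mixture(x, np.ones(4), 2)
        assert fit.means_ == pytest.approx([0.05, 50.05], abs=1e-3)
        assert fit.weights_ == pytest.approx([0.5, 0.5], abs=1e-6)


class TestEMProperties:
    def test_loglik_monotone_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 15))
            x = rng.normal(0, 10, n)
            s2 = rng.uniform(0.2, 5.0, n)
            k = int(rng.integers(1, min(n, 4) + 1))
            fit = fit_mixture(x, s2, k, n_restarts=1, seed=0)
            diffs = np.diff(fit.loglik_path_)
            assert (diffs >= -1e-9).all()

    def test_responsibilities_and_weights_normalized(self, rng):
        x = rng.normal(0, 10, 12)
        fit = fit_mixture(x, np.ones(12), 3)
        assert fit.weights_.sum() == pytest.approx(1.0, abs=1e-9)
        assert fit.responsibilities_.sum(axis=1) == pytest.approx(np.ones(12), abs=1e-9)

    def test_means_sorted_and_permutation_invariant(self, rng):
        x = np.array([1.0, 2.0, 30.0, 31.0, 60.0])
        s2 = np.array([1.0, 1.0, 2.0, 2.0, 1.0])
        fit = fit_mixture(x, s2, 2)
        perm = rng.permutation(5)
        fit_p = fit_mixture(x[perm], s2[perm], 2)
        assert (np.diff(fit.means_) > 0).all()
        assert fit.means_ == pytest.approx(fit_p.means_, abs=1e-6)
        assert fit.loglik_ == pytest.approx(fit_p.loglik_, abs=1e-6)

    def test_k_above_n_or_bad_input_raise(self):
        with pytest.raises(ValueError):
            fit_mixture([1.0, 2.0], [1.0, 1.0], 3)
        with pytest.raises(ValueError):
            fit_mixture([1.0, np.nan], [1.0, 1.0], 1)
        with pytest.raises(ValueError):
            fit_mixture([1.0, 2.0], [1.0, 0.0], 1)

    def test_em_attains_grid_oracle_small_instances(self, rng):
        """Best-of-restarts EM log-likelihood >= brute-force oracle - 1e-6
        on n<=6 instances (the oracle itself is grid-limited)."""
        for _ in range(5):
            n = int(rng.integers(4, 7))
            centers = rng.choice([0.0, 12.0], n)
            x = centers + rng.normal(0, 1, n)
            s2 = rng.uniform(0.5, 2.0, n)
            fit = fit_mixture(x, s2, 2, n_restarts=8, seed=1)
            oracle = grid_oracle_k2(x, s2, step=0.1)
            assert fit.loglik_ >= oracle - 1e-6


class TestCriteriaAndSelection:
    def test_criteria_formulas_direct(self):
        out = information_criteria(loglik=-10.0, class_loglik=-12.0, k=2, n=10)
        p = 3
        assert out["AIC"] == pytest.approx(20 + 2 * p)
        assert out["AICc"] == pytest.approx(out["AIC"] + 2 * p * (p + 1) / (10 - p - 1))
        assert out["AIC3"] == pytest.approx(20 + 3 * p)
        assert out["BIC"] == pytest.approx(20 + p * np.log(10))
        assert out["AWE"] == pytest.approx(24 + 2 * p * (1.5 + np.log(10)))

    def test_aicc_infinite_when_underdetermined(self):
        out = information_criteria(-5.0, -5.0, k=3, n=5)  # p=5, n<=p+1
        assert np.isinf(out["AICc"])

    def test_single_cluster_wins_all_five(self, rng):
        x = rng.normal(20, 1, 8)
        s2 = np.ones(8)
        fits = {k: fit_mixture(x, s2, k, seed=0) for k in (1, 2, 3)}
        chosen, winners = select_model(fits)
        assert chosen == 1
        assert all(w == 1 for w in winners.values())

    def test_vote_rule_and_tie_breaks(self):
        class Fake:
            def __init__(self, k, crit):
                self.n_components = k
                self.criteria_ = crit

        # 2 wins 3 criteria -> chosen
        fits = {
            1: Fake(1, {"AIC": 1.0, "AICc": 1.0, "AIC3": 5.0, "BIC": 5.0, "AWE": 5.0}),
            2: Fake(2, {"AIC": 2.0, "AICc": 2.0, "AIC3": 1.0, "BIC": 1.0, "AWE": 1.0}),
        }
        assert select_model(fits)[0] == 2
        # winners {1:2, 2:2, 3:1} -> most-votes tie -> smaller K
        fits3 = {
            1: Fake(1, {"AIC": 0.0, "AICc": 0.0, "AIC3": 9.0, "BIC": 9.0, "AWE": 9.0}),
            2: Fake(2, {"AIC": 5.0, "AICc": 5.0, "AIC3": 0.0, "BIC": 0.0, "AWE": 9.0}),
            3: Fake(3, {"AIC": 5.0, "AICc": 5.0, "AIC3": 5.0, "BIC": 5.0, "AWE": 0.0}),
        }
        assert select_model(fits3)[0] == 1

    def test_empty_fit_list_raises(self):
        with pytest.raises(ValueError):
            select_model({})

    def test_k_recovery_on_separated_clusters(self, rng):
        """Five-criterion vote recovers K on clearly separated data."""
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            x = np.concatenate([r.normal(0, 1, 6), r.normal(30, 1, 6)])
            s2 = np.ones(12)
            fits = {k: fit_mixture(x, s2, k, seed=rep) for k in (1, 2, 3)}
            hits += select_model(fits)[0] == 2
        assert hits >= 0.8 * n_rep
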