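"""Gaussian mixture with known per-observation variances, and model selection.

The clustering model behind meta-QTL discovery: on one chromosome, the
projected peak positions x_i are treated as noisy observations of K true
loci,

    x_i | component k  ~  Normal(mu_k, s_i^2),

where s_i^2 is *known* per observation (derived from each QTL's projected
95% CI, s_i = CI_i/3.92) and is not re-estimated. Free parameters are the K
means and K−1 independent mixing proportions, so p = 2K − 1.

Fitting is EM with deterministic-seeded restarts (quantile seeding plus
jitter). The number of components is chosen by vote over five information
criteria — AIC, corrected AIC (AICc), AIC3, BIC and the approximate weight
of evidence (AWE, computed from the classification log-likelihood under
hard max-posterior assignments):

    AIC  = −2L + 2p
    AICc = AIC + 2p(p+1)/(n−p−1)          (infinite when n ≤ p+1)
    AIC3 = −2L + 3p
    BIC  = −2L + p ln n
    AWE  = −2L_c + 2p(3/2 + ln n)

A component count wins outright when it minimizes at least three of the
five criteria; otherwise the count winning the most criteria is taken,
ties resolved toward fewer components.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

_LOG_2PI = np.log(2.0 * np.pi)


class HeteroscedasticGaussianMixture(BaseEstimator):
    """1-D Gaussian mixture with fixed, observation-specific variances.

    Parameters
    ----------
    n_components : int
        Number of mixture components K.
    n_restarts : int
        EM restarts from perturbed quantile initializations; the best
        log-likelihood wins. Restart 0 is pure quantile seeding.
    max_iter : int
        EM iteration cap per restart.
    tol : float
        Convergence threshold on the log-likelihood increment.
    random_state : int or None
        Seed for the jittered restarts (deterministic given the seed).

    Attributes
    ----------
    means_ : ndarray of shape (K,), sorted ascending.
    weights_ : ndarray of shape (K,), mixing proportions summing to 1.
    responsibilities_ : ndarray of shape (n, K).
    loglik_ : float — final observed-data log-likelihood.
    loglik_path_ : ndarray — per-iteration log-likelihood of the winning
        restart (non-decreasing).
    criteria_ : dict — AIC/AICc/AIC3/BIC/AWE of the fit.
    n_iter_ : int
    """

    def __init__(
        self,
        n_components: int = 1,
        n_restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-8,
        random_state: int | None = 0,
    ):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None, *, s2=None):
        """Fit by EM. ``X`` is (n,) or (n, 1) positions; ``s2`` the known
        per-observation variances (defaults to 1 for every observation)."""
        x = np.asarray(X, dtype=float).reshape(-1)
        n = x.size
        k = self.n_components
        if s2 is None:
            s2 = np.ones(n)
        s2 = np.asarray(s2, dtype=float).reshape(-1)
        if s2.shape != x.shape:
            raise ValueError("s2 must match X in length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(s2))):
            raise ValueError("non-finite input")
        if np.any(s2 <= 0):
            raise ValueError("all observation variances must be positive")
        if k < 1 or k > n:
            raise ValueError(f"need 1 <= n_components <= n, got K={k}, n={n}")

        rng = np.random.default_rng(self.random_state)
        quantile_mu = np.quantile(x, (np.arange(k) + 0.5) / k)
        scale = x.std() if x.std() > 0 else 1.0

        best = None
        for restart in range(max(1, self.n_restarts)):
            mu = quantile_mu.copy()
            if restart > 0:
                mu = mu + rng.normal(0.0, 0.1 * scale, size=k)
            pi = np.full(k, 1.0 / k)
            mu, pi, resp, ll, path = self._em(x, s2, mu, pi)
            if best is None or ll > best[3]:
                best = (mu, pi, resp, ll, path)

        mu, pi, resp, ll, path = best
        order = np.argsort(mu, kind="stable")
        self.means_ = mu[order]
        self.weights_ = pi[order]
        self.responsibilities_ = resp[:, order]
        self.loglik_ = float(ll)
        self.loglik_path_ = np.asarray(path)
        self.n_iter_ = len(path)
        self.x_ = x
        self.s2_ = s2
        self.criteria_ = information_criteria(
            self.loglik_, self._classification_loglik(), self.n_components, n
        )
        return self

    def _em(self, x, s2, mu, pi):
        prev = -np.inf
        path = []
        resp = None
        for _ in range(self.max_iter):
            logr = self._log_resp(x, s2, mu, pi)
            ll = float(logsumexp(logr, axis=1).sum())
            path.append(ll)
            resp = np.exp(logr - logsumexp(logr, axis=1, keepdims=True))
            # M-step: inverse-variance weighted means, mean responsibilities
            w = resp / s2[:, None]
            denom = w.sum(axis=0)
            mu = np.where(denom > 0, (w * x[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), mu)
            pi = resp.mean(axis=0)
            pi = np.clip(pi, 1e-300, None)
            pi = pi / pi.sum()
            if abs(ll - prev) < self.tol:
                break
            prev = ll
        return mu, pi, resp, path[-1], path

    @staticmethod
    def _log_resp(x, s2, mu, pi):
        """Unnormalized log responsibilities log pi_k + log N(x_i; mu_k, s_i^2)."""
        d = x[:, None] - mu[None, :]
        return (
            np.log(pi)[None, :]
            - 0.5 * (_LOG_2PI + np.log(s2))[:, None]
            - 0.5 * d * d / s2[:, None]
        )

    def _classification_loglik(self) -> float:
        """Log-likelihood under hard max-posterior assignments (for AWE)."""
        logr = self._log_resp(self.x_, self.s2_, self.means_, self.weights_)
        return float(logr[np.arange(self.x_.size), np.argmax(logr, axis=1)].sum())

    def predict(self, X, s2=None):
        """Max-posterior component index for each observation."""
        x = np.asarray(X, dtype=float).reshape(-1)
        if s2 is None:
            s2 = np.ones_like(x)
        s2 = np.asarray(s2, dtype=float).reshape(-1)
        logr = self._log_resp(x, s2, self.means_, self.weights_)
        return np.argmax(logr, axis=1)

    def score(self, X, y=None, *, s2=None):
        """Total log-likelihood of ``X`` under the fitted mixture."""
        x = np.asarray(X, dtype=float).reshape(-1)
        if s2 is None:
            s2 = np.ones_like(x)
        s2 = np.asarray(s2, dtype=float).reshape(-1)
        logr = self._log_resp(x, s2, self.means_, self.weights_)
        return float(logsumexp(logr, axis=1).sum())


def n_free_params(k: int) -> int:
    """K means + (K−1) independent mixing proportions."""
    return 2 * k - 1


def information_criteria(loglik: float, class_loglik: float, k: int, n: int) -> dict[str, float]:
    """The five model-choice criteria for a K-component fit on n points."""
    p = n_free_params(k)
    aic = -2.0 * loglik + 2.0 * p
    aicc = aic + (2.0 * p * (p + 1) / (n - p - 1)) if n > p + 1 else np.inf
    aic3 = -2.0 * loglik + 3.0 * p
    bic = -2.0 * loglik + p * np.log(n)
    awe = -2.0 * class_loglik + 2.0 * p * (1.5 + np.log(n))
    return {"AIC": aic, "AICc": aicc, "AIC3": aic3, "BIC": bic, "AWE": awe}


CRITERIA = ("AIC", "AICc", "AIC3", "BIC", "AWE")


def fit_mixture(
    x,
    s2,
    n_components: int,
    n_restarts: int = 5,
    seed: int | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> HeteroscedasticGaussianMixture:
    """Functional wrapper over :class:`HeteroscedasticGaussianMixture`."""
    return HeteroscedasticGaussianMixture(
        n_components=n_components,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(x, s2=s2)


def select_model(
    fits: dict[int, HeteroscedasticGaussianMixture] | list[HeteroscedasticGaussianMixture],
) -> tuple[int, dict[str, int]]:
    """Choose K by the five-criterion vote.

    Returns ``(chosen_K, winners)`` where ``winners`` maps each criterion to
    the K minimizing it (ties toward smaller K). A K minimizing at least
    three criteria wins; otherwise the K with most wins, ties toward the
    smaller K.
    """
    if not fits:
        raise ValueError("no fits to select among")
    if not isinstance(fits, dict):
        fits = {f.n_components: f for f in fits}
    ks = sorted(fits)
    winners: dict[str, int] = {}
    for crit in CRITERIA:
        winners[crit] = min(ks, key=lambda k: (fits[k].criteria_[crit], k))
    votes: dict[int, int] = {}
    for k in winners.values():
        votes[k] = votes.get(k, 0) + 1
    for k in ks:
        if votes.get(k, 0) >= 3:
            return k, winners
    best = min(votes, key=lambda k: (-votes[k], k))
    return best, winners
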