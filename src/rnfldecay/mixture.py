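"""Finite mixtures of univariate von Mises distributions.

The von Mises ("circular normal") density with location mu and
concentration kappa >= 0 is

    f(x | mu, kappa) = exp(kappa cos(x - mu)) / (2 pi I0(kappa)),

I0 the modified Bessel function of order 0; kappa = 0 is the uniform
circle.  A K-component mixture sum_k alpha_k vM(mu_k, kappa_k) is fit
by EM: the E-step computes posterior responsibilities, the M-step sets
alpha_k to the mean responsibility, mu_k to the responsibility-weighted
circular mean and kappa_k by inverting the Bessel ratio
A(kappa) = I1/I0 at the weighted mean resultant length (Best-Fisher
three-regime start refined by Newton steps).  The number of components
is chosen by minimizing BIC = -2 loglik + (3K - 1) ln n.

Interfaces are in degrees; computation is in radians.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_random_state

KAPPA_MAX = 500.0


def _bessel_ratio(kappa: np.ndarray | float) -> np.ndarray | float:
    """A(kappa) = I1(kappa)/I0(kappa), computed with scaled Bessels."""
    return special.i1e(kappa) / special.i0e(kappa)


def inv_bessel_ratio(rbar: float, kappa_max: float = KAPPA_MAX) -> float:
    """Invert A(kappa) = rbar for the ML concentration estimate.

    Best-Fisher three-regime approximation refined by 5 Newton steps
    on A(kappa) - rbar; capped at ``kappa_max`` to avoid overflow as
    rbar -> 1.
    """
    if not 0.0 <= rbar <= 1.0:
        raise ValueError("mean resultant length must lie in [0, 1]")
    if rbar < 1e-12:
        return 0.0
    if rbar > 1.0 - 1e-12:
        return kappa_max
    if rbar < 0.53:
        kappa = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        kappa = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        kappa = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    kappa = min(max(kappa, 1e-8), kappa_max)
    for _ in range(5):
        a = _bessel_ratio(kappa)
        # A'(kappa) = 1 - A/kappa - A^2
        da = 1.0 - a / kappa - a * a
        if da <= 0:
            break
        kappa -= (a - rbar) / da
        if not np.isfinite(kappa):
            return kappa_max
        kappa = min(max(kappa, 1e-8), kappa_max)
    return float(kappa)


def vm_pdf(x_deg, mu_deg: float, kappa: float):
    """von Mises density at angle(s) ``x_deg`` (per-radian density)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    x = np.deg2rad(np.asarray(x_deg, dtype=float))
    mu = np.deg2rad(mu_deg)
    # exp(k cos d)/ (2 pi I0(k)) = exp(k (cos d - 1)) / (2 pi i0e(k))
    out = np.exp(kappa * (np.cos(x - mu) - 1.0)) / (2 * np.pi * special.i0e(kappa))
    return float(out) if out.ndim == 0 else out


def _log_vm_pdf_matrix(theta: np.ndarray, mu: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log densities, numerically stable for large kappa."""
    cosd = np.cos(theta[:, None] - mu[None, :])
    return kappa[None, :] * (cosd - 1.0) - np.log(
        2 * np.pi * special.i0e(kappa)[None, :]
    )


class ConvergenceError(RuntimeError):
    """EM violated its guaranteed log-likelihood ascent."""


class VonMisesMixture(BaseEstimator, ClusterMixin):
    """Finite von Mises mixture fit by EM, sklearn estimator style.

    Parameters
    ----------
    n_components : int
        Number of mixture components K (clusters of decay directions).
    n_restarts : int
        Random restarts from Dirichlet-like responsibility draws; the
        restart with the best log-likelihood is kept.
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        EM iteration cap per restart; hitting it flags
        ``converged_ = False`` rather than raising.
    kappa_max : float
        Concentration cap (guards the degenerate all-identical case).
    random_state : int, RandomState or None
        Seed for the restarts.

    Attributes
    ----------
    means_deg_ : (K,) component locations in [0, 360), sorted ascending
        so fits are comparable across seeds (label switching resolved).
    kappas_ : (K,) concentrations.
    weights_ : (K,) mixing proportions, summing to 1.
    loglik_ : best attained log-likelihood.
    bic_ : -2 loglik + (3K - 1) ln n.
    responsibilities_ : (n, K) posterior membership weights.
    labels_ : maximum-responsibility component per training angle.
    converged_ : whether the best restart converged within max_iter.
    """

    def __init__(
        self,
        n_components: int = 1,
        n_restarts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 500,
        kappa_max: float = KAPPA_MAX,
        random_state=None,
    ) -> None:
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.kappa_max = kappa_max
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None) -> "VonMisesMixture":
        theta = self._check_angles(X)
        n, K = theta.size, self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if n < K:
            raise ValueError(f"need at least K={K} angles, got {n}")
        rng = check_random_state(self.random_state)

        best = None
        n_restarts = 1 if K == 1 else self.n_restarts
        for _ in range(n_restarts):
            result = self._fit_once(theta, K, rng)
            if best is None or result["loglik"] > best["loglik"]:
                best = result

        means_deg = np.rad2deg(best["mu"]) % 360.0
        order = np.argsort(means_deg)
        self.means_deg_ = means_deg[order]
        self.kappas_ = best["kappa"][order]
        self.weights_ = best["alpha"][order]
        self.loglik_ = float(best["loglik"])
        self.converged_ = bool(best["converged"])
        self.n_iter_ = int(best["n_iter"])
        self.n_features_in_ = 1
        self.bic_ = float(-2.0 * self.loglik_ + (3 * K - 1) * np.log(n))
        self.responsibilities_ = self._responsibilities(theta)
        self.labels_ = np.argmax(self.responsibilities_, axis=1)
        return self

    def _fit_once(self, theta: np.ndarray, K: int, rng) -> dict:
        n = theta.size
        if K == 1:
            resp = np.ones((n, 1))
        else:
            # random responsibility initialization (uniform Dirichlet draw)
            resp = rng.gamma(1.0, 1.0, size=(n, K))
            resp /= resp.sum(axis=1, keepdims=True)
        loglik = -np.inf
        converged = False
        mu = kappa = alpha = None
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        for it in range(1, self.max_iter + 1):
            mu, kappa, alpha = self._m_step(sin_t, cos_t, resp)
            cosd = cos_t[:, None] * np.cos(mu)[None, :] + sin_t[:, None] * np.sin(mu)[None, :]
            log_dens = (
                kappa[None, :] * (cosd - 1.0)
                - np.log(2 * np.pi * special.i0e(kappa))[None, :]
                + np.log(alpha)[None, :]
            )
            m = log_dens.max(axis=1, keepdims=True)
            w = np.exp(log_dens - m)
            norm = w.sum(axis=1, keepdims=True)
            new_loglik = float(np.sum(np.log(norm) + m))
            # EM guarantees ascent; tolerate only roundoff-scale dips
            if new_loglik < loglik - 1e-6 * (1.0 + abs(loglik)):
                raise ConvergenceError(
                    f"log-likelihood decreased at iteration {it}: "
                    f"{loglik} -> {new_loglik}"
                )
            resp = w / norm
            if new_loglik - loglik <= self.tol * (1.0 + abs(new_loglik)):
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
        return {
            "mu": mu, "kappa": kappa, "alpha": alpha,
            "loglik": loglik, "converged": converged, "n_iter": it,
        }

    def _m_step(self, sin_t: np.ndarray, cos_t: np.ndarray, resp: np.ndarray):
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        alpha = nk / resp.shape[0]
        s = resp.T @ sin_t
        c = resp.T @ cos_t
        mu = np.arctan2(s, c)
        rbar = np.clip(np.hypot(s, c) / nk, 0.0, 1.0)
        kappa = np.array([inv_bessel_ratio(r, self.kappa_max) for r in rbar])
        alpha = np.maximum(alpha, 1e-300)
        alpha /= alpha.sum()
        return mu, kappa, alpha

    # ------------------------------------------------------------------
    def _check_angles(self, X) -> np.ndarray:
        theta = np.asarray(X, dtype=float)
        if theta.ndim == 2 and theta.shape[1] == 1:
            theta = theta[:, 0]
        if theta.ndim != 1:
            raise ValueError("angles must be a 1-D array of degrees")
        if np.any(~np.isfinite(theta)):
            raise ValueError("angles must be finite (drop NA directions first)")
        return np.deg2rad(theta % 360.0)

    def _responsibilities(self, theta: np.ndarray) -> np.ndarray:
        log_dens = (
            _log_vm_pdf_matrix(theta, np.deg2rad(self.means_deg_), self.kappas_)
            + np.log(self.weights_)[None, :]
        )
        return np.exp(log_dens - special.logsumexp(log_dens, axis=1, keepdims=True))

    def predict_proba(self, X) -> np.ndarray:
        """Posterior component membership for angle(s) in degrees."""
        return self._responsibilities(self._check_angles(X))

    def predict(self, X) -> np.ndarray:
        """Maximum-responsibility component labels (ties -> lower index)."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score_samples(self, X) -> np.ndarray:
        theta = self._check_angles(X)
        log_dens = (
            _log_vm_pdf_matrix(theta, np.deg2rad(self.means_deg_), self.kappas_)
            + np.log(self.weights_)[None, :]
        )
        return special.logsumexp(log_dens, axis=1)

    def score(self, X, y=None) -> float:
        return float(np.mean(self.score_samples(X)))

    def bic(self, X) -> float:
        """BIC = -2 loglik + (3K - 1) ln n on the given angles."""
        loglik = float(self.score_samples(X).sum())
        n = self._check_angles(X).size
        return -2.0 * loglik + (3 * self.n_components - 1) * np.log(n)


def fit_mixture_em(
    angles_deg,
    K: int,
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed=None,
) -> VonMisesMixture:
    """Fit a K-component von Mises mixture by EM (functional wrapper)."""
    return VonMisesMixture(
        n_components=K, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
        random_state=seed,
    ).fit(angles_deg)


def select_K(
    angles_deg,
    K_range=range(1, 6),
    n_restarts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed=None,
) -> VonMisesMixture:
    """Fit each K in ``K_range`` and return the BIC-minimizing mixture.

    The full BIC table is attached to the returned estimator as
    ``bic_table_`` (dict K -> BIC) for reporting.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    rng = check_random_state(seed)
    fits = {}
    for K in K_range:
        fits[K] = fit_mixture_em(
            angles_deg, K, n_restarts=n_restarts, tol=tol, max_iter=max_iter,
            seed=rng.randint(2**31 - 1),
        )
    best_K = min(fits, key=lambda K: fits[K].bic_)
    best = fits[best_K]
    best.bic_table_ = {K: fits[K].bic_ for K in K_range}
    return best


def assign_clusters(fit: VonMisesMixture, angles_deg) -> np.ndarray:
    """Maximum-responsibility cluster labels for the given angles."""
    return fit.predict(angles_deg)


def sample_vonmises_mixture(
    n: int, means_deg, kappas, weights, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` angles (degrees) from a von Mises mixture.

    Returns (angles_deg, component_labels); used for simulation-based
    checks of parameter recovery.
    """
    means_deg = np.asarray(means_deg, dtype=float)
    kappas = np.asarray(kappas, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(means_deg.size, size=n, p=weights)
    angles = rng.vonmises(np.deg2rad(means_deg)[comp], kappas[comp])
    return np.rad2deg(angles) % 360.0, comp
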