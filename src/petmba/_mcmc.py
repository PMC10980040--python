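"""Low-level MCMC building blocks for the hierarchical models.

The hierarchical fits combine conjugate Gibbs updates for the
linear-Gaussian layers (fixed effects, individual random effects) with
adaptive random-walk Metropolis updates for the nonlinear TAC-level
parameters and for variance/correlation hyperparameters.  These helpers
keep that machinery in one place.
"""

from __future__ import annotations

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))


def normal_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * (LOG_2PI + z * z) - np.log(sd)


def half_normal_logpdf(x, scale):
    """Log density of |N(0, scale^2)| evaluated at x > 0 (-inf otherwise)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2,
        -np.inf,
    )
    return out


def lkj_logdensity(omega: np.ndarray, eta: float = 2.0) -> float:
    """Unnormalized LKJ log density: (eta - 1) log det(Omega)."""
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return -np.inf
    return (eta - 1.0) * logdet


def is_pd_corr(omega: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(omega)
        return True
    except np.linalg.LinAlgError:
        return False


def mvn_logpdf_rows(x: np.ndarray, cov: np.ndarray) -> float:
    """Sum of MVN(0, cov) log densities over rows of x."""
    from scipy.linalg import solve_triangular

    n, k = x.shape
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    sol = solve_triangular(L, x.T, lower=True)
    quad = np.sum(sol**2)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (n * k * LOG_2PI + n * logdet + quad)


def draw_mvn_from_precision(rng: np.random.Generator, prec: np.ndarray, lin: np.ndarray):
    """Draw from N(prec^-1 lin, prec^-1) via Cholesky of the precision."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, lin)
    z = rng.standard_normal(lin.size)
    # solve L^T x = z gives covariance prec^-1
    from scipy.linalg import solve_triangular

    return mean + solve_triangular(L.T, z, lower=False)


def gibbs_linear(rng, X, z, noise_sd, prior_mean, prior_sd):
    """Conjugate draw of beta in z = X beta + e, e ~ N(0, noise_sd^2 I),
    with independent N(prior_mean, prior_sd^2) priors per coefficient."""
    P0 = 1.0 / np.asarray(prior_sd, dtype=float) ** 2
    prec = (X.T @ X) / noise_sd**2 + np.diag(P0)
    lin = (X.T @ z) / noise_sd**2 + P0 * np.asarray(prior_mean, dtype=float)
    return draw_mvn_from_precision(rng, prec, lin)


def mh_log_scale(rng, current, loglik_fn, log_prior_fn, step=0.3):
    """One Metropolis update of a positive scalar on the log scale.

    ``loglik_fn``/``log_prior_fn`` take the scalar on its natural scale.
    Returns (new_value, accepted).
    """
    prop = current * np.exp(step * rng.standard_normal())
    # include the log-scale Jacobian on both sides
    cur_lp = loglik_fn(current) + log_prior_fn(current) + np.log(current)
    prop_lp = loglik_fn(prop) + log_prior_fn(prop) + np.log(prop)
    if np.log(rng.uniform()) < prop_lp - cur_lp:
        return prop, True
    return current, False


def sample_lkj(rng, d: int, eta: float = 2.0) -> np.ndarray:
    """Draw a correlation matrix from the LKJ(eta) distribution (onion method)."""
    if d == 1:
        return np.eye(1)
    beta = eta + (d - 2) / 2.0
    r12 = 2.0 * rng.beta(beta, beta) - 1.0
    S = np.array([[1.0, r12], [r12, 1.0]])
    for k in range(2, d):
        beta -= 0.5
        y = rng.beta(k / 2.0, beta)
        a = rng.standard_normal(k)
        a /= np.linalg.norm(a)
        z = np.linalg.cholesky(S) @ (np.sqrt(y) * a)
        S = np.block([[S, z[:, None]], [z[None, :], np.ones((1, 1))]])
    return S


def mh_corr_matrix(rng, omega, loglik_fn, eta=2.0, step=0.12, n_sweeps=1):
    """Random-walk Metropolis over the off-diagonal entries of a correlation
    matrix, with an LKJ(eta) prior; proposals violating positive
    definiteness are rejected."""
    k = omega.shape[0]
    cur = omega.copy()
    cur_ll = loglik_fn(cur) + lkj_logdensity(cur, eta)
    for _ in range(n_sweeps):
        for i in range(k):
            for j in range(i + 1, k):
                prop = cur.copy()
                prop[i, j] = prop[j, i] = np.clip(
                    cur[i, j] + step * rng.standard_normal(), -0.999, 0.999
                )
                if not is_pd_corr(prop):
                    continue
                prop_ll = loglik_fn(prop) + lkj_logdensity(prop, eta)
                if np.log(rng.uniform()) < prop_ll - cur_ll:
                    cur, cur_ll = prop, prop_ll
    return cur


class AdaptiveScale:
    """Per-walker scalar step-size adaptation toward a target acceptance
    rate (Robbins-Monro during warmup, frozen afterwards)."""

    def __init__(self, n: int, init_log_step: float = np.log(0.1), target: float = 0.25):
        self.log_step = np.full(n, init_log_step)
        self.target = target

    def step(self) -> np.ndarray:
        return np.exp(self.log_step)

    def update(self, accepted: np.ndarray, rate: float) -> None:
        self.log_step += rate * (accepted.astype(float) - self.target)
        np.clip(self.log_step, np.log(1e-4), np.log(2.0), out=self.log_step)
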