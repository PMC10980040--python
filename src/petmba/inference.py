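"""Posterior and analytic summaries.

Group contrasts as percent differences with credible intervals and
directional probabilities, analytic tail probabilities of the
group-difference prior, extraction and comparison of individual-level
random effects, descriptive comparison of correlation matrices, power /
sample-size calculations and the probability of superiority, and the
RMSE comparison between hierarchical and per-TAC NLS estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .draws import PosteriorDraws

__all__ = [
    "ContrastSummary",
    "PowerResult",
    "prior_tail_probability",
    "summarize_contrast",
    "extract_individual_effects",
    "compare_correlation_matrices",
    "power_sample_size",
    "probability_of_superiority",
    "rmse_comparison",
]


@dataclass(frozen=True)
class ContrastSummary:
    """Posterior summary of one named group x region contrast.

    Percent differences are computed draw-wise as 100 (exp(beta) - 1) and
    then summarized by quantiles; the directional probability uses the tie
    convention P(beta > 0) = mean(beta > 0) + 0.5 mean(beta == 0).
    """

    name: str
    percent_median: float
    ci80: tuple
    ci95: tuple
    p_positive: float
    p_negative: float

    def __post_init__(self):
        if not (self.ci95[0] <= self.ci80[0] and self.ci80[1] <= self.ci95[1]):
            raise ValueError("80% interval must nest inside the 95% interval")

    def as_dict(self) -> dict:
        return {
            "contrast": self.name,
            "percent": self.percent_median,
            "lo80": self.ci80[0],
            "hi80": self.ci80[1],
            "lo95": self.ci95[0],
            "hi95": self.ci95[1],
            "p_positive": self.p_positive,
            "p_negative": self.p_negative,
        }


@dataclass(frozen=True)
class PowerResult:
    d: float
    alpha: float
    power: float
    n_per_group: int
    n_ci: tuple | None = None

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n per group must be at least 2")


def prior_tail_probability(sd: float, pct: float, side: str = "two_sided_within") -> float:
    """Tail probability of a Normal(0, sd) prior on a log-scale contrast.

    For a percent threshold ``pct``, ``two_sided_within`` returns
    P(|beta| < ln(1 + pct/100)); ``increase_beyond`` returns
    P(beta > ln(1 + pct/100)); ``decrease_beyond`` returns
    P(beta < -ln(1 + pct/100)).  With sd = 0.2 the prior places 64% of its
    mass on differences below 20%, 81% below 30%, and 9% on increases
    beyond 30%.
    """
    if sd <= 0:
        raise ValueError("prior SD must be positive")
    if pct <= 0:
        raise ValueError("percent threshold must be positive")
    z = np.log1p(pct / 100.0) / sd
    if side == "two_sided_within":
        return float(stats.norm.cdf(z) - stats.norm.cdf(-z))
    if side == "increase_beyond":
        return float(stats.norm.sf(z))
    if side == "decrease_beyond":
        return float(stats.norm.cdf(-z))
    raise ValueError(f"unknown side {side!r}")


def _directional(draws: np.ndarray):
    p_pos = float(np.mean(draws > 0) + 0.5 * np.mean(draws == 0))
    return p_pos, 1.0 - p_pos


def summarize_contrast(draws: PosteriorDraws, name: str) -> ContrastSummary:
    """Summarize a named contrast from posterior draws (see ContrastSummary)."""
    if name not in draws:
        available = ", ".join(n for n in draws.names if n.startswith("beta_"))
        raise KeyError(f"unknown contrast {name!r}; available contrasts: {available}")
    beta = draws.get(name)
    pct = 100.0 * np.expm1(beta)
    lo95, lo80, med, hi80, hi95 = np.percentile(pct, [2.5, 10.0, 50.0, 90.0, 97.5])
    p_pos, p_neg = _directional(beta)
    return ContrastSummary(
        name=name,
        percent_median=float(med),
        ci80=(float(lo80), float(hi80)),
        ci95=(float(lo95), float(hi95)),
        p_positive=p_pos,
        p_negative=p_neg,
    )


def contrast_table(draws: PosteriorDraws, prefix: str = "beta_group") -> pd.DataFrame:
    """Contrast summaries for every parameter starting with ``prefix``."""
    rows = [
        summarize_contrast(draws, n).as_dict() for n in draws.names if n.startswith(prefix)
    ]
    return pd.DataFrame(rows)


def extract_individual_effects(
    draws: PosteriorDraws, parameter: str, adjusted: bool = True
) -> pd.Series:
    """Posterior-mean individual-level estimates for one model parameter.

    With ``adjusted=True`` (default) these are the partially pooled random
    effects proper: one value per subject, adjusted for region means and
    covariates by construction of the model.  With ``adjusted=False`` the
    total subject-level score is returned (random effect plus the subject's
    covariate and group contributions); the score is invariant to how the
    posterior splits structure between coefficients and random effects,
    which makes it the stable choice for cross-model comparisons of
    individual-level estimates.  ``parameter`` is the hierarchy label
    (e.g. ``logBPND``, ``logBPP``, ``logBPF``, ``logK1``).
    """
    if not adjusted and any(n.startswith("subject_score[") for n in draws.names):
        prefix = "subject_score["
    elif any(n.startswith("u_rb[") for n in draws.names):
        prefix = "u_rb["
    else:
        prefix = "u["
    names = [n for n in draws.names if n.startswith(prefix) and n.endswith(f",{parameter}]")]
    if not names:
        labels = sorted({n.split(",")[-1][:-1] for n in draws.names if n.startswith("u[")})
        raise KeyError(
            f"no individual effects for {parameter!r}; model includes: {', '.join(labels)}"
        )
    sids = [n[len(prefix):].split(",")[0] for n in names]
    vals = [draws.mean(n) for n in names]
    return pd.Series(vals, index=sids, name=parameter).sort_index()


def compare_correlation_matrices(matrices: list, labels: list | None = None) -> pd.DataFrame:
    """Pairwise distances between correlation-matrix estimates.

    Returns max element-wise absolute difference and Frobenius distance for
    each pair; purely descriptive (no hypothesis test).
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    k = mats[0].shape
    for m in mats[1:]:
        if m.shape != k:
            raise ValueError("correlation matrices must share dimensions")
    labels = labels or [f"m{i}" for i in range(len(mats))]
    rows = []
    for i in range(len(mats)):
        for j in range(i + 1, len(mats)):
            diff = mats[i] - mats[j]
            rows.append(
                {
                    "a": labels[i],
                    "b": labels[j],
                    "max_abs_diff": float(np.max(np.abs(diff))),
                    "frobenius": float(np.linalg.norm(diff)),
                }
            )
    return pd.DataFrame(rows)


def omega_posterior_mean(draws: PosteriorDraws, dim: int = 5) -> np.ndarray:
    """Posterior-mean individual-level correlation matrix from draws."""
    om = np.eye(dim)
    for i in range(dim):
        for j in range(i + 1, dim):
            om[i, j] = om[j, i] = draws.mean(f"Omega[{i},{j}]")
    return om


def _power_two_sample_t(n: int, d: float, alpha: float) -> float:
    """Power of the two-sided two-sample t-test at n per group via the
    noncentral t distribution."""
    df = 2 * n - 2
    ncp = abs(d) * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def power_sample_size(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    d_ci: tuple | None = None,
    n_max: int = 10_000_000,
) -> PowerResult:
    """Smallest n per group giving the target power for a two-sided
    two-sample t-test at effect size d (Cohen's d).

    Optionally propagates a confidence interval on d into an interval on n.
    """
    if d == 0:
        raise ValueError("effect size must be nonzero")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")

    def solve(dd: float) -> int:
        lo, hi = 2, 4
        while _power_two_sample_t(hi, dd, alpha) < power:
            hi *= 2
            if hi > n_max:
                raise ValueError("target power unattainable within n limit")
        while lo < hi:
            mid = (lo + hi) // 2
            if _power_two_sample_t(mid, dd, alpha) >= power:
                hi = mid
            else:
                lo = mid + 1
        return lo

    n = solve(d)
    n_ci = None
    if d_ci is not None:
        hi_d, lo_d = max(map(abs, d_ci)), min(map(abs, d_ci))
        n_ci = (solve(hi_d), solve(lo_d))
    return PowerResult(d=d, alpha=alpha, power=power, n_per_group=n, n_ci=n_ci)


def probability_of_superiority(d: float) -> float:
    """P(X > Y) for X ~ N(d, 1), Y ~ N(0, 1): Phi(d / sqrt(2))."""
    return float(stats.norm.cdf(d / np.sqrt(2.0)))


def rmse_comparison(truth: np.ndarray, hier_est: np.ndarray, nls_est: np.ndarray) -> float:
    """Percent RMSE reduction of hierarchical vs NLS estimates.

    All arrays are aligned log-scale estimates (same subject x region
    ordering).  Returns 100 (1 - RMSE_hier / RMSE_nls).
    """
    truth = np.asarray(truth, dtype=float)
    h = np.asarray(hier_est, dtype=float)
    n = np.asarray(nls_est, dtype=float)
    if not (truth.shape == h.shape == n.shape):
        raise ValueError("truth and estimate arrays must be aligned")
    rmse_h = float(np.sqrt(np.mean((h - truth) ** 2)))
    rmse_n = float(np.sqrt(np.mean((n - truth) ** 2)))
    if rmse_n == 0:
        raise ValueError("NLS RMSE is zero; comparison undefined")
    return 100.0 * (1.0 - rmse_h / rmse_n)
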