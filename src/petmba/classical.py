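"""Classical (non-Bayesian) analysis arms.

Univariate linear mixed-effects modelling of log binding potential, a
one-way ANOVA of the log plasma free fraction across groups with pairwise
percent-difference contrasts, and a penalized thin-plate-spline drift model
of log f_P over the scan date with REML smoothing selection — the tool used
to ask whether apparent group differences in f_P can be explained by
temporal measurement drift when groups were not recruited concurrently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LMEResult",
    "DriftResult",
    "fit_lme_logbp",
    "fp_group_anova",
    "fp_drift_model",
]


@dataclass
class LMEResult:
    fixed_effects: pd.DataFrame  # term, estimate, se, z, p
    random_intercept_var: float
    residual_var: float
    contrasts: pd.DataFrame  # group-by-region contrasts with percent CIs
    converged: bool
    singular: bool

    def __post_init__(self):
        if self.random_intercept_var < 0 or self.residual_var < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class DriftResult:
    smooth_F: float
    smooth_p: float
    smooth_edf: float
    group_F: float
    group_p: float
    date_grid: np.ndarray
    smooth_fitted: np.ndarray
    smooth_se: np.ndarray
    basis_dim: int

    def __post_init__(self):
        if self.smooth_edf > self.basis_dim - 1 + 1e-8:
            raise ValueError("effective df cannot exceed basis dimension - 1")


# ---------------------------------------------------------------------------
# univariate LME on log BP
# ---------------------------------------------------------------------------


def fit_lme_logbp(
    table: pd.DataFrame,
    outcome: str = "log_bp",
    reference_group: str = "HV",
) -> LMEResult:
    """REML fit of log BP ~ region + sex + age + group:region + (1 | subject).

    ``table`` has one row per subject x region with columns subject_id,
    region, group, sex, age and the outcome.  Group-by-region contrasts are
    reported as percent differences, 100 (exp(b) - 1), with Wald CIs
    transformed the same way.
    """
    import statsmodels.formula.api as smf

    df = table.copy()
    needed = {"subject_id", "region", "group", "sex", "age", outcome}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.groupby("subject_id")["region"].nunique().min() < 2:
        raise ValueError("each subject needs at least 2 regions")
    df["age_z"] = (df["age"] - df["age"].mean()) / df["age"].std()
    df["group"] = pd.Categorical(
        df["group"], categories=[reference_group] + sorted(set(df["group"]) - {reference_group})
    )
    formula = f"{outcome} ~ C(region) + C(sex) + age_z + C(group):C(region)"
    model = smf.mixedlm(formula, df, groups=df["subject_id"])
    import warnings as _w

    singular = False
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs")
        except Exception:
            res = model.fit(reml=True)
    re_var = float(np.squeeze(res.cov_re.values))
    if re_var < 1e-10:
        singular = True
    fe = pd.DataFrame(
        {
            "term": res.fe_params.index,
            "estimate": res.fe_params.values,
            "se": res.bse_fe.values,
            "z": res.fe_params.values / res.bse_fe.values,
            "p": 2 * stats.norm.sf(np.abs(res.fe_params.values / res.bse_fe.values)),
        }
    )
    rows = []
    z95 = stats.norm.ppf(0.975)
    for term, est, se in zip(fe["term"], fe["estimate"], fe["se"]):
        if ":C(group)" in term or "C(group)" in term and ":" in term:
            rows.append(
                {
                    "term": term,
                    "log_diff": est,
                    "se": se,
                    "percent": 100 * np.expm1(est),
                    "lo95": 100 * np.expm1(est - z95 * se),
                    "hi95": 100 * np.expm1(est + z95 * se),
                }
            )
    return LMEResult(
        fixed_effects=fe,
        random_intercept_var=max(re_var, 0.0),
        residual_var=float(res.scale),
        contrasts=pd.DataFrame(rows),
        converged=bool(res.converged),
        singular=singular,
    )


# ---------------------------------------------------------------------------
# f_P group ANOVA
# ---------------------------------------------------------------------------


def fp_group_anova(
    subjects: pd.DataFrame,
    value_col: str = "f_P_measured",
    log_transform: bool = True,
    adjust: str = "tukey",
) -> dict:
    """One-way ANOVA of log f_P across groups with pairwise contrasts.

    Pairwise differences are reported as percent differences
    100 (exp(delta) - 1) with Tukey-adjusted p-values by default
    (``adjust='none'`` for unadjusted t-tests).
    """
    groups = subjects["group"].unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = []
    for g in groups:
        vals = subjects.loc[subjects["group"] == g, value_col].to_numpy(dtype=float)
        if vals.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        samples.append(np.log(vals) if log_transform else vals)
    F, p = stats.f_oneway(*samples)
    k = len(samples)
    n = sum(s.size for s in samples)
    df_between, df_within = k - 1, n - k
    # pooled within-group variance for pairwise contrasts
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ms_within = ss_within / df_within
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = samples[i].mean() - samples[j].mean()
            se = np.sqrt(ms_within * (1 / samples[i].size + 1 / samples[j].size))
            if adjust == "tukey":
                q = abs(diff) / (se / np.sqrt(2.0))
                pr = float(stats.studentized_range.sf(q, k, df_within))
            elif adjust == "none":
                pr = float(2 * stats.t.sf(abs(diff) / se, df_within))
            else:
                raise ValueError(f"unknown adjustment {adjust!r}")
            rows.append(
                {
                    "a": groups[i],
                    "b": groups[j],
                    "log_diff": float(diff),
                    "percent": float(100 * np.expm1(diff)) if log_transform else float(diff),
                    "p": pr,
                }
            )
    return {
        "F": float(F),
        "df": (df_between, df_within),
        "p": float(p),
        "pairwise": pd.DataFrame(rows),
    }


# ---------------------------------------------------------------------------
# thin-plate-spline drift model
# ---------------------------------------------------------------------------


def _tps_basis(x: np.ndarray, knots: np.ndarray):
    """Low-rank 1-D thin-plate spline basis: null space [1, x] plus radial
    terms |x - knot|^3 linearly constrained to be orthogonal to the null
    space, with the standard bending-energy penalty."""
    E = np.abs(x[:, None] - knots[None, :]) ** 3
    Ek = np.abs(knots[:, None] - knots[None, :]) ** 3
    T = np.column_stack([np.ones_like(knots), knots])  # null space at knots
    # constraint: delta' T = 0  ->  project onto the complement
    q, _ = np.linalg.qr(T, mode="complete")
    Z = q[:, 2:]  # (k, k-2) basis of the constrained coefficient space
    Xw = E @ Z  # wiggly design
    P = Z.T @ Ek @ Z  # penalty on constrained coefficients
    # symmetrize and stabilise
    P = (P + P.T) / 2.0
    return Xw, P


def fp_drift_model(
    subjects: pd.DataFrame,
    value_col: str = "f_P_measured",
    date_col: str = "scan_date",
    basis_dim: int = 10,
    n_grid: int = 100,
) -> DriftResult:
    """Penalized regression of log f_P on group fixed effects plus a
    thin-plate spline over the scan date, smoothing parameter by REML.

    The spline uses ``basis_dim`` basis functions (including the linear
    null space) with knots at date quantiles; the smooth and group terms
    get approximate Wald F-tests using the penalized fit's effective
    degrees of freedom.
    """
    df = subjects
    x = df[date_col].to_numpy(dtype=float)
    y = np.log(df[value_col].to_numpy(dtype=float))
    if np.unique(x).size < max(20, basis_dim):
        raise ValueError("need at least 20 distinct scan dates")
    groups = pd.Categorical(df["group"])
    G = pd.get_dummies(groups, drop_first=True).to_numpy(dtype=float)
    n = y.size

    xs = (x - x.mean()) / x.std()
    knots = np.quantile(np.unique(xs), np.linspace(0.02, 0.98, basis_dim))
    Xw, P = _tps_basis(xs, knots)
    # transform so the penalty is the identity: Xw L^-T with P = L L'
    w_evals, w_vecs = np.linalg.eigh(P)
    w_evals = np.clip(w_evals, 1e-10 * w_evals.max(), None)
    Linv = w_vecs / np.sqrt(w_evals)
    Zt = Xw @ Linv  # coefficients now have iid N(0, sb^2) working prior
    Xf = np.column_stack([np.ones(n), xs, G])  # fixed: intercept, linear date, groups
    q_f = Xf.shape[1]
    q_w = Zt.shape[1]

    X = np.column_stack([Xf, Zt])

    def reml_neg_loglik(log_lam):
        lam = np.exp(log_lam)
        D = np.concatenate([np.zeros(q_f), np.full(q_w, lam)])
        A = X.T @ X + np.diag(D)
        try:
            L = np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            return 1e10
        beta = np.linalg.solve(A, X.T @ y)
        rss = float(np.sum((y - X @ beta) ** 2) + lam * np.sum(beta[q_f:] ** 2))
        # REML profile criterion for the working linear mixed model
        logdet_A = 2.0 * np.sum(np.log(np.diag(L)))
        df_resid = n - q_f
        return float(
            0.5 * df_resid * np.log(rss) + 0.5 * logdet_A - 0.5 * q_w * log_lam
        )

    from scipy.optimize import minimize_scalar

    opt = minimize_scalar(reml_neg_loglik, bounds=(-10, 25), method="bounded")
    lam = float(np.exp(opt.x))
    D = np.concatenate([np.zeros(q_f), np.full(q_w, lam)])
    A = X.T @ X + np.diag(D)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (X.T @ y)
    fitted = X @ beta
    H_diag_df = float(np.trace(Ainv @ (X.T @ X)))
    edf_total = H_diag_df
    # effective df of the smooth: trace restricted to the wiggly block + the
    # linear date term (part of the smooth in the usual decomposition)
    F_full = X.T @ X
    edf_by_coef = np.diag(Ainv @ F_full)
    edf_smooth = float(edf_by_coef[1] + edf_by_coef[q_f:].sum())
    sigma2 = float(np.sum((y - fitted) ** 2) / (n - edf_total))
    Vb = Ainv @ F_full @ Ainv * sigma2  # Bayesian-sandwich covariance

    # Wald F for the smooth term (linear date + wiggly coefficients)
    idx_smooth = np.array([1] + list(range(q_f, q_f + q_w)))
    bs = beta[idx_smooth]
    Vs = Vb[np.ix_(idx_smooth, idx_smooth)]
    # pseudo-inverse rank-limited to the effective df
    evals, evecs = np.linalg.eigh((Vs + Vs.T) / 2.0)
    order = np.argsort(evals)[::-1]
    r = max(int(np.ceil(edf_smooth)), 1)
    keep = order[:r]
    stat = float(bs @ evecs[:, keep] @ np.diag(1.0 / evals[keep]) @ evecs[:, keep].T @ bs)
    smooth_F = stat / edf_smooth
    smooth_p = float(stats.f.sf(smooth_F, edf_smooth, n - edf_total))

    # Wald F for the group term
    idx_g = np.arange(2, q_f)
    if idx_g.size:
        bg = beta[idx_g]
        Vg = Vb[np.ix_(idx_g, idx_g)]
        statg = float(bg @ np.linalg.solve(Vg, bg))
        group_F = statg / idx_g.size
        group_p = float(stats.f.sf(group_F, idx_g.size, n - edf_total))
    else:
        group_F, group_p = np.nan, np.nan

    # fitted smooth (date part only, centred) on a grid
    gx = np.linspace(xs.min(), xs.max(), n_grid)
    Ew = np.abs(gx[:, None] - knots[None, :]) ** 3
    q, _ = np.linalg.qr(np.column_stack([np.ones_like(knots), knots]), mode="complete")
    Zc = q[:, 2:]
    Gw = Ew @ Zc @ Linv
    Xg = np.column_stack([np.zeros((n_grid, 1)), gx[:, None], np.zeros((n_grid, len(idx_g))), Gw])
    sm_fit = Xg @ beta
    sm_fit -= sm_fit.mean()
    sm_se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, Vb, Xg), 0.0))
    date_grid = gx * x.std() + x.mean()

    return DriftResult(
        smooth_F=float(smooth_F),
        smooth_p=smooth_p,
        smooth_edf=edf_smooth,
        group_F=float(group_F),
        group_p=group_p,
        date_grid=date_grid,
        smooth_fitted=sm_fit,
        smooth_se=sm_se,
        basis_dim=basis_dim,
    )
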