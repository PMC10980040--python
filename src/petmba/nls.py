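"""Conventional per-TAC weighted nonlinear least-squares quantification.

Fits the 2TCM (in the BP_ND, BP_P or BP_F parameterization) or SRTM to a
single TAC by weighted NLS on the natural-log parameter scale, with a fixed
multi-start grid and box constraints.  Frame weights follow the standard
scheme: the square root of the product of frame duration and the mean TAC
value after un-correcting for radioactive decay, normalized to mean 1 per
TAC (point estimates are invariant to the normalization).

These per-TAC estimates are the input for the parameter-level hierarchical
model and the comparison arm for the joint hierarchical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import InputFunction, RefModelGrid, TacModelGrid, TissueTAC

__all__ = [
    "C11_HALF_LIFE_MIN",
    "FitResult",
    "compute_weights",
    "fit_2tc_nls",
    "fit_srtm_nls",
    "fit_cohort_nls",
    "ref_curve_from_tac",
]

C11_HALF_LIFE_MIN = 20.364

TWOTC_PARAM_NAMES = {
    "BPND": ("logK1", "logVND", "logBPND", "logk4", "logvB"),
    "BPP": ("logK1", "logVND", "logBPP", "logk4", "logvB"),
    "BPF": ("logK1_fP", "logVND_fP", "logBPF", "logk4", "logvB"),
}
SRTM_PARAM_NAMES = ("logR1", "logk2prime", "logBPND")

# box constraints in the engine parameterization (logK1, logVND, logBPND, logk4, logvB);
# they prevent divergence on noisy raphe-like TACs
_ENGINE_LO = np.log(np.array([1e-3, 1e-2, 1e-3, 1e-3, 1e-4]))
_ENGINE_HI = np.log(np.array([1.0, 10.0, 100.0, 1.0, 0.2]))

# 8 fixed starting points spanning plausible ranges (no randomness)
_STARTS_2TC = np.array(
    [
        [np.log(K1), np.log(VND), np.log(BP), np.log(0.035), np.log(0.04)]
        for K1 in (0.05, 0.15)
        for VND in (0.3, 1.0)
        for BP in (0.5, 4.0)
    ]
)

_SRTM_LO = np.log(np.array([0.1, 1e-3, 1e-6]))
_SRTM_HI = np.log(np.array([10.0, 2.0, 100.0]))
_STARTS_SRTM = np.array(
    [
        [np.log(R1), np.log(k2p), np.log(BP)]
        for R1 in (0.7, 1.2)
        for k2p in (0.05, 0.3)
        for BP in (0.3, 3.0)
    ]
)


@dataclass
class FitResult:
    """Weighted-NLS fit of one TAC."""

    param_names: tuple
    estimates: np.ndarray  # log scale
    se: np.ndarray
    rss: float  # weighted residual sum of squares
    converged: bool
    weights: np.ndarray
    model: str  # "2tc" | "srtm"
    mode: str  # BPND | BPP | BPF | srtm

    def as_dict(self) -> dict:
        return dict(zip(self.param_names, self.estimates))


def compute_weights(tac: TissueTAC, half_life: float = C11_HALF_LIFE_MIN) -> np.ndarray:
    """Frame weights: sqrt(duration x decay-uncorrected concentration).

    The TAC is decay-corrected; un-correction multiplies each frame by
    2^(-t_mid / half_life) using the frame midpoint.  Negative frame values
    are clamped to zero before the square root.  Weights are normalized to
    mean 1 per TAC.
    """
    if half_life <= 0:
        raise ValueError("half-life must be positive")
    sched = tac.schedule
    if np.any(sched.frame_duration <= 0):
        raise ValueError("frame durations must be positive")
    uncorr = tac.c_tissue * 2.0 ** (-sched.frame_mid / half_life)
    w = np.sqrt(sched.frame_duration * np.clip(uncorr, 0.0, None))
    total = w.sum()
    if total <= 0:
        raise ValueError("degenerate weights: all frames non-positive")
    return w / (total / w.size)


def _mode_to_engine(x: np.ndarray, mode: str) -> np.ndarray:
    """Map a mode-space parameter vector to the engine parameterization."""
    if mode == "BPND":
        return x
    if mode == "BPP":
        # logBPND = logBPP - logVND
        return np.array([x[0], x[1], x[2] - x[1], x[3], x[4]])
    if mode == "BPF":
        # on the f_P-scaled input the engine takes (K1*, VND*, BPND* = BPF/VND*)
        return np.array([x[0], x[1], x[2] - x[1], x[3], x[4]])
    raise ValueError(f"unknown mode {mode!r}")


def _engine_to_mode(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "BPND":
        return x
    return np.array([x[0], x[1], x[2] + x[1], x[3], x[4]])


def _mode_bounds(mode: str, log_fp_shift: float = 0.0):
    """Box constraints in mode space; for BPF the K1 and V_ND boxes shift by
    -log f_P (the scaled parameters are K1/f_P, V_ND/f_P)."""
    lo = _ENGINE_LO.copy()
    hi = _ENGINE_HI.copy()
    lo[:2] += log_fp_shift
    hi[:2] += log_fp_shift
    if mode == "BPND":
        return lo, hi
    # logBP{P,F} = logBPND + logVND(-scaled): box covering the engine box
    lo2, hi2 = lo.copy(), hi.copy()
    lo2[2] = lo[2] + lo[1]
    hi2[2] = hi[2] + hi[1]
    return lo2, hi2


def _multistart_ls(residual, jac, starts, lo, hi, xtol=1e-10, ftol=1e-10):
    best = None
    for x0 in starts:
        x0c = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                residual, x0c, jac=jac, bounds=(lo, hi), xtol=xtol, ftol=ftol, gtol=1e-10
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18:
            break
    return best


def _se_from_jacobian(res, n_obs: int) -> np.ndarray:
    p = res.x.size
    dof = max(n_obs - p, 1)
    s2 = 2.0 * res.cost / dof
    JtJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.pinv(JtJ)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se


def fit_2tc_nls(
    tac: TissueTAC,
    input_fn: InputFunction,
    f_P: float | None = None,
    mode: str = "BPND",
    weights: np.ndarray | None = None,
    grid: TacModelGrid | None = None,
    n_starts: int = 8,
    tol: float = 1e-10,
) -> FitResult:
    """Fit the 2TCM to one TAC by weighted NLS.

    ``mode`` selects the parameterization: BPND (log K1, V_ND, BP_ND, k4,
    v_B), BPP (BP_P = V_ND BP_ND replaces BP_ND) or BPF (f_P-scaled input;
    K1/f_P, V_ND/f_P, BP_F).  All modes describe the same family of model
    curves; estimates are reported in the mode's own parameters.
    """
    if mode not in TWOTC_PARAM_NAMES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(TWOTC_PARAM_NAMES)}")
    if mode == "BPF":
        if f_P is None:
            raise ValueError("mode='BPF' requires f_P")
        if not (0.0 < f_P <= 1.0):
            raise ValueError("f_P must be in (0, 1]")
        input_fn = input_fn.scale_parent(f_P)
    if grid is None or mode == "BPF":
        grid = TacModelGrid(input_fn, tac.schedule)
    w = compute_weights(tac) if weights is None else np.asarray(weights, dtype=float)
    y = tac.c_tissue

    def residual(x):
        frames = grid.frames_2tc(_mode_to_engine(x, mode)[None, :])[0]
        return w * (frames - y)

    def jac(x):
        # forward differences evaluated in one batched engine call
        h = 1e-6
        X = np.vstack([x] + [x + h * np.eye(5)[i] for i in range(5)])
        E = np.vstack([_mode_to_engine(xi, mode) for xi in X])
        F = grid.frames_2tc(E)
        return (w[:, None]) * (F[1:] - F[0]).T / h

    log_fp_shift = -float(np.log(f_P)) if mode == "BPF" else 0.0
    lo, hi = _mode_bounds(mode, log_fp_shift)
    shift = np.array([log_fp_shift, log_fp_shift, 0.0, 0.0, 0.0])
    starts = np.array([_engine_to_mode(s + shift, mode) for s in _STARTS_2TC[:n_starts]])
    res = _multistart_ls(residual, jac, starts, lo, hi, xtol=tol, ftol=tol)
    if res is None:
        return FitResult(
            TWOTC_PARAM_NAMES[mode],
            np.full(5, np.nan),
            np.full(5, np.nan),
            np.inf,
            False,
            w,
            "2tc",
            mode,
        )
    converged = bool(res.success)
    return FitResult(
        TWOTC_PARAM_NAMES[mode],
        res.x.copy(),
        _se_from_jacobian(res, y.size),
        float(2.0 * res.cost),
        converged,
        w,
        "2tc",
        mode,
    )


def ref_curve_from_tac(ref_tac: TissueTAC):
    """Continuous reference curve from a measured reference-region TAC:
    frame values placed at frame midpoints, zero at time zero, constant
    after the last midpoint up to the end of the last frame."""
    sched = ref_tac.schedule
    t = np.concatenate([[0.0], sched.frame_mid, [sched.frame_end[-1]]])
    c = np.concatenate([[0.0], ref_tac.c_tissue, [ref_tac.c_tissue[-1]]])
    return t, np.clip(c, 0.0, None)


def fit_srtm_nls(
    tac: TissueTAC,
    ref_tac: TissueTAC | tuple,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Fit SRTM to one TAC by weighted NLS against a reference-region TAC.

    ``ref_tac`` is either a TissueTAC (interpolated to a continuous curve)
    or a (time, conc) tuple describing the reference curve directly.
    """
    if isinstance(ref_tac, TissueTAC):
        ref_t, ref_c = ref_curve_from_tac(ref_tac)
    else:
        ref_t, ref_c = ref_tac
    grid = RefModelGrid(ref_t, ref_c, tac.schedule)
    w = compute_weights(tac) if weights is None else np.asarray(weights, dtype=float)
    y = tac.c_tissue

    def residual(x):
        return w * (grid.frames_srtm(x[None, :])[0] - y)

    def jac(x):
        h = 1e-6
        X = np.vstack([x] + [x + h * np.eye(3)[i] for i in range(3)])
        F = grid.frames_srtm(X)
        return (w[:, None]) * (F[1:] - F[0]).T / h

    res = _multistart_ls(residual, jac, _STARTS_SRTM, _SRTM_LO, _SRTM_HI)
    if res is None:
        return FitResult(
            SRTM_PARAM_NAMES, np.full(3, np.nan), np.full(3, np.nan), np.inf, False, w, "srtm", "srtm"
        )
    return FitResult(
        SRTM_PARAM_NAMES,
        res.x.copy(),
        _se_from_jacobian(res, y.size),
        float(2.0 * res.cost),
        bool(res.success),
        w,
        "srtm",
        "srtm",
    )


def fit_cohort_nls(
    cohort,
    model: str = "2tc",
    mode: str = "BPND",
    reference_region: str = "cer_wm",
) -> pd.DataFrame:
    """Fit every TAC of a synthetic or loaded cohort; returns the tidy
    parameter table (one row per subject x region x parameter).

    For SRTM the reference region's TAC is excluded from the fitted set and
    used as the reference curve.
    """
    rows = []
    fp = dict(zip(cohort.subjects["subject_id"], cohort.subjects["f_P_measured"]))
    if model == "2tc":
        by_subject = {}
        for tac in cohort.tacs:
            by_subject.setdefault(tac.subject_id, []).append(tac)
        for sid, tacs in by_subject.items():
            grid = TacModelGrid(cohort.inputs[sid], tacs[0].schedule)
            for tac in tacs:
                fit = fit_2tc_nls(
                    tac, cohort.inputs[sid], f_P=fp.get(sid), mode=mode, grid=grid
                )
                for name, est, se in zip(fit.param_names, fit.estimates, fit.se):
                    rows.append((sid, tac.region_id, model, mode, name, est, se, fit.converged))
    elif model == "srtm":
        refs = {t.subject_id: t for t in cohort.tacs if t.region_id == reference_region}
        if not refs:
            raise ValueError(f"no TACs for reference region {reference_region!r}")
        for tac in cohort.tacs:
            if tac.region_id == reference_region:
                continue
            fit = fit_srtm_nls(tac, refs[tac.subject_id])
            for name, est, se in zip(fit.param_names, fit.estimates, fit.se):
                rows.append(
                    (tac.subject_id, tac.region_id, model, "srtm", name, est, se, fit.converged)
                )
    else:
        raise ValueError(f"unknown model {model!r}")
    return pd.DataFrame(
        rows,
        columns=["subject_id", "region", "model", "mode", "parameter", "estimate", "se", "converged"],
    )
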