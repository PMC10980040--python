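"""Forward kinetic models for PET time-activity curves.

Implements the two-tissue compartment model (2TCM) with a fractional blood
volume term and the simplified reference tissue model (SRTM), together with
the measured-data containers (frame schedules, arterial input functions,
tissue TACs) and conversions between micro-parameters (K1, k2, k3, k4) and
macro-parameters (V_ND, BP_ND, BP_P, BP_F, V_T).

All times are in minutes.  Radioactivity units are arbitrary but must be
consistent between input functions and TACs.  Input functions are treated as
piecewise-linear between their sample points and zero before time zero; the
model curves are therefore sums of exponentials convolved with a
piecewise-linear function, which this module evaluates in closed form per
segment (no ODE stepping).  Frame values are frame averages: the time
integral of the model curve over the frame divided by the frame duration,
matching how scanners bin counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrameSchedule",
    "InputFunction",
    "TissueTAC",
    "TwoTCParams",
    "FreeTwoTCParams",
    "SRTMParams",
    "simulate_2tc_tac",
    "simulate_free_input_tac",
    "simulate_srtm_tac",
    "macro_from_micro",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frame timing: start and duration per frame, in minutes."""

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        ends = start + dur
        if np.any(np.diff(start) <= 0) or np.any(start[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must be time-ordered and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.frame_start.size

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration

    @property
    def total_duration(self) -> float:
        """Sum of frame durations in minutes."""
        return float(self.frame_duration.sum())

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 20-frame, 110-minute schedule: 3 x 1/3, 3 x 1, 3 x 2, 2 x 5, 9 x 10 min."""
        dur = np.concatenate(
            [
                np.full(3, 1.0 / 3.0),
                np.full(3, 1.0),
                np.full(3, 2.0),
                np.full(2, 5.0),
                np.full(9, 10.0),
            ]
        )
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(frame_start=start, frame_duration=dur)


@dataclass(frozen=True)
class InputFunction:
    """Arterial input data on a dense time grid.

    ``c_plasma_parent`` is the metabolite-corrected parent concentration in
    plasma (the AIF); ``c_wholeplasma`` is total plasma radioactivity, used
    as a proxy for whole blood in the vascular term.  Both are interpreted
    piecewise-linearly between grid points and zero before time zero.  No
    extrapolation beyond the last sample: requesting times past the grid is
    an error.
    """

    time: np.ndarray
    c_plasma_parent: np.ndarray
    c_wholeplasma: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        cp = np.asarray(self.c_plasma_parent, dtype=float)
        cw = np.asarray(self.c_wholeplasma, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "c_plasma_parent", cp)
        object.__setattr__(self, "c_wholeplasma", cw)
        if t.ndim != 1 or t.shape != cp.shape or t.shape != cw.shape:
            raise ValueError("time and concentration arrays must be 1-D and equal length")
        if t[0] != 0.0:
            raise ValueError("input time grid must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("input time grid must be strictly increasing")
        if np.any(cp < 0) or np.any(cw < 0):
            raise ValueError("input concentrations must be non-negative")

    @property
    def t_max(self) -> float:
        return float(self.time[-1])

    def check_covers(self, t_end: float) -> None:
        if t_end > self.t_max + 1e-9:
            raise ValueError(
                f"input function support [0, {self.t_max:g}] min does not cover "
                f"requested interval up to {t_end:g} min "
                f"(uncovered: ({self.t_max:g}, {t_end:g}])"
            )

    def parent_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        self.check_covers(float(np.max(t)) if t.size else 0.0)
        return np.interp(t, self.time, self.c_plasma_parent, left=0.0)

    def wholeplasma_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        self.check_covers(float(np.max(t)) if t.size else 0.0)
        return np.interp(t, self.time, self.c_wholeplasma, left=0.0)

    def scale_parent(self, factor: float) -> "InputFunction":
        """Return a copy with the parent plasma curve multiplied by ``factor``
        (used for the free-fraction-corrected input: AIF x f_P)."""
        return InputFunction(self.time, self.c_plasma_parent * factor, self.c_wholeplasma)


@dataclass
class TissueTAC:
    """A measured or simulated regional time-activity curve."""

    subject_id: str
    region_id: str
    schedule: FrameSchedule
    c_tissue: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.c_tissue = np.asarray(self.c_tissue, dtype=float)
        if self.c_tissue.shape != (self.schedule.n_frames,):
            raise ValueError("c_tissue length must equal number of frames")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.c_tissue.shape:
                raise ValueError("weights length must equal number of frames")
            if np.any(self.weights < 0):
                raise ValueError("weights must be non-negative")


# ---------------------------------------------------------------------------
# parameter vectors (log scale)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoTCParams:
    """2TCM parameters on the natural-log scale.

    The free parameters are log K1 (mL cm^-3 min^-1), log V_ND (= K1/k2),
    log BP_ND (= k3/k4), log k4 (min^-1) and log v_B (blood volume
    fraction).  Micro- and macro-parameters are exposed as derived
    properties.
    """

    log_K1: float
    log_VND: float
    log_BPND: float
    log_k4: float
    log_vB: float

    def __post_init__(self):
        if self.vB >= 1.0:
            raise ValueError("v_B must be below 1")

    # micro
    @property
    def K1(self) -> float:
        return float(np.exp(self.log_K1))

    @property
    def k2(self) -> float:
        return self.K1 / self.VND

    @property
    def k3(self) -> float:
        return self.BPND * self.k4

    @property
    def k4(self) -> float:
        return float(np.exp(self.log_k4))

    @property
    def vB(self) -> float:
        return float(np.exp(self.log_vB))

    # macro
    @property
    def VND(self) -> float:
        return float(np.exp(self.log_VND))

    @property
    def BPND(self) -> float:
        return float(np.exp(self.log_BPND))

    @property
    def BPP(self) -> float:
        return self.VND * self.BPND

    @property
    def VT(self) -> float:
        return self.VND * (1.0 + self.BPND)

    def BPF(self, f_P: float) -> float:
        _check_fp(f_P)
        return self.BPP / f_P

    @classmethod
    def from_micro(cls, K1: float, k2: float, k3: float, k4: float, vB: float) -> "TwoTCParams":
        if min(K1, k2, k3, k4, vB) <= 0:
            raise ValueError("micro-parameters must be strictly positive")
        return cls(
            log_K1=float(np.log(K1)),
            log_VND=float(np.log(K1 / k2)),
            log_BPND=float(np.log(k3 / k4)),
            log_k4=float(np.log(k4)),
            log_vB=float(np.log(vB)),
        )

    def to_free(self, f_P: float) -> "FreeTwoTCParams":
        _check_fp(f_P)
        return FreeTwoTCParams(
            log_K1_over_fP=self.log_K1 - np.log(f_P),
            log_VND_over_fP=self.log_VND - np.log(f_P),
            log_BPF=self.log_VND + self.log_BPND - np.log(f_P),
            log_k4=self.log_k4,
            log_vB=self.log_vB,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.log_K1, self.log_VND, self.log_BPND, self.log_k4, self.log_vB])


@dataclass(frozen=True)
class FreeTwoTCParams:
    """2TCM parameters for the free-fraction-corrected (BP_F) parameterization.

    Equivalent to :class:`TwoTCParams` after rescaling the input by the
    plasma free fraction f_P: K1/f_P, V_ND/f_P and BP_F = BP_P/f_P replace
    K1, V_ND and BP_ND, while k4 and v_B are unchanged.
    """

    log_K1_over_fP: float
    log_VND_over_fP: float
    log_BPF: float
    log_k4: float
    log_vB: float

    def to_standard(self, f_P: float) -> TwoTCParams:
        _check_fp(f_P)
        log_fp = float(np.log(f_P))
        log_VND = self.log_VND_over_fP + log_fp
        log_BPP = self.log_BPF + log_fp
        return TwoTCParams(
            log_K1=self.log_K1_over_fP + log_fp,
            log_VND=log_VND,
            log_BPND=log_BPP - log_VND,
            log_k4=self.log_k4,
            log_vB=self.log_vB,
        )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.log_K1_over_fP, self.log_VND_over_fP, self.log_BPF, self.log_k4, self.log_vB]
        )


@dataclass(frozen=True)
class SRTMParams:
    """SRTM parameters on the natural-log scale: R1, k2' (reference efflux)
    and BP_ND.  Derived: k2 = R1 * k2', k2a = k2 / (1 + BP_ND)."""

    log_R1: float
    log_k2prime: float
    log_BPND: float

    @property
    def R1(self) -> float:
        return float(np.exp(self.log_R1))

    @property
    def k2prime(self) -> float:
        return float(np.exp(self.log_k2prime))

    @property
    def BPND(self) -> float:
        return float(np.exp(self.log_BPND))

    @property
    def k2(self) -> float:
        return self.R1 * self.k2prime

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BPND)

    def as_array(self) -> np.ndarray:
        return np.array([self.log_R1, self.log_k2prime, self.log_BPND])


def _check_fp(f_P: float) -> None:
    if not (0.0 < f_P <= 1.0):
        raise ValueError(f"f_P must be in (0, 1], got {f_P}")


# ---------------------------------------------------------------------------
# exponential-convolution engine
#
# The workhorse: y(t) = int_0^t exp(-theta (t-u)) c(u) du for piecewise-linear
# c on knots t_0 < ... < t_M.  Within segment m with c(t_m + s) = a + b s:
#   y(t_m + s) = y_m E(s) + a A(s) + b B(s)
#   E = exp(-theta s), A = (1-E)/theta, B = (s - A)/theta
# and the segment integral of y is
#   int_0^D y ds = y_m A(D) + a B(D) + b IB(D),  IB = (D^2/2 - B)/theta.
# Small theta*D is handled by series expansion (limits A->D, B->D^2/2,
# IB->D^3/6 as theta->0).
# ---------------------------------------------------------------------------


def _eab(theta: np.ndarray, delta: np.ndarray):
    """E, A, B, IB for rates ``theta`` (shape R) and segment lengths ``delta``
    (shape M), broadcast to (R, M)."""
    th = np.asarray(theta, dtype=float)[:, None]
    d = np.asarray(delta, dtype=float)[None, :]
    x = th * d
    small = x < 1e-4
    xs = np.where(small, x, 1.0)  # safe values for series branch
    E = np.exp(-x)
    with np.errstate(divide="ignore", invalid="ignore"):
        A_exact = (1.0 - E) / th
        B_exact = (d - A_exact) / th
        IB_exact = (d * d / 2.0 - B_exact) / th
    A_ser = d * (1.0 - xs / 2.0 + xs**2 / 6.0 - xs**3 / 24.0)
    B_ser = d * d * (0.5 - xs / 6.0 + xs**2 / 24.0 - xs**3 / 120.0)
    IB_ser = d**3 * (1.0 / 6.0 - xs / 24.0 + xs**2 / 120.0 - xs**3 / 720.0)
    A = np.where(small, A_ser, A_exact)
    B = np.where(small, B_ser, B_exact)
    IB = np.where(small, IB_ser, IB_exact)
    return E, A, B, IB


def exp_conv_pl(theta: np.ndarray, t: np.ndarray, c: np.ndarray):
    """Convolve exp(-theta t) with a piecewise-linear curve.

    Parameters
    ----------
    theta : (R,) non-negative rates.
    t : (M+1,) strictly increasing knots starting at 0.
    c : (M+1,) curve values at the knots.

    Returns
    -------
    y : (R, M+1) convolution values at the knots.
    seg_int : (R, M) integral of y over each segment.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    t = np.asarray(t, dtype=float)
    c = np.asarray(c, dtype=float)
    delta = np.diff(t)
    a = c[:-1]
    b = np.diff(c) / delta
    E, A, B, IB = _eab(theta, delta)
    M = delta.size
    R = theta.size
    y = np.zeros((R, M + 1))
    seg = np.empty((R, M))
    yk = np.zeros(R)
    for m in range(M):
        seg[:, m] = yk * A[:, m] + a[m] * B[:, m] + b[m] * IB[:, m]
        yk = yk * E[:, m] + a[m] * A[:, m] + b[m] * B[:, m]
        y[:, m + 1] = yk
    return y, seg


def _trapz_segments(t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Exact integral of a piecewise-linear curve over each segment."""
    return 0.5 * (c[1:] + c[:-1]) * np.diff(t)


def _union_grid(input_time: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Knot grid containing the input samples and all frame boundaries up to
    the end of the last frame."""
    t_end = float(schedule.frame_end[-1])
    bounds = np.concatenate([schedule.frame_start, schedule.frame_end])
    grid = np.union1d(input_time[input_time <= t_end + 1e-12], bounds)
    grid = grid[grid <= t_end + 1e-12]
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
    return grid


def _frame_index_for_segments(grid: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Map each grid segment to the frame containing it (-1 if in a gap)."""
    mid = 0.5 * (grid[:-1] + grid[1:])
    idx = np.searchsorted(schedule.frame_start, mid, side="right") - 1
    idx = np.clip(idx, 0, schedule.n_frames - 1)
    inside = (mid >= schedule.frame_start[idx]) & (mid <= schedule.frame_end[idx])
    return np.where(inside, idx, -1)


def frame_average(seg_int: np.ndarray, seg_frame: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Sum segment integrals into frames and divide by frame duration.

    ``seg_int`` has shape (..., M); returns shape (..., n_frames)."""
    F = schedule.n_frames
    out = np.zeros(seg_int.shape[:-1] + (F,))
    for f in range(F):
        mask = seg_frame == f
        if mask.any():
            out[..., f] = seg_int[..., mask].sum(axis=-1)
    return out / schedule.frame_duration


# ---------------------------------------------------------------------------
# 2TCM impulse response and batched evaluation
# ---------------------------------------------------------------------------


def twotc_exponentials(logpars: np.ndarray):
    """Rates and coefficients of the 2TCM impulse response.

    ``logpars`` has shape (n, 5): columns log K1, log V_ND, log BP_ND,
    log k4, log v_B.  Returns theta (n, 2), phi (n, 2), vB (n,) with
    IRF(t) = phi_1 exp(-theta_1 t) + phi_2 exp(-theta_2 t).
    """
    lp = np.atleast_2d(np.asarray(logpars, dtype=float))
    K1 = np.exp(lp[:, 0])
    VND = np.exp(lp[:, 1])
    BPND = np.exp(lp[:, 2])
    k4 = np.exp(lp[:, 3])
    vB = np.exp(lp[:, 4])
    k2 = K1 / VND
    k3 = BPND * k4
    s = k2 + k3 + k4
    disc = np.sqrt(np.maximum(s * s - 4.0 * k2 * k4, 0.0))
    # avoid exactly repeated roots (measure-zero); keep them distinct
    disc = np.maximum(disc, 1e-12 * s)
    th1 = 0.5 * (s + disc)
    th2 = 0.5 * (s - disc)
    phi1 = K1 * (th1 - k3 - k4) / (th1 - th2)
    phi2 = K1 * (k3 + k4 - th2) / (th1 - th2)
    return np.stack([th1, th2], axis=1), np.stack([phi1, phi2], axis=1), vB


class TacModelGrid:
    """Precomputed grid context for repeated TAC-model evaluation.

    Holds the union knot grid (input samples plus frame boundaries), the
    input curves resampled onto it (exact for piecewise-linear inputs whose
    knots are included), the segment-to-frame map, and the frame integrals
    of the whole-plasma curve.  Used by the NLS fitter and the hierarchical
    sampler, where the same input is evaluated for many parameter vectors.
    """

    def __init__(self, input_fn: InputFunction, schedule: FrameSchedule):
        input_fn.check_covers(float(schedule.frame_end[-1]))
        self.schedule = schedule
        self.grid = _union_grid(input_fn.time, schedule)
        self.cp = np.interp(self.grid, input_fn.time, input_fn.c_plasma_parent)
        self.cwp = np.interp(self.grid, input_fn.time, input_fn.c_wholeplasma)
        self.seg_frame = _frame_index_for_segments(self.grid, schedule)
        wp_seg = _trapz_segments(self.grid, self.cwp)
        self.wp_frame = frame_average(wp_seg, self.seg_frame, schedule)

    def curve_2tc(self, logpars: np.ndarray, parent_scale: np.ndarray | float = 1.0) -> np.ndarray:
        """Model curve values at the grid knots (no frame averaging)."""
        lp = np.atleast_2d(np.asarray(logpars, dtype=float))
        theta, phi, vB = twotc_exponentials(lp)
        n = lp.shape[0]
        y, _ = exp_conv_pl(theta.reshape(-1), self.grid, self.cp)
        y = y.reshape(n, 2, -1)
        tissue = np.einsum("nk,nkt->nt", phi, y)
        scale = np.asarray(parent_scale, dtype=float)
        if scale.ndim == 1:
            scale = scale[:, None]
        return (1.0 - vB)[:, None] * tissue * scale + vB[:, None] * self.cwp[None, :]

    def frames_2tc(self, logpars: np.ndarray, parent_scale: np.ndarray | float = 1.0) -> np.ndarray:
        """Frame-averaged 2TCM curves for a batch of log-parameter vectors.

        ``parent_scale`` optionally multiplies the parent input per row
        (the f_P-corrected input); shape scalar or (n,).
        """
        from ._kernels import conv_frames

        lp = np.atleast_2d(np.asarray(logpars, dtype=float))
        theta, phi, vB = twotc_exponentials(lp)
        n = lp.shape[0]
        delta = np.diff(self.grid)
        rates = theta.reshape(-1)
        a = np.broadcast_to(self.cp[:-1], (rates.size, delta.size))
        b = np.broadcast_to(np.diff(self.cp) / delta, (rates.size, delta.size))
        acc = conv_frames(rates, delta, a, b, self.seg_frame, self.schedule.n_frames)
        fr = acc.reshape(n, 2, -1) / self.schedule.frame_duration
        tissue = np.einsum("nk,nkf->nf", phi, fr)
        scale = np.asarray(parent_scale, dtype=float)
        if scale.ndim == 1:
            scale = scale[:, None]
        return (1.0 - vB)[:, None] * tissue * scale + vB[:, None] * self.wp_frame[None, :]


class RefModelGrid:
    """Grid context for SRTM evaluation against a continuous reference curve.

    ``ref_time``/``ref_conc`` define the reference TAC piecewise-linearly.
    """

    def __init__(self, ref_time: np.ndarray, ref_conc: np.ndarray, schedule: FrameSchedule):
        ref_time = np.asarray(ref_time, dtype=float)
        ref_conc = np.asarray(ref_conc, dtype=float)
        t_end = float(schedule.frame_end[-1])
        if ref_time[-1] < t_end - 1e-9:
            raise ValueError(
                f"reference curve support [0, {ref_time[-1]:g}] does not cover "
                f"the schedule (uncovered: ({ref_time[-1]:g}, {t_end:g}])"
            )
        self.schedule = schedule
        self.grid = _union_grid(ref_time, schedule)
        self.cref = np.interp(self.grid, ref_time, ref_conc)
        self.seg_frame = _frame_index_for_segments(self.grid, schedule)
        ref_seg = _trapz_segments(self.grid, self.cref)
        self.ref_frame = frame_average(ref_seg, self.seg_frame, schedule)

    def curve_srtm(self, logpars: np.ndarray) -> np.ndarray:
        """SRTM model curve values at the grid knots."""
        lp = np.atleast_2d(np.asarray(logpars, dtype=float))
        R1 = np.exp(lp[:, 0])
        k2 = R1 * np.exp(lp[:, 1])
        k2a = k2 / (1.0 + np.exp(lp[:, 2]))
        y, _ = exp_conv_pl(k2a, self.grid, self.cref)
        return R1[:, None] * self.cref[None, :] + (k2 - R1 * k2a)[:, None] * y

    def frames_srtm(self, logpars: np.ndarray) -> np.ndarray:
        """Frame-averaged SRTM curves for a batch of (log R1, log k2',
        log BP_ND) vectors."""
        from ._kernels import conv_frames

        lp = np.atleast_2d(np.asarray(logpars, dtype=float))
        R1 = np.exp(lp[:, 0])
        k2 = R1 * np.exp(lp[:, 1])
        k2a = k2 / (1.0 + np.exp(lp[:, 2]))
        delta = np.diff(self.grid)
        a = np.broadcast_to(self.cref[:-1], (k2a.size, delta.size))
        b = np.broadcast_to(np.diff(self.cref) / delta, (k2a.size, delta.size))
        acc = conv_frames(k2a, delta, a, b, self.seg_frame, self.schedule.n_frames)
        fr = acc / self.schedule.frame_duration
        return R1[:, None] * self.ref_frame[None, :] + ((k2 - R1 * k2a))[:, None] * fr


# ---------------------------------------------------------------------------
# public single-TAC simulation API
# ---------------------------------------------------------------------------


def simulate_2tc_tac(
    params: TwoTCParams,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    subject_id: str = "sim",
    region_id: str = "sim",
) -> TissueTAC:
    """Simulate a noiseless frame-averaged 2TCM tissue TAC.

    The model curve is C(t) = (1 - v_B) (C1(t) + C2(t)) + v_B C_wholeplasma(t)
    where C1, C2 are the free/non-displaceable and specifically bound
    compartments driven by the parent plasma input.
    """
    grid = TacModelGrid(input_fn, schedule)
    conc = grid.frames_2tc(params.as_array()[None, :])[0]
    return TissueTAC(subject_id, region_id, schedule, conc)


def simulate_free_input_tac(
    params: FreeTwoTCParams,
    f_P: float,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    subject_id: str = "sim",
    region_id: str = "sim",
) -> TissueTAC:
    """Simulate a 2TCM TAC under the f_P-corrected parameterization.

    The parent input is multiplied by f_P and the parameters are K1/f_P,
    V_ND/f_P, BP_F; the resulting tissue curve is identical to the standard
    parameterization with the equivalent :class:`TwoTCParams`.
    """
    _check_fp(f_P)
    scaled = input_fn.scale_parent(f_P)
    grid = TacModelGrid(scaled, schedule)
    lp = params.as_array().copy()
    # free-parameterization columns: K1/fP, VND/fP, BPF; the engine expects
    # (K1*, VND*, BPND*) with BPND* = BPF / (VND/fP)
    lp_engine = np.array([lp[0], lp[1], lp[2] - lp[1], lp[3], lp[4]])
    conc = grid.frames_2tc(lp_engine[None, :])[0]
    return TissueTAC(subject_id, region_id, schedule, conc)


def simulate_srtm_tac(
    params: SRTMParams,
    ref_time: np.ndarray,
    ref_conc: np.ndarray,
    schedule: FrameSchedule,
    subject_id: str = "sim",
    region_id: str = "sim",
) -> TissueTAC:
    """Simulate a noiseless frame-averaged SRTM target-region TAC.

    C_T(t) = R1 C_ref(t) + (k2 - R1 k2a) [C_ref (x) exp(-k2a t)].
    """
    grid = RefModelGrid(ref_time, ref_conc, schedule)
    conc = grid.frames_srtm(params.as_array()[None, :])[0]
    return TissueTAC(subject_id, region_id, schedule, conc)


def macro_from_micro(params: TwoTCParams, f_P: float | None = None) -> dict:
    """Macro-parameters implied by a 2TCM parameter vector.

    Returns V_ND, BP_ND, BP_P and V_T; BP_F is included when ``f_P`` is
    given and raises otherwise if requested downstream.
    """
    out = {
        "V_ND": params.VND,
        "BP_ND": params.BPND,
        "BP_P": params.BPP,
        "V_T": params.VT,
    }
    if f_P is not None:
        out["BP_F"] = params.BPF(f_P)
    return out
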