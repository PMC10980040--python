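"""Compiled inner loops for the convolution engine.

The exponential-convolution recursion over input segments is the hot path
of both the NLS fitter and the hierarchical sampler.  When numba is
available the fused kernel (segment coefficients + recursion) is
JIT-compiled; otherwise a NumPy fallback with identical semantics is used.

Per segment of length D with input c(s) = a + b s and rate theta, the
propagation coefficients are

    E = exp(-theta D), A = (1 - E)/theta, B = (D - A)/theta,
    IB = (D^2/2 - B)/theta,

with series expansions near theta D = 0; the convolution value advances as
y -> y E + a A + b B and the segment integral is y A + a B + b IB,
accumulated into the frame containing the segment.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _conv_frames_nb(theta, delta, a, b, seg_frame, n_frames):  # pragma: no cover
    R = theta.shape[0]
    M = delta.shape[0]
    acc = np.zeros((R, n_frames))
    for r in range(R):
        th = theta[r]
        y = 0.0
        for m in range(M):
            d = delta[m]
            x = th * d
            if x < 1e-4:
                A = d * (1.0 - x / 2.0 + x * x / 6.0 - x * x * x / 24.0)
                B = d * d * (0.5 - x / 6.0 + x * x / 24.0 - x * x * x / 120.0)
                IB = d * d * d * (1.0 / 6.0 - x / 24.0 + x * x / 120.0 - x * x * x / 720.0)
                E = np.exp(-x)
            else:
                E = np.exp(-x)
                A = (1.0 - E) / th
                B = (d - A) / th
                IB = (d * d / 2.0 - B) / th
            f = seg_frame[m]
            if f >= 0:
                acc[r, f] += y * A + a[r, m] * B + b[r, m] * IB
            y = y * E + a[r, m] * A + b[r, m] * B
    return acc


def _conv_frames_np(theta, delta, a, b, seg_frame, n_frames):
    from .kinetics import _eab

    E, A, B, IB = _eab(theta, delta)
    R, M = E.shape
    acc = np.zeros((R, n_frames))
    y = np.zeros(R)
    for m in range(M):
        f = seg_frame[m]
        if f >= 0:
            acc[:, f] += y * A[:, m] + a[:, m] * B[:, m] + b[:, m] * IB[:, m]
        y = y * E[:, m] + a[:, m] * A[:, m] + b[:, m] * B[:, m]
    return acc


def conv_frames(theta, delta, a, b, seg_frame, n_frames):
    """Frame integrals of exp(-theta t) (x) piecewise-linear input.

    ``theta`` (R,) rates; ``delta`` (M,) segment lengths; ``a``/``b``
    (R, M) per-segment input intercepts/slopes; ``seg_frame`` (M,) maps each
    segment to its frame (-1 = outside all frames).  Returns (R, n_frames)
    integrals of the convolution over each frame (not yet divided by frame
    durations).
    """
    theta = np.ascontiguousarray(theta, dtype=np.float64)
    delta = np.ascontiguousarray(delta, dtype=np.float64)
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    seg_frame = np.ascontiguousarray(seg_frame, dtype=np.int64)
    if HAVE_NUMBA:
        return _conv_frames_nb(theta, delta, a, b, seg_frame, n_frames)
    return _conv_frames_np(theta, delta, a, b, seg_frame, n_frames)
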