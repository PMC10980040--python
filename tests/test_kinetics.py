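"""Kinetic forward-model tests: analytic oracles, model reductions, invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from petmba.kinetics import (
    FrameSchedule,
    FreeTwoTCParams,
    InputFunction,
    SRTMParams,
    TacModelGrid,
    TwoTCParams,
    exp_conv_pl,
    macro_from_micro,
    simulate_2tc_tac,
    simulate_free_input_tac,
    simulate_srtm_tac,
)


def exp_input(rate=1.0, t_dense_end=20.0, h=0.001, t_end=112.0, n_tail=200):
    """Exponential plasma curve sampled densely enough that the
    piecewise-linear interpolation error is below 1e-7."""
    t = np.concatenate([np.arange(0.0, t_dense_end, h), np.linspace(t_dense_end, t_end, n_tail)])
    c = np.exp(-rate * t)
    return InputFunction(time=t, c_plasma_parent=c, c_wholeplasma=c.copy())


@pytest.fixture(scope="module")
def schedule():
    return FrameSchedule.default()


def test_default_schedule_is_20_frames_110_minutes(schedule):
    assert schedule.n_frames == 20
    assert schedule.total_duration == pytest.approx(110.0, abs=1e-9)
    # 3 x 1/3, 3 x 1, 3 x 2, 2 x 5, 9 x 10
    assert np.allclose(schedule.frame_duration[:3], 1.0 / 3.0)
    assert np.allclose(schedule.frame_duration[-9:], 10.0)
    assert schedule.frame_end[-1] == pytest.approx(110.0)


def test_schedule_validation_rejects_bad_frames():
    with pytest.raises(ValueError):
        FrameSchedule(frame_start=[0.0, 1.0], frame_duration=[1.0, -1.0])
    with pytest.raises(ValueError):
        FrameSchedule(frame_start=[0.0, 0.5], frame_duration=[1.0, 1.0])  # overlap


def test_exp_conv_engine_matches_quadrature():
    """Segment-exact convolution vs adaptive quadrature on a random
    piecewise-linear curve, across rate magnitudes incl. the theta->0 limit."""
    rng = np.random.default_rng(0)
    t = np.concatenate([[0.0], np.sort(rng.uniform(0.01, 10.0, 20))])
    c = rng.uniform(0.0, 5.0, t.size)

    def cp(u):
        return np.interp(u, t, c)

    M = t.size - 1
    for theta in [0.0, 1e-9, 1e-5, 0.3, 2.0, 30.0]:
        y, seg = exp_conv_pl(np.array([theta]), t, c)
        val = quad(lambda u: np.exp(-theta * (t[-1] - u)) * cp(u), 0, t[-1], limit=500)[0]
        assert y[0, -1] == pytest.approx(val, abs=2e-6)
        integ = quad(
            lambda s: quad(
                lambda u: np.exp(-theta * (s - u)) * cp(u), 0, s, limit=300
            )[0],
            t[M - 1],
            t[M],
            limit=100,
        )[0]
        assert seg[0, M - 1] == pytest.approx(integ, abs=2e-6)


def test_zero_input_gives_zero_tac(schedule):
    t = np.linspace(0.0, 112.0, 300)
    zero = InputFunction(t, np.zeros_like(t), np.zeros_like(t))
    p = TwoTCParams(np.log(0.1), np.log(0.5), np.log(2.0), np.log(0.05), np.log(0.05))
    tac = simulate_2tc_tac(p, zero, schedule)
    assert np.allclose(tac.c_tissue, 0.0)


def test_bpnd_zero_reduces_to_one_tissue_model(schedule):
    """k3 -> 0 collapses the 2TCM to a 1TC model with the same K1, k2, v_B."""
    inp = exp_input(h=0.01)
    K1, VND, k4, vB = 0.1, 0.5, 0.05, 0.05
    p = TwoTCParams(np.log(K1), np.log(VND), -60.0, np.log(k4), np.log(vB))
    tac = simulate_2tc_tac(p, inp, schedule)
    # 1TC oracle: frame averages of (1-vB) K1 exp(-k2 t) (x) Cp + vB Cwp
    grid = TacModelGrid(inp, schedule)
    k2 = K1 / VND
    _, seg = exp_conv_pl(np.array([k2]), grid.grid, grid.cp)
    from petmba.kinetics import frame_average

    fr = frame_average(seg, grid.seg_frame, schedule)[0]
    oracle = (1 - vB) * K1 * fr + vB * grid.wp_frame
    assert np.allclose(tac.c_tissue, oracle, rtol=1e-10, atol=1e-12)


def closed_form_2tc_frames(K1, VND, BPND, k4, vB, schedule, rate=1.0):
    """Analytic frame averages for Cp(t) = exp(-rate t), C_wb = Cp.

    The model curve is a sum of exponentials; each term and the vascular
    term integrate in closed form over the frames.
    """
    k2 = K1 / VND
    k3 = BPND * k4
    s = k2 + k3 + k4
    disc = np.sqrt(s * s - 4 * k2 * k4)
    th1, th2 = (s + disc) / 2, (s - disc) / 2
    phi1 = K1 * (th1 - k3 - k4) / (th1 - th2)
    phi2 = K1 * (k3 + k4 - th2) / (th1 - th2)

    def term_integral(theta, a, b):
        # int_a^b (exp(-theta t) - exp(-rate t)) / (rate - theta) dt
        first = (np.exp(-theta * a) - np.exp(-theta * b)) / theta
        second = (np.exp(-rate * a) - np.exp(-rate * b)) / rate
        return (first - second) / (rate - theta)

    a, b = schedule.frame_start, schedule.frame_end
    tissue = phi1 * term_integral(th1, a, b) + phi2 * term_integral(th2, a, b)
    vasc = (np.exp(-rate * a) - np.exp(-rate * b)) / rate
    return ((1 - vB) * tissue + vB * vasc) / schedule.frame_duration


def test_2tc_matches_closed_form_for_exponential_input(schedule):
    inp = exp_input()
    K1, VND, BPND, k4, vB = 0.1, 0.5, 2.0, 0.05, 0.05
    p = TwoTCParams(np.log(K1), np.log(VND), np.log(BPND), np.log(k4), np.log(vB))
    tac = simulate_2tc_tac(p, inp, schedule)
    oracle = closed_form_2tc_frames(K1, VND, BPND, k4, vB, schedule)
    assert np.max(np.abs(tac.c_tissue - oracle)) < 1e-6


def test_schedule_past_input_support_raises(schedule):
    t = np.linspace(0.0, 50.0, 100)
    inp = InputFunction(t, np.exp(-t), np.exp(-t))
    p = TwoTCParams(np.log(0.1), np.log(0.5), np.log(2.0), np.log(0.05), np.log(0.05))
    with pytest.raises(ValueError, match="uncovered"):
        simulate_2tc_tac(p, inp, schedule)


# --- free-fraction parameterization ---------------------------------------


def test_free_input_equals_standard_parameterization(schedule):
    inp = exp_input(h=0.01)
    p = TwoTCParams(np.log(0.1), np.log(0.5), np.log(2.0), np.log(0.05), np.log(0.05))
    f_P = 0.07
    free = p.to_free(f_P)
    tac_std = simulate_2tc_tac(p, inp, schedule)
    tac_free = simulate_free_input_tac(free, f_P, inp, schedule)
    assert np.max(np.abs(tac_std.c_tissue - tac_free.c_tissue)) < 1e-10


def test_free_input_fp_one_is_identity(schedule):
    inp = exp_input(h=0.01)
    free = FreeTwoTCParams(np.log(0.1), np.log(0.5), np.log(1.0), np.log(0.05), np.log(0.05))
    # with f_P = 1 the numeric parameter values coincide with the standard ones
    p = TwoTCParams(np.log(0.1), np.log(0.5), np.log(1.0) - np.log(0.5), np.log(0.05), np.log(0.05))
    tac_free = simulate_free_input_tac(free, 1.0, inp, schedule)
    tac_std = simulate_2tc_tac(p, inp, schedule)
    assert np.allclose(tac_free.c_tissue, tac_std.c_tissue, atol=1e-12)


def test_free_params_round_trip():
    p = TwoTCParams(np.log(0.12), np.log(0.4), np.log(3.0), np.log(0.04), np.log(0.03))
    f_P = 0.08
    back = p.to_free(f_P).to_standard(f_P)
    assert np.allclose(p.as_array(), back.as_array(), atol=1e-12)


def test_fp_out_of_range_rejected(schedule):
    inp = exp_input(h=0.01)
    free = FreeTwoTCParams(np.log(0.1), np.log(0.5), np.log(1.0), np.log(0.05), np.log(0.05))
    for bad in [0.0, -0.1, 1.5]:
        with pytest.raises(ValueError):
            simulate_free_input_tac(free, bad, inp, schedule)


# --- SRTM ------------------------------------------------------------------


def test_srtm_identity_when_target_equals_reference(schedule):
    t = np.linspace(0.0, 112.0, 1000)
    cref = np.exp(-0.1 * t) * t  # arbitrary smooth curve
    p = SRTMParams(log_R1=0.0, log_k2prime=np.log(0.15), log_BPND=-60.0)
    tac = simulate_srtm_tac(p, t, cref, schedule)
    # frame averages of the reference curve itself
    from petmba.kinetics import RefModelGrid

    ref_frames = RefModelGrid(t, cref, schedule).ref_frame
    assert np.allclose(tac.c_tissue, ref_frames, rtol=1e-9, atol=1e-12)


def test_srtm_zero_reference_gives_zero(schedule):
    t = np.linspace(0.0, 112.0, 300)
    p = SRTMParams(np.log(0.8), np.log(0.15), np.log(1.5))
    tac = simulate_srtm_tac(p, t, np.zeros_like(t), schedule)
    assert np.allclose(tac.c_tissue, 0.0)


def test_srtm_matches_closed_form_for_exponential_reference(schedule):
    """C_ref = exp(-0.1 t): the convolution and its frame integrals are
    available in closed form."""
    rate = 0.1
    h = 0.001
    t = np.concatenate([np.arange(0.0, 60.0, h), np.linspace(60.0, 112.0, 300)])
    cref = np.exp(-rate * t)
    R1, k2p, BPND = 0.8, 0.15, 1.5
    p = SRTMParams(np.log(R1), np.log(k2p), np.log(BPND))
    tac = simulate_srtm_tac(p, t, cref, schedule)

    k2 = R1 * k2p
    k2a = k2 / (1 + BPND)
    a, b = schedule.frame_start, schedule.frame_end

    def eint(theta, a, b):
        return (np.exp(-theta * a) - np.exp(-theta * b)) / theta

    conv_int = (eint(k2a, a, b) - eint(rate, a, b)) / (rate - k2a)
    oracle = (R1 * eint(rate, a, b) + (k2 - R1 * k2a) * conv_int) / schedule.frame_duration
    assert np.max(np.abs(tac.c_tissue - oracle)) < 1e-6


# --- macro-parameters -------------------------------------------------------


def test_macro_from_micro_hand_example():
    p = TwoTCParams.from_micro(K1=0.1, k2=0.2, k3=0.05, k4=0.025, vB=0.05)
    m = macro_from_micro(p, f_P=0.08)
    assert m["V_ND"] == pytest.approx(0.5, rel=1e-12)
    assert m["BP_ND"] == pytest.approx(2.0, rel=1e-12)
    assert m["BP_P"] == pytest.approx(1.0, rel=1e-12)
    assert m["V_T"] == pytest.approx(1.5, rel=1e-12)
    assert m["BP_F"] == pytest.approx(12.5, rel=1e-12)


def test_unit_vnd_makes_bpp_equal_bpnd():
    p = TwoTCParams(np.log(0.1), 0.0, np.log(2.3), np.log(0.05), np.log(0.05))
    assert p.BPP == pytest.approx(p.BPND, rel=1e-12)


def test_vt_identity_over_parameter_draws():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p = TwoTCParams(*rng.normal([-2.3, -0.7, 0.7, -3.0, -3.0], 0.5))
        assert p.VT == pytest.approx(p.VND + p.BPP, rel=1e-12)


def test_bpf_requires_fp():
    p = TwoTCParams.from_micro(0.1, 0.2, 0.05, 0.025, 0.05)
    out = macro_from_micro(p)
    assert "BP_F" not in out
    with pytest.raises(ValueError):
        p.BPF(0.0)


# --- cross-model invariants --------------------------------------------------


def test_frame_average_converges_to_point_evaluation():
    """1-second frames approximate pointwise evaluation of the model curve."""
    inp = exp_input(h=0.01, t_dense_end=10.0, t_end=15.0)
    p = TwoTCParams(np.log(0.1), np.log(0.5), np.log(2.0), np.log(0.05), np.log(0.05))
    dur = np.full(600, 1.0 / 60.0)
    start = np.arange(600) / 60.0 + 5.0  # away from the sharp initial rise
    sched = FrameSchedule(start, dur)
    tac = simulate_2tc_tac(p, inp, sched)
    grid = TacModelGrid(inp, sched)
    points = grid.curve_2tc(p.as_array()[None, :])[0]
    mid = np.interp(sched.frame_mid, grid.grid, points)
    rel = np.abs(tac.c_tissue - mid) / np.abs(mid)
    assert np.max(rel) < 1e-4


def test_srtm_and_2tc_coincide_for_shared_1tc_kinetics():
    """When target and reference both follow 1TC kinetics with a common V_ND
    and no blood volume, SRTM with BP_ND = 0 reproduces the 2TCM curve."""
    sched = FrameSchedule.default()
    inp = exp_input(rate=0.5, h=0.005, n_tail=2000)
    VND = 0.6
    K1_ref, K1_tgt = 0.09, 0.12
    # reference TAC as a continuous curve on a fine grid
    pref = TwoTCParams(np.log(K1_ref), np.log(VND), -60.0, np.log(0.05), -60.0)
    grid = TacModelGrid(inp, sched)
    ref_curve = grid.curve_2tc(pref.as_array()[None, :])[0]

    ptgt = TwoTCParams(np.log(K1_tgt), np.log(VND), -60.0, np.log(0.05), -60.0)
    tac_2tc = simulate_2tc_tac(ptgt, inp, sched)

    psrtm = SRTMParams(
        log_R1=np.log(K1_tgt / K1_ref),
        log_k2prime=np.log(K1_ref / VND),
        log_BPND=-60.0,
    )
    tac_srtm = simulate_srtm_tac(psrtm, grid.grid, ref_curve, sched)
    rel = np.abs(tac_srtm.c_tissue - tac_2tc.c_tissue) / np.maximum(np.abs(tac_2tc.c_tissue), 1e-12)
    assert np.max(rel) < 1e-3


def test_srtm_params_derived_quantities():
    p = SRTMParams(np.log(0.8), np.log(0.15), np.log(1.5))
    assert p.k2 == pytest.approx(0.12, rel=1e-12)
    assert p.k2a == pytest.approx(0.12 / 2.5, rel=1e-12)
    p0 = SRTMParams(np.log(0.8), np.log(0.15), -60.0)
    assert p0.k2a == pytest.approx(p0.k2, rel=1e-6)
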