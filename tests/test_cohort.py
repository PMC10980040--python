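"""Synthetic-cohort generator tests: determinism, structure, noise model."""

import numpy as np
import pandas as pd
import pytest

from petmba.cohort import (
    CohortConfig,
    assign_scan_dates,
    fp_drift_function,
    generate_cohort,
)


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortConfig(n_hv=4, n_nrm=3, n_ae=3, seed=9))


def test_default_config_sample_composition():
    cfg = CohortConfig()
    assert (cfg.n_hv, cfg.n_nrm, cfg.n_ae) == (57, 50, 53)
    assert cfg.n_subjects == 160
    assert len(cfg.regions) == 8 and "RN" in cfg.regions


def test_generator_is_bit_reproducible(small_cohort):
    again = generate_cohort(CohortConfig(n_hv=4, n_nrm=3, n_ae=3, seed=9))
    pd.testing.assert_frame_equal(small_cohort.subjects, again.subjects)
    pd.testing.assert_frame_equal(small_cohort.tac_table(), again.tac_table())
    pd.testing.assert_frame_equal(small_cohort.blood_table(), again.blood_table())
    assert np.array_equal(small_cohort.truth.log_params, again.truth.log_params)


def test_different_seed_changes_data(small_cohort):
    other = generate_cohort(CohortConfig(n_hv=4, n_nrm=3, n_ae=3, seed=10))
    assert not np.array_equal(small_cohort.truth.log_params, other.truth.log_params)


def test_degenerate_config_reproduces_fixed_effects_exactly():
    """All SDs zero, no noise: every subject x region sits at the structured
    mean and the TACs equal the noiseless model curves."""
    cfg = CohortConfig(
        n_hv=2, n_nrm=2, n_ae=0, seed=3, noise_base=0.0,
        ind_sd=np.zeros(5), tac_sd=np.zeros(5),
        beta_age_logK1=0.0, beta_sex_logK1=0.0, beta_age_logVND=0.0, beta_sex_logVND=0.0,
        delta_nrm_rn=0.0, delta_nrm_proj=0.0,
    )
    coh = generate_cohort(cfg)
    theta = coh.truth.log_params
    # identical parameters across subjects within region
    assert np.allclose(theta, theta[:1], atol=1e-12)
    for j, r in enumerate(cfg.regions):
        assert theta[0, j, 2] == pytest.approx(cfg.region_log_bpnd[r], abs=1e-12)
    # TACs equal the model curve exactly
    from petmba.kinetics import TacModelGrid

    tac = coh.tacs[0]
    grid = TacModelGrid(coh.inputs[tac.subject_id], tac.schedule)
    model = grid.frames_2tc(theta[0, 0][None, :])[0]
    assert np.allclose(tac.c_tissue, model, atol=1e-12)


def test_group_effects_enter_bp_only():
    cfg = CohortConfig(
        n_hv=1, n_nrm=1, n_ae=0, seed=3, noise_base=0.0,
        ind_sd=np.zeros(5), tac_sd=np.zeros(5),
        beta_age_logK1=0.0, beta_sex_logK1=0.0, beta_age_logVND=0.0, beta_sex_logVND=0.0,
    )
    coh = generate_cohort(cfg)
    th = coh.truth.log_params
    rn = list(cfg.regions).index("RN")
    dl = list(cfg.regions).index("DLPFC")
    # BP differs by the configured deltas, other parameters are identical
    assert th[1, rn, 2] - th[0, rn, 2] == pytest.approx(cfg.delta_nrm_rn, abs=1e-12)
    assert th[1, dl, 2] - th[0, dl, 2] == pytest.approx(cfg.delta_nrm_proj, abs=1e-12)
    for p in (0, 1, 3, 4):
        assert np.allclose(th[1, :, p], th[0, :, p], atol=1e-12)


def test_individual_deviation_correlation_recovery():
    """Law-of-large-numbers check on the correlated individual deviations."""
    om = np.eye(5)
    om[np.triu_indices(5, 1)] = 0.5
    om = (om + om.T) - np.diag(np.diag(om))
    cfg = CohortConfig(
        n_hv=5000, n_nrm=0, n_ae=0, seed=12, omega=om, noise_base=0.0,
        tac_sd=np.zeros(5),
    )
    coh = generate_cohort(cfg)
    emp = np.corrcoef(coh.truth.ind_dev.T)
    assert np.max(np.abs(emp[np.triu_indices(5, 1)] - 0.5)) < 0.03


def test_non_pd_omega_rejected():
    om = np.full((5, 5), 0.99)
    np.fill_diagonal(om, 1.0)
    om[0, 1] = om[1, 0] = -0.99  # breaks positive definiteness
    with pytest.raises(ValueError, match="positive-definite"):
        generate_cohort(CohortConfig(n_hv=2, n_nrm=0, n_ae=0, omega=om))


def test_noise_matches_configured_model():
    """The generated frame noise follows SD = base x mean(clean TAC) x
    region scale / weight: standardized noise has unit variance."""
    from petmba.nls import compute_weights
    from petmba.kinetics import TissueTAC

    cfg = CohortConfig(n_hv=10, n_nrm=10, n_ae=0, seed=5, noise_base=0.08)
    cfg0 = CohortConfig(n_hv=10, n_nrm=10, n_ae=0, seed=5, noise_base=0.0)
    noisy = generate_cohort(cfg)
    clean = generate_cohort(cfg0)
    zs = []
    for tn, tc in zip(noisy.tacs, clean.tacs):
        assert (tn.subject_id, tn.region_id) == (tc.subject_id, tc.region_id)
        w = compute_weights(tc)
        scale = cfg.region_noise_scale.get(tn.region_id, 1.0)
        sd = cfg.noise_base * tc.c_tissue.mean() * scale / w
        zs.append((tn.c_tissue - tc.c_tissue) / sd)
    z = np.concatenate(zs)
    assert z.std() == pytest.approx(1.0, abs=0.05)
    assert abs(z.mean()) < 0.06  # ~3.4 standard errors at this replicate count


# --- f_P drift -------------------------------------------------------------


def test_drift_none_is_identity():
    cfg = CohortConfig(drift_shape="none")
    assert np.allclose(fp_drift_function(np.linspace(0, 3650, 50), cfg), 1.0)


def test_drift_linear_endpoint():
    cfg = CohortConfig(drift_shape="linear", drift_linear_total=-0.30)
    assert fp_drift_function(0.0, cfg) == pytest.approx(1.0)
    assert fp_drift_function(cfg.study_span_days, cfg) == pytest.approx(0.70)


def test_drift_smooth_matches_closed_form():
    cfg = CohortConfig(drift_shape="smooth")
    d = np.linspace(0, cfg.study_span_days, 33)
    x = d / cfg.study_span_days
    expected = 1.0 + cfg.drift_smooth_amp * np.sin(2 * np.pi * x) + cfg.drift_smooth_trend * (
        x - 0.5
    )
    assert np.allclose(fp_drift_function(d, cfg), expected, atol=1e-12)


def test_drift_unknown_shape_errors():
    cfg = CohortConfig()
    cfg.drift_shape = "wiggly"
    with pytest.raises(ValueError, match="drift shape"):
        fp_drift_function(0.0, cfg)


def test_drift_with_staggered_dates_induces_spurious_fp_difference():
    """With staggered recruitment and pure measurement drift (no true group
    effect), the measured f_P differs between groups while true f_P does not
    — the fixture behind the drift-confound analysis."""
    cfg = CohortConfig(seed=4, date_mode="staggered", drift_shape="linear")
    coh = generate_cohort(cfg)
    s = coh.subjects
    true_gap = np.log(s[s.group == "HV"]["f_P_true"]).mean() - np.log(
        s[s.group == "NRM"]["f_P_true"]
    ).mean()
    meas_gap = np.log(s[s.group == "HV"]["f_P_measured"]).mean() - np.log(
        s[s.group == "NRM"]["f_P_measured"]
    ).mean()
    assert abs(true_gap) < 0.1
    assert meas_gap > 0.08  # HV measured earlier, less drift -> higher f_P


# --- scan dates ------------------------------------------------------------


def test_concurrent_dates_are_exchangeable_across_groups():
    cfg = CohortConfig(seed=6, date_mode="concurrent")
    dates = assign_scan_dates(cfg)
    s = np.repeat(["HV", "NRM", "AE"], (cfg.n_hv, cfg.n_nrm, cfg.n_ae))
    means = [dates[s == g].mean() for g in ("HV", "NRM", "AE")]
    spread = cfg.study_span_days
    assert max(means) - min(means) < 0.15 * spread


def test_staggered_dates_order_hv_before_nrm():
    cfg = CohortConfig(seed=6, date_mode="staggered")
    dates = assign_scan_dates(cfg)
    s = np.repeat(["HV", "NRM", "AE"], (cfg.n_hv, cfg.n_nrm, cfg.n_ae))
    assert dates[s == "HV"].mean() < dates[s == "AE"].mean() < dates[s == "NRM"].mean()


def test_dates_deterministic_under_seed():
    cfg = CohortConfig(seed=8, date_mode="staggered")
    assert np.array_equal(assign_scan_dates(cfg), assign_scan_dates(cfg))
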