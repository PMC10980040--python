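"""Joint hierarchical model tests: recovery, contrasts, priors, calibration.

Chains are short and cohorts reduced; the checks are on posterior locations
and probabilities, not on full convergence diagnostics.
"""

import numpy as np
import pytest

from petmba.cohort import CohortConfig, generate_cohort
from petmba.hier import HierModelSpec, fit_hier, fit_region_contrast_model, fit_subgroup
from petmba.inference import prior_tail_probability, summarize_contrast


def quick_spec(**kw):
    base = dict(n_chains=2, n_warmup=300, n_draws=300, seed=7)
    base.update(kw)
    return HierModelSpec(**base)


FIVE_REGIONS = ("DLPFC", "MPFC", "ACC", "PCC", "RN")


def test_null_recovery_on_degenerate_cohort():
    """Zero-noise, zero-SD cohort: global intercepts land within 2 posterior
    SDs of the generating values and the group-effect intervals cover 0."""
    cfg = CohortConfig(
        n_hv=5, n_nrm=5, n_ae=0, seed=11, noise_base=0.0,
        ind_sd=np.zeros(5), tac_sd=np.zeros(5),
        delta_nrm_rn=0.0, delta_nrm_proj=0.0,
    )
    coh = generate_cohort(cfg)
    dr = fit_hier(coh, quick_spec(n_warmup=250, n_draws=250))
    for name, truth in (
        ("mu[logK1]", cfg.mu_logK1),
        ("mu[logVND]", cfg.mu_logVND),
        ("mu[logk4]", cfg.mu_logk4),
    ):
        arr = dr.get(name)
        assert abs(arr.mean() - truth) < 2 * arr.std() + 0.02
    for r in ("DLPFC", "RN"):
        arr = dr.get(f"bp_mean[{r}]")
        assert abs(arr.mean() - cfg.region_log_bpnd[r]) < 2 * arr.std() + 0.02
    b = dr.get("beta_group[NRM,RN]")
    lo, hi = np.percentile(b, [2.5, 97.5])
    assert lo < 0 < hi


def test_rn_group_effect_recovery_within_interval():
    """+15% raphe effect on a reduced cohort: the generating value lies
    within the contrast's own 95% interval.  (At 24 subjects the interval is
    wide — between-individual BP variation dominates — so the directional
    check lives in the next test at a detectably sized effect.)"""
    cfg = CohortConfig(n_hv=12, n_nrm=12, n_ae=0, seed=31)
    coh = generate_cohort(cfg)
    dr = fit_hier(coh, quick_spec(regions=FIVE_REGIONS, n_warmup=400, n_draws=400))
    s = summarize_contrast(dr, "beta_group[NRM,RN]")
    target_pct = 100 * (1.15 - 1)
    assert s.ci95[0] - 2 < target_pct < s.ci95[1] + 2


def test_rn_group_effect_detected_when_power_adequate():
    """A 40% raphe effect (theoretical power > 97% at this size) is detected
    with directional probability above 0.9 and recovered within the 95%
    interval."""
    cfg = CohortConfig(
        n_hv=12, n_nrm=12, n_ae=0, seed=37,
        delta_nrm_rn=float(np.log(1.4)), delta_nrm_proj=float(np.log(1.2)),
    )
    coh = generate_cohort(cfg)
    dr = fit_hier(coh, quick_spec(regions=FIVE_REGIONS, n_warmup=400, n_draws=400))
    s = summarize_contrast(dr, "beta_group[NRM,RN]")
    assert s.p_positive > 0.9
    assert s.ci95[0] - 2 < 40.0 < s.ci95[1] + 2


def test_region_contrast_model_detects_rn_dominance():
    """Raphe effect twice the projection effect: P(beta_RN > beta_proj) >
    0.9, and the projection random-slope SD stays small when projection
    effects are homogeneous."""
    cfg = CohortConfig(
        n_hv=12, n_nrm=12, n_ae=0, seed=33,
        delta_nrm_rn=float(np.log(1.3)), delta_nrm_proj=float(np.log(1.3)) / 2,
    )
    coh = generate_cohort(cfg)
    dr = fit_region_contrast_model(coh, quick_spec(regions=FIVE_REGIONS, n_warmup=400, n_draws=400))
    diff = dr.get("beta_group_rn_minus_proj[NRM]")
    assert (diff > 0).mean() > 0.9
    # generator projection effects are homogeneous -> slope SD concentrates low
    assert dr.get("tau_slope[NRM]").mean() < 0.1


def test_region_contrast_model_null_when_effects_equal():
    cfg = CohortConfig(
        n_hv=10, n_nrm=10, n_ae=0, seed=35,
        delta_nrm_rn=np.log(1.1), delta_nrm_proj=np.log(1.1),
    )
    coh = generate_cohort(cfg)
    dr = fit_region_contrast_model(coh, quick_spec(regions=FIVE_REGIONS))
    p = (dr.get("beta_group_rn_minus_proj[NRM]") > 0).mean()
    assert 0.1 < p < 0.9


def test_prior_only_run_reproduces_prior_tail_probabilities():
    """With the likelihood switched off, the sampled group contrast follows
    its Normal(0, 0.2) prior: tail probabilities match the analytic values
    within Monte-Carlo error."""
    cfg = CohortConfig(n_hv=4, n_nrm=4, n_ae=0, seed=3)
    coh = generate_cohort(cfg)
    spec = quick_spec(prior_only=True, n_chains=2, n_warmup=200, n_draws=1500, store_theta=False)
    dr = fit_hier(coh, spec)
    b = dr.get("beta_group[NRM,RN]")
    mc_err = 3.0 / np.sqrt(len(b) / 10)  # generous allowance for autocorrelation
    assert np.mean(np.abs(b) < np.log(1.2)) == pytest.approx(
        prior_tail_probability(0.2, 20), abs=max(0.05, mc_err)
    )
    assert np.mean(np.abs(b) < np.log(1.3)) == pytest.approx(
        prior_tail_probability(0.2, 30), abs=max(0.05, mc_err)
    )
    assert np.mean(b > np.log(1.3)) == pytest.approx(
        prior_tail_probability(0.2, 30, "increase_beyond"), abs=max(0.04, mc_err)
    )
    assert abs(b.mean()) < 0.05


def test_reparameterization_coherence_bpnd_vs_bpp():
    """BP_P inferred from the BPND-mode fit (V_ND x BP_ND draws) agrees with
    the BPP-mode fit's direct BP_P estimates on clean data (within 5%)."""
    cfg = CohortConfig(
        n_hv=8, n_nrm=0, n_ae=0, seed=17, noise_base=0.01,
    )
    coh = generate_cohort(cfg)
    regions = ("DLPFC", "MPFC", "hip", "RN")
    d_nd = fit_hier(coh, quick_spec(mode="BPND", regions=regions))
    d_pp = fit_hier(coh, quick_spec(mode="BPP", regions=regions))
    sids = coh.subjects["subject_id"]
    diffs = []
    for sid in sids:
        for r in regions:
            bpp_from_nd = d_nd.mean(f"theta[{sid},{r},logVND]") + d_nd.mean(
                f"theta[{sid},{r},logBPND]"
            )
            bpp_direct = d_pp.mean(f"theta[{sid},{r},logBPP]")
            diffs.append(bpp_from_nd - bpp_direct)
    assert np.max(np.abs(diffs)) < np.log(1.05)


def test_subgroup_fits_recover_shared_correlation_structure():
    """Two groups generated from one Omega: each subgroup's estimated
    correlation matrix tracks the empirical correlation of that group's
    realized individual deviations, refitting is internally consistent, and
    the two groups' matrices differ only at the sampling-noise scale.

    Note on scale: the empirical correlation of n=20 individual effects has
    a standard error near 0.2, so element-wise differences between matched
    subgroups of several tenths are statistically expected; the assertions
    target recovery and consistency rather than tight numerical agreement.
    """
    from petmba.inference import compare_correlation_matrices, omega_posterior_mean

    cfg = CohortConfig(n_hv=20, n_nrm=20, n_ae=0, seed=19, noise_base=0.02)
    coh = generate_cohort(cfg)
    off = np.triu_indices(5, 1)

    def spec(seed=7):
        return quick_spec(n_chains=1, n_warmup=400, n_draws=700, seed=seed,
                          store_theta=False)

    oms = {g: omega_posterior_mean(fit_subgroup(coh, g, spec())) for g in ("HV", "NRM")}
    groups = coh.subjects["group"].to_numpy()
    for g in ("HV", "NRM"):
        emp = np.corrcoef(coh.truth.ind_dev[groups == g].T)[off]
        assert np.corrcoef(oms[g][off], emp)[0, 1] > 0.3
    # shared-truth comparison: differences stay at the sampling-noise scale
    table = compare_correlation_matrices([oms["HV"], oms["NRM"]], ["HV", "NRM"])
    assert table["max_abs_diff"].iloc[0] < 0.9
    # internal consistency: same data, different sampler seed
    om_again = omega_posterior_mean(fit_subgroup(coh, "HV", spec(99)))
    assert np.corrcoef(oms["HV"][off], om_again[off])[0, 1] > 0.7


def test_subgroup_requires_enough_subjects():
    cfg = CohortConfig(n_hv=2, n_nrm=4, n_ae=0, seed=1)
    coh = generate_cohort(cfg)
    with pytest.raises(ValueError, match="fewer than 3"):
        fit_subgroup(coh, "HV", quick_spec())


def test_null_calibration_of_group_effect_interval():
    """Across 20 null simulations the 95% interval of the RN group effect
    covers 0 in at least 85% of runs."""
    covered = 0
    n_rep = 20
    for rep in range(n_rep):
        cfg = CohortConfig(
            n_hv=4, n_nrm=4, n_ae=0, seed=500 + rep,
            delta_nrm_rn=0.0, delta_nrm_proj=0.0,
        )
        coh = generate_cohort(cfg)
        spec = quick_spec(
            n_chains=1, n_warmup=250, n_draws=250,
            regions=("DLPFC", "hip", "RN"), store_theta=False,
        )
        dr = fit_hier(coh, spec)
        lo, hi = np.percentile(dr.get("beta_group[NRM,RN]"), [2.5, 97.5])
        if lo < 0 < hi:
            covered += 1
    assert covered >= int(0.85 * n_rep)


def test_rhat_warning_is_recorded_not_silent():
    cfg = CohortConfig(n_hv=4, n_nrm=0, n_ae=0, seed=2)
    coh = generate_cohort(cfg)
    # absurdly short chains: R-hat flags must appear in warnings, not raise
    dr = fit_hier(coh, quick_spec(n_chains=2, n_warmup=30, n_draws=30,
                                  regions=("DLPFC", "RN"), store_theta=False))
    assert "convergence" in dr.meta
    if dr.meta["convergence"]["flagged"]:
        assert any("R-hat" in w for w in dr.warnings)


def test_bpf_mode_requires_fp_column():
    cfg = CohortConfig(n_hv=4, n_nrm=0, n_ae=0, seed=2)
    coh = generate_cohort(cfg)
    coh.subjects = coh.subjects.drop(columns=["f_P_measured"])
    with pytest.raises(ValueError, match="f_P"):
        fit_hier(coh, quick_spec(mode="BPF"))
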