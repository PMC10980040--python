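"""Synthetic study-cohort generator with known ground truth.

Emulates a three-group receptor-ligand PET study (healthy volunteers HV,
not-recently-medicated patients NRM, antidepressant-exposed patients AE)
with the default sample sizes 57/50/53, the 20-frame / 110-minute frame
schedule, multi-region TACs generated from the 2TCM with region-dependent
noise (worst in the raphe nuclei), correlated individual-level log kinetic
parameters, group effects on log BP concentrated in the raphe nuclei
(projection-region effects about half as large), and a plasma free fraction
f_P with optional group shifts and/or temporal measurement drift over the
scan dates.

Everything is reproducible bit-for-bit from (CohortConfig, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import FrameSchedule, InputFunction, TacModelGrid, TissueTAC

__all__ = [
    "PARAM_NAMES",
    "GROUPS",
    "SubjectRecord",
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "fp_drift_function",
    "assign_scan_dates",
]

# canonical ordering of the 2TCM log-parameter vector used throughout
PARAM_NAMES = ("logK1", "logVND", "logBPND", "logk4", "logvB")
GROUPS = ("HV", "NRM", "AE")

PROJECTION_REGIONS = ("DLPFC", "MPFC", "ACC", "PCC", "hip", "amy", "ins")
RAPHE = "RN"
CEREBELLUM = ("cer_gm", "cer_wm")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str  # "female" | "male"
    f_P_true: float
    f_P_measured: float
    scan_date: float  # days since study start

    def __post_init__(self):
        if not (0.0 < self.f_P_true < 1.0 and 0.0 < self.f_P_measured < 1.0):
            raise ValueError("f_P must be in (0, 1)")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _default_region_bpnd() -> dict:
    # plausible regional BP_ND pattern for a 5-HT1A antagonist ligand:
    # high in hippocampus and cortical projection regions, moderate in the
    # raphe, near-zero in cerebellar white matter
    return {
        "DLPFC": np.log(2.5),
        "MPFC": np.log(3.5),
        "ACC": np.log(3.0),
        "PCC": np.log(2.8),
        "hip": np.log(4.5),
        "amy": np.log(3.0),
        "ins": np.log(3.3),
        "RN": np.log(2.0),
        "cer_gm": np.log(0.30),
        "cer_wm": np.log(0.05),
    }


def _default_region_dev() -> dict:
    # additive per-region deviations of logK1/logVND/logk4/logvB from the
    # global means (BP has its own per-region means above)
    dev = {r: np.zeros(4) for r in PROJECTION_REGIONS + (RAPHE,) + CEREBELLUM}
    dev["RN"] = np.array([-0.25, -0.15, 0.0, 0.10])
    dev["hip"] = np.array([-0.10, 0.05, 0.0, 0.0])
    dev["cer_gm"] = np.array([0.05, -0.10, 0.0, 0.05])
    dev["cer_wm"] = np.array([-0.30, -0.40, 0.0, -0.10])
    return dev


def _default_omega() -> np.ndarray:
    # moderate positive coupling between delivery and distribution volume,
    # weaker elsewhere; symmetric positive-definite with unit diagonal
    om = np.eye(5)
    pairs = {(0, 1): 0.5, (0, 3): 0.2, (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.15, (0, 4): 0.1}
    for (i, j), v in pairs.items():
        om[i, j] = om[j, i] = v
    return om


@dataclass
class CohortConfig:
    """Generator settings; the defaults define the emulated study conditions."""

    n_hv: int = 57
    n_nrm: int = 50
    n_ae: int = 53
    include_cerebellum: bool = False

    # population means (log scale)
    mu_logK1: float = float(np.log(0.09))
    mu_logVND: float = float(np.log(0.55))
    mu_logk4: float = float(np.log(0.035))
    mu_logvB: float = float(np.log(0.045))
    region_log_bpnd: Mapping[str, float] = field(default_factory=_default_region_bpnd)
    region_dev: Mapping[str, np.ndarray] = field(default_factory=_default_region_dev)

    # between-individual structure
    ind_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.15, 0.20, 0.25, 0.15, 0.20])
    )
    omega: np.ndarray = field(default_factory=_default_omega)
    tac_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.03, 0.05, 0.05, 0.05, 0.05])
    )

    # group effects on log BP_ND (HV is reference)
    delta_nrm_rn: float = float(np.log(1.15))
    delta_nrm_proj: float = float(np.log(1.075))
    delta_ae_rn: float = 0.0
    delta_ae_proj: float = 0.0
    # optional group elevation of reference-region (cerebellar) log BP_ND,
    # applied to both patient groups; probes indirect-quantification bias
    delta_patient_cerebellum: float = 0.0

    # covariate effects
    beta_age_logK1: float = -0.03  # per SD of age
    beta_sex_logK1: float = -0.05  # male - female
    beta_age_logVND: float = 0.02
    beta_sex_logVND: float = 0.0

    # plasma free fraction model
    fp_mu_log: float = float(np.log(0.07))
    fp_sd_log: float = 0.25
    fp_group_shift: Mapping[str, float] = field(
        default_factory=lambda: {"HV": 0.0, "NRM": 0.0, "AE": 0.0}
    )
    drift_shape: str = "none"  # none | linear | smooth
    drift_linear_total: float = -0.30  # multiplicative change over the study span
    drift_smooth_amp: float = 0.15
    drift_smooth_trend: float = -0.20

    # scan dates
    date_mode: str = "concurrent"  # concurrent | staggered
    study_span_days: float = 3650.0

    # measurement noise: per-frame SD = noise_base * mean(model TAC) *
    # region_scale / weight, with NLS-style decay-uncorrected weights
    noise_base: float = 0.05
    region_noise_scale: Mapping[str, float] = field(
        default_factory=lambda: {"RN": 3.0, "cer_wm": 1.5}
    )

    # input-function template (linear rise to a peak, tri-exponential decay)
    aif_amplitude: float = 30.0
    aif_peak_time: float = 0.8
    aif_lambdas: np.ndarray = field(default_factory=lambda: np.array([4.0, 0.25, 0.012]))
    aif_weights: np.ndarray = field(default_factory=lambda: np.array([0.70, 0.20, 0.10]))
    aif_jitter_sd: float = 0.20
    parent_fraction_floor: float = 0.15
    parent_fraction_rate: float = 0.08

    seed: int = 1

    @property
    def regions(self) -> tuple:
        base = PROJECTION_REGIONS + (RAPHE,)
        return base + CEREBELLUM if self.include_cerebellum else base

    @property
    def n_subjects(self) -> int:
        return self.n_hv + self.n_nrm + self.n_ae

    def validate(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (5, 5) or not np.allclose(om, om.T):
            raise ValueError("omega must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(om), 1.0):
            raise ValueError("omega must have unit diagonal")
        if np.min(np.linalg.eigvalsh(om)) <= 0:
            raise ValueError("omega must be positive-definite")
        if min(self.n_hv, self.n_nrm, self.n_ae) < 0:
            raise ValueError("group sizes must be non-negative")
        if np.any(np.asarray(self.ind_sd) < 0) or np.any(np.asarray(self.tac_sd) < 0):
            raise ValueError("SDs must be non-negative")
        if self.drift_shape not in ("none", "linear", "smooth"):
            raise ValueError(f"unknown drift shape {self.drift_shape!r}")
        if self.date_mode not in ("concurrent", "staggered"):
            raise ValueError(f"unknown date mode {self.date_mode!r}")


@dataclass
class GroundTruth:
    """Generating quantities for a synthetic cohort."""

    log_params: np.ndarray  # (n_subjects, n_regions, 5), true TAC-level values
    ind_dev: np.ndarray  # (n_subjects, 5) individual deviations
    fixed_effects: dict
    omega: np.ndarray
    regions: tuple
    subject_ids: list


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    inputs: dict  # subject_id -> InputFunction
    tacs: list  # TissueTAC, noisy
    truth: GroundTruth
    schedule: FrameSchedule
    config: CohortConfig

    def tac_table(self) -> pd.DataFrame:
        rows = []
        for tac in self.tacs:
            for s, d, c in zip(
                tac.schedule.frame_start, tac.schedule.frame_duration, tac.c_tissue
            ):
                rows.append((tac.subject_id, tac.region_id, s, d, c))
        return pd.DataFrame(
            rows, columns=["subject_id", "region", "frame_start_min", "frame_dur_min", "conc"]
        )

    def blood_table(self) -> pd.DataFrame:
        rows = []
        for sid, inp in self.inputs.items():
            for t, p, w in zip(inp.time, inp.c_plasma_parent, inp.c_wholeplasma):
                rows.append((sid, t, p, w))
        return pd.DataFrame(rows, columns=["subject_id", "time_min", "parent_plasma", "whole_plasma"])


# ---------------------------------------------------------------------------


def fp_drift_function(scan_date, config: CohortConfig) -> np.ndarray:
    """Multiplicative distortion of the measured f_P as a function of scan date.

    ``none`` returns 1 everywhere; ``linear`` interpolates from 1 at day 0 to
    1 + drift_linear_total at the end of the study span; ``smooth`` is a fixed
    sinusoid-plus-trend curve.
    """
    d = np.asarray(scan_date, dtype=float)
    x = d / config.study_span_days
    if config.drift_shape == "none":
        return np.ones_like(x)
    if config.drift_shape == "linear":
        return 1.0 + config.drift_linear_total * x
    if config.drift_shape == "smooth":
        return 1.0 + config.drift_smooth_amp * np.sin(2.0 * np.pi * x) + config.drift_smooth_trend * (
            x - 0.5
        )
    raise ValueError(f"unknown drift shape {config.drift_shape!r}")


def assign_scan_dates(config: CohortConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Scan dates (days since study start) per subject, HV block first.

    ``concurrent`` interleaves all groups uniformly over the study span;
    ``staggered`` places HV earliest, then AE, then NRM on average, emulating
    a study in which most controls were imaged before the patients.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    span = config.study_span_days
    if config.date_mode == "concurrent":
        return rng.uniform(0.0, span, config.n_subjects)
    shapes = {"HV": (1.2, 2.8), "NRM": (2.8, 1.2), "AE": (2.0, 2.0)}
    parts = []
    for g, n in zip(GROUPS, (config.n_hv, config.n_nrm, config.n_ae)):
        a, b = shapes[g]
        parts.append(span * rng.beta(a, b, n))
    return np.concatenate(parts)


def _aif_template(t, amplitude, t_peak, lambdas, weights):
    """Linear rise to the peak, tri-exponential decay afterwards."""
    t = np.asarray(t, dtype=float)
    rise = amplitude * t / t_peak
    decay = amplitude * np.sum(
        weights[:, None] * np.exp(-lambdas[:, None] * (t[None, :] - t_peak)), axis=0
    ) / weights.sum()
    return np.where(t <= t_peak, rise, decay)


def _input_grid() -> np.ndarray:
    return np.concatenate(
        [np.linspace(0.0, 3.0, 31), np.linspace(3.4, 10.0, 17), np.linspace(10.8, 111.0, 81)]
    )


def _make_input(config: CohortConfig, rng: np.random.Generator) -> InputFunction:
    amp = config.aif_amplitude * np.exp(rng.normal(0.0, config.aif_jitter_sd))
    tp = config.aif_peak_time * np.exp(rng.normal(0.0, config.aif_jitter_sd / 2))
    t = _input_grid()
    parent = _aif_template(t, amp, tp, np.asarray(config.aif_lambdas), np.asarray(config.aif_weights))
    pf = config.parent_fraction_floor + (1.0 - config.parent_fraction_floor) * np.exp(
        -config.parent_fraction_rate * t
    )
    whole = parent / pf
    return InputFunction(time=t, c_plasma_parent=parent, c_wholeplasma=whole)


def _sex_code(sex: str) -> float:
    # male - female contrast, coded +/- 0.5
    return 0.5 if sex == "male" else -0.5


FEMALE_FRACTION = {"HV": 32 / 57, "NRM": 34 / 50, "AE": 30 / 53}
AGE_RANGE = (18.0, 70.0)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a full synthetic dataset with known ground truth.

    Log kinetic parameters are built as global/region means + covariate terms
    + group effects (on log BP only) + correlated individual deviations +
    TAC-level deviations; TACs are simulated through the 2TCM forward model
    with additive Gaussian noise whose per-frame SD is inversely proportional
    to the NLS weights, scaled per region (largest in the raphe nuclei).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    regions = config.regions
    n = config.n_subjects
    groups = np.repeat(GROUPS, (config.n_hv, config.n_nrm, config.n_ae))

    # demographics
    ages = rng.uniform(*AGE_RANGE, n)
    sexes = np.array(
        ["female" if rng.uniform() < FEMALE_FRACTION[g] else "male" for g in groups]
    )
    dates = assign_scan_dates(config, rng)

    # plasma free fraction: true values and measured (drift-distorted) values
    shift = np.array([config.fp_group_shift.get(g, 0.0) for g in groups])
    f_true = np.exp(rng.normal(config.fp_mu_log + shift, config.fp_sd_log))
    f_true = np.clip(f_true, 1e-3, 0.5)
    f_meas = np.clip(f_true * fp_drift_function(dates, config), 1e-4, 0.9)

    # individual-level deviations, correlated across the 5 log parameters
    ind_sd = np.asarray(config.ind_sd, dtype=float)
    omega = np.asarray(config.omega, dtype=float)
    cov = np.diag(ind_sd) @ omega @ np.diag(ind_sd)
    if np.all(ind_sd > 0):
        u = rng.multivariate_normal(np.zeros(5), cov, size=n, method="cholesky")
    else:
        L = np.diag(ind_sd) @ np.linalg.cholesky(omega + 1e-12 * np.eye(5))
        u = rng.standard_normal((n, 5)) @ L.T

    age_z = (ages - ages.mean()) / ages.std() if n > 1 else np.zeros(n)
    sex_c = np.array([_sex_code(s) for s in sexes])

    # structured means per subject x region
    mu = np.array([config.mu_logK1, config.mu_logVND, 0.0, config.mu_logk4, config.mu_logvB])
    R = len(regions)
    theta = np.zeros((n, R, 5))
    for j, r in enumerate(regions):
        dev = np.asarray(config.region_dev[r], dtype=float)
        theta[:, j, 0] = mu[0] + dev[0]
        theta[:, j, 1] = mu[1] + dev[1]
        theta[:, j, 2] = config.region_log_bpnd[r]
        theta[:, j, 3] = mu[3] + dev[2]
        theta[:, j, 4] = mu[4] + dev[3]
        # group effects on log BP
        if r == RAPHE:
            theta[:, j, 2] += np.where(groups == "NRM", config.delta_nrm_rn, 0.0)
            theta[:, j, 2] += np.where(groups == "AE", config.delta_ae_rn, 0.0)
        elif r in PROJECTION_REGIONS:
            theta[:, j, 2] += np.where(groups == "NRM", config.delta_nrm_proj, 0.0)
            theta[:, j, 2] += np.where(groups == "AE", config.delta_ae_proj, 0.0)
        elif r in CEREBELLUM:
            theta[:, j, 2] += np.where(groups != "HV", config.delta_patient_cerebellum, 0.0)
    # covariates
    theta[:, :, 0] += (config.beta_age_logK1 * age_z + config.beta_sex_logK1 * sex_c)[:, None]
    theta[:, :, 1] += (config.beta_age_logVND * age_z + config.beta_sex_logVND * sex_c)[:, None]
    # individual and TAC-level deviations
    theta += u[:, None, :]
    tac_dev = rng.standard_normal((n, R, 5)) * np.asarray(config.tac_sd)[None, None, :]
    theta += tac_dev

    # subject records
    sids = [f"s{i + 1:03d}" for i in range(n)]
    records = [
        SubjectRecord(sids[i], groups[i], float(ages[i]), sexes[i], float(f_true[i]),
                      float(f_meas[i]), float(dates[i]))
        for i in range(n)
    ]
    subjects = pd.DataFrame(
        {
            "subject_id": sids,
            "group": groups,
            "age": ages,
            "sex": sexes,
            "f_P_true": f_true,
            "f_P_measured": f_meas,
            "scan_date": dates,
        }
    )

    # input functions and noisy TACs
    from .nls import compute_weights  # deferred: avoids import cycle at module load

    schedule = FrameSchedule.default()
    inputs = {}
    tacs = []
    for i, sid in enumerate(sids):
        inp = _make_input(config, rng)
        inputs[sid] = inp
        grid = TacModelGrid(inp, schedule)
        clean = grid.frames_2tc(theta[i])  # (R, F)
        for j, r in enumerate(regions):
            scale = config.region_noise_scale.get(r, 1.0)
            # noise variates are drawn regardless of the noise level so that
            # a zero-noise rerun of the same config+seed yields the exact
            # clean counterpart of every TAC
            eps = rng.standard_normal(schedule.n_frames)
            if config.noise_base > 0:
                w = compute_weights(TissueTAC(sid, r, schedule, clean[j]))
                sd = config.noise_base * float(np.mean(clean[j])) * scale / w
                noisy = clean[j] + eps * sd
            else:
                noisy = clean[j].copy()
            tacs.append(TissueTAC(sid, r, schedule, noisy))

    fixed_effects = {
        "mu": mu,
        "region_log_bpnd": dict(config.region_log_bpnd),
        "delta_nrm_rn": config.delta_nrm_rn,
        "delta_nrm_proj": config.delta_nrm_proj,
        "delta_ae_rn": config.delta_ae_rn,
        "delta_ae_proj": config.delta_ae_proj,
        "beta_age_logK1": config.beta_age_logK1,
        "beta_sex_logK1": config.beta_sex_logK1,
        "beta_age_logVND": config.beta_age_logVND,
        "beta_sex_logVND": config.beta_sex_logVND,
    }
    truth = GroundTruth(
        log_params=theta,
        ind_dev=u,
        fixed_effects=fixed_effects,
        omega=omega,
        regions=regions,
        subject_ids=sids,
    )
    return SyntheticCohort(subjects, inputs, tacs, truth, schedule, config)
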