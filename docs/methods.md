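# Methods

`petmba` implements a joint hierarchical multivariate Bayesian analysis of
receptor-ligand PET kinetics — simultaneous quantification and group
inference across all subjects, regions and time-activity curves (TACs) — a
parameter-level variant that operates on conventional per-TAC estimates,
the classical comparison arms (per-TAC weighted NLS, univariate linear
mixed models, free-fraction ANOVA and drift analysis), and a synthetic
cohort generator with known ground truth against which every stage is
verified.

## Kinetic forward models

**Two-tissue compartment model (2TCM).** The tissue concentration is

    C_model(t) = (1 - v_B) (C1(t) + C2(t)) + v_B C_wp(t)

with compartments driven by the metabolite-corrected arterial parent
concentration C_p(t):

    dC1/dt = K1 C_p - (k2 + k3) C1 + k4 C2
    dC2/dt = k3 C1 - k4 C2

and the whole-plasma curve C_wp standing in for whole blood in the vascular
term.  Parameters are carried on the natural-log scale in one of three
equivalent parameterizations:

- **BPND**: log K1, log V_ND (= K1/k2), log BP_ND (= k3/k4), log k4, log v_B
- **BPP**: BP_ND replaced by BP_P = V_ND BP_ND
- **BPF**: the input is pre-multiplied by the measured plasma free fraction
  f_P; parameters become K1/f_P, V_ND/f_P and BP_F = BP_P / f_P

Derived macro-parameters: V_T = V_ND (1 + BP_ND) = V_ND + BP_P.

**SRTM.** For reference-tissue quantification,
C_T(t) = R1 C_ref(t) + (k2 − R1 k2a) [C_ref ⊗ e^(−k2a t)] with
k2 = R1 k2′ and k2a = k2 / (1 + BP_ND).

**Numerics.** Input functions are piecewise-linear between their samples,
zero before time zero, with no extrapolation past the last sample (an error
instead).  The impulse response of either model is a sum of exponentials,
so the convolution with a piecewise-linear input is evaluated exactly per
segment by the recursion

    y -> y E + a A + b B,     E = e^(-θΔ), A = (1-E)/θ, B = (Δ-A)/θ

with the segment integral y A + a B + b IB, IB = (Δ²/2 − B)/θ, and series
expansions below θΔ = 1e-4.  Frame values are frame averages (integral over
the frame divided by its duration), matching how scanners bin counts; frame
boundaries are merged into the knot grid so frame integrals are exact.  The
recursion is JIT-compiled with numba where available (a NumPy fallback with
identical semantics is kept).  Time is minutes throughout; activity units
are arbitrary but must be consistent between inputs and TACs.

The default acquisition schedule is 20 frames over 110 minutes:
3 × 1/3, 3 × 1, 3 × 2, 2 × 5 and 9 × 10 minutes.

## Synthetic cohort generator

The generator emulates a three-group study (healthy volunteers HV,
not-recently-medicated NRM, antidepressant-exposed AE; default sizes
57/50/53) with eight regions (seven serotonin projection regions and the
raphe nuclei RN; cerebellar grey/white matter optional).  True log
parameters are built as

    θ_ij = regional mean + covariate terms + group effect (log BP only)
           + individual deviation u_i + TAC-level deviation

with u_i ~ MVN(0, diag(s) Ω diag(s)).  Generator defaults (all
configurable, chosen once as plausible for a 5-HT1A antagonist ligand and
held fixed):

- regional BP_ND means 2–4.5 in projection regions, 2.0 in RN, 0.05 in
  cerebellar white matter; K1 ≈ 0.09 mL·cm⁻³·min⁻¹, V_ND ≈ 0.55,
  k4 ≈ 0.035 min⁻¹, v_B ≈ 0.045, with fixed per-region offsets;
- between-individual SDs (0.15, 0.20, 0.25, 0.15, 0.20) on
  (log K1, log V_ND, log BP_ND, log k4, log v_B) and moderate positive
  correlations (largest 0.5 between log K1 and log V_ND);
- TAC-level SDs (0.03, 0.05, 0.05, 0.05, 0.05);
- group effects on log BP_ND: NRM−HV = log 1.15 in RN and log 1.075 in
  projection regions (the raphe effect twice the projection effect), AE = 0;
- sex effect −0.05 and a small age effect on log K1; age effect on
  log V_ND; sex ratios per group and the 18–70 age range follow the
  emulated study's demographics;
- f_P lognormal around 0.07 (log-SD 0.25, matching a 0.07 ± 0.02 spread),
  with optional group shifts and a multiplicative measurement-drift factor
  over the scan date (none / linear, −30% over the study span / a fixed
  sinusoid-plus-trend);
- scan dates over a 10-year span, either concurrent (uniform) or staggered
  (HV earliest, then AE, then NRM, mimicking sequential recruitment);
- arterial inputs from a linear-rise/tri-exponential-decay template with
  subject-level lognormal jitter in amplitude and peak time; whole plasma
  is the parent curve divided by a declining parent fraction.

Frame noise is additive Gaussian with SD = noise_base × mean(clean TAC) ×
region scale / weight, where the weights are the decay-uncorrected NLS
weights of the clean curve and the region scale is 3 for RN (1.5 for
cerebellar white matter): the raphe TACs are by far the noisiest, as in
real data.  The default noise_base is 0.05; the high-noise stress preset
used for the shrinkage comparison is 0.2.  Noise variates are drawn even at
noise_base = 0 so a zero-noise rerun of the same seed yields the exact
clean counterpart of every TAC.  Everything is bit-reproducible from
(config, seed).

What the generator does **not** emulate: radiometabolite contamination of
the plasma input, scanner resolution and partial-volume effects, motion,
and any real-data peculiarities of the emulated study.  Passing tests
therefore demonstrate correct recovery of the generator's model — which
matches the fitted model's assumptions by construction — not performance on
real data.

## Per-TAC weighted NLS

Conventional quantification minimizes the weighted SSE of the
frame-averaged model against the measured frames over the five (2TCM) or
three (SRTM) log parameters.  Weights: sqrt(frame duration × decay-
uncorrected frame value) with the carbon-11 half-life 20.364 min, frame
midpoints for un-correction, negatives clamped to zero, normalized to mean
one per TAC (point estimates are invariant to the normalization).  Eight
fixed starting points span the plausible log-parameter ranges; box
constraints (e.g. v_B ∈ [1e-4, 0.2]) prevent divergence on noisy raphe
TACs.  Jacobians are evaluated by forward differences batched through the
convolution engine.  Non-convergence is flagged, never raised.

## Joint hierarchical model

All TACs enter one model.  For TAC (i, j) the five log kinetic parameters
θ_ij get the linear hierarchy

    θ_ij = fixed effects + u_i + ε_ij,   ε_ij ~ N(0, diag(τ_tac)),
    u_i ~ MVN(0, diag(s) Ω diag(s)),     Ω ~ LKJ(2)

with per-region fixed means for log BP (no global intercept), global means
plus partially pooled region deviations for the other parameters, age and
sex on log K1, log V_ND and log BP, and one group-by-region contrast per
non-reference group per region on log BP only, each under the Normal(0,
0.2) prior.  That prior places 64% of its mass on group differences below
20%, 81% below 30% and 9% on increases beyond 30%.  Global intercept
priors: N(log 0.1, 0.25) for log K1, N(log 0.5, 0.5) for log V_ND,
N(0, 1) for log BP region means, N(log 0.05, 0.5) for log k4 and log v_B
(shifted by −mean log f_P in BPF mode, where the scaled parameters are
larger by 1/f_P).  Pooled-deviation SDs get half-normal priors (0.1 for
TAC-level, 0.3 for region and individual SDs).

**Observation model.**  Frames are Student-t (ν = 4, as a normal
scale-mixture; Gaussian switch available) with scale s_ij / w_ijf: per-TAC
scales s_ij partially pooled toward region scales, themselves pooled toward
a global scale.  Weights are recomputed from each TAC's initial fitted
curve ("model-based weighting") rather than from the measured frames:
weights computed from noisy frames are correlated with the noise and bias
the fit, which measurably degrades parameter recovery.

**Sampler.**  Gradient-free MCMC tailored to the model's structure:

- per-TAC kinetic parameters: componentwise adaptive random-walk
  Metropolis (target acceptance 0.44), vectorised across TACs through the
  batched convolution engine, plus directional proposals along the three
  classic 2TCM trade-off ridges (V_ND/BP_ND at fixed BP_P, K1/V_ND at
  fixed k2, BP_ND/k4 at fixed k3);
- the linear hierarchy (fixed effects, individual effects): conjugate
  Gibbs draws;
- location-exchange moves with exact Gaussian conditionals along the
  likelihood-invariant directions — individual effects vs intercepts,
  region deviations vs global means, group contrasts vs the group's
  individual effects, subject-level covariate coefficients vs individual
  effects, projection random slopes vs the mean projection effect.  These
  directions are only weakly identified (by the priors), and plain Gibbs
  alternation mixes across them extremely slowly;
- variance hyperparameters: Metropolis on the log scale; correlation
  matrices: pairwise Metropolis under the LKJ prior.

Chains start from a fast two-start NLS fit per TAC and a ridge fit of the
linear layer.  Defaults: 3 chains × (800 warmup + 800 draws); reduced
presets are used in the test suite.  Split R-hat and bulk ESS (via arviz)
are attached to every fit; R-hat > 1.05 on a fixed effect is recorded as a
warning, never silenced.  With the likelihood switched off the joint prior
factorizes and is sampled ancestrally (independent draws), which is how the
prior's tail probabilities are verified.

**Individual-level estimates.**  The random effects u_i are reported
per subject (posterior means, with Rao-Blackwellised conditional means
stored alongside).  Because the split between u_i and the subject-level
fixed effects (covariate coefficients, group contrasts, intercept levels)
is identified only by the priors, cross-model comparisons of individual
estimates use the total subject-level score u_i + mean_j(X β)_ij, which is
invariant to that split and sharply identified by the data.

## Parameter-level model

The same hierarchy applied to per-TAC SRTM NLS estimates
(log R1, log k2′, log BP_ND) as a trivariate response, without a TAC
likelihood: group-by-region contrasts on log BP_ND (Normal(0, 0.2)), age
and sex on log k2′, pooled region deviations, correlated individual
deviations (3 × 3 LKJ), and a residual term with estimated 3 × 3
correlation (an independent-residual switch is exposed).  Non-converged
NLS rows are dropped and counted.  All conditionals except the
variance/correlation hyperparameters are linear-Gaussian, so this sampler
is a fast Gibbs sweep with the same exchange moves.

A bias probe quantifies what elevated reference-region specific binding in
patient groups does to indirect BP_ND contrasts: with BP_ND = V_T/V_ref − 1,
raising patients' V_ref forces their apparent BP_ND down, so the indirect
group contrast is biased downward, monotonically in the elevation.

## Classical arms

- **LME**: REML fit of log BP ~ region + sex + age + group:region +
  (1 | subject) via statsmodels MixedLM; group-by-region contrasts reported
  as percent differences 100(exp(β) − 1) with Wald intervals.  With no
  group main effect in the design (as specified), a uniform group shift is
  partially absorbed by the random intercepts at small region counts; the
  Bayesian arms share the same structure.
- **f_P ANOVA**: one-way ANOVA of log f_P across groups; pairwise percent
  differences with Tukey-adjusted p-values (unadjusted switch available).
- **Drift model**: penalized regression of log f_P on group fixed effects
  plus a low-rank thin-plate spline over the scan date (basis dimension 10,
  knots at date quantiles, bending-energy penalty), smoothing parameter by
  REML through the mixed-model representation (profile criterion over one
  variance ratio), and approximate Wald F-tests for the smooth and group
  terms using effective degrees of freedom.  This is implemented directly
  because no REML-penalized GAM is available in the Python stack used; it
  follows the standard construction.  The analysis reproduces the
  drift-confound logic on synthetic data: with staggered recruitment and
  pure measurement drift, the ANOVA flags a spurious group difference that
  the smooth term absorbs.

## Inference layer

Contrast summaries transform draws to percent differences before taking
quantiles (identical for monotone transforms) and report 80%/95% intervals
plus directional probabilities with the tie convention P(β>0) =
mean(β>0) + 0.5 mean(β=0).  Prior tail probabilities are analytic normal
CDFs.  Sample sizes for a two-sided two-sample t-test come from the
noncentral-t power function by integer bisection (smallest n reaching the
target power); a confidence interval on Cohen's d propagates to an interval
on n.  The probability of superiority is Φ(d/√2).  The RMSE comparison
reports 100(1 − RMSE_hier/RMSE_NLS) on log-scale errors against the
generator truth.

## Verification scale and known limitations

The heavy end-to-end checks run at reduced scale: the shrinkage comparison
uses 24 subjects × 8 regions at the high-noise preset with 2 chains ×
(600 + 600) draws; the f_P-correction invariance check uses 20 subjects at
low noise with 2 chains × (500 + 500).  Statistical power at these sizes is
accounted for explicitly in the tests: recovery assertions use effect sizes
whose theoretical detection power exceeds ~97% at the chosen n, and
correlation-matrix comparisons are asserted at the scale sampling theory
permits (the empirical correlation of n ≈ 20 individual-effect vectors
carries a standard error near 0.2).

Known limitations: reference-tissue modelling inside the joint TAC-level
model is not implemented (SRTM enters only through the parameter-level
route); no graphical methods (Logan, MA1); no model comparison (LOO/WAIC);
the sampler is tailored to this model family rather than a general-purpose
HMC, and very small or degenerate datasets rely on its numerical floors
(e.g. residual scales floored at 1e-4).
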