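# petmba

Hierarchical multivariate Bayesian quantification and analysis of
receptor-ligand PET pharmacokinetic data.

## The problem

Quantifying receptor binding from dynamic PET produces, for every subject
and brain region, a time-activity curve (TAC) whose shape is governed by
the two-tissue compartment model (2TCM): delivery K1, non-displaceable
distribution volume V_ND = K1/k2, specific binding BP_ND = k3/k4, efflux
k4 and the vascular fraction v_B.  Binding potential can be referenced to
non-displaceable uptake (BP_ND), total plasma parent (BP_P = V_ND·BP_ND)
or free plasma parent (BP_F = BP_P/f_P, with f_P the plasma free
fraction), or estimated indirectly through a reference region with SRTM.
Conventional practice fits each TAC separately by weighted nonlinear least
squares and then runs a univariate group analysis on one binding outcome —
discarding the other kinetic parameters, and performing very poorly in
small, noisy regions such as the raphe nuclei.

`petmba` instead fits **all TACs of all subjects jointly**: each TAC's five
log kinetic parameters are partially pooled through region means,
covariate effects, correlated individual-level deviations and TAC-level
deviations, with group contrasts on log binding potential under a sceptical
Normal(0, 0.2) prior — one that places 64% of its prior mass on group
differences below 20%, 81% below 30%, and only 9% on increases beyond 30%.
A parameter-level variant applies the same multivariate hierarchy to
per-TAC SRTM estimates when a joint TAC-level fit is not available.  The
package ships a fully specified synthetic-cohort generator (three groups,
eight regions, 20-frame/110-minute schedule, raphe-dominant noise,
free-fraction drift), so every stage is verifiable by parameter recovery.

Intended users: PET methodologists and biostatisticians who want a tested,
reproducible reference implementation of joint hierarchical kinetic
modelling with classical comparison arms.

## Worked example

```python
import numpy as np
from petmba.cohort import CohortConfig, generate_cohort
from petmba.hier import HierModelSpec, fit_hier
from petmba.inference import summarize_contrast

# a reduced synthetic study: 12 controls vs 12 patients, a 40% raphe
# binding elevation and half that in projection regions
cfg = CohortConfig(n_hv=12, n_nrm=12, n_ae=0, seed=37,
                   delta_nrm_rn=float(np.log(1.4)),
                   delta_nrm_proj=float(np.log(1.2)))
cohort = generate_cohort(cfg)

spec = HierModelSpec(n_chains=2, n_warmup=400, n_draws=400, seed=7,
                     regions=("DLPFC", "MPFC", "ACC", "PCC", "RN"))
draws = fit_hier(cohort, spec)
s = summarize_contrast(draws, "beta_group[NRM,RN]")
print(f"RN contrast: {s.percent_median:+.1f}% "
      f"[80% CI {s.ci80[0]:+.1f}, {s.ci80[1]:+.1f}] "
      f"P(beta>0) = {s.p_positive:.3f}")
```

Output:

```
RN contrast: +26.7% [80% CI +15.1, +40.5] P(beta>0) = 1.000
```

The posterior median of the not-recently-medicated vs control raphe
contrast is +26.7% (the generating +40% effect shrunk by the sceptical
prior at this sample size), the 80% credible interval spans +15% to +41%
(`s.ci95` holds the 95% one), and the posterior probability that the
contrast is positive is ~1: the raphe elevation is detected.

A command-line interface mirrors the library:

```bash
petmba simulate --seed 1 --outdir data/
petmba fit-nls --data data/ --outdir nls/
petmba fit-hier --data data/ --outdir fit/ --chains 3 --draws 800
petmba summarize --draws fit/draws.tsv.gz --outdir summary/
```

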