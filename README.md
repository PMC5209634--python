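# b16sim

Mechanistic modeling of CD8+ T cell control of B16F10 melanoma growth, with
empirical-Bayesian calibration.

Transplantable B16 melanoma in C57Bl/6 mice is a standard pre-clinical
system for cancer immunotherapy, and a recurring question in that system is
*which* mechanism limits the efficacy of tumor-infiltrating CD8+ T cells —
too few cells, too little cytotoxicity per cell, progressive functional
deactivation, or loss of MHC class I antigen presentation by the tumor.
`b16sim` implements a three-compartment ordinary-differential-equation
model of the anti-tumor response to adenovirus vaccination (rHuAd5-hgp100 /
rHuAd5-hDCT) and to adoptive T cell transfer, plus the statistical
machinery needed to confront it with time-series data and to weigh
competing model topologies against each other.  It is aimed at systems
biologists and computational immunologists who want a tested, reproducible
pipeline for this class of tumor–immune calibration problem.

## The model

Three compartments: lymph node (fixed volume V_ln), blood (fixed V_b =
1200 mm^3), and a tumor microenvironment whose volume
V_t = eps + C_MHC- + C_MHC+ + V_i * sum(T_E3x) changes with tumor burden.
Key mechanisms, in the field's standard notation:

- vector antigen LV set to 1e5 RLU/mm^3 at the immunization day, decaying
  as dLV/dt = -k_d2 LV;
- age-structured clonal expansion in the node, T_E1a -> ... -> T_E1d, with
  factor-2 progeny per division, antigen-saturable rates LV/(LV+k_g), and
  a checkpoint brake (1 - T_E1d^2/(k_a^2 + T_E1d^2));
- trafficking node <-> blood <-> tumor with compartment-volume conversions;
  adoptive transfer adds cells/V_b to the blood pool instantaneously;
- tumor cells split by MHC class I status: division drives MHC-I+ -> MHC-I-
  (protein halves per division), IFNG restores presentation at
  c_3 IFNG/(k_1+IFNG), and killing is the encounter term
  c_4 (T_E3/V_t)(C_MHC+/V_t) V_t — only antigen-presenting cells die;
- cytokine concentrations obey the product rule
  dC/dt = (1/V)dN/dt - (C/V^2)dV/dt in the changing-volume compartment.

Two variants: **V2** with one tumor-infiltrating lymphocyte (TIL) state (36
free parameters) and **V3** with four TIL states deactivating at
a_4 + a_5 IFNG/(k_1+IFNG), each step scaling cytotoxicity and IFNG output
by gamma (41 free parameters).  Calibration uses the likelihood
P(Y|theta) ∝ [1/SSE(theta)]^(N_obs/2) with an adaptive Metropolis-Hastings
sampler (learned proposal covariance, target acceptance 0.2), Gelman-Rubin
convergence on the *predicted* series, thinning every 200th step, Bayes
Ratios of per-measurand maximum likelihoods for model comparison, and
posterior-ensemble scenario simulation.  `docs/methods.md` has the full
account.

No real measurements ship with the package: a synthetic-data module
reproduces the calibration study's design (three treatment groups, eight
measurands, 448 records, a day-8 outlier block removed by Student's
t-test) from a documented ground-truth parameter table, so every stage of
the pipeline is testable end to end.

## Worked example

```python
import numpy as np
import b16sim as b
from b16sim import synthetic_data as sd, observables as ob, experiments as ex

p = sd.true_parameters("V3")
geom = b.DEFAULT_GEOMETRY
grid = np.arange(0.0, 20.01, 0.25)
for group in ("untreated", "hDCT"):
    traj = b.simulate("V3", p, geom, sd.group_protocol(group), grid)
    print(group, traj.interp(traj.ct(), [10, 15, 20]))

obs = sd.generate(p, "V3", sd.default_design(),
                  sd.NoiseModel(outlier_factor=8.0), seed=1)
filtered, pval = sd.flag_day8_outliers(obs)
print(len(obs), pval, len(obs) - len(filtered))

out = ex.sensitivity_analysis(p, scenarios={"c3_x10": {"c3": 10.0}},
                              n_draws=1, seed=0)
print(out["reference"].median, out["c3_x10"].median)
```

prints (values in mm^3 at days 10/15/20):

```
untreated  tumor mm^3 @ d10/15/20:    18.27    63.78   222.62
hDCT       tumor mm^3 @ d10/15/20:     8.56     7.19     5.98
generated 448 records; day-8 outlier t-test p = 2.80e-18; 9 records removed
day-19 tumor size, ACT reference: 64.5 mm^3; c3 x 10: 0.018 mm^3
```

Untreated tumors grow exponentially at k_p2 - k_d4 = 0.25/day; hDCT
immunization (day 5) holds the tumor near 6–9 mm^3 because its cytotoxic
rate is four orders of magnitude higher than hgp100's.  The generated
448-record dataset carries an injected day-8 artifact in the untreated
qRT-PCR block, which the pooled-variance t-test flags (p = 2.8e-18) and
removes (9 records).  In the adoptive-transfer scenario, multiplying the
MHC-I restoration rate c_3 by 10 collapses the day-19 tumor from 64.5 mm^3
to 0.02 mm^3 — antigen presentation, not TIL number, is the bottleneck.

A `b16sim` command-line interface wraps the same library:
`b16sim generate|simulate|calibrate|compare|scenario|pipeline --help`.

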