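# Methods

## Model structure

The model describes a primary CD8+ T cell response against a defined tumor
antigen (hgp100 or hDCT, delivered by a replication-defective adenovirus
vector) and its effect on subcutaneously implanted B16F10 melanoma, across
three well-mixed compartments.  Time is in days throughout.

**Lymph node** (fixed volume `Vln`).  Vector antigen `LV` (RLU/mm^3) is set
to `LV0 = 1e5` instantaneously on the immunization day and decays
exponentially at rate `kd2` (the vector does not replicate; antigen
production is zero).  Naive CD8+ T cells are recruited from the blood in
proportion to `TN * LV/(LV+kg)` and enter an age-structured differentiation
chain `TE1a -> TE1b -> TE1c -> TE1d`: each transition is a division, so the
flux out of one state appears doubled in the next (protein content halves at
division; the discrete states stand in for a continuous maturation
variable).  Clonal expansion is braked by an immune-checkpoint factor
`1 - TE1d^2/(ka^2 + TE1d^2)`, a saturable negative feedback from the
terminally differentiated state.  `TE1d` is the only state that leaves the
node (rate `a12`), with return trafficking `a21`; compartment-size changes
are handled by `Vb/Vln` volume ratios.

**Blood** (fixed volume `Vb = 1200 mm^3`).  Naive cells are produced at the
derived rate `c1 = kd1 * TN0` so that `TN = TN0` is a steady state before
immunization.  Effectors `TE2` are fed by the lymph node, die at `kd3`, and
traffic reversibly to the tumor (`a23` in; `a32` out, weighted by the
MHC-I-negative volume fraction `Cneg/Vt`, i.e. cells leave when they cannot
find antigen).  An adoptive transfer of `n` cells is an instantaneous jump
`TE2 += n/Vb`; 3e6 cells therefore raise `TE2` by exactly 2500 cells/mm^3.

**Tumor microenvironment** (volume
`Vt = eps + Cneg + Cpos + Vi * sum(TE3x)`, changing in time).  Tumor mass is
carried in volume units and split by MHC class I status.  Division sends
both daughters of an MHC-I+ cell to the negative pool (`+2*kp2*Cpos` into
`Cneg`, `-kp2*Cpos` out of `Cpos`) because surface protein halves per
division; IFNG restores presentation at the saturable rate
`c3 * IFNG/(k1+IFNG)`.  Both pools die at `kd4` independent of T cells.
Killing is a mass-action encounter term
`c4 * (TE3/Vt) * (Cpos/Vt) * Vt` — only MHC-I+ cells are visible to TILs.
TILs (absolute cell counts) enter as `a23*TE2*Vb`, egress in proportion to
`Cneg/Vt`, proliferate in proportion to `Cpos/Vt` (`kp3a`), and die
(`kd5a`); `c4a, kp3a, kd5a` are antigen-specific (one value per immunogen).

Cytokines (IFNG, TNFa; mol/mm^3) live in the changing-volume compartment,
so their concentration equations follow the product rule
`dC/dt = (1/Vt) dN/dt - (C/Vt) dVt/dt` where `N = C*Vt` is the molecule
count.  The implementation computes `dVt/dt` by summing the
already-computed state derivatives, which is algebraically identical to
writing out every dilution term; the test suite verifies both a pointwise
identity against independent molecule bookkeeping and, over 20 simulated
days, agreement with a separately coded and separately integrated
molecule-count system to 0.1% relative error.  IFNG is secreted at `kc1`
per active TIL and cleared at `kd6`; TNFa has a basal rate `kc3` plus a
saturable autocrine feedback `kc2 * TNFa/(k2+TNFa)`, cleared at `kd7`.

**V2 vs V3.**  V2 keeps one TIL state `TE3`.  V3 resolves four states
`TE3a..TE3d` connected by a deactivation flux
`a4 + a5 * IFNG/(k1+IFNG)` (constitutive plus IFNG-fed negative feedback);
each step multiplies cytotoxicity and IFNG output by `gamma in (0,1]`
(`c4b = gamma*c4a`, …, and IFNG secretion weighted `TE3a + gamma*TE3b +
gamma^2*TE3c + gamma^3*TE3d`).  Deactivated states share one proliferation
(`kp3b`) and death (`kd5b`) rate.  Tying `c4b..c4d` to a single geometric
factor keeps the V3 table at exactly 41 free parameters against V2's 36.
With `a4 = a5 = 0`, `gamma = 1`, `kp3b = kp3a`, `kd5b = kd5a`, V3 reduces
exactly to V2 (tested at trajectory level).  In V2 the egressing TIL state
is `TE3`; in V3 only the newly immigrated `TE3a` egresses.

**Fixed geometry** (not calibrated, configurable):
`Vb = 1200 mm^3` (forced by the 3e6-cell / 2500 cells-per-mm^3 dose
conversion), `Vln = 40 mm^3`, `Vi = 2e-7 mm^3` (single T cell),
`Vc = 1.5e-6 mm^3` (single tumor cell), `eps = 1e-3 mm^3` (stromal volume
that keeps `Vt > 0`).  Unobserved states start at 2e-16 ("near zero");
`Cneg(0) = implant_cells * Vc`, `TN(0) = TN0`.

## Observation model

Eight measurands map trajectories to the assays:

| measurand | map | units |
|---|---|---|
| luciferase | `LV` | RLU/mm^3 |
| LN activated CD8 | `beta5 * (TE1a+..+TE1d)` | a.u. |
| blood percent | `100 * TE2/(TE2 + beta4)`, clamped to [0, 100] | % |
| tumor volume | `Cneg + Cpos` | mm^3 |
| TCRa mRNA | `BG1 + beta1 * sum(TE3x)/Vt` | rel. expr. |
| IFNG mRNA | `BG2 + beta2 * (TE3a + g*TE3b + g^2*TE3c + g^3*TE3d)/Vt` | rel. expr. |
| TNFa mRNA | `BG3 + beta3 * (kc2*TNFa/(k2+TNFa) + kc3) * sum(TE3x)/Vt` | rel. expr. |
| TIL count | `sum(TE3x)` (absolute cells) | cells |

`BG1..BG3` are non-specific assay backgrounds (every transcript prediction
is bounded below by its background), `beta1..beta3` assay scales.  The
percent readout needs a denominator that the assays never define, so the
total blood CD8 concentration `beta4` is a free scale; likewise the lymph
node readout has unspecified units and gets a free linear scale `beta5`.
Both choices keep the free-parameter counts at 36/41.  Tumor sizes stay in
the model's native mm^3; published mm^2 tumor-area axes are not
geometrically converted (no conversion is defined), which is flagged in the
scenario outputs.

## Synthetic study generator

The generator emulates the calibration campaign: three groups (untreated,
hgp100, hDCT), implantation of 1e6 B16F10 cells at day 0, immunization at
day 5, observation days 5–18 with TIL counts only at days 10 and 15, and a
total of exactly 448 records.  Only that total is recorded for the original
data, so the per-slot breakdown (3 replicates per group x measurand x day;
4 for untreated tumor volume and for TIL counts) is fixed once in
`synthetic_data.default_design()` and documented there.  Replicate scatter
is multiplicative lognormal (`sigma = 0.3` on the natural log) for strictly
positive measurands and additive Gaussian (2 percentage points) for the
blood percent; both are configurable.  An optional day-8 multiplicative
shift on the untreated qRT-PCR block emulates the outlier block in the
original data; `flag_day8_outliers` applies the removal rule — a two-sided
pooled-variance Student's t-test of the pooled day-8 transcript values
against all other untreated days, removal at `p < alpha` (default 1e-3).

The ground-truth parameter table (`synthetic_data.true_parameters`) adopts
the published posterior medians for the cytotoxic rates
(`c4a` = 0.0038 / 118.4 mm^6 cell^-1 day^-1 for hgp100 / hDCT under V3;
0.0084 / 101.8 under V2 — the 1e4-fold antigen contrast).  Every other
value is a physiological choice fixed once to reproduce the study's
qualitative behavior: untreated tumors grow exponentially at
`kp2 - kd4 = 0.25`/day to ~220 mm^3 by day 20; the blood effector response
peaks near 29% of total CD8 around day 13; hDCT immunization holds the
tumor near 6–9 mm^3 through day 20 with escape after day 25, while hgp100
tracks the untreated curve; and under V3 the IFNG transcript peaks at day
~14, two days before TCRa/TNFa, because feedback deactivation
(`a5 >> a4`, log10 a4/a5 = -2.3) strips IFNG output faster than it removes
cells.  IFNG is saturating (`k1` well below the IFNG level whenever TILs
are present), so tumor control is conversion-limited: the asymmetry between
the antigens comes from the fraction of converted MHC-I+ volume that is
killed rather than recycled by division, which is ~1 for hDCT and ~0.1 for
hgp100.

What the generator does **not** emulate: biological cage/batch structure or
any replicate correlation; measurement censoring and detection limits; the
carrying-capacity plateau real B16 tumors reach (~350 mm^2); inter-animal
kinetic heterogeneity (all replicates share one true trajectory).  Passing
the recovery tests therefore demonstrates that the pipeline is correct and
internally calibrated, not that the model fits any real dataset.

## Calibration machinery

**Likelihood.**  Goodness of fit is the summed squared error between
observations and predictions joined on (group, measurand, day), with
per-(group, measurand) partial sums retained.  The likelihood is
`P(Y|theta) ∝ (1/SSE)^(N_obs/2)`, i.e.
`log L = -(N_obs/2) log SSE` — the Gaussian likelihood with the noise
variance profiled out.  SSE below 1e-12 is clamped with a warning (the
likelihood is improper at SSE -> 0).  Residuals are computed on log10
values for strictly positive measurands and linearly for the percent
readout; this equalizes scales across measurands that span six orders of
magnitude and matches the generator's lognormal noise.  The scale is
configurable.

**Parameterization and prior.**  Sampling runs in log10 parameter space
under a uniform prior on a bounded box, `[1e-8, 1e8]` per rate by default;
`gamma` is sampled on a linear scale in (0, 1].  For desk-scale runs an
optional narrower box (+/- `bounds_halfwidth` decades around the initial
guess) is available — with hundreds of observations the posterior occupies
~0.01 decades per identifiable direction, and no random search can locate
it inside a 16-decade box at desk budgets.

**Start.**  Simulated annealing with geometric cooling over the
log-likelihood; the starting temperature defaults to the standard deviation
of the log-likelihood over the initial uniform draws (so acceptance works
on the objective's natural scale at any `N_obs`), the step width cools with
the square root of the temperature, and the best of several independent
restarts (default 3) is used.  A zero-step schedule degenerates to the best
initial draw.

**Sampler.**  Metropolis-Hastings with a multivariate Gaussian proposal.
During the learning period the proposal covariance is re-estimated every
100 steps from the trailing half of the chain history (dropping the early
climb toward the mode, which would otherwise leave the frozen proposal
elongated along the approach path), and the global scale follows a
Robbins-Monro recursion with decaying gain toward the target acceptance
fraction 0.2.  After the learning period both are frozen, so the remainder
is a valid fixed-kernel MH chain.  Proposals outside the prior box are
rejected.  Each chain archives every step: coordinates, log-likelihood,
per-measurand SSE and the predicted series on the observation days.

**Convergence and pooling.**  The Gelman-Rubin potential scale reduction
factor is computed on the archived predicted series (not raw parameters),
per time point, over two or more chains after burn-in.  A prediction column
that is constant and identical across chains (e.g. LV at the immunization
day, pinned by the event) is converged by construction and reports 1.0; a
column constant within chains but different between them raises a
degenerate-variance error.  `pool` refuses to pool (overridable) while any
predicted series has R-hat above 1.1, then retains steps
`burn, burn+stride, …` (stride 200 by default) from each chain and
concatenates.  Credible bands are pointwise medians and 2.5/97.5
percentiles over the ensemble.  The point estimate ("expectation maximum")
is the best-likelihood retained sample, ties resolving to the first in
chain/step order.

**Desk-scale profile.**  Full-scale runs (4 chains x >= 1e6 steps, learning
period 1e5, burn-in 3e5) are supported by the same code path but take
CPU-weeks.  The default test profile calibrates a practically identifiable
subset of parameters (vector decay `kd2`, lymph-node proliferation `kp1`,
blood effector death `kd3`, tumor growth `kp2`, the blood-readout scale
`beta4` and MHC-I restoration `c3` — the rest fixed at their generating
values) on a reduced design (untreated + hDCT groups, 280 records) with 4
chains x 5e4 steps, a 1e4-step learning period, burn-in 2e4 and a
+/-2-decade prior box, completing in ~10 minutes on one CPU.  Subsets that
include practically non-identifiable pairs (e.g. a secretion rate with its
assay scale) leave the chains in distinct ridges of the flat directions at
this chain length; the identifiability report is the tool for spotting
such pairs before calibrating them.  Chains start from one annealed point with small jittered
dispersal; the Gelman-Rubin check is correspondingly a within-basin mixing
diagnostic at this scale.

## Model comparison

The Bayes Ratio between models r and i is the ratio of the *maximum*
per-measurand likelihood over the retained converged samples,
`B_ri = Max_k P(Y|theta_k, M_r) / Max_k P(Y|theta_k, M_i)`, with that
measurand's own `N_obs` in the exponent and each (group, measurand) pair
scored independently.  Bands: B in [1, 3] weak, (3, 20] positive, (20, 150]
strong, > 150 very strong; below 1 the evidence favors the other model.
The lower boundary is closed (B = 1 classifies as weak).  No
marginal-likelihood estimators (harmonic mean, bridge sampling) are used —
the max-likelihood ratio is the statistic of record.

Posterior structure: pairwise Pearson correlations of log10 parameters
across the ensemble, with |r| > 0.95 flagged practically non-identifiable
(constant columns report NaN and are never flagged), and log10 ratio
statistics of named parameter groups (mean, SD, exceedance probabilities),
e.g. the deactivation balance `a4/a5` or the deactivated cell-fate share
`(a4+a5)/(kp3a+kd5a+a4+a5)`.

## Scenario experiments

The ACT validation uses a protocol with no vaccine, an implant of 5e5
cells, transfers of 3e6 cells at days 10 and 15 (TE2 jumps of 2500
cells/mm^3) and the hgp100 antigen-specific rates (pmel-1 cells recognize
gp100).  The sensitivity scan draws parameter sets with replacement from
the posterior ensemble (jointly, preserving correlations), applies
multiplicative overrides — `kc1 x 1e5`, `kp3a x 1e5`, `kd5a x 1e-5`, all
three together, `a32 x 1e-5` (the text's "K32", read as the tumor-egress
trafficking rate: reducing it retains TILs), `gamma := 1` (equalizing
`c4a..c4d`), `a4 & a5 x 1e-5`, `c3 x 3` and `c3 x 10` — and snapshots tumor
size at day 19.  The "c3 decreased by a factor of 3" phrasing in the source
narrative contradicts its own context and is implemented as an increase.
Scenario medians are compared with a two-sided Mann-Whitney rank-sum test
(the size distributions are heavily skewed, so a distribution-free test is
appropriate; identical samples report p = 1).  All scenarios of one
analysis share the seed, so factor-1 overrides reproduce the reference
distribution bit-for-bit and p-values isolate the perturbation.

The timing scan immunizes with hDCT at days 0/5/10 against a half-size
implant (5e5 cells), optionally combined with `c3 x 3`, and returns
credible bands of blood CD8 concentration and tumor size to day 50 per arm,
plus an untreated arm.  Later immunization shifts the blood CD8 peak later
(tested); tumor sizes are in mm^3 (see above).

## Numerical choices

- Stiff piecewise integration with LSODA (`rtol = 1e-6`, `atol = 1e-9` by
  default); protocol events are stop-and-restart state jumps, never steep
  forcing functions.  Values reported at an event day are post-event
  (right-continuous).  The RHS kernels are numba-compiled with IEEE error
  semantics so pathological parameter draws produce inf/nan and a graceful
  integrator failure (scored as zero likelihood) rather than an exception.
- LV decay is always active; before the bolus LV is 2e-16, so the decay of
  the pre-immunization branch is immaterial (< 1e-16 RLU/mm^3 throughout).
- Small negative integrator dust is clamped to zero between segments; the
  non-negativity guarantee is `state >= -10 * atol` along trajectories.
- The t-test pools the three transcripts' day-8 values as one sample; with
  fewer than two values on either side it raises rather than guessing.
- `mxstep = 4000` bounds the integrator inside the calibration hot path;
  an exhausted budget is treated as a failed (zero-likelihood) draw.

## Known limitations

- No carrying capacity: untreated tumors grow exponentially without bound,
  so long-horizon untreated simulations (day 50) reach volumes no real
  tumor attains.  This is by design; the model is not meant for the
  plateau regime.
- The desk-scale convergence diagnostic is within-basin (jittered starts
  from one annealed point); fully dispersed starts at full chain lengths
  are supported but not exercised by the tests.
- The SSE likelihood treats all residuals of a scale class as
  exchangeable; there is no per-measurand noise parameter.
- Antigen-specific kinetics are resolved only for the two immunogens
  studied; no CD4+ compartment, no spatial structure, no vector
  re-administration.
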