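# Methods

## The model

Dexmedetomidine disposition is described by a three-compartment mammillary
model with first-order elimination from the central compartment,
parameterised as clearances and volumes: elimination clearance CL,
intercompartmental clearances Q2 (rapid) and Q3 (slow), and volumes V1
(central), V2, V3. The kinetics are linear, so the amount vector obeys
`da/dt = A a + b(t)` with a piecewise-constant input `b`. The engine
diagonalises the rate matrix once per parameter set and propagates the state
exactly across each constant-rate segment; cumulative elimination is
integrated analytically from the same eigen-expansion, which makes the
mass-balance identity (dosed − eliminated = amounts present) an independent
audit rather than a bookkeeping tautology. A stiff ODE integration
(`scipy.solve_ivp`, LSODA at rtol 1e−11) serves as the reference oracle in
tests; agreement is at the 1e−11 level, far inside the 1e−4 contract.

### Covariate model

Parameters are standardised to a 70 kg adult male (height 1.76 m, predicted
fat-free mass 56.1 kg) by theory-based allometry on *normal fat mass*
(NFM = FFM + Ffat·fat mass), with exponent 3/4 for clearances and 1 for
volumes. Clearances scale on FFM alone (Ffat_CL fixed at 0); volumes scale
on NFM with Ffat_V = 0.293, i.e. about 29% of fat mass behaves like
fat-free mass for distribution volume. The standard NFM is recomputed per
parameter class from the reference subject with that class's Ffat, so the
reference subject maps exactly onto the typical values.

Fat-free mass is taken from a DXA-style measurement when available;
otherwise it is predicted — Al-Sallami equations below 18 years (an age- and
sex-dependent prefactor on the adult form, male limit 0.88 and female limit
1.11 at birth), Janmahasatian equations from 18 years. Elimination clearance
additionally carries a sigmoid maturation factor in postmenstrual age,
MF = PMA^Hill/(TM50^Hill + PMA^Hill) with TM50 = 52.4 weeks and Hill fixed
at 1: about 43% of mature clearance at term and 79% at three years.
Maturation applies to CL only; Q2/Q3 use the allometric factor without
maturation, since the maturation function describes the maturation of
elimination clearance. Missing PMA is imputed as `age·52.18 + 40` weeks
(term birth assumed).

## The synthetic-trial generator

No individual-level clinical data are distributed, so every downstream
stage is exercised on simulated trials that emulate the five pooled study
designs: a TCI adult study (represented by its published surrogate — 2 µg/kg
over 10 min then 1 µg/kg/h for 2 h), a paediatric post-cardiac-surgery
study (1–4 µg/kg over 10 min, sparse sampling), an obese/non-obese adult
infusion study (0.5 µg/kg then 0.25 or 0.5 µg/kg/h), an adult laparoscopy
study (0.5 µg/kg then 0.5 µg/kg/h, long washout) and a short low-dose study
in healthy volunteers. Covariates are drawn per design: age uniform (adults)
or log-uniform (children), height from an age–height reference curve ±5%,
weight log-uniform within the design's weight or BMI range (children: around
a growth-reference median), sex Bernoulli(0.5), all clipped to the pooled
envelope of 3.1–152 kg. The growth reference is a 13-point interpolation of
published growth-chart medians — adequate for generating plausible
covariate combinations, not for auxology.

Between-subject variability is lognormal per parameter (defaults: PPV% of
35.8 for CL, 103.9/41.8/61.6 for V1/V2/V3, 63.2/89.7 for Q2/Q3). Residual
error is the combined proportional + additive form
SD = sqrt(pred²·cv² + sd²)·exp(η_RUV) with cv = 0.19, sd = 0.004 µg/L and a
32% lognormal subject-level scale effect. Observations below the 0.005 µg/L
quantification floor are redrawn rather than censored, so the estimator need
not model below-quantification records. What passing tests on these trials
demonstrate is internal consistency of the whole pipeline — that the
estimator recovers what the generator put in at realistic designs, noise
levels and sample sizes. They cannot demonstrate robustness to features the
generator does not emulate: assay-specific error structure, dropout,
model misspecification of the structural kinetics, or covariate
distributions of any particular clinic.

## Estimation

The marginal likelihood is approximated per subject by a Laplace expansion
at the conditional mode of the random effects — the
first-order-conditional-with-interaction analogue: the residual SD is
evaluated at the conditional prediction. The conditional mode is found by a
penalised Gauss-Newton search with a backtracking line search and
Levenberg-style damping on rejection; the gradient includes the interaction
terms from the prediction-dependent residual variance (both the weight
1/g² and the log g² penalty move with the prediction — omitting them leaves
the search at a false stationary point a few tenths of a −2LL unit above
the mode, enough to visibly distort population estimates). The curvature
term uses the Gauss-Newton Hessian J'WJ + Ω⁻¹, which is positive definite
by construction. On one-random-effect subjects the objective agrees with
64-node adaptive Gauss-Hermite quadrature to ~0.1 units (contract: 0.5).
The mode search always starts from the prior mean so the objective is a
deterministic function of the parameters; warm starts were tried and
rejected because the path dependence corrupted outer finite-difference
gradients.

The per-subject contribution runs as a compiled (numba) kernel; the
interpreted kinetics in `model_core` is the reference implementation the
kernel is tested against. Population parameters — typical values, omega
standard deviations and the proportional error — are optimised on the log
scale with L-BFGS-B (finite-difference gradients, step 1e−5 on the log
scale, a ±4 log-unit trust box, and a large finite penalty in place of
non-finite objective values, which the line search handles better than
inf). Convergence to "three significant digits" is operationalised as
relative parameter change below 1e−3 with objective change below 0.01.
Confidence intervals come from a central-finite-difference Hessian of the
−2LL at the optimum (delta method back to the natural scale), and
alternatively from a stratified nonparametric bootstrap (resampling
subjects within study, refitting, percentile intervals; non-converged
replicates are excluded and counted). The subject-level residual-scale
effect η_RUV is simulated but not estimated by the default fit model; its
effect is absorbed into the residual CV estimate and, empirically, leaves
typical-value recovery unbiased.

### Parameter-recovery experiment

The headline recovery experiment simulates 100 subjects per replicate — 55
paediatric (ages from two days to 16 years, so ≈35 subjects are under two
years) and 45 adults across the four adult designs, all with a rich 15-point
sampling grid — and refits from initial values displaced by factors of 2 or
1/2, estimating all six typical values, TM50, six omegas and the
proportional error. A single replicate of this size leaves 3–5% sampling
scatter on typical clearance and 10–15% on TM50 (TM50 and CL_std are
partially confounded through the adult maturation plateau), so the
experiment reports the median of three independent replicates. Runtime is
roughly 1–3 minutes per replicate on one CPU.

## Diagnostics

Prediction errors follow the Sheiner–Beal convention, pe = Cp − Co, with
bias = mean(pe) and precision = rmse; the percent variant normalises by the
prediction. The prediction-corrected VPC multiplies each observation (and
each of its simulated replicates) by median(PRED in bin)/PRED with PRED the
typical-value prediction, bins by default 8 quantile bins of time after
first dose (bins under 5 observations are merged), and compares observed
10/50/90th percentiles with 95% confidence bands of the same percentiles
across ≥100 simulated population replicates. Self-simulation at 500
subjects puts the observed percentiles inside the bands in ≈95% of bins;
halving CL in the evaluated model throws the observed median below the band
in terminal bins.

## Dosing

The steady-state maintenance rate is pure arithmetic, CL·Css·60/weight in
µg/kg/h. The loading dose is defined as the constant-rate 30-minute
infusion whose end-of-infusion concentration equals the target (solved by
`brentq` to 1e−6 µg/L; 30 minutes because rapid loading provokes
haemodynamic instability). The stepped maintenance schedule recomputes, at
each step, the rate that balances elimination at the target plus the net
flux into the still-filling peripheral compartments; simulated concentration
stays within 2% of target beyond 45 minutes and the rates decay to CL·Css.
The demographic dosing table assumes male subjects (the standardisation
subject is male). Computed clearances for the table's younger rows run some
5–15% below the published simulated table under every FFM-equation variant
tried (the original simulation software and its FFM conventions are not
fully specified); the 20-year row agrees within 2%. The published loading
doses (0.31–0.40 µg/kg) are not reproducible under end-of-infusion
targeting with V1 = 25.2 L/70 kg and are reported as computed, roughly
1.0–1.3 µg/kg, a documented discrepancy.

## Numerical choices and edge cases

- Internal units: min, L, L/min, µg, µg/L; the CLI converts hours on input.
- Eigenvalue 0 (a decoupled compartment, e.g. Q3 = 0) is handled by the
  analytic limits of (e^{λτ}−1)/λ and its integral; both have series
  branches below |λτ| = 1e−8.
- Negative computed fat mass (predicted FFM above body weight) is clamped
  to zero with a warning.
- The likelihood-ratio boundary is strict: ΔOBJ exactly 3.84 on one degree
  of freedom is not significant.
- Shrinkage is clipped to [0, 100]% and undefined (NaN with a warning) for
  a zero omega.
- Variance decomposition clamps a negative covariate-explained variance to
  zero with a warning.
- ELS note: with prediction-proportional weighting, the fixed-effects
  objective on noise-free data is minimised O(cv²) away from the exact
  interpolant — visible in tests only because they use tiny assumed errors.

The recovery design's sampling grid ends at 480 minutes. Extending it deep
into the washout (900–1200 min) was tried and rejected: simulated
concentrations there approach the quantification floor, where the
generator's redraw policy makes the observation noise non-Gaussian and the
Gaussian likelihood responds with badly distorted optima. The price of the
truncated grid is that the slow peripheral volume V3 — identified mainly by
late washout — carries a median bias of roughly −15% at this design, while
CL, TM50 and V1 recover with median biases near zero, −2% and +11%
respectively over an eight-replicate sweep.

## Known limitations

- FOCE-I is approximated by Laplace-at-the-mode with a Gauss-Newton
  curvature, not by NONMEM's exact linearisation; differences are well below
  sampling noise at the tested scales but the objective values are not
  NONMEM-comparable to the decimal.
- Omega is diagonal; no inter-occasion variability; no below-quantification
  handling.
- The generator's covariate distributions are design-shaped approximations,
  not resamples of the original demographics, so recovered-parameter
  uncertainty here need not match the published confidence intervals.
- Effect-site modelling, haemodynamic response and assay error structure
  are out of scope.
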