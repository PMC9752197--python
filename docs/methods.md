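# Methods

## Structural model

Disposition is a three-compartment mammillary system with first-order
elimination from the central compartment, parameterised by clearances and
volumes (CL, V1, Q2, V2, Q3, V3; units L/h and L, amounts in mg, times in h,
concentrations in mg/L).  A linear-versus-saturable elimination comparison is
a standard step in developing such models; this package implements the linear
form only, which is the structure the pipeline is built around, and does not
provide Michaelis–Menten elimination.

Oral input uses a transit-compartment chain: the absorbed fraction `F·Dose`
enters a chain of `n_transit` compartments, all with rate constant `ktr`, and
the final (depot) compartment empties into central at the dose-specific
absorption rate constant (`ka_fed` or `ka_fasted`).  Food status is a
dose-level covariate, so crossover fed/fasted designs are representable; a
subject receiving both carries two independent chains in the state vector.
Design choices here:

- `n_transit` defaults to 3 — enough to produce a realistic sigmoid
  absorption onset while keeping the state small; it is a model setting, not
  an estimated quantity.
- The fed/fasted distinction is carried by `ka` alone; `ktr` is shared.
  Setting `ktr = None` ties the transit rate to the dose's `ka`, a common
  alternative parameterisation; the default is an independent `ktr`.
- No absorption lag time: the transit chain itself supplies the delay.
- IV doses enter the central compartment; an infusion is a zero-order input
  over its duration.

### Numerics

Profiles are propagated exactly between events (doses, infusion ends,
sampling times) with the matrix exponential of the full linear system;
constant infusion input uses the standard augmented-matrix form, so no
inversion of the system matrix is required.  The matrix exponential is robust
to the repeated eigenvalue (`ktr`, multiplicity `n_transit`) that makes the
transit chain defective and defeats eigendecomposition-based closed forms.
All per-segment propagators for one profile are formed in a single stacked
`scipy.linalg.expm` call.  Observations falling exactly on a dose time are
evaluated *before* the dose (pre-dose/trough convention), on both the
simulation and estimation paths.

Because the system is linear, every profile splits as `a(t) + F·b(t)` with
`a` the IV response and `b` the oral response per unit bioavailability.  The
estimator exploits this: moving along the bioavailability random effect never
re-propagates the kinetics, and profile pairs are memoised on the clearance
random effect.

Steady-state metrics for a periodic regimen come from the exact linear-system
identities: the pre-dose state solves `(I − e^{Aτ}) x_ss = d` with `d` the
one-interval response, and `AUC_τ = (−A^{-1} b)_central / V1` for the total
per-interval input `b` (hence `AUC_τ = F·Dose/CL` exactly).  Cmax/Cmin are
read off a 400-point grid over one interval.

## Population model and covariates

Body weight is the only covariate: fixed-exponent allometric scaling with
0.75 on all clearances and 1.0 on all volumes about a 70 kg reference — the
standard theory-based choice when an "allometric scaling approach" is wanted
without estimating exponents.  The exponents and reference weight are
configurable, and estimating them is a possible extension (they are ordinary
fixed effects), but the default pipeline fixes them.

Random effects are log-normal on CL and F with a diagonal covariance — the
two parameters whose variability the analysis quantifies.  IIV on F is *not*
truncated at 1: a log-normal with a typical value ≤ 1 can exceed 1 in the
upper tail.  This keeps a single CV% parameterisation clean; a logit-normal
alternative would bound F at 1 at the cost of a less interpretable
variability scale.  IIV magnitudes are reported as the log-normal CV,
`100·sqrt(exp(ω²) − 1)`; at the magnitudes involved here (≤ ~35%) this
differs from the naive `100·ω` by well under a percentage point, so either
convention round-trips within the reporting precision.

Residual error is combined proportional + additive, shared across routes and
studies — the safest default for data pooling rich early-phase profiles with
sparse patient samples, where a proportional-only model degenerates near
troughs and an additive-only model misweights peaks.

## Estimation

The marginal likelihood of each subject integrates the conditional data
likelihood over the random effects.  The package maximises the Laplace
approximation: each subject's joint −2 log density `h(η)` is minimised by a
damped Newton iteration (finite-difference derivatives, gradient tolerance
1e−6), and

```
−2 log L_i ≈ h(η̂) − d·log 2π + log det(∇²h(η̂)/2).
```

The curvature of the data term is kept exact, so for the proportional error
model this behaves like FOCE with interaction; for a model linear in η the
approximation is exact, which is how the engine is verified (a log-scale
linear mixed model against the closed-form marginal normal −2LL).  Subjects
without oral doses carry no information on η_F; that dimension integrates
out exactly and is dropped from their inner problem (EBE reported as 0).
Random effects with ω² = 0 are dropped globally, collapsing the objective to
a fixed-effects weighted least-squares criterion (also tested against an
independent oracle).

The outer search runs Nelder–Mead on transformed coordinates — log for
typical values and residual SDs, log-SD for variances — so positivity holds
by construction; convergence uses an absolute objective tolerance of 0.05
(−2LL units) and 1e−3 on the transformed parameters.  Inner modes are
warm-started across outer evaluations.  Parameter regions where predictions
blow up return a large finite penalty with a diagnostic flag rather than
raising.  A seeded multi-start option perturbs the initial vector for
robustness; the default is a single start.  Standard errors (optional, off by
default) come from a finite-difference Hessian of the objective with the
delta method back to the natural scale.

Observations with MDV = 1 are excluded from the likelihood; no
below-quantification-limit handling is implemented.

Shrinkage: `η-shrinkage_k = 100·(1 − SD(η̂_k)/ω_k)` with the sample SD
(ddof = 1) over all subjects, and `ε-shrinkage = 100·(1 − SD(IWRES))` at the
empirical Bayes modes.  ω_k = 0 makes η-shrinkage undefined; it is reported
as missing with a warning.

## Diagnostics

The pcVPC corrects each observation by `pcDV = DV · PREDbin / PRED`, where
`PRED` is the population prediction (η = 0) and `PREDbin` the median `PRED`
in the observation's time bin — the proportional, natural-scale correction
appropriate for a model without a lower bound.  Non-positive predictions
(e.g. pre-first-dose samples) are excluded with a warning.  Binning is
quantile-based on time (default target 8 bins, minimum 10 observations,
under-filled bins merged with a log notice) or explicit edges.  Observed and
simulated replicates pass through the same binning/correction/quantile code,
and all quantiles are numpy's linear-interpolation (type-7) definition.
Reported statistics are the 5th/50th/95th percentiles with 90% simulation
bands from `n_sim ≥ 100` seeded replicates of the dataset's own design.  The
acceptance surface is the table of numbers; rendering is an optional
matplotlib helper.

CWRES uses the first-order linearisation about the EBE with the residual
variance at the individual prediction (interaction retained):
`cov = G Ω G' + diag(v(IPRED))`, `CWRES = chol(cov)^{-1}(DV − IPRED + G η̂)`.

## Synthetic program

The generator is the package's stand-in for the pooled clinical program; no
study-level design tables are public, so the default roster is an explicit
reconstruction constrained to the pooled totals of 138 subjects and 2637 PK
samples: three Phase 1 IV studies (single dose, 7-day multiple dose, long
infusion; 15/16/12 subjects with 17/32/15 samples each), two Phase 1 PO
studies (fed/fasted crossover, 25×30; 14-day q24h, 20×37), and two sparse
Phase 2 IV studies in patients (30 and 20 subjects, 4 samples each).  Body
weights are log-normal: median 75 kg for healthy volunteers, 55 kg for MAC
patients (both 15% CV) — magnitudes chosen to express the lower weight of
the patient population, not estimates.  The reference typical values
(CL 12 L/h, V1 30 L, Q2 8, V2 60, Q3 2, V3 120, ka_fed 0.6, ka_fasted 1.2,
ktr 1.5 1/h, F 0.85) are likewise synthetic, plausible for a renally cleared
oral/IV antibacterial at 500 mg q24h; the IIV variances correspond to CVs of
7.9% (CL) and 32.7% (F) and residual error is 10% proportional + 0.05 mg/L
additive.

Randomness is seeded per (seed, study index, subject index) with independent
`SeedSequence` streams, so editing one study leaves every other study's
subjects bit-identical.  The generator does not emulate dropout, BQL
censoring, or dose modifications; what passing tests show is that the
estimator and diagnostics behave correctly when the model family is true,
not that the model describes any particular real dataset.

## Recovery experiment

The headline check simulates five replicate trials of 100 rich-sampled
subjects (40 IV-infusion, 30 PO-fed, 30 PO-fasted; 12 samples over 36 h) and
refits θ_CL, θ_F, ω²_CL, ω²_F and σ_prop from deliberately offset starting
values (CL +30%, F −15%, both CVs at 20%, σ_prop at 0.15), holding the
remaining structural constants and σ_add at their design values — the
experiment targets the variability components and the parameters that
identify them, and 100 single-dose subjects carry little information on the
deep-compartment constants.  The reported quantities are the 5-seed medians
of the recovered CVs.  Problem sizes (100 subjects, 12 samples, 5 seeds)
were chosen as the smallest design that pins the clearance CV to well under
a percentage point of Monte-Carlo error.

## Known limitations

- Single residual-error model across studies; no between-occasion
  variability; no covariates beyond weight and food.
- Diagonal random-effect covariance restricted to CL and F.
- The Laplace objective matches NONMEM-class estimators at the level of the
  statistical model, not software numerics; no SAEM/importance sampling.
- Finite-difference inner derivatives cap the practical inner gradient
  tolerance around 1e−6.
- The default roster and typical values are reconstructions; only the pooled
  totals and the variability CVs are anchored quantities.
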