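# ebopk

Population pharmacokinetics of epetraborole (EBO), an oral/IV boron-containing
leucyl-tRNA-synthetase inhibitor in development for *Mycobacterium avium*
complex (MAC) lung disease.  The package re-implements, as a tested and
reusable pipeline, the kind of pooled Phase 1 / Phase 2 analysis used to
support dose selection for this compound:

- **Structural model** — three-compartment mammillary disposition with linear
  elimination; IV input as bolus or zero-order infusion; oral input through a
  chain of transit compartments (Erlang absorption delay) with separate
  first-order absorption rate constants for fed and fasted dosing and an
  absolute bioavailability term *F*.  Profiles are propagated exactly with the
  matrix exponential of the full linear system.
- **Population model** — allometric body-weight scaling (exponent 0.75 on
  clearances, 1.0 on volumes, 70 kg reference), log-normal interindividual
  variability (IIV) on CL and *F*, combined proportional + additive residual
  error.
- **Estimation** — nonlinear mixed-effects by maximising the Laplace
  approximation to the marginal likelihood (FOCE-with-interaction behaviour),
  with empirical Bayes estimates and eta/epsilon shrinkage reporting.
- **Diagnostics** — goodness-of-fit residual tables (PRED/IPRED/IWRES/CWRES)
  and prediction-corrected visual predictive checks (pcVPC).
- **Synthetic trials** — a fully seeded generator emulating a pooled program
  of 5 Phase 1 studies (3 IV, 2 PO, rich sampling, healthy volunteers) and
  2 Phase 2 studies (IV, sparse sampling, lower-body-weight patients),
  totalling 138 subjects and 2637 PK samples, plus steady-state exposure
  simulation for q24h regimens.

## Model

For individual *i* with body weight `WT_i`:

```
CL_i = θ_CL · (WT_i/70)^0.75 · exp(η_CL,i)     η_CL ~ N(0, ω²_CL)
Q2_i, Q3_i ∝ (WT_i/70)^0.75                    V1_i, V2_i, V3_i ∝ (WT_i/70)^1.0
F_i  = θ_F · exp(η_F,i)                        η_F  ~ N(0, ω²_F)
```

Oral doses deposit `F_i · Dose` into a chain of `n` transit compartments
(rate `ktr`) feeding a depot that empties into the central compartment at
`ka_fed` or `ka_fasted` per dose.  Observations follow

```
DV = C(t) · (1 + σ_prop · ε1) + σ_add · ε2 ,    ε ~ N(0, 1)
```

IIV is reported as a log-normal CV: `CV% = 100·sqrt(exp(ω²) − 1)`.

## Worked example

```python
import ebopk as e

truth = e.default_model()                      # reference population model
data  = e.generate(e.default_program(), truth, seed=7)
print(data.n_subjects, data.n_observations)    # 138 2637

# steady-state exposures of 500 mg PO (fed) q24h at the 70 kg reference
exp = e.simulate_regimen_exposures(truth, e.DoseEvent(0, 500, "PO", 0, True),
                                   n_subjects=1000, seed=7)
print(round(exp["AUC_tau"].median(), 1))       # 34.3  (mg·h/L; θ_F·Dose/θ_CL = 35.4)

# refit the variability components from a rich-sampling recovery trial
from ebopk.experiments import run_iiv_recovery
res = run_iiv_recovery(seed=1, n_replicates=1)
print(round(res["cv_cl_percent"], 1), round(res["cv_f_percent"], 1))
```

The last line prints the recovered CV% of clearance and bioavailability
(`8.1 28.9` for this seed; the generating values are 7.9 and 32.7):
the fit separates between-subject variability from residual noise and from
the allometric weight effect, which is the core competency the package is
built to demonstrate.

The same pipeline is scriptable from the shell (`ebopk generate`, `ebopk
fit`, `ebopk vpc`, `ebopk exposures`); every subcommand takes `--seed` and
writes a run log alongside its output.

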