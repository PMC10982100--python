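# Methods

`neuralpk` fits low-dimensional neural ordinary differential equations
(neural ODEs) to single-dose concentration–time data. This note records the
models, the synthetic-data conditions, the training procedure, the
evaluation conventions, and the design choices that were genuinely open.

## Model structures

A neural ODE replaces the right-hand side of a compartmental ODE with small
trainable networks. Every component network has one hidden layer of ReLU
units and an identity output, `f(x) = W2·relu(W1_eff·x + b1) + b2`; with a
scalar input this is a continuous piecewise-linear function with at most
`n_hid` kinks. Time-input networks carry the input-weight restriction
`w_eff = −(w²)` (the raw weight remains the trainable quantity), which
forces every hidden ReLU argument to decrease in `t`: beyond a finite onset
`max_i b1_i/(−w_eff,i)` the network output equals `b2` exactly, so explicit
time dependence vanishes and solutions cannot grow without bound. That
restriction encodes the PK fact that after distribution/absorption
transients the dynamics are autonomous.

Six structures are provided (`x_C` is the measured central state, `x_A` an
absorption state, `d` dose, `V` volume of distribution):

| structure  | equations | estimates V | route |
|---|---|---|---|
| basic      | `x_C' = f^C(x_C, t)` | yes | IV bolus |
| separated  | `x_C' = f^C1(x_C) + (d/V)·f^C2(t)` | yes | IV bolus |
| absorption | `x_A' = d·f^A1(t) − f^A2(x_A)`; `x_C' = f^A2(x_A) − f^C1(x_C) − d·f^C2(t)` | no | oral |
| infusion   | `x_C' = (kin/V)·1(t≤tinf) + f^C1(x_C) + (d/V)·f^C2(t)` | yes | IV infusion |
| mech_elim  | absorption pair with known `−kel·x_C` elimination | no | oral |
| mech_abs   | `x_A' = −ka·x_A` (known ka); `x_C' = ka·x_A − f^C1(x_C) − (d/V)·f^C2(t)` | yes | oral |

Signs and initial conditions are implemented exactly as the structures are
written (the absorption structure scales its time term by raw dose `d`
without `V`, since `f^A2` can absorb scaling). `V` is stored and optimized
as `log V` to enforce positivity. The separated structure is the default
recommendation; the basic two-input form exists for completeness.

`n_hid = 20` per component network is the default width; it exceeds what
these PK scenarios need and is deliberately not tuned.

## Synthetic data: the study conditions

The generator simulates mass-action compartment models with
`scipy.integrate` at tight tolerances (rtol 1e−8, atol 1e−10) and applies
multiplicative proportional error `c·(1 + cv·ε)`, `ε ~ N(0,1)`, clipped at
zero, with `cv = 0.10` by default (the residual-error magnitude is a
package choice: it produces scatter consistent with typical PK assay error
and a visible overfitting contrast). All units are arbitrary but
consistent.

Scenario registry (dose groups × sampling times, all geometric spacing):

| scenario | generating model | parameters | groups | times | unseen regimen |
|---|---|---|---|---|---|
| overfit_onecomp | 1-cmt IV | kel 0.1, V 2 | d=1, 1 replicate | 5 on [1,50] | — |
| interp_onecomp | 1-cmt IV | kel 0.1, V 2 | d=1, 50 | 5 on [1,50] | d=5,10,20,35 |
| twocomp_iv | 2-cmt IV | +k12=k21=0.2 | d=1, 10 | 5 on [1,50] | d=5 |
| po_plain | 1-cmt PO | +ka=0.2 | d=5, 15 | 7 on [1,50] | d=10 |
| po_transit4 | PO, 4 transits | +ktr=0.1 | d=5, 15 | 10 on [10,100] | d=10 |
| po_transit8 | PO, 8 transits | +ktr=0.1 | d=5, 15 | 10 on [10,150] | d=10 |
| infusion | 1-cmt infusion | kel 0.1, V 2 | kin=1, 10 (tinf 6) | 7 on [1,50] | kin=7/tinf=4, kin=5/tinf=8 |
| tmdd_iv | TMDD IV | kel .1, kon .25, koff .01, ksyn .5, kdeg .25, kint .1 | d=50, 200 | 7 on [1,60] | d=100 (WMSE, log eval) |
| tmdd_po | TMDD oral | +kabs 0.15 | d=50, 200 | 10 on [1,60] | d=100 (WMSE, log eval) |

Pooled scenarios carry 8 replicates per time point; the overfitting
demonstration uses a single replicate. Two conditions differ from a naive
reading of "horizon 50, sample from t=1 everywhere":

* **Transit horizons.** With `ntr = 8`, `ktr = 0.1`, `ka = 0.2` the mean
  absorption delay is ≈ 85 time units — the curve peaks near t ≈ 90. A
  t ≤ 50 horizon would end before the peak, so the transit scenarios run
  to 100 (4 transits) and 150 (8 transits).
* **Transit sampling start.** Geometric sampling from t = 1 would place six
  of ten samples inside the absorption lag where the concentration is
  essentially zero; samples there measure nothing and leave the entire
  rise/peak/decline constrained by four points. Transit-scenario sampling
  therefore starts at t = 10, the end of the lag — a standard
  design-of-experiments consideration for delayed-absorption profiles.

The TMDD receptor starts at its turnover baseline `ksyn/kdeg = 2`; an IV
bolus enters as ligand concentration `d/V` with `V = 2`.

What the generator does **not** emulate: inter-individual variability,
covariates, multiple dosing, assay limits of quantification, irregular or
subject-specific sampling. Passing tests therefore demonstrate behavior on
idealized mean-profile data, not robustness to population heterogeneity or
real assay artifacts.

## Training

Training is pooled full-batch gradient descent: each epoch solves the
model once per dose group from the group's initial condition, pools the
squared residuals of every replicate, and takes one Adam step on all
network parameters (raw weights under the restriction) and `log V` where
present. Losses are the mean squared error and the observation-weighted
WMSE `(1/N)Σ (pred−obs)²/obs` (used when observations span decades, e.g.
TMDD); with unequal replicate counts the divisor is the total observation
count, which reduces to `m·n` for rectangular designs. Fitting stays on
the natural concentration scale and predictions are never clamped —
negative extrapolations are informative failures, not artifacts to hide.

Gradients are exact derivatives of the discrete solution: the solver is
classic RK4 on a fixed grid that contains every measurement time (and the
infusion cutoff as a grid knot), with forward sensitivities propagated
through the same stages — the sensitivity RK4 is algebraically the
derivative of the state RK4, so gradient checks against finite differences
pass at machine-level tolerance. The default training grid bounds steps at
`h_max = 2` time units (1 for TMDD, whose transition is steeper); final
evaluation re-solves with an adaptive solver at rtol 1e−6/atol 1e−8 and
the two agree to ~1e−3 on trained models. A numba kernel implements the
same solve for speed; the numpy path is the reference and the two are
tested equal to ~1e−13.

The learning rate follows a triangular cycle per 200 epochs starting at
1e−3. The cycle floor is 1e−6: with a higher floor (1e−4) Adam enters a
limit cycle around the sharp loss valley and the loss plateaus about two
orders of magnitude above what the same run reaches when each cycle trough
lets the iterate settle. Best-loss tracking (`track_best`) returns the
parameters at the lowest recorded loss. A diverged solve triggers a
learning-rate halving and restart from the best iterate, at most three
times. Runs are bit-reproducible given the seed. No train/validation split
and no hyperparameter tuning is performed.

### Initialization

Hidden layers use the standard uniform fan-in scheme. Two amendments, both
recorded with their reasons:

* **Near-identity output.** Output layers are scaled by 0.1 at
  initialization. An unscaled random concentration net easily places
  positive feedback on the state; with initial conditions up to
  `d/V = 100` the trajectory explodes exponentially before training has
  signal, and Adam then crawls. Starting near the identity flow removes
  this failure mode.
* **Classical initial estimates.** Where a classical PK analysis would
  compute initial estimates, the package does the same, from the data
  only: `V₀ = d_max/c_first` for bolus/oral structures that estimate V
  (for infusion: kel from the terminal log-linear slope, then V from the
  end-of-infusion concentration); for absorption-type structures, the
  elimination ramp `kel·x`, a fast linear transfer for `f^A2`, and a
  deconvolution estimate of the absorption flux
  `(dC/dt + kel·C)/d` projected onto the restricted-ReLU hinge basis for
  `f^A1`. The delayed-absorption scenarios motivated the last of these:
  random time nets start with all their kinks near t = 0, and gradient
  descent settles into dose-inconsistent basins long before it can move
  kinks out to a peak at t ≈ 90 — basins it provably does not leave even
  after 150k epochs. Initialization only; every parameter remains free.

### Restarts and selection

`train_multistart` trains several seeded initializations (deterministic
offsets of the master seed) and returns the best. Training loss alone is a
poor selector: restarts with indistinguishable pooled losses can differ by
an order of magnitude in unseen-dose error, because with two dose groups a
flexible model can fit both while being wildly dose-inconsistent in
between. Selection therefore prefers the lowest-loss restart **among those
passing a dose-monotonicity screen**: the model's own prediction at the
geometric mid-dose must lie between its own predictions at the two
training doses (within 5% of the curve scale) — true of every system
modeled here, checked without any oracle or held-out data. If no restart
passes, the lowest-loss restart is returned.

## Evaluation

* **Derivative-vs-state profiles** plot `dx_C/dt` against `x_C` along a
  trajectory; for a one-compartment system this is the line `−kel·x_C`.
  Profiles of trained models are sampled on a dense grid and compared with
  the mechanistic profile by interpolating both onto a common
  concentration grid (mean and max absolute discrepancy).
* **Unseen-regimen reports** simulate the trained model and the generating
  mechanistic model for a held-out regimen and report relative RMSE (RMSE
  divided by the oracle's mean). "Agrees well" is operationalized as
  relative RMSE ≤ 0.15 — a package-declared tolerance, configurable and
  logged.
* **Evaluation grid.** Curves are compared on a geometric time grid at 4×
  the scenario's sampling density, starting at the first sampling time.
  Sparse designs constrain the trajectory only at that resolution: a
  trained model can wander between measurements while predicting every
  observed time point well, so a uniform dense grid would grade behavior
  the design never constrained (most visibly inside the steep TMDD
  transition between two adjacent samples).
* **TMDD log-space comparison.** TMDD concentrations span 10² to 10⁻³, so
  curves are compared as `log10(c/10⁻³)` (decades above the smallest
  observed magnitude, which also floors negative predictions), and the
  relative RMSE divides by the oracle's mean decades-above-floor. The
  window starts at the first sampling time, excluding the initial
  rapid-binding transient that the sampling cannot resolve.

## Scaled-down problem sizes

Desk-scale runs used throughout the tests and the reproduction script:
20k–60k epochs for one-compartment/PO/infusion scenarios, 100k for TMDD,
2–6 restarts, training grid steps of 1–2 time units. These budgets were
chosen so each scenario trains in seconds-to-minutes on one CPU core while
reaching its noise floor; the defaults in `TrainingConfig` are deliberately
modest and callers scale up freely.

## Numerical details and degenerate inputs

* Integration restarts at declared breakpoints (the infusion cutoff), and
  each span evaluates the right-hand side strictly on its own side of the
  discontinuity, so no stage straddles the jump.
* `constancy_onset` returns `inf` when a restricted unit has a positive
  bias and an exactly zero effective weight (the unit never switches off).
* A width-0 network degenerates to its output bias and is supported
  end-to-end (it was used to test whether the absorption structure needs
  its dose-scaled time term at all; fits generalized worse without it, so
  the full structure is kept).
* `wmse` rejects nonpositive observations (undefined weights); noise is
  clipped at zero in generation, and zero-valued observations only occur
  in lag phases that the transit designs avoid sampling.
* CSV round-trips use full-precision decimal (`round_trip` float parsing);
  checkpoints are plain JSON and restore bit-identical parameters.

## Known limitations

* Single-dose regimens only; no inter-individual variability, covariates,
  or uncertainty quantification.
* Extrapolation beyond the trained dose range is expected to fail (and a
  test asserts that it does); the package reports, not fixes, this.
* The dose-monotonicity screen assumes concentration is monotone in dose,
  which holds for the systems here but not for every conceivable PK model
  (e.g. capacity-limited absorption with competing elimination).
* Training is full-batch on CPU; the engine targets these small pooled
  datasets, not large populations.
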